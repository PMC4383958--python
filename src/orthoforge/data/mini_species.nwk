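((CAEEL:50,HUMAN:50)Metazoa:30,(ARATH:40,ORYSA:40)Viridiplantae:40)Root;
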