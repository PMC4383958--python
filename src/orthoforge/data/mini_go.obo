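format-version: 1.2
ontology: go/mini

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0032502
name: developmental process
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0009791
name: post-embryonic development
namespace: biological_process
is_a: GO:0032502 ! developmental process

[Term]
id: GO:0002164
name: larval development
namespace: biological_process
is_a: GO:0009791 ! post-embryonic development

[Term]
id: GO:0002119
name: nematode larval development
namespace: biological_process
alt_id: GO:0099911
is_a: GO:0002164 ! larval development

[Term]
id: GO:0009553
name: embryo sac development
namespace: biological_process
is_a: GO:0032502 ! developmental process

[Term]
id: GO:0006396
name: RNA processing
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0016072
name: rRNA metabolic process
namespace: biological_process
is_a: GO:0006396 ! RNA processing

[Term]
id: GO:0000967
name: rRNA 5'-end processing
namespace: biological_process
is_a: GO:0016072 ! rRNA metabolic process

[Term]
id: GO:0099999
name: withdrawn process
namespace: biological_process
is_obsolete: true
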