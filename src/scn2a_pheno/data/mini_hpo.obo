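format-version: 1.2
ontology: mini-hpo
remark: Hand-written 30-term neurology-flavored mini ontology for tests and examples. Term ids reuse familiar HPO accessions for readability; the DAG shape (including the two-parent Autism diamond) is a fixture, not the real HPO.

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000118
name: Phenotypic abnormality
is_a: HP:0000001 ! All

[Term]
id: HP:0000707
name: Abnormality of the nervous system
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0012638
name: Abnormal nervous system physiology
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0012639
name: Abnormal nervous system morphology
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0012443
name: Abnormality of brain morphology
is_a: HP:0012639 ! Abnormal nervous system morphology

[Term]
id: HP:0002126
name: Polymicrogyria
is_a: HP:0012443 ! Abnormality of brain morphology

[Term]
id: HP:0000238
name: Hydrocephalus
is_a: HP:0012443 ! Abnormality of brain morphology

[Term]
id: HP:0000252
name: Microcephaly
is_a: HP:0012639 ! Abnormal nervous system morphology

[Term]
id: HP:0001250
name: Seizure
alt_id: HP:0002279
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0002197
name: Generalized-onset seizure
is_a: HP:0001250 ! Seizure

[Term]
id: HP:0007359
name: Focal-onset seizure
is_a: HP:0001250 ! Seizure

[Term]
id: HP:0011097
name: Epileptic spasm
is_a: HP:0001250 ! Seizure

[Term]
id: HP:0012469
name: Infantile spasms
is_a: HP:0011097 ! Epileptic spasm

[Term]
id: HP:0002133
name: Status epilepticus
is_a: HP:0001250 ! Seizure

[Term]
id: HP:0002353
name: EEG abnormality
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0002521
name: Hypsarrhythmia
is_a: HP:0002353 ! EEG abnormality

[Term]
id: HP:0010851
name: EEG with burst suppression
is_a: HP:0002353 ! EEG abnormality

[Term]
id: HP:0012759
name: Neurodevelopmental abnormality
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0012758
name: Neurodevelopmental delay
is_a: HP:0012759 ! Neurodevelopmental abnormality

[Term]
id: HP:0001263
name: Global developmental delay
is_a: HP:0012758 ! Neurodevelopmental delay

[Term]
id: HP:0001249
name: Intellectual disability
is_a: HP:0012759 ! Neurodevelopmental abnormality

[Term]
id: HP:0002342
name: Intellectual disability, moderate
is_a: HP:0001249 ! Intellectual disability

[Term]
id: HP:0000708
name: Behavioral abnormality
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0000729
name: Autistic behavior
is_a: HP:0000708 ! Behavioral abnormality

[Term]
id: HP:0000717
name: Autism
is_a: HP:0000729 ! Autistic behavior
is_a: HP:0012759 ! Neurodevelopmental abnormality

[Term]
id: HP:0000733
name: Stereotypy
is_a: HP:0000708 ! Behavioral abnormality

[Term]
id: HP:0100022
name: Abnormality of movement
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0002072
name: Chorea
is_a: HP:0100022 ! Abnormality of movement

[Term]
id: HP:0001337
name: Tremor
is_a: HP:0100022 ! Abnormality of movement
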