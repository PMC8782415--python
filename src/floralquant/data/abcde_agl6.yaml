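# Default ABCDE + AGL6 floral organ identity model.
#
# Four whorls, outermost (whorl 1, sepals) to innermost (whorl 4, carpels);
# importance weights 1..4 outside-in (reproductive organs weighted highest).
# Organ identity requires the joint presence of the listed gene classes;
# AGL6 is modeled as a competence class required everywhere but excluded
# from the base model (in_base_model: false), so it receives a residual
# contribution value rather than entering the mutant-loss normalization.
#
# reference_gradients carries the published gradient vector, which is not
# reproducible from the importance x contribution product (the computed
# vector is 0.577, 1.616, 2.424, 2.308); both are available downstream and
# provenance is always recorded.

organs:
  - name: sepals
    whorl_index: 1
    importance: 1
    required_classes: [A, E, AGL6]
  - name: petals
    whorl_index: 2
    importance: 2
    required_classes: [A, B, E, AGL6]
  - name: stamens
    whorl_index: 3
    importance: 3
    required_classes: [B, CD, E, AGL6]
  - name: carpels
    whorl_index: 4
    importance: 4
    required_classes: [CD, E, AGL6]

gene_classes:
  - name: A
    builds_organs: [sepals, petals]
  - name: B
    builds_organs: [petals, stamens]
  - name: CD
    builds_organs: [stamens, carpels]
  - name: E
    builds_organs: [sepals, petals, stamens, carpels]
  - name: AGL6
    builds_organs: [sepals, petals, stamens, carpels]
    in_base_model: false

reproductive_organs: [stamens, carpels]
early_reproductive_classes: [B, CD]

reference_gradients:
  sepals: 0.572
  petals: 1.606
  stamens: 2.409
  carpels: 2.288
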