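# synthetic fixture, seed=0; regenerate with `floralquant synth --fixtures <dir>`
early_reproductive_classes: []
gene_classes:
- builds_organs:
  - organ2
  - organ4
  in_base_model: true
  name: g1
- builds_organs:
  - organ3
  - organ4
  in_base_model: true
  name: g2
- builds_organs:
  - organ1
  - organ2
  in_base_model: true
  name: g3
- builds_organs:
  - organ1
  - organ2
  - organ3
  - organ4
  in_base_model: true
  name: E*
- builds_organs:
  - organ1
  - organ2
  - organ3
  - organ4
  in_base_model: false
  name: C*
ground_truth:
  base_organ_weights:
    organ1: 0.2
    organ2: 0.3
    organ3: 0.2
    organ4: 0.3
  contributions:
    E*: 0.384615384615
    g1: 0.230769230769
    g2: 0.192307692308
    g3: 0.192307692308
  mutant_loss:
    E*: 1.0
    g1: 0.6
    g2: 0.5
    g3: 0.5
organs:
- importance: 1.0
  name: organ1
  required_classes:
  - C*
  - E*
  - g3
  whorl_index: 1
- importance: 2.0
  name: organ2
  required_classes:
  - C*
  - E*
  - g1
  - g3
  whorl_index: 2
- importance: 3.0
  name: organ3
  required_classes:
  - C*
  - E*
  - g2
  whorl_index: 3
- importance: 4.0
  name: organ4
  required_classes:
  - C*
  - E*
  - g1
  - g2
  whorl_index: 4
reproductive_organs: []
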