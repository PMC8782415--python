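{
  "description": "Published reference values for the default ABCDE+AGL6 model: the contribution/gradient tables and the AHP worked-example step tables, exactly as printed in the source study, plus the registry of known printed discrepancies. Used only for comparison (diff report) and as declared reference inputs; never as a substitute for computation.",
  "base_organ_weights": {"sepals": 0.2, "petals": 0.3, "stamens": 0.3, "carpels": 0.2},
  "mutant_loss": {"A": 0.5, "B": 0.6, "CD": 0.5, "E": 1.0},
  "contributions": {"A": 0.192, "B": 0.231, "CD": 0.192, "E": 0.385},
  "agl6_contribution": 0.077,
  "gradients": {"sepals": 0.572, "petals": 1.606, "stamens": 2.409, "carpels": 2.288},
  "combination_members": {
    "A": ["A"], "B": ["B"], "CD": ["CD"], "E": ["E"], "AGL6": ["AGL6"],
    "ABE": ["A", "B", "E"], "BCE": ["B", "CD", "E"],
    "AB": ["A", "B"], "BC": ["B", "CD"],
    "ABE6": ["A", "B", "E", "AGL6"], "BCE6": ["B", "CD", "E", "AGL6"],
    "ALL": ["A", "B", "CD", "E", "AGL6"], "ABCE": ["A", "B", "CD", "E"]
  },
  "combination_table": {
    "A":    {"sepals": 0.192, "petals": 0.192, "stamens": 0.0,   "carpels": 0.0},
    "B":    {"sepals": 0.0,   "petals": 0.231, "stamens": 0.231, "carpels": 0.0},
    "CD":   {"sepals": 0.0,   "petals": 0.0,   "stamens": 0.192, "carpels": 0.192},
    "E":    {"sepals": 0.385, "petals": 0.385, "stamens": 0.385, "carpels": 0.385},
    "AGL6": {"sepals": 0.077, "petals": 0.077, "stamens": 0.077, "carpels": 0.077},
    "ABE":  {"sepals": 0.577, "petals": 0.808, "stamens": 0.616, "carpels": 0.385},
    "BCE":  {"sepals": 0.385, "petals": 0.616, "stamens": 0.808, "carpels": 0.577},
    "AB":   {"sepals": 0.192, "petals": 0.421, "stamens": 0.0,   "carpels": 0.0},
    "BC":   {"sepals": 0.0,   "petals": 0.231, "stamens": 0.423, "carpels": 0.0},
    "ABE6": {"sepals": 0.654, "petals": 0.885, "stamens": 0.693, "carpels": 0.462},
    "BCE6": {"sepals": 0.462, "petals": 0.693, "stamens": 0.885, "carpels": 0.654},
    "ALL":  {"sepals": 0.654, "petals": 0.885, "stamens": 0.885, "carpels": 0.654},
    "ABCE": {"sepals": 0.577, "petals": 0.808, "stamens": 0.808, "carpels": 0.577}
  },
  "pairwise_matrix": {
    "labels": ["sepals", "petals", "stamens", "carpels"],
    "values": [
      [1.0,    0.9584, 1.1738, 1.1440],
      [1.0434, 1.0,    1.9669, 1.9169],
      [0.8519, 0.5084, 1.0,    2.3477],
      [0.8741, 0.5216, 0.4259, 1.0]
    ]
  },
  "column_sums": {"sepals": 3.7694, "petals": 2.9884, "stamens": 4.5666, "carpels": 6.4086},
  "normalized_matrix": [
    [0.2652, 0.3207, 0.2570, 0.1785],
    [0.2768, 0.3346, 0.4307, 0.2991],
    [0.2260, 0.1701, 0.2190, 0.3663],
    [0.2319, 0.1745, 0.0933, 0.1560]
  ],
  "priority": {"sepals": 0.2554, "petals": 0.3353, "stamens": 0.2554, "carpels": 0.1639},
  "weighted_sum": {"sepals": 1.0641, "petals": 1.4183, "stamens": 1.0283, "carpels": 0.6708},
  "ratios": {"sepals": 4.1664, "petals": 4.2299, "stamens": 4.0262, "carpels": 4.0927},
  "lambda_max": 4.1288,
  "ci": 0.0429,
  "admissible_orders": ["B -> CD -> AGL6 -> E -> A", "B -> CD -> AGL6/E -> A"],
  "known_discrepancies": [
    {"table": "combination_table", "row": "AB", "col": "petals", "kind": "known-typo",
     "note": "printed 0.421; the row-sum convention gives 0.192+0.231 = 0.423"},
    {"table": "combination_table", "row": "AB", "col": "stamens", "kind": "known-typo",
     "note": "printed 0; the row-sum convention gives B's 0.231"},
    {"table": "combination_table", "row": "BC", "col": "carpels", "kind": "known-typo",
     "note": "printed 0; the row-sum convention gives CD's 0.192"},
    {"table": "gradients", "row": "sepals", "col": "value", "kind": "method-discrepancy",
     "note": "printed 0.572; importance x contribution product gives 1 x 0.577 = 0.577"},
    {"table": "gradients", "row": "petals", "col": "value", "kind": "method-discrepancy",
     "note": "printed 1.606; product gives 2 x 0.808 = 1.616"},
    {"table": "gradients", "row": "stamens", "col": "value", "kind": "method-discrepancy",
     "note": "printed 2.409; product gives 3 x 0.808 = 2.424"},
    {"table": "gradients", "row": "carpels", "col": "value", "kind": "method-discrepancy",
     "note": "printed 2.288; product gives 4 x 0.577 = 2.308"},
    {"table": "normalized_matrix", "row": "sepals", "col": "sepals", "kind": "known-typo",
     "note": "printed 0.2652 truncates 1/3.7694 = 0.26529 where the table's other discriminating cells round half-up (0.2653)"},
    {"table": "priority", "row": "stamens", "col": "value", "kind": "known-typo",
     "note": "printed 0.2554 reuses 0.2660 where the normalized matrix prints 0.2260; recomputation gives 0.2454"}
  ]
}
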