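# Methods

## The gene–organ model

A `FloralModel` is a bipartite membership structure: organs (ordered by
whorl, outermost first) each require a set of gene classes; gene classes
list the organs they build; the two views must agree. Classes are split
into *base* classes (A, B, CD, E — they enter weight counting and
contribution normalization) and *non-base* competence classes (AGL6 —
required for development everywhere but not an identity builder). The
default model treats C and D jointly as one CD class and ships as
`data/abcde_agl6.yaml`; any other model can be supplied as YAML with the
same keys. Intra-class paralogs (AP3/PI, SEP1–4) are out of scope: the
unit of analysis is the class.

### Contribution scoring

With unit contributions (default 1 per base class per organ), organ
weights are w(o) = units(o)/Σ units — 0.2/0.3/0.3/0.2 for
sepals/petals/stamens/carpels. A class's mutant-loss value is
1 − Σ w(o) over the organs its mutant still forms. Mutant phenotypes
default to the set-complement rule (an organ forms iff it does not
require the class), with an explicit per-class override table because
observed phenotypes are data, not a theorem; for the default model the
rule and the reported phenotypes coincide. Losses normalized over base
classes give the contributions (A 0.192, B 0.231, CD 0.192, E 0.385 at
3 dp); degenerate models (all losses zero) are an error.

The competence residual assumes the reproductive organs' weight share
(w(stamens)+w(carpels) = 0.5) is fully accounted for by the early
reproductive classes plus the competence class, so
AGL6 = 0.5 − B − CD = 0.077. The early class list (default B, CD) is a
model parameter; an empty list returns the bare share, and a negative
residual is returned with a warning rather than clipped.

### Rounding

Contribution values round half-up at 3 decimals by default: that
reproduces the published 0.231 from 0.23077 (truncation would print
0.230). All rounding goes through `decimal` on the shortest string
representation of the value, because binary floats cannot truncate
decimals reliably (e.g. √(0.572·2.288) must truncate to 1.1440, not
1.1439). Policies are recorded on every result object.

### Gradient values

G(o) = importance(o) × Σ contributions of o's base builders, importance
1..4 outside-in (reproductive organs weighted highest, petals twice
sepals on regeneration-capacity grounds). With the 3-dp contributions
the products are 0.577, 1.616, 2.424, 2.308. The published vector
(0.572, 1.606, 2.409, 2.288) is *not* reproducible from that formula;
it ships as a reference fixture on the model config, is used as the
input to the AHP worked example (matching the published chain), and is
flagged as a method discrepancy in the diff report. Both vectors carry a
`provenance` field; nothing is silently corrected.

## The AHP chain

Judgments are built from scores as a_ij = √(s_i·s_j) for i<j, reciprocal
fill, unit diagonal. The geometric-mean construction is what the
published worked matrix actually contains (every printed entry matches
√(g_i·g_j); the plain product never does); `ratio` (s_i/s_j, perfectly
consistent) and `product` constructions are available for comparison.
Note the geometric-mean matrix is generally *not* consistent — that is
the point of the CI check.

Priorities are column-normalized row means (the worked example's
method), λ_max is the mean of component ratios (A·V)_i/V_i, CI =
(λ_max − n)/(n − 1), CR = CI/RI. A principal-eigenvector λ_max
(`lambda_max_eigen`) is provided as a cross-check; for any positive
reciprocal matrix the mean-ratio estimate is ≥ n (each off-diagonal pair
contributes t + 1/t ≥ 2), so CI ≥ 0 under either method.

Two rounding profiles are first-class:

* `EXACT_PROFILE` (default): no intermediate rounding; use this for any
  new analysis. On the published gradients it gives λ = 4.1270,
  CI = 0.0423.
* `REPLICATION_PROFILE`: pairwise entries and reciprocals truncated at
  4 dp; normalization, priorities, A·V product terms (rounded per term
  before summing — the convention the published A×V table follows),
  ratios, λ and CI rounded half-up at 4 dp. This reproduces the
  published step tables digit for digit: λ = 4.1288, CI = 0.0429.

The published priority vector contains one transcription slip (its
stamens entry reuses 0.2660 where the normalized matrix prints 0.2260;
recomputation gives 0.2454), so the replication pipeline feeds the λ/CI
stage the priority vector *as published*, recording both vectors. The
diff report classifies this and every other non-matching printed cell
(one truncated cell in the normalized matrix; three subset-table cells)
as `known-typo`, and the gradient vector as `method-discrepancy`; any
other mismatch would surface as `unexplained`.

### Random index

RI is Saaty's mean CI of random reciprocal matrices. Both the tabulated
constants (0.58, 0.90, 1.12, … for n = 3, 4, 5, …) and a seeded
Monte-Carlo estimator are provided; the ensemble is the standard one —
upper-triangle entries i.i.d. uniform on the 17-point scale
{1/9, …, 1/2, 1, 2, …, 9}, reciprocal fill. Inside the estimator CI uses
the principal eigenvalue, the convention behind the tabulated constants;
with the mean-ratio λ the same ensemble averages ≈ 0.92 at n = 4 and no
longer matches the table. At n = 4 the estimator gives ≈ 0.88–0.90
(modern large-replicate estimates sit slightly below Saaty's 0.90).
Acceptance is reported under both Saaty's CR ≤ 0.1 rule and the bare
CI ≤ 0.1 rule, since the replicated analysis applied the latter.

## Emergence orders

Scenarios are weak orders: ordered set partitions of the free classes
({AGL6, E, A} by default) appended to a fixed prefix (B then CD, the
phylogenetic reading; both are parameters). Enumeration is exhaustive
(ordered Bell numbers 1, 3, 13, 75, …; guarded at six free classes) and
is checked in the tests against an independent rank-map counting oracle.

The case analysis behind the published conclusion is formalized as two
pure rules: **E-before-A** (strict: with A present but E absent no
flower forms) and **competence-before-E** (non-strict: E without AGL6
gives defective development). Filtering is rule-order independent and
produces an audit trail naming the eliminating rule per rejected
scenario. With the default model exactly two of the 13 scenarios
survive. Stage timelines report the model-derived formable organ set per
stage via `formable_organs` (requirements ⊆ present, plus all
globally-required and competence classes present); note the model
derivation makes petals impossible without A, whereas one narrative
sub-case of the source analysis asserts otherwise — the timeline
reports the model's answer.

## Tree-derived order

`emergence_order` ranks classes by split depth: for each tip, the
deepest ancestor whose subtree still contains another class; per class,
the minimum over its tips (earliest divergence of any member, which also
handles non-monophyletic classes, with a warning). Depth is counted in
nodes by default because the order is read off topology; a
branch-length mode exists. Trees are interpreted as rooted exactly as
written (basal polytomies allowed); support values are ignored. The
packaged `example_topology.nwk` is a synthetic transcription of the
stated subfamily order — a ladder ending in an AGL6/E/A trifurcation,
two tips per class — not an inferred posterior tree.

## Chord-diagram export

Sectors are organs (whorl order), gene classes (model order) and any
configured combination rows; links carry each source's contribution into
each organ it builds, so organ sector totals equal incoming link weight
by construction and the files round-trip exactly. CSVs are UTF-8, LF,
fixed column order, 6-decimal fixed point — re-runs are byte-identical.
The bundled `render_circos.R` (circlize) is an optional secondary
renderer; the data contract, not the figure, is the tested artifact.

## Synthetic data

`generate_model` draws Bernoulli(density) memberships (default density
0.5, re-drawn until every organ has a base builder; 4 organs / 3 base
classes by default, matching the scale of the real model), optionally
adds an E-like global class and an AGL6-like competence class, and
computes base weights, losses and contributions in closed form *at
generation time, with its own arithmetic* — the ground truth is an
independent oracle, not a call into the pipeline. What the generator
does not emulate: correlated memberships, paralog redundancy within a
class, or partial (quantitative) organ requirement — so passing
recovery tests shows the arithmetic is right, not that the biological
model is. Consistent ratio matrices and random Saaty matrices complete
the fixtures; all generators are deterministic under a fixed seed.

## Problem sizes and numerics

Everything is desk-scale: 4×4 matrices, 13 scenarios, trees with ≤ a few
dozen tips. The full replication bundle runs in well under a second; the
Monte-Carlo RI at 10,000 replicates takes a few seconds. Degenerate
inputs are handled explicitly: zero-loss models and non-positive scores
are errors, n ≤ 2 random indices return 0 (2×2 reciprocal matrices are
always consistent), negative competence residuals warn, and ties in
ranks/depths are first-class rather than broken arbitrarily.

## Known limitations

* The contribution scheme inherits the source analysis's assumptions:
  equal units per class-organ membership, additivity across classes, and
  a residual definition for competence classes tied to the
  reproductive-organ share. None of these are validated biology; they
  are the model being replicated, made explicit and parameterized.
* The published gradient vector and a handful of printed table cells are
  not derivable from the stated formulas; they are carried as reference
  fixtures with explicit provenance and surfaced in the diff report
  rather than resolved.
* Emergence-order rules encode the narrative case analysis; alternative
  rule sets are easy to supply but no likelihood or dating framework is
  offered, and the tree reader extracts topological order only.
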