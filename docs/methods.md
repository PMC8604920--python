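# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `wpnet`, in the order the pipeline runs.

## Synthetic claims generator

The generator emulates the structure of private health-insurance claims:
one row per (patient, episode, ICD code), patient-level age and gender,
2–50 admission episodes per patient, one or more codes per episode, both
ICD-9 and ICD-10 codes in the same cohort. It does **not** emulate realistic
ICD marginal frequencies, longitudinal disease progression, calendar-time
admissions, or coding noise; passing tests therefore demonstrate that the
pipeline recovers *planted* shared-diagnosis structure, not that it would
attain any particular accuracy on real claims.

Cases and controls draw episode codes from three blocks via a per-episode
multinomial over blocks followed by a uniform draw within the block:

| parameter | default | why |
|---|---|---|
| n_cases / n_controls | 200 / 200 | balanced two-class design matching the balanced-control sampling used downstream |
| case-enriched block | 15 cardiovascular codes (heart failure, arrhythmia, pulmonary-circulation, peripheral-vascular) | contains the default target disease, so planted group membership and the pipeline's label almost always coincide |
| control-enriched block | 23 codes over ten non-cardiac comorbidity groups | spreads control–control overlap over many groups so the network is assortative rather than uniformly dense |
| shared background block | 12 codes over six common comorbidities (hypertension, obesity, depression, …) | gives the two groups realistic common ground and produces between-group edges |
| block probabilities | case (0.70, 0.05, 0.25); control (0.0, 0.70, 0.30) | strong but imperfect separation; a case may, with small probability, never draw a target code and legitimately ends up labelled as a control |
| episodes / codes per episode | 2–6 / 1–2 | keeps per-patient diagnosis sets small (≈ 2–4 groups) so edge weights are informative; real per-patient distributions are not publicly characterised, so these are deliberate, documented choices |
| ages | uniform over 40–90 years | chronic-disease-relevant range; no age–label effect is planted |
| smoking prevalence | 0.45 cases / 0.15 controls | smoking is a major behavioural risk factor for cardiovascular and pulmonary disease; this difference is the only node-feature signal and is what graph aggregation amplifies |
| smoking encoding | one smoking ICD code ("F17" or "3051") appended to a random episode of each smoker | lets the smoking feature be *derived* from codes downstream instead of leaking a column |

The ICD version of a generated code is inferred from its shape (leading
letter → ICD-10), so ICD-9 V- and E-codes cannot be used in the default
pool; this is a known limitation of the generator, not of the matcher.

Ground-truth labels live in a separate table from the claims so no pipeline
stage can read them. Generation is a pure function of (spec, seed).
`inject_filter_violations` appends flagged patients with exactly one or more
than fifty episodes for testing the admission filters.

## ICD matching and cohort construction

Code patterns are literals (`427.31`), wildcard prefixes (`428.x`, which
matches `428` and any `428.*`), or inclusive ranges (`426.2–426.53`,
`J40.x–J47.x`). Range semantics: both endpoints must share their alphabetic
prefix; the remainder is compared as (integer category, decimal fraction),
and a `.x` endpoint spans its whole category. A range whose endpoints have
different alphabetic prefixes or are reversed parses but matches nothing —
this keeps verbatim published code tables (which contain misprints such as
`I05.x–108.x`) loadable; the packaged default grouping table uses corrected
forms (`I11.0`, `I43.x`, `I50.x`, `I05.x–I08.x`, `426.6–426.89`) and the
verbatim variant is shipped alongside.

Filtering applies, in order: (i) at least two distinct admission episodes;
(iii) at most fifty (exclusion, not truncation — frequent admissions signal
recurrent treatment rather than distinct diagnoses); (ii) episode rows whose
codes match no comorbidity group are dropped, and the minimum-episode rule
is re-applied to the survivors. Dropping rows rather than whole patients in
step (ii) is the adopted reading of an ambiguous rule; it is idempotent and
unit-tested. ICD-9 and ICD-10 rows may coexist within one patient; matching
dispatches on each row's version.

A patient's grouped diagnosis set collects every matching comorbidity group
**including** the target disease (cases legitimately share the target
condition as a comorbidity) but **excluding** the smoking group, which is
treated as a behavioural node feature, not a disease node. Age is min–max
normalised over the cohort; a zero-range cohort maps to all zeros to avoid
division by zero. Balanced controls are drawn uniformly without replacement
under a seed.

## Weighted patient network

The projection uses set semantics: multiple episodes with the same grouped
diagnosis count once. Edge weight is the exact shared-group count, so
`1 ≤ w(u,v) ≤ min(deg_bip(u), deg_bip(v))`. Patients isolated after
projection are removed, which is why the network's node count can be
slightly below the cohort size. All exported matrices (adjacency, features)
use sorted patient ID as the canonical node order.

## Network features

Edge weights are tie strengths, so shortest-path measures use distance
`1/w`. Eigenvector centrality runs power iteration on the weighted
adjacency (tolerance 1e-8, max 1000 iterations; non-convergence is an
explicit error). The weighted clustering coefficient is Onnela's
geometric-mean definition (bounded in [0, 1], weights scaled by the network
maximum). Closeness is computed on weighted distances by default with an
unweighted toggle, since conventions differ; disconnected graphs use the
Wasserman–Faust reachable-set scaling. On unit-weight networks every
weighted variant reduces exactly to its unweighted counterpart (tested).

## Graph neural networks

Both models are implemented in numpy with hand-derived gradients (verified
against central finite differences to ~1e-10 in the tests) and a manual
Adam optimiser, because the models must be inspectable down to the
propagation rule.

**GCN.** Three graph-convolution layers (16, 16, 1): the most literal
reading of "three layers, hidden size 16, sigmoid output". An alternative
2-convolution + dense head is available behind `GCNConfig.dense_head`.
Self-loops always enter with weight 1; with an edge-weighted adjacency the
raw weights enter `Ã = A + I` directly, and with all weights 1 the weighted
model is bit-identical to the binary one (tested).

**GAT.** Attention logits `LeakyReLU(a_src·Wh_u + a_dst·Wh_v)` with
negative slope 0.2, softmax over neighbourhoods that include a self-loop
(standard practice; the attention formula itself is silent on self-loops).
Layer 1: K = 8 heads × F = 8 features, ELU, concatenated (64-dim
embeddings). Output layer: a single head, head-averaged (trivially, for one
head), sigmoid. Edge weights do not enter the default GAT — attention is
left to learn tie strength; an optional mode multiplies post-softmax
coefficients by edge weights (self-loop 1) and renormalises, preserving the
sum-to-one invariant.

**Training.** Full-batch BCE on the train mask, computed from logits via
`logaddexp` for stability; Adam lr 0.01, β = (0.9, 0.999); dropout p = 0.3
applied to every layer's input (including the output layer's input — the
broadest reading of "all layers") and active only during training steps;
at most 1000 epochs. Early stopping monitors validation loss (the
conventional monitor), waits `patience = 30` epochs after the best epoch,
halts on the following one, and restores the best-validation weights.
Weight initialisation is Glorot-uniform from the config seed; dropout draws
from an independent stream of the same seed, so runs are bit-reproducible.

**Splits.** Stratified 0.60/0.20/0.20 masks: per class, shuffled indices
are cut at rounded proportions, so sizes are within one node of target per
class; both classes must be present.

## Evaluation

Support-weighted averaging for precision/recall/F1 was chosen because
back-calculating published confusion rows pins it down: per-class
precisions 89.75%/97.91% on counts (TP 254, TN 234, FP 29, FN 5) combine to
the printed 93.86% only under support weighting. Weighted recall then
equals accuracy identically (asserted as a property test). Threshold 0.5
with ties classified positive. A class with zero predicted members gets
precision 0 with a warning.

Baselines: logistic regression (C ∈ {0.1, 1, 10}), RBF-SVM
(C ∈ {0.1, 1, 10}), random forest (100/300 trees × depth {∞, 5}), MLP
(hidden (32,16) or (64,32)). The grid entry with the best validation-split
accuracy is scored on the test split; features are standardised on
training-split statistics. "With network features" means concatenating the
five network features onto the three patient features — for the GNNs as
well as the baselines.

t-SNE export: 2 components, perplexity 30 (reduced automatically in the CLI
for small cohorts), 1000 iterations, PCA initialisation, fixed seed.

## Problem sizes

Tests and examples run cohorts of 60–400 patients with 200/200 as the
standard configuration; networks at this scale have a few hundred nodes and
tens of thousands of weighted edges, which dense numpy linear algebra
handles in seconds while exercising every code path, including the
full-batch attention tensors (K × N × N).

## Known limitations

- The comorbidity grouping table is a configurable subset of the Elixhauser
  categories, not a complete 31-group clinical mapping.
- The GAT's dense attention tensors scale as O(K·N²) memory; cohorts beyond
  ~10⁴ nodes would need sparse attention, which is out of scope.
- The generator plants a single target-disease block; multi-disease or
  longitudinal structure is not modelled.
- No ICD-9↔ICD-10 cross-mapping is attempted.
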