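# Methods

`riceflavor` implements a flavor-typing workflow for fragrant rice that
combines three measurement channels: GC-MS volatile-compound tables, GC-O
(olfactometry) sensory-panel logs, and wet-lab functional components
(resistant starch, fat acidity). This note describes the models and
procedures, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Relative contents and class summaries

GC-MS reports peak areas in arbitrary units. Within a sample, each
compound's **relative content** is its share of the total peak area,
`c_i = 100 · a_i / Σ_j a_j` (percent), so per-sample contents sum to 100 to
floating precision (checked at 1e-9). A printed "—" cell means *not
detected* and is represented as the absence of a record, never as content
0; explicit zero rows are rejected at ingest so presence/absence logic
downstream is unambiguous.

Chemical classes (alcohol, phenol, aldehyde, acid, ester, hydrocarbon,
ketone, heterocycle) are carried as **input data**, not inferred from
structure. The packaged shared-compound table lists 2-decenal under the
hydrocarbons; this classification is preserved verbatim for fidelity to the
source table even though an aldehyde assignment would be the systematic
one.

Sum-to-100 validation of *ingested* percentage tables is opt-in
(`check_sums=True`, default tolerance ±1.0 absolute). Published tables
typically print only a subset of each sample's compounds — the packaged
shared-compound table covers 28 of the reference sample's 56 — so a
mandatory sum check would reject exactly the tables the package ships.
Normalized output always satisfies the 1e-9 conservation check.

## Shared, common and key compounds

- **Shared with a reference**: compounds detected in the reference sample
  and in at least one (rule `any`, default) or all (rule `all`) of a
  comparison group. The `any` reading is the default because it is the only
  one consistent with the packaged 28-row shared table, whose rows include
  undetected cells in the comparison samples; the strict reading returns 12
  on the same table. Both are exposed.
- **Common compounds of a flavor type**: detected in *every* sample of the
  type (rule `all`; `any` and `at_least_k` available).
- **Key compounds**: the type-exclusive regions of the Venn partition of
  the per-type common sets. The partition is computed exactly by
  enumerating each compound's membership vector, so it generalizes to any
  number of types and cannot produce inconsistent region counts.

Detection uses a strict threshold `content > min_content` with
`min_content = 0` by default: trace compounds down to 0.26% appear in the
study tables as detected, so any positive default would silently drop real
detections.

## FQ/AI spectrograms and characteristic compounds

Each GC-O smelling event is matched to the nearest same-sample GC-MS peak
within a retention-time tolerance (default **0.2 min**, configurable; ties
break by smallest time difference, then lexically smallest name, so
assignment is deterministic). Per compound and sample:

- **FQ** (identification frequency): distinct evaluators with at least one
  assigned event, `0 ≤ FQ ≤ n_evaluators` (panel size 4 by default).
- **AI** (average intensity): mean ordinal score (1–5) over the
  *perceiving* evaluators only, half-up-rounded to one decimal,
  `0 ≤ AI ≤ 5.0`, with `FQ = 0 ⇒ AI = 0`. Averaging over perceiving
  evaluators is forced by arithmetic: a four-evaluator panel can only reach
  a reported AI of 4.8 if non-perceivers are excluded (4.75 → 4.8 under
  half-up rounding). An evaluator with several events for one compound
  counts once in FQ and contributes their maximum score (configurable to
  mean); the maximum is the conservative choice for an ordinal "how strong
  was it at its strongest" reading.

A compound is a **characteristic flavor compound** of a type when
`FQ ≥ 3` or `AI ≥ 3.0` in at least `min(min_samples, n_samples_of_type)`
samples of the type (`min_samples = 2` by default). The effective-minimum
rule exists because a one-sample flavor type could otherwise never satisfy
an "in two or more samples" requirement, yet such types do receive
characteristic-compound calls in practice.

The cross-type **consensus table** lists compounds perceived (`FQ ≥ 1`
somewhere) in at least two flavor types, ordered by retention time with
pooled descriptors.

## Volatile–functional association

Two complementary views:

1. **Pairwise**: Pearson r between each class's total content and each
   functional component across samples (≥ 3 shared samples required).
   Zero-variance inputs are flagged `undefined`, never reported as 0.
2. **Model**: a single-hidden-layer feed-forward regression network — 4
   hidden units, symmetric-sigmoid hidden activation
   `2/(1+e^(−2x))−1` (computed as `tanh`, to which it is identical),
   linear output — trained by batch gradient descent on mean squared
   error. Inputs are min–max scaled to [−1, 1] per feature (the
   conventional pairing with a symmetric sigmoid); targets are
   standardized internally, which leaves the correlation score invariant
   and makes the default learning rate (0.05) scale-free. Weights start
   uniform in [−0.5, 0.5] from a seeded generator; training is fully
   deterministic given the seed. The association score is
   `R = Pearson(observed, predicted)`, computed either on the training
   samples or by leave-one-out refitting; the output always labels the
   mode, because the two can differ dramatically at small n (with 8
   samples and 21 free parameters the training-mode R is essentially a
   capacity measurement, not an association measurement — which is why the
   pipeline restricts network inputs to a configured compound subset
   rather than the full table).

Gradient correctness is verified against central finite differences
(≤ 1e-6) in the test suite.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, with full
ground truth:

- **Design**: 3 flavor types with 4/3/1 samples (the study layout) and a
  4-evaluator panel; ~45 compounds per sample drawn from the 8 classes in
  roughly the published census proportions (hydrocarbons most numerous).
- **Roster**: shared compounds (in every sample), type-specific compounds
  (the planted key compounds, disjoint across types), and background
  compounds. Backgrounds are placed in exactly one sample each, drawn only
  from multi-sample types; this guarantees no background can enter any
  type's common set, which keeps the planted key sets exactly identifiable
  in the no-noise limit. The cost is that single-sample types carry no
  sample-unique clutter — a deliberate identifiability/realism trade.
- **Areas**: lognormal (`log-mean 1.0, log-sd 0.6`), giving the
  heavy-tailed content distribution typical of volatile profiles.
  Retention times sit on a 0.5-min grid with 0.05-min per-sample jitter,
  well inside the 0.2-min matching tolerance, so peak assignment is
  unambiguous unless deliberately stressed.
- **Panel model**: planted *strong* (characteristic) compounds are
  perceived by all evaluators with latent intensity 4.5; every other
  present compound is *weak* — one randomly chosen evaluator perceives it
  with probability `logistic(1.5 · ln content)` and latent intensity 2.0.
  Ordinal scores are the latent value plus `Normal(0, intensity_sd)`,
  rounded half-up and clamped to 1–5. A globally strong compound (perceived
  in every type, in the spirit of 2-acetyl-1-pyrroline) is planted by
  default.
- **Functional components**: resistant starch is a type-level mean
  (defaults 0.4 / 0.65 / 0.8%, inside the 0.3–0.8% band) plus small noise.
  Fat acidity is linear in the *latent log areas* of three designated
  signal compounds, `y = 19 + β·(z − μ) + ε` with β = (3.0, 2.2, 1.5),
  centring the values in the 15.5–22.8 mg/100 g band. Defining the signal
  on the latent log areas keeps the population signal variance in closed
  form, `Var(signal) = σ_z² Σβ²`, so the noise needed for any target
  population correlation R follows exactly from
  `R² = Var(signal)/(Var(signal)+σ_ε²)`. The default noise is calibrated
  to R = 0.86. Detection dropout removes records from the measured table
  but never perturbs fat acidity: the grain's chemistry is not an
  instrument artifact.

### What the generator does not emulate

No co-elution, shared or drifting retention times, chromatographic
baseline effects, inter-evaluator bias, descriptor vocabulary drift,
compound-class-dependent detection thresholds, or correlated presence
structure beyond the shared/specific/background split. Passing the
recovery tests therefore demonstrates that the *procedures* are correct
under the stated statistical model, not that the workflow is robust to
every artifact of real GC-MS/GC-O data.

### Dropout sensitivity of strict intersections

The strict all-samples common rule is brittle under independent
per-(sample, compound) detection dropout: a planted key compound of a
k-sample type survives with probability `(1−p)^k` (≈ 0.66 for a 4-sample
type at p = 0.1), and shared compounds that drop out of other types' common
sets leak into exclusive Venn regions as false keys — the single-sample
type is most exposed. Mean key-set Jaccard at p = 0.1 is therefore around
0.5–0.6, not near 1. The test suite checks this degradation against the
closed-form survival expectation rather than pretending robustness; users
with lossy data should prefer the `at_least_k` common rule.

## Numerical conventions

- Rounding of reported AI values and display contents is half-up
  (`decimal.Decimal`), one and two decimals respectively; all computations
  use full precision.
- Name canonicalization trims, collapses internal whitespace and
  lower-cases; it is idempotent and leaves locants and stereo-prefixes
  (`cis-`, `4(14)`) intact, unifying the printed spelling variants of the
  same compound.
- All randomness flows through `numpy.random.default_rng(seed)`;
  identical (config, seed) pairs produce byte-identical output trees.

## Results not reproducible from the printed tables

The packaged fixtures carry only what the study printed. The following
therefore cannot be reproduced at the desk and are **not** asserted
anywhere: the 188-compound full census (raw instrument data not
published), the per-type common-compound counts behind the coincidence
diagram (13/20/9/14/7 — the printed shared table supports only 12 for the
popcorn type under the strict rule), the specific per-type
characteristic-compound lists (per-evaluator GC-O records not published),
and the real-data association R = 0.86 (the exact network input set is not
enumerated). Each is covered instead by the corresponding synthetic
recovery or calibration property, which validates the procedure rather
than the historical number.
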