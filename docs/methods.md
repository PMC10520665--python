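# Methods

## The synthetic cohort generator

Clinical IVF embryo datasets are proprietary, so all analyses here run on a
seeded generator whose design goal is to reproduce the *statistical
structure* the analyses rely on, not embryology itself.

### Generative model

For cycle *c* with latent cohort quality `q_c ~ N(0, σ_q)` (default σ_q = 1):

* **Cohort size** `max(2, Poisson(μ_size + δ·q_c))`, μ_size = 10, δ = 1, so
  better cohorts are somewhat larger (observed clinically: positive cohorts
  average ≈10.6 embryos vs ≈9.9 for negative).
* **Embryo quality** `e_i = ρ·q_c + sqrt(1 − ρ²)·ε_i`, `ε_i ~ N(0, 1)`.
  The within-cohort loading ρ (default 0.7) is the single dial that makes
  siblings resemble each other; ρ = 0 makes them exchangeable with
  non-siblings. No published estimate of this correlation exists, so the
  default is chosen to reproduce the qualitative sibling-similarity and
  cohort-contribution effects, not any reported coefficient.
* **Event times** (minutes from fertilization) for event *k*:
  `t_ik = μ_k + u_ck − γ_k·e_i + w_ik`, with cohort random effect
  `u_ck ~ N(0, σ_cohort,k)`, embryo noise `w_ik ~ N(0, σ_embryo,k)`, and a
  quality coupling γ_k (faster development in better embryos). Stage means
  μ follow consensus time-lapse timings (t2 27 h … tSB 104 h); the
  cohort-effect SDs grow with developmental stage (30 → 90 min) so the
  sibling/non-sibling gap widens at later events, as observed. Times are
  sorted within each embryo to enforce t2 < t3 < t4 < t8 < tM < tSB
  (cheaper than rejection sampling and approximately marginal-preserving).
  The pronuclei-fade time tPNf is drawn ≈2 h before t2 and t7 ≈3 h before
  t8, with their own noise, so the completion rules are *approximately*
  right rather than tautologically exact.
* **Blastulation** `Bernoulli(sigmoid(1.2·e_i + 0.1))`. The intercept was
  set so the sibling blastulation fraction lands in the clinically reported
  0.41–0.49 band (simulated ≈0.44; ≈0.49 in positive vs ≈0.38 in negative
  cohorts). Non-blastulating embryos carry no tSB and no Gardner score.
* **Gardner score** for blastulating embryos by ordinal thresholding of
  `e_i` plus part-specific noise: expansion grades 2–6 (grade 6, hatched,
  deliberately rare), ICM and TE letters A–D. A small fraction (7%) of
  scores is deleted to mimic annotation loss.
* **Transfer selection** ranks blastocysts by Gardner quality (expansion,
  then ICM, then TE, seeded random tie-break) and transfers the top one —
  or top two with probability 0.15, in which case the pair receives one
  shared outcome, matching the study population's restriction to
  concordant double transfers. A cycle whose embryos all fail to
  blastulate transfers its top-quality embryo instead (every simulated
  cycle must carry a label; such cycles are rare under the defaults).
* **Implantation** `Bernoulli(sigmoid(0.8·e_i + 2.0·(f_c − 0.45)
  − 0.05·(age − 35) − 0.4 + η_c))`, where `f_c` is the sibling blastulation
  fraction and `η_c ~ N(0, 1)` is an independent uterine term. The uterine
  noise produces negative outcomes for high-quality embryos — the label
  ambiguity that makes negative labels unreliable. The cohort term gives
  the sibling features genuine predictive content beyond the embryo's own
  quality (shared maternal and laboratory factors); its slope was
  calibrated so that adding cohort features to a kinetics+morphology+age
  model yields a replicated AUC gain in the 0.04–0.1 range that the
  analysis is designed to detect (measured ≈0.07 at 300 cohorts). The
  intercept puts the positive:negative cohort ratio near the clinically
  reported 58:42. Zeroing ρ and the cohort slope defines the null regime
  in which the cohort features are provably uninformative.
* **Missingness** is completely at random, per event: 5–10% for cleavage
  events, 20% for tM and tSB, 30% for the auxiliary tPNf and t7. Only
  rates, not a mechanism, are reported for the real data, so MCAR is the
  neutral choice; informative missingness (e.g. arrested embryos losing
  late events) is *not* modelled.
* **Image-model score** `dl_confidence = sigmoid(e_i + N(0, 0.5))` stands
  in for a CNN confidence output as a single scalar column; no image model
  is trained here.

### What passing tests do and do not show

The generator plants exactly the directional effects the analyses test:
sibling similarity increasing with ρ, higher blastulation in positive
cohorts, and a cohort contribution to prediction. Green tests therefore
demonstrate that the *pipeline recovers planted structure of this kind* —
they say nothing about effect sizes in real clinical data, which this
model deliberately does not calibrate beyond the marginal rates quoted
above. Features of real data that are not emulated: informative
missingness, annotator bias, clinic effects, ploidy, day-3 transfers,
multi-cycle patients.

## Annotation completion

Stage 1 applies the five expert offset rules (t2 = tPNf + 120 min,
t4 = t3 + 60, t3 = t4 − 60, t8 = t7 + 180, tM = tSB − 360). Each rule
fires only when its source event was actually observed — so the circular
t3/t4 pair fills neither when both are missing, and application order
cannot matter. Stage 2 fills embryos missing exactly one of the six core
events with the mean of that event over the five nearest fully annotated
embryos; nearness is plain Euclidean distance on the min–max-normalised
events the two embryos share (bounds fitted on all observed values in the
dataset). Fewer than six fully annotated embryos is a hard error. Embryos
still missing two or more events are excluded from kinetic features — the
single-gap scope is deliberate: multi-gap imputation would manufacture
most of an embryo's profile. The procedure is idempotent and fully logged
(method, value, neighbour set per completion).

A completed tSB is an imputed *time*, not evidence of blastulation:
cohort features always count blastulation from the raw annotations
(observed tSB or an assigned Gardner score, which exists only for
blastocysts).

## Similarity conventions

Non-sibling pairs are subsampled with a seed (default: as many as there
are sibling pairs) because exhaustive cross-cohort enumeration is O(n²).
Profile distances use per-feature min–max bounds fitted once on the full
analysis set and shared by both pair types, with no √d division; the
sub-vector (five intervals vs six event times) is an explicit parameter.
A zero-range feature contributes zero with a warning. Triplet enumeration
is exact up to a seeded uniform subsample above `max_triplets` (default
10⁶ — full enumeration can exceed 1.6 million triplets even on moderate
datasets). Label-wise cohort comparisons exclude *all* transferred embryos
from the sibling set; per-embryo cohort feature vectors exclude only the
embryo under evaluation, so for a double transfer each transferred embryo
sees the other as a sibling.

## Modelling protocol

Both arms of a pair share the split, the tuning protocol and the seed; the
with-cohort arm differs only by the 16 extra columns (which never drop
rows, so the test scores are matched by construction). Splits are at the
cycle level, label-stratified, 80/20. Tuning is grid search by 5-fold
cross-validated AUC over the six XGBoost dimensions — number of trees,
gamma, max depth, subsample, colsample_bytree, min_child_weight — with a
deliberately small default grid ({100, 300} × {0} × {2, 3} × {1} × {0.8} ×
{1, 5}) sized for ~300-row training sets; the grid is config-replaceable.
The tuning criterion and fold count are this package's choices (no
reference values exist for them). Extra-trees feature selection to ten
columns is applied only where configured — by default for model pairs that
include the image-score column, mirroring the lower-data regime it was
introduced for — and is fitted on training rows only. Replication uses ten
independent stratified repartitions (not a partitioned 10-fold), with the
Wilcoxon signed-rank applied both to matched per-embryo test scores within
a split and to matched per-replicate AUC pairs. All-zero score differences
return p = 1 rather than an error.

## Attribution and rescue

Shapley values are computed by XGBoost's native exact tree-path algorithm
in margin (log-odds) space, where the efficiency axiom holds to
single-precision round-off (the test tolerance 1e-3 reflects float32 tree
accumulation, not an approximation). Rankings are invariant to the output
space. For attribution runs the three Gardner parts are recoded ordinally
(expansion 1–6, A→4 … D→1) instead of one-hot, so each part appears as one
interpretable feature. The rescue analysis uses the 0.5 operating
threshold (no calibrated operating point is defined for these scores) and
compares rescued embryos' cohort features against the mean over *all*
cohorts of the erroneous label in the full dataset — the reference is a
population mean, not a test-set statistic — by Wilcoxon signed-rank on the
differences from that mean; a single rescued embryo is reported without a
test.

## Problem sizes and determinism

Default analyses use 300 simulated cycles (~3000 embryos, ~340 transferred),
ten replicates for replicated AUCs, and 600 cycles for the null-control
regime, where a tighter band demands more statistical power. The end-to-end
`run-all` smoke configuration uses 60 cycles. Every stage seed is derived by
hashing (global seed, stage name), all estimators run single-threaded with
fixed seeds, and report JSON is written with sorted keys, so a full run is
byte-reproducible from its config.

## Known limitations

* The cohort feature vector enumerates 16 entries (size, blastulation
  fraction, hatched fraction, 13 Gardner fractions); clinical descriptions
  of this feature set sometimes quote 17 without an enumerable 17th — the
  count here is what the definitions support.
* "Hatched" is defined as expansion grade ≥ 5; grading schemes differ on
  whether grade 5 (hatching) counts, and no operational definition is
  universal.
* AUCs at 300 cycles carry test sets of only ~60 embryos; single-split
  AUC differences are noisy (SD ≈ 0.07 across repartitions) and only
  replicate means are interpretable.
* Gardner fractions use the total sibling count as denominator, so
  blocks sum to ≤ 1 and "no blastulation" shows up as missing mass — an
  annotated-sibling denominator would change the fractions' meaning.
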