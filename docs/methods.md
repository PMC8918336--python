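# Methods

## The model

The KM index treats a hemispheric infarction as a space-occupancy problem.
Infarcted tissue swells by a factor `m` (default 2.8 — a software-dependent
volumetry constant; vendors that estimate larger cores would need a smaller
value); penumbra proceeds to infarction with probability `n`, which the
therapy determines; and the brain's baseline occupancy is the ratio of
perfused parenchyma (`v_MTT`) to scanned intracranial volume (`v_MIP`),
so that atrophy lowers the index:

    KM = (n · (m · v_I + v_P) + v_MTT) / v_MIP

`n` falls linearly over the mTICI reperfusion ladder, 1.0 at grade 0 to
0.5 at grade 3 in steps of 0.1 (grade 1 = 0.9 by the same linear rule),
is 1.0 without thrombectomy, and is multiplied by λ = 0.70 when rtPA is
given. λ is applied whether or not a thrombectomy was performed: lysis is
modelled as a penumbra-salvage factor independent of the mechanical
result. An index above 1 means the swollen tissue exceeds the free
intracranial space and a midline shift is expected.

The time-weighted KMT variant raises `n` to the onset-to-groin time factor
t (3 for ≤ 4.5 h, 2 for ≤ 8 h, 1 beyond), refitting λ(t) = 0.87, and keeps
the core's swelling ratio fixed via mᵗ = m · nᵗ. An alternative published
grouping scales core and penumbra jointly by m · nᵗ; it is inconsistent
with the t-th-root relation above, so it is available only behind
`literal_grouping=True`. An unknown onset time (wake-up or unclear-onset
stroke) maps to t = 1, the most conservative (highest-index) value.

### Discretization

Scores: 0 below index 1.005, 20 at or above 1.195, otherwise the first two
decimals of the index, i.e. half-away-from-zero rounding of
100 · (index − 1). The product is snapped to nine decimals before rounding
so that decimal inputs such as 1.075 land on their intended half-way
point. Risk classes key off the integer score (0–2 low, 3–7 moderate,
8–13 high, 14–20 severe) rather than the raw index, because the published
index bins leave gaps (e.g. between 1.07 and 1.08) that the score bins
close.

## Volumetry

Label maps use one integer volume per scan: 0 outside, 1 MIP coverage,
2 MTT brain, 3 penumbra, 4 infarct core, with nesting enforced (core and
penumbra inside the MTT brain inside the MIP coverage). Core and penumbra
are disjoint labels; `PerfusionVolumes.v_lesion` exposes their sum for the
inclusive-penumbra convention, since vendor conventions differ. Volumes
are voxel counts times the spacing product from the NIfTI header — no
partial-volume weighting, matching how clinical perfusion software counts
voxels. Orientation metadata is passed through untouched; volumes are
orientation-invariant. Separate boolean masks are accepted and merged
under strict nesting validation that names the offending label pair.

## Calibration

The fitting procedure the index derives from is a correlation
maximization: choose parameters so the Pearson correlation between the
index and the maximum observed midline shift is highest. The
implementation is a deterministic coordinate search — a grid over
m ∈ {0.1, 0.2, …, 5.0}, then a coarse scan plus golden-section refinement
of λ on (0.05, 1] to a 1e-3 tolerance, repeated for two sweeps. Ties break
toward smaller m and larger λ (the weaker weighting). Patients without a
recorded shift contribute 0 mm (the outcome is the *maximum* shift; none
observed is zero), switchable to dropping them. λ is unidentifiable in a
cohort that is all-rtPA or rtPA-free, and the search refuses such input
rather than returning a boundary value.

### A documented bias of correlation calibration

With a heavily zero-censored outcome (≈ 87 % of patients shift 0 mm) the
population Pearson objective is *not* maximized at the generating
parameters: censoring makes the outcome a convex function of the true
index, which rewards candidate indices with heavier right tails, and
because the core-volume distribution is strongly right-skewed
(mean ≈ SD forces skew), up-weighting the core — i.e. a larger m — creates
exactly such tails. On synthetic cohorts the objective peaks near m ≈ 4
when the data were generated at m\* = 2.8, while a linear (uncensored)
outcome recovers m\* exactly with the same search code. λ is far less
affected (recovered within ≈ 0.1). The same mechanism can mask the small
contribution of the occupied-space term B under heavy censoring. The test
suite pins the recovery properties in the regimes where they are
mathematically attainable and keeps the censored-regime m-recovery check
at its nominal tolerance as a known-failing, documented limitation of the
method itself — any correlation-maximizing fit of a swelling ratio
against a mostly-zero shift outcome inherits it.

## Evaluation

Thresholding is strict `>` (an index *above* the cut-off predicts a
shift), switchable to `≥`. AUC is computed from the Mann–Whitney U
statistic (ties count one half), with an asymptotic tie- and
continuity-corrected p-value — adequate for cohorts of this size; exact
small-sample p-values are out of scope. The ROC staircase's trapezoidal
area equals U/(n₁·n₂) to 1e-12 by construction, and the suite asserts the
identity on every input. Two cut-off selectors are provided and labelled,
since derivation-cohort reports rarely state which was used: Youden's J
and a sensitivity-first rule (most specific threshold whose sensitivity
still clears a floor — screening-test logic). Univariate tables report
Pearson r, a regression line in the orientation factor = intercept +
slope · MLS, and mark p > 0.05 as NS; constant factors are marked
degenerate instead of erroring. Risk tables report raw counts with
explicit per-class denominators; an empty class is flagged rather than
reported as a silent NaN.

## Synthetic cohorts

The generator reproduces the derivation cohort's printed statistics:
volume means/SDs (penumbra 87.77 ± 37.15, core 53.81 ± 49.71,
MIP 1086.26 ± 105.59, MTT 950.27 ± 105.69 cm³), the 132/186 thrombectomy
fraction with mTICI counts (12, 2, 10, 33, 9, 66), a 50.53 % rtPA rate,
and a 51/186 unknown-onset fraction. Design choices:

- **Moment-matched truncation.** Printed volume statistics are sample
  moments of non-negative data, so the 0-truncated normals for core and
  penumbra are parameterized so their *post-truncation* moments equal the
  printed values (solved numerically once and cached). Naive truncation of
  a normal with the printed moments would inflate the core mean by
  ~13 cm³ and push the mean index from ≈ 1.014 to ≈ 1.03. The core's
  coefficient of variation (≈ 0.92) puts the fitted pre-truncation mean
  far below zero, so these draws use the inverse CDF, not rejection.
- **Shared head size.** The MTT volume is drawn as a fraction
  (0.875 ± 0.035, truncated to [0.6, 0.995]) of the MIP volume, so
  v_MTT ≤ v_MIP always holds; the lesion pair is resampled until
  core + penumbra ≤ v_MTT (a rare event). Volumes are otherwise
  independent given head size — no joint distribution of core vs penumbra
  vs occlusion site is published, so independence is assumed.
- **Zero-inflated hinge outcome.** The maximum shift is
  max(0, 40 mm · (KM\* − 1.09) + ε), ε ~ N(0, 1.5 mm), zeroed with
  probability 0.4, where KM\* is the index at the true parameters
  (2.8, 0.70). The offset and inflation are set by construction so the
  positivity rate matches the study's 24/186; measured over seeds this
  yields ≈ 12 % positives, r(KM\*, MLS) ≈ 0.64 and AUC ≈ 0.94, close to
  the study's 24/186, 0.61 and 0.91. DHC requires a shift ≥ 4 mm (then
  fires with probability 0.8); death probabilities are 0.25 after DHC,
  0.10 with a shift, 0.02 otherwise — plausibility choices, as no such
  conditional rates are published.
- **Per-patient RNG sub-streams** derived from the seed, so growing or
  shrinking a cohort never changes other patients' draws; identical seeds
  give byte-identical CSVs.
- An optional `age_atrophy_effect` links higher age to lower occupied
  space (off by default; used only for a qualitative sign check).

What passing tests on these cohorts do *not* show: real CTP volumetry
errors (motion, bone edges in the MIP, mistimed contrast), correlated
lesion/vessel anatomy, or clinically realistic DHC decision-making. The
generator validates pipeline mechanics and statistical identities, not
clinical performance.

## Numerical choices

- Index computations are plain double arithmetic; the KM/KMT t = 1
  identity is exact in floating point.
- Golden-section λ refinement: tolerance 1e-3, bracketed by a 20-point
  coarse scan; intervals narrower than the tolerance return their
  midpoint.
- Cohort CSVs store floats via `repr` (shortest exact form), so
  write → read round-trips are lossless; blank cells are missing values,
  never zero.
- Degenerate inputs fail loudly: constant series, one-class outcomes,
  zero intracranial volume and nesting violations all raise typed
  validation errors instead of propagating NaNs.

## Test problem sizes

Unit and property tests run on cohorts of 25–800 patients; the recovery
acceptance check uses 20 cohorts of 500; distributional checks use a
single 5000-patient draw. These sizes give stable statistics while keeping
the full suite fast.
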