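# Methods

This note documents the models, estimators, parameter choices and numerical
conventions behind `operant_stereo`, and what the synthetic generators do
and do not emulate.

## 1. FI-EXT behaviour analysis

### Schedule model

A session is an ordered event stream (left/right presses, rewards, schedule
annotations).  The multiple FI-EXT schedule is: sequences of seven 2-min
fixed intervals (FI), each closed by the first left press after the
interval elapses (the rewarded press, followed by 3 s of reward access),
then a 5-min extinction (EXT) component; two sequences per daily session;
analysis restricted to testing days 23–32, by which time responding has
stabilised.

Parsing conventions (chosen once, applied everywhere):

* An FI component stays open until the rewarded press; presses between the
  nominal 120 s and the reward accrue to the 12th 10 s bin.  This follows
  the schedule's actual operation — there is no deadline after the interval
  elapses.
* The first FI of every sequence is excluded from all FI metrics (press
  curves, IRTs, the overall rate *p*), since post-EXT behaviour is
  systematically different.
* An inter-response time (IRT) is the gap between consecutive left presses
  *within* one FI component: the timer resets at each `fi_start` and at
  each reward, so no IRT spans reward consumption or a component boundary.
* IRT duration bins are the gap-free half-open thirds
  [0, ⅓), [⅓, ⅔), [⅔, 1), [1, 4⁄3), [4⁄3, 5⁄3), [5⁄3, 2), [2, ∞) s;
  a boundary IRT of exactly ⅓ s falls in the second bin.  An IRT belongs
  to the 10 s FI segment containing its terminating press and is assigned
  whole, never split.
* Right-lever presses are ingested and ignored (only the left lever is
  rewarded or analysed).

### Burst index

With overall left-press rate *p* (total included-FI presses over total
included-FI seconds), a memoryless responder puts probability
exp(−p·t₁) − exp(−p·t₂) in IRT bin [t₁, t₂).  The burst index is the sum
of (observed − expected) *relative* frequencies over the three sub-1 s
bins.  Relative frequencies (proportions of all IRTs) rather than raw
counts make the index independent of total response rate; the sign
convention makes excess short-IRT responding positive.  A historical form
of the expected-frequency formula carries the opposite sign; it is exposed
behind `expected_irt_frequencies(..., literal_sign=True)` for
compatibility, but the index itself always scores burstiness positive.
For a homogeneous exponential responder the index is zero in expectation;
the test suite verifies |mean| < 0.02 across seeds for rates spanning
0.1–2 presses/s.  Note the index is *not* zero for a non-bursty but
scalloped responder: the within-interval rate growth alone produces a
modest short-IRT excess relative to the single-rate exponential benchmark
(about +0.09 at the default control parameters), which is precisely the
behaviour of the statistic on real scalloped responding.

## 2. Synthetic operant cohorts

Each animal is an inhomogeneous renewal responder with within-FI intensity

    r(τ) = terminal_rate · (τ/120)^k,    k = 2 by default,

sampled by inversion of the cumulative intensity; the rewarded press
follows the interval's end after an exponential wait at the terminal rate.
Bursts are post-press cascades: with probability `burst_prob` a press
spawns a geometric number (mean `burst_size_mean`) of extra presses with
exponential IRTs of scale `burst_irt_scale_s` (≈0.1 s, well under the
0.33 s bin edge).  EXT components show a hard pause (`pause_s`) followed
by homogeneous low-rate pressing.  Animal heterogeneity is a
mean-preserving lognormal multiplier (CV 20%) on `terminal_rate`, chosen
to match the 10–30% between-animal CVs typical of these preparations;
days are i.i.d. given the phenotype (true day-to-day autocorrelation is
unreported for this task and is not modelled).

Default phenotypes (the package's study conditions) were calibrated by
Monte-Carlo so that the full pipeline reproduces the observed group-mean
burst indices of ~0.09 (control) and ~0.22 (treated) over days 23–32:

| parameter           | control | treated |
|---------------------|--------:|--------:|
| terminal_rate (/s)  |    0.44 |    0.85 |
| scallop exponent k  |       2 |       2 |
| burst_prob          |   0.005 |    0.16 |
| burst_size_mean     |     1.5 |     1.8 |
| burst_irt_scale (s) |    0.12 |    0.10 |
| ext_resume_rate (/s)|    0.05 |    0.08 |
| pause_s (s)         |      60 |      55 |

Both phenotypes satisfy the scallop stability criteria (group bin-1 mean
< 0.5, bin-11 mean > 1.5); the treated phenotype's higher terminal rate
also produces the last-60 s hyperactivity contrast.

What the generator does *not* emulate: acquisition/training dynamics (logs
are testing-phase only), within-session fatigue, day-to-day carry-over,
and any biophysics of the underlying injury.  Passing tests therefore
show that the analysis recovers the statistical structure it assumes, not
that real rats have that structure.

## 3. Design-based stereology

### Estimators

All estimators are the classical design-based forms on systematic uniform
random samples, in mm-based units with per-point/per-frame areas derived
from printed-montage geometry: a(p) = (grid spacing / magnification)²,
ASF = (frame side / magnification)².

* Cavalieri: V_ref = ΣP · a(p) · t · s, with section thickness
  t = 5 µm and sampling interval s (20 or 40).
* Physical disector: N_v = ΣQ⁻ / TSV with TSV = ΣF · ASF · t, and
  N = V_ref · N_v ≡ (V_ref/TSV)·ΣQ⁻.  The identity N = V_ref·N_v is
  enforced to 1 part in 10⁹ per animal.
* Point-sampled intercepts: v_V = (π/3)·l̄³ with l̄ the per-animal mean of
  per-neuron mean intercept lengths — the manual-ruler convention.  The
  estimator for which the PSI identity E[(π/3)l³] = v_V holds exactly,
  (π/3)·mean(l³), is available via `estimator="mean_of_cubes"`; on
  lognormal-size populations the cube-of-mean convention reads ~10–20%
  lower, which is documented rather than corrected.

### Counting-direction modes

The disector protocol that counts a neuron when its nucleus appears in
either section of the pair but not the other ("bidirectional") samples
twice the thickness that TSV = ΣF·ASF·t books.  This ambiguity is a
parameter, never a silent choice:

* `unidirectional` (default) — tops counted in the reference section
  only; unbiased with the single-thickness TSV;
* `bidirectional_corrected` — bidirectional counts with TSV doubled;
* `bidirectional_paper_literal` — bidirectional counts against the
  single-thickness TSV, reproducing the literal printed combination; on a
  phantom this overestimates N by a factor of ~2 (verified ratio 2.005 ±
  0.01 over 100 replicates), which is exactly why the mode exists.

### Coefficients of error

* CE(V_ref): the Gundersen–Jensen systematic-sampling approximation from
  per-section point counts, CE = √((3A − 4B + C)/240)/ΣP with
  A = ΣPᵢ², B = ΣPᵢPᵢ₊₁, C = ΣPᵢPᵢ₊₂.  The smoothness-class constant
  (1/240, smooth-boundary class, no nugget term) is the era-standard
  choice for these preparations and is exposed as a parameter; lag sums
  truncate naturally for short series.
* CE(N_v) = 1/√ΣQ⁻ (Poisson counting error).
* CE(N) = √(CE(V_ref)² + CE(N_v)²) — quadrature of independent factors of
  N = V_ref·N_v.  No printed formula exists for this quantity; quadrature
  reproduces the published per-group values to the third decimal in most
  rows, with small residuals attributable to group-averaging order.
* CE(v_V) = CV/√n over within-animal per-neuron volume estimates.
* Group mean CE = √(n⁻¹ Σ CEᵢ²); by Jensen this is never below the
  arithmetic mean of the CEs.

The precision audit computes, per group × region × quantity, the ratio
mean-CE²/CV² (CV = between-animal SD/mean) and flags cells with ratio
≥ 0.5.  A flagged cell is not a failure: when biological variance is
genuinely low the sampling error may legitimately dominate, and the flag
carries the CV so the reader can judge.  CV = 0 yields an infinite ratio
with an explicit "zero biological variance" note.

## 4. Stereological phantoms

The phantom is an axis-aligned ellipsoid (semi-axis ratio 3:2:1; a box
option exists for worst-case boundary tests) of known volume with uniform
neuron centres (rejection sampling) and lognormal somal volumes
(mean-preserving parameterisation).  Defaults are scaled to a young-rat
VTA: 0.682 mm³, 11,479 neurons, mean somal volume 1659 µm³ (CV 25%).
Slicing uses 5 µm slabs, systematic pair selection every s-th section
after a uniform random start, fresh uniform point-grid and frame-grid
offsets per section, and frame subsampling on a (i+j) mod k lattice with
random phase.

Two deliberate modelling choices keep counting unbiasedness separable from
profile geometry:

* each neuron contributes a single counting point — its nucleolus (soma
  centre) by default.  Centres are uniform over the region, so the
  expected disector count per fully-interior frame equals density × frame
  volume exactly; the alternative `counting_point="top"` (nuclear top)
  shifts points upward by one radius and loses a small fraction of
  neurons above the region pole;
* disector frames must lie entirely inside the section profile
  (`frame_rule="inside"`).  The classical ≥half-in acceptance rule is
  available (`frame_rule="half_in"`), but on a phantom whose neuron
  population stops exactly at the drawn boundary it books the full frame
  area against partially populated boundary frames and biases the density
  low; a test demonstrates the direction of that bias.  With the default
  rule the sampled subvolume is a strict subset of the reference space
  and the Monte-Carlo checks show |relative bias| < 2% for both the
  Cavalieri volume and the disector N over 200 replicate samplings
  (typical observed: volume within 0.1%, N within 0.7%).

Intercept simulation uses the spherical-symmetry reduction of
point-sampled linear intercepts: a soma is hit with probability
proportional to its volume, and the chord through a uniform interior
point reproduces the PSI length distribution exactly; at 10⁴ intercepts
the mean-of-cubes estimator recovers a monodisperse sphere volume within
2%.

## 5. Group statistics

* Normality gate: Shapiro–Wilk per group at α = 0.05; any failure routes
  the comparison to the Mann–Whitney U.  (The specific screen is a
  convention choice; the era-standard bench workflow used an equivalent
  gate.)  n < 3 defaults to parametric with a warning.
* Pooled-variance t-test, from raw values or (mean, SD, n) summaries —
  the two entry points agree identically.
* Mann–Whitney U: reported as min(U₁, U₂); p is exact by full label
  enumeration for combined n ≤ 12 (verified against independent
  brute-force enumeration and scipy), otherwise normal approximation with
  tie correction and continuity correction.
* One-tailed p-values use the observed-direction convention (half the
  two-tailed p), matching how directional tests are reported in this
  literature.
* Split-plot ANOVA: between-subjects factor (group) tested over subjects
  within groups; within-subjects factor (time) and the interaction over
  the subject × time residual.  No sphericity correction is applied by
  default (plain F with integer df); the decomposition satisfies
  SS conservation to 1e-9 and matches pingouin exactly.
* Bonferroni: p·m clipped at 1, with the family size m declared
  explicitly; for behaviour–anatomy correlations m defaults to the number
  of anatomical regions tested per behavioural metric.

## 6. Pipeline and reproducibility

All randomness derives from a single master seed via `SeedSequence`
spawning (one substream per animal or phantom), so any two runs with the
same configuration and seed are byte-identical; CSV floats are written at
6 significant digits (10 for raw event times) and each output directory
carries a manifest with the config, its hash, the seed and row counts.
The default synthetic stereology stage draws per-animal phantom sizes
around group means (control 11,479 / treated 8,894 neurons; volumes
0.682 / 0.585 mm³; lognormal CV 10%), which links anatomy to the
behavioural group labels and lets the correlation stage recover the
negative behaviour–anatomy association.

Problem sizes used by the shipped checks — 5 replicate cohorts of 9–10
animals × 32 sessions for the behaviour calibration, 200 replicate
samplings of an ~11,500-neuron phantom for estimator unbiasedness, 10⁴
intercepts for the PSI identity — were chosen so Monte-Carlo error sits
well inside the tolerances being asserted.

## 7. Known limitations

* The operant simulator's renewal structure cannot represent serial
  correlation between FIs or drift across days.
* The phantom's uniform density and smooth boundary are favourable for
  the Gundersen CE's smoothness class; irregular real anatomy would raise
  CE(V_ref) relative to the phantom.
* The published per-animal raw data are unavailable, so specific F, U and
  r values from the original cohorts are not reproducible; they are
  replaced by property checks (estimator unbiasedness, null calibration,
  exact-test equivalence) plus arithmetic recomputed from published
  summary statistics.
* The audit's CV uses the plain SD/mean of the per-animal estimates; no
  small-sample CV correction is applied.
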