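# Methods

## The index model

The PF index scores one ablation lesion from the two delivery parameters
the operator controls: the mean catheter contact force `F` (grams) and the
number of delivered PFA applications `n`:

    PFI(F, n) = A · ( B(F) · ln n + C(F) ),
    B(F) = b0 + b1·F  [mm],   C(F) = c0 + c1·F  [mm].

Assumptions built into this form:

* **Asymptotic dose response.** Depth grows logarithmically in application
  count — each further application adds a strictly smaller increment
  (concavity of `ln`). This is the qualitative shape reported for
  ventricular PFA lesions.
* **Affine force modulation.** Both the dose slope `B` and the
  single-application offset `C` increase linearly with force. The source
  equation is ambiguous about whether its `B(·)`, `C(·)` depend on dose or
  force; affine-in-force with `n` as the application count is the simplest
  form consistent with a log dose effect plus a force effect at fixed dose,
  and it is the form this package commits to.
* **Natural logarithm, A = 100.** The log base and the overall scale are
  each redundant with the scale of (b0, b1, c0, c1); fixing `ln` and
  A = 100 makes the parameters identifiable and puts `B`, `C` directly in
  millimetres of expected depth, so that `PFI/100` *is* the depth
  prediction.
* **Validity domain.** Forces 5–80 g (no ablations were performed below
  5 g; data above 80 g are excluded from analyses), doses 1–14
  applications. `IndexParameters` requires `B(F) > 0` and `C(F) > 0` across
  the force range; since both are affine, positivity at the two endpoints
  is checked.

### Titration to target

`simulate_titration` delivers applications one at a time; after application
`k` the running index is evaluated at the *running mean* of the
per-application forces (the studies report a single mean CF per lesion).
Delivery stops at the first `k` where the index reaches the target — the
"foot pedal" rule — or at the application cap (default 14, protocol runs
use 12). Consequences that the tests assert: trajectories are strictly
increasing; overshoot past the target is strictly smaller than the final
increment; with the calibrated defaults, 300 is attainable at every force
stratum, 450 only above ≈35 g, and 600 nowhere within 12 applications at
≤80 g — the attained index under a 600 target saturates around 530–570,
reproducing the study's observation that 600 "resided within the 550
range".

## Synthetic data

No per-lesion data were deposited; the generators emulate the *statistical
structure* of the two arms and are the basis of all study-level checks.

### Characterization arm (111 lesions)

Per lesion: CF stratum drawn with weights 41.7/42.7/15.6 % (the published
40/41/15 % renormalized — the missing 4 % was delivered above 80 g and
excluded), CF uniform within the stratum range (5–25 / 26–50 / 51–80 g);
dose drawn from {3, 6, 9, 12} kept as balanced as integer counts allow;
depth = PFI(F, n)/100 + N(0, σ_depth); width from a plateauing log-dose
model

    width = w0 + w_log · ln(min(n, 9)) + w_force·F + N(0, σ_width),

with the plateau at 9 applications taken from the study's width-profile
description. Depths reaching the configured wall thickness (default 10 mm)
are censored at it, flagged transmural and excluded; simulated depths below
0.1 mm are floored there and flagged (the smallest real lesion was 0.90 mm,
so both events are rare under the defaults).

### Calibration of the characterization generator

`calibrate_char_generator` fixes (b0, b1, c0, c1, σ_depth) by weighted
least squares on (marginal statistic, target) constraints, where each
model-implied statistic is an **exact expectation under the design
distribution** (closed-form moments of the CF mixture and the dose set —
no simulation in the loop).

Identifiability deserves care here. Writing `l = ln n − E[ln n]` and
`f = F − E[F]`, the depth surface decomposes exactly as

    depth = m + K1·l + s·f + b1·f·l + noise,

with `m` the overall mean, `K1 = b0 + b1·E[F]` the dose slope at the mean
force, and `s = c1 + b1·E[ln n]` the force slope at the mean dose. Dose
marginals, CF-stratum marginals and the CF regression slope constrain only
(m, K1, s): the interaction coefficient `b1` is invisible to every marginal
mean (it multiplies a centred product) and enters only the variance. The
calibration therefore solves the constraint least squares with a small
ridge penalty (10⁻⁴) that resolves the `b1` direction toward the
minimum-norm solution; constraint sets with fewer than 5 entries, or whose
mean-type entries span fewer than 3 of the four parameter directions, raise
an identifiability error. Round-trip tests use per-cell
(stratum × dose) mean constraints, which are full rank and recover known
parameters to 1 %.

**Choice of default constraint set.** The published Part-1 statistics are
mutually inconsistent under this design: the three CF-stratum depth means
(2.98 / 3.82 / 4.23 mm at stratum mean forces 15 / 37.5 / 65 g) are not
collinear in force, so no affine-in-force surface can match all three *and*
the published CF regression line (slope 0.0209 mm/g); likewise the
published overall SD (1.2 mm), regression r² (0.08) and slope cannot all
hold at the design's force variance. The default calibration therefore
constrains exactly the statistics the generator is contracted to
reproduce — the ×3 and ×12 dose-marginal means (2.48, 4.52 mm), the CF
regression slope and r², and the overall mean depth (3.6 mm) — each
weighted by the reciprocal of its sampling SE reconstructed from the
printed SDs and group sizes. Depth noise comes out of the r² constraint
(σ_depth ≈ 1.09 mm), the same construction the validation generator uses.
The statistics *not* imposed are reported by
`characterization_diagnostics`: the implied CF-stratum means are
3.26 / 3.73 / 4.30 mm and the implied overall SD is 1.39 mm — visibly, not
silently, off their printed values. Calibrated defaults:
b0 = 1.2101 mm, b1 = 0.0077 mm/g, c0 = 0.6512 mm, c1 = 0.0064 mm/g.

The width model is pinned directly: `w_force` is the published width-on-CF
slope (0.0422 mm/g); `w_log = 1.0 mm` gives the reported "slight" width
rise from ×3 to ×9; `w0` then places the overall mean width at 12.2 mm and
`σ_width` completes the overall width SD of 3.3 mm. The published width
regression intercept (10.633 mm) is consequently missed by ≈0.19 mm — the
overall mean is the quantity honored.

### Validation arm (73 lesions)

Attained PFI is normal within each intended-target stratum with the
published means/SDs (307±21 n=29, 460±24 n=23, 547±34 n=21); stratum
membership is by *intended* target, never attained value (the attained
ranges overlap). Two depth modes exist because the published per-stratum
depth summaries and the published depth-on-index regression are mutually
inconsistent under within-stratum independence (the strata SDs imply a
pooled r² near 0.39, not the published 0.66):

* **mode A ("A_linear")** honors the regression: depth = 0.923 +
  0.640·(PFI/100) + N(0, σ), with σ from the closed form
  `derive_noise_sd_for_r2`: σ = |β₁|·sd(x)·√((1−r²)/r²) ≈ 0.479 mm, where
  Var(x) = 1.088 is the exact mixture variance of PFI/100 under the strata.
  Used for the slope/intercept/r² checks; it also reproduces the 300-stratum
  depth mean (2.89 vs printed 2.86 mm) without being calibrated to it.
* **mode B ("B_strata")** honors the per-stratum depth summaries
  (2.86±0.67, 3.92±0.73, 4.41±0.94 mm), independent of within-stratum PFI.
  Used for the ±2 mm accuracy check; the implied replicate-averaged
  accuracy is 93–94 % against the published 95 %, within the ±3-point band
  the inconsistency allows.

Neither mode is presented as the raw study data. Contact forces are drawn
from the published validation CF occupancy (29/30/14 lesions over
low/high/very-high), independent of PFI; application counts are back-filled
by inverting the default index at the drawn force. Both are structural
furniture (they feed the force-relation figure analog), not calibrated
quantities.

### What the generators do **not** emulate

Per-animal clustering and random effects (lesions are independent, as in
the source analyses); right-vs-left-ventricle depth differences (the
chamber label is cosmetic); the true within-stratum force distribution
(uniform is assumed; the simulated overall CF is 32.4±18.7 g against the
published 32±17 g); any electrical pulse-train physics, catheter geometry
or chronic lesion evolution. Passing checks therefore show that the
*analysis machinery* recovers the published statistical structure from data
generated under it — not that the index is biologically validated beyond
what the source study established.

## Fitting

`PFIndexModel` estimates (b0, b1, c0, c1) from per-lesion (force, dose,
depth) triples with A fixed at 100. The surface is linear in the
parameters, so the unconstrained optimum is the closed-form least-squares
solution; it is accepted when it satisfies the positivity invariants (the
generic case). Otherwise the fit restarts from a deterministic 3×3×3×3 grid
(b0, c0 ∈ {0.5, 1.5, 3.0} mm; b1, c1 ∈ {0, 0.02, 0.05} mm/g) under the
linear inequality constraints B(5), B(80), C(5), C(80) > 0 (SLSQP,
ftol 10⁻⁹), keeping the smallest-rss solution and breaking rss ties by the
smaller parameter norm. Designs with a single dose level or a single force
value are rejected as unidentifiable before fitting. Standard errors come
from σ̂²(XᵀX)⁻¹.

**Recovery benchmark.** At σ = 0.3 mm and n = 500 the benchmark design uses
forces uniform on 5–80 g and doses cycling over {1, 3, 6, 12}: the
single-application arm is required because without near-zero log-dose
leverage the offset parameters c0, c1 cannot be pinned to 10 % at that
noise level (their analytic SEs are ~0.12 mm and 0.0024 mm/g under the
{3,6,9,12} protocol design). With truth (b0 = 1.5, b1 = 0.03, c0 = 2.0,
c1 = 0.04) every 10 % band is ≥3.5 analytic SEs wide, and the acceptance
test requires each parameter within 10 % of truth in ≥95 % of 100
replicates.

## Statistics

Two-sided tests at α = 0.05 throughout, no multiple-testing correction
(matching the source analyses). One-way ANOVA is classical
(equal-variance); χ² is Pearson without continuity correction. Outlier
screening is per dose group: a lesion is flagged when its depth deviates
from the group median by more than k = 3 (configurable) times the group MAD
scaled by 1.4826 — the source only says "absolute deviation … per their
respective application group", so the scaled-MAD rule with k = 3 is this
package's concrete reading. Groups smaller than 3 are skipped with a
warning. Strata summaries carry a pooled row whose mean is the exact
Σnᵢmᵢ/Σnᵢ identity; the ±2 mm accuracy metric counts analyzable
(non-excluded) lesions with |depth − PFI/100| ≤ tolerance.

## Pipeline numerics and reproducibility

All randomness flows from a single integer seed through named
`SeedSequence` substreams (one per stage/cell); identical config + seed
reproduces byte-identical CSVs and reports. Exclusion accounting is
reconciled in every report (n_input = n_analyzed + n_excluded with
per-reason counts). Replicate experiments use 500 replicates of the 73- and
111-lesion datasets (1000 for the accuracy metric) — sizes at which the
Monte-Carlo SE of every replicate-averaged statistic is at least an order
of magnitude below its comparison tolerance, while the whole experiment
suite runs in seconds.

## Known limitations

* The affine-in-force resolution of `B(·)`, `C(·)` is a documented design
  choice, not the source's disclosed intent; the source never published its
  constants, so calibrated parameters are *a* defensible reconstruction,
  not *the* clinical system's values.
* The interaction coefficient b1 is structurally unidentifiable from
  marginal summary statistics (it needs per-cell means or raw data); its
  default value is the ridge-selected minimum-norm representative and
  should not be interpreted substantively.
* The published summary statistics are mutually inconsistent in places
  (strata-mean non-collinearity, r²-vs-SD tension, strata percentages vs
  counts); every such conflict is resolved explicitly as described above
  and surfaced in diagnostics rather than absorbed silently.
* Whether the clinical real-time index uses instantaneous or averaged force
  is unstated; the running-mean convention here matches the per-lesion
  reporting but may not match the device.
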