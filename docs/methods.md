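# Methods

## Steady-state control-of-breathing model

The model treats ventilatory control as a negative feedback loop between the
lungs ("plant") and the chemoreceptors ("controller"), evaluated at steady
state. Two curves fix the system:

* **Isometabolic hyperbola.** At fixed metabolic CO₂ production V̇CO₂ (ml/min,
  STPD), alveolar ventilation and alveolar CO₂ trade off as
  V̇A = k·V̇CO₂/paCO₂ with k = 0.863 hard-coded (this constant converts
  ml/min STPD and mmHg into L/min BTPS; all other unit conventions follow
  from it and no automatic unit conversion is attempted). Alveolar and
  arterial CO₂ tensions are treated as equal and written paCO₂.
* **Chemosensitivity line.** Ventilation responds linearly to CO₂ above the
  apnea threshold AT with slope CG (controller gain, L/min/mmHg) and is
  clamped to zero at and below AT — negative ventilation is meaningless, so
  the line is rectified rather than extrapolated.

**Operating point.** Equating the two curves gives
CG·p² − CG·AT·p − k·V̇CO₂ = 0, whose unique root above AT,
p = (AT + √(AT² + 4k·V̇CO₂/CG))/2, is used in closed form: the discriminant
always exceeds AT², so the root exists for every valid parameter set and no
iteration, branching or tolerance is involved. A bracketing bisection solver
exists only in the test suite as an independent oracle (agreement to 1e−6 mmHg
over 1000 random systems).

**Derived quantities.** Plant gain is the reciprocal tangent slope of the
hyperbola at eupnea, PG = p²/(k·V̇CO₂), which obeys the identity PG·V̇A = p
(tested to 1e−9). Loop gain is reported as the raw product CG·PG (≈ 8.1 at
the default baseline) and is used **only for relative change**; it is not
rescaled to match dynamically measured loop-gain values (which are an order of
magnitude smaller), and no frequency-domain component — mixing gain,
circulatory delay — is modelled. CO₂ reserve is p − AT; ventilatory reserve is
measured along the hyperbola, k·V̇CO₂/AT − V̇A_eup.

**Baseline parameterisation.** A baseline is specified by the three pooled
control-condition anchors (V̇CO₂ = 206 ml/min, eupneic paCO₂ = 38.2 mmHg,
AT = 33.5 mmHg by default); the controller gain is *derived* from them
(≈ 0.990 L/min/mmHg) so that the line passes through the eupneic point on the
hyperbola. The model-implied baseline plant gain (≈ 8.2 mmHg/L/min) and CO₂
reserve (4.7 mmHg) differ from the pooled *measured* values (5.42 and
4.0 respectively); the two are not reconciled — the package follows the model
geometry throughout, since the simulations only report percent changes.

## Interventions and sweeps

An intervention multiplies AT, V̇CO₂ and CG by (1 + pct/100) and re-solves the
operating point. Percent changes of all derived quantities are exact; display
rounding to 1 decimal is applied only in reports. Loop-gain changes satisfy
%ΔLG = ((1+%ΔCG/100)(1+%ΔPG/100) − 1)·100 to 1e−9 by construction, which the
tests verify against direct recomputation.

**Sweep self-consistency.** When one baseline anchor is swept, the others are
held at their pooled values and the apnea threshold is re-derived as
AT = p − V̇A_eup/CG, so every grid point is a coherent system (line through
the eupneic point). Holding AT fixed instead would reverse the direction of
the eupneic-paCO₂ effect — the convention was checked against a brute-force
alternative during design. Sweep ranges default to the physiological spans
CG 0.5–3 L/min/mmHg, eupneic paCO₂ 30–50 mmHg, V̇CO₂ 155–255 ml/min, on 101
evenly spaced points (the grid density is a package choice; results are
insensitive to it since every point is closed-form). Values outside the span
warn but compute; grid points with impossible geometry (e.g. a controller gain
so low the re-derived AT is negative) are flagged in a validity mask and carry
NaN rather than being dropped.

**Threshold shift convention.** The left shift is applied multiplicatively
(−15% of each baseline's *own* AT) at every grid point by default.
`shift_mode="absolute"` instead applies the fixed mmHg equivalent of the
percentage at the pooled AT (−5.025 mmHg for −15%) everywhere; the two agree
at the pooled baseline and differ off it.

**Relative reduction.** Sweep outputs are indexed as RR = %ΔLG / %ΔLG₀ where
%ΔLG₀ is the loop-gain change of the same intervention at the pooled baseline
(−21.76%, printing as −21.8). The normaliser is the exactly recomputed value,
not its rounded display form, so RR = 1 at the pooled point to machine
precision; it is held fixed across the grid rather than recomputed per point.

## Meta-analysis engine

Effects are log ratios of means, ln(m̄_t/m̄_c), with delta-method variance
s_t²/(n_t·m̄_t²) + s_c²/(n_c·m̄_c²); means must be positive. Pooling is
inverse-variance: the fixed-effect fit supplies Cochran's Q,
I² = max(0, (Q−df)/Q)·100 and the DerSimonian–Laird between-study variance
τ² = max(0, (Q−df)/(Σw − Σw²/Σw)), truncated at zero. Random-effects weights
are 1/(v+τ²). The default `auto` mode pools with random effects exactly when
I² > 30% — both forced modes are available. Inference is two-sided
normal-theory (no Knapp–Hartung adjustment); the estimator choice is the
standard contemporaneous one for this literature. With a single study the
pooled result equals the study and Q = I² = τ² = 0.

Design choices where the convention was genuinely open:

* every comparison is treated as two independent arms, including
  crossover/baseline-controlled designs (within-subject correlations are
  rarely reported; treating them as independent is conservative for the
  pooled variance);
* the weighted control SD is the weight-averaged study SD, not a pooled
  variance; `sd_mode="pooled"` gives the root-mean-square alternative;
* meta-regression uses weights 1/(v+τ²) with τ² from the intercept-only
  DL fit (overridable) and the fixed-scale covariance (X′WX)⁻¹ — no residual
  rescaling — matching normal-theory meta-regression;
* the Hedges-corrected SMD effect shares the same pooling path, as a
  scale-free cross-check when ratio effects are suspect.

Implied absolute differences map a ratio and its CI bounds through
x ↦ x·mean_wt − mean_wt on the weighted control mean; monotonicity of the map
preserves CI ordering.

## Synthetic study generator

No per-study summaries are published for the pooled control-of-breathing
outcomes, so the engine is validated on simulated study sets. Each study draws
a true log-ratio from Normal(ln ROM, τ²), a control mean from
Normal(38.2, 3.7²) — the location and between-study spread of the pooled
eupneic-paCO₂ control distribution — and a within-arm coefficient of variation
from U(0.08, 0.15), typical of within-study paCO₂ SDs of 3–6 mmHg. Observed
arm means and SDs are **sample statistics of actual per-subject draws**
(normal by default, a mean/SD-matched lognormal for strictly positive
outcomes), so small-sample noise in the variance formula is genuinely
exercised. Defaults are 20 studies of 50 subjects per arm with true ROM 0.85
(the pooled apnea-threshold effect) and τ² = 0. Generation is deterministic
given the seed; replicate seeds in `recovery_experiment` derive from the
config seed.

What passing calibration shows — and does not. Under the default conditions
the 95% CI covers the truth in ≈ 95% of 2000 replicates, mean I² ≈ 9.7, and
with τ² = 0.04 over 50 studies the median DL estimate is ≈ 0.041. This
validates the pooling arithmetic and its nominal coverage under the generative
model; it says nothing about design heterogeneity, correlated arms, selective
reporting or non-normal outcomes in real study sets, none of which the
generator emulates. One stated limit: with arms sharing CV and sample-size
range, the leading-order bias of ln(mean) cancels between arms, so pooled
log-ratio bias sits at Monte-Carlo noise level (~1e−4) at every n; the
consistency tests therefore assert a monotone RMSE decrease with n and bias
within MC error, not a monotone bias decrease.

## Problem sizes and numerical choices

Model quantities are closed-form, so all published-value reproductions run in
milliseconds at full grid density (101 points). Calibration runs use 2000
replicates for coverage (≈ 1.5 s), 500 for τ² recovery, and 300 per point for
consistency checks — sizes chosen so Monte-Carlo error is well inside the
stated tolerance bands. Tolerances: intersection residual and tangent
identity 1e−9; closed-form vs. bisection 1e−6 mmHg; log↔ratio round trips
1e−12; display comparisons at 1 decimal.

## Known limitations

Steady-state and linear only: no dynamic (frequency-domain) loop gain, mixing
gain or circulatory delay; no hypoxic ventilatory response or O₂–CO₂
interaction (normoxia is assumed, and the chemosensitivity slope is taken
identical above and below eupnea); no dead-space/minute-ventilation
partitioning; no prediction of apnea-severity outcomes. The raw loop-gain
product is not comparable to dynamically measured loop gain except through
relative change.
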