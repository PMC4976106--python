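# Methods

## Scope and model

`mesocon` analyses coupled gas-exchange + chlorophyll-a fluorescence
records of C3 leaves under progressive drought. The physical model is the
two-resistor CO2 diffusion chain

    A_N = g_s,CO2 (C_a - C_i) = g_m (C_i - C_c),     g_s,CO2 = g_s,H2O / 1.6,

coupled to the Rubisco-limited branch of the Farquhar–von Caemmerer–Berry
demand model

    A = Vcmax (C_c - Γ*) / (C_c + Kc (1 + O/Ko)).

Only the Rubisco-limited branch is implemented: all fits are restricted to
the initial-slope region (C < 300 µmol mol⁻¹ by default), and the
limitation solver inherits this assumption. There is no
RuBP-regeneration/TPU state, no temperature response (the kinetic
constants are used at their 25 °C literature values even though such
campaigns typically run near 21 °C — a deliberate replication of field
practice), and no energy-balance leaf model.

The supply–demand intersection is the smaller root of a quadratic in A,

    A² - A [g (C_a + K̄) + Vcmax] + g Vcmax (C_a - Γ*) = 0,

with g the series conductance and K̄ = Kc(1+O/Ko); the root is evaluated
in the numerically stable form 2c/(b+√(b²-4c)) and always satisfies
C_c > Γ* for positive parameters. With one conductance infinite the
corresponding drawdown vanishes; with both infinite the closed-form demand
at C_a is returned exactly. An independent bracketing solver
(`solve_assimilation_bisect`) is kept solely for cross-verification.

## Estimators

**Compensation point and day respiration (Laisk).** Low-C_i response
lines measured at several irradiances share a common point (C_i*, −R_d).
Each line is fitted by OLS; the joint intersection minimises
Σ_k (a_k + b_k x − y)² — a 2-unknown linear least-squares problem — rather
than averaging pairwise intersections (those are kept as a dispersion
diagnostic). Near-parallel lines (slope spread < 1e-6) raise an
ill-conditioning error; slopes not increasing with irradiance are
reported as a warning. Points above a configurable C_i ceiling
(default 300) are excluded to stay within the linear region.

**α·β calibration (Valentini).** Under < 1 % O2, J_f = 4(A_N + R_d), so
the regression of Φ_CO2 = (A_N+R_d)/PPFD on Φ_PSII = (F_m′−F_s)/F_m′ has
slope α·β/4. The default regression carries an intercept; it is reported,
and a warning is recorded when |intercept| > 2 SE. A through-origin
variant is selectable. Calibration fails loudly when the slope is
non-positive or α·β leaves (0, 1].

**Mesophyll conductance (variable-J).** The point estimator is

    g_m = A_N / (C_i − Γ*·[J_f + 8(A_N+R_d)] / [J_f − 4(A_N+R_d)]).

Estimates are flagged, never dropped: `J_DEFICIT` when
J_f ≤ 4(A_N+R_d), `NEGATIVE_DRAWDOWN` when the implied C_i − C_c ≤ 0, and
`CEILING` above a configurable validity ceiling (default 10 mol m⁻² s⁻¹ —
the estimator explodes near its singular denominator and published
campaigns do not state a screening rule, so the ceiling is explicit and
configurable). Γ* and R_d come from each genotype's own Laisk fit by
default, overridable by configuration.

**Day-level protocol and jackknife.** Field protocols take several
instrument readings per leaf-day (four in the campaign emulated here) and
report their mean. The day estimate inverts the channel means; because
the inversion is a smooth nonlinear function of those means it carries an
O(1/n) bias, removed by the leave-one-out jackknife
g_jack = n·g(all) − (n−1)·mean_i g(without i). The jackknife is the
default and is exact (a no-op) on noiseless data. Residual mean bias at
the well-watered extreme (g_m ≳ 0.7, CO2 drawdown ~35 µmol mol⁻¹) is the
method's known fragility: there the inversion is strongly convex in the
measured channels and its uncorrected ensemble-mean bias is positive for
any realistic channel noise; estimates there should be read as
median-accurate rather than mean-accurate. At severe stress a second,
smaller effect appears: with g_s ~ 0.1 mol m⁻² s⁻¹ the instrument's own
C_i = C_a − A/g_s construction is biased by the g_s ratio noise, so the
chain (not the estimator) is off-centre by ~1–2 %.

**Carboxylation capacity.** Given Γ*, R_d and kinetics, the demand is
linear in Vcmax, so the least-squares estimate over initial-slope points
is the exact projection Vcmax = Σf·y / Σf², f = (C−Γ*)/(C+K̄) — closed
form, no iteration; its SE comes from the residual variance. Points at or
below Γ* are excluded. `y` adds R_d to measured A_N by default (gross
demand); `use_rd=False` fits net A. The default basis is C_i, matching
how such fits are conventionally reported; this yields an *apparent*
Vcmax biased low by finite g_m. The `basis="cc"` option fits on
chloroplast CO2 (e.g. from the variable-J stage) and removes that bias —
it is the basis under which a simulated campaign's generating Vcmax is
recovered exactly, and the basis used for the drought fold-change checks.

**Limitation partition.** Raw partition at C_a = 380 µmol mol⁻¹:
A_Ca (both conductances measured), A_Ci (g_s → ∞, so C_i = C_a), A_Cc
(g_m → ∞ with g_s measured, so C_c = C_i by construction — this resolves
an ambiguity in how the A_Cc reference level is usually phrased);
L_S = 100(A_Ci−A_Ca)/A_Ci, L_M = 100(A_Cc−A_Ca)/A_Cc. Rates come from
the model (default; deterministic) or from monotone PCHIP interpolation
of a measured curve, where A_Cc is the intersection of the measured
A(C_c) relation with the stomatal supply line (the two modes then agree
within 5 % when the curve itself is model-generated). Because drought
time series are conventionally expressed as a percentage of the
well-watered maximum, a sequential WW-normalized variant is also emitted:
A0 (measured) → A1 (g_s restored to WW) → A3 (WW maximum);
L_S = 100(A1−A0)/A3, L_M = 100(A3−A1)/A3, so the two sum to the total
loss and L_M absorbs the combined mesophyll-diffusion + biochemical
(non-stomatal) component. The raw partition carries the stomatal/
mesophyll *ordering* signal; the normalized one carries the
severe-stress *magnitude* (~60–80 % culminations).

## Synthetic campaigns

The generator emulates a 21-day withholding-of-water experiment on four
winter wheat genotypes. Latent trajectories are phenomenological, not
mechanistic: RWC declines monotonically 100 → 40 % with a
genotype-specific speed (faster for the two genotypes that closed stomata
by day ~11 in the reference campaign); g_s, g_m and Vcmax follow monotone
shape-preserving (PCHIP) curves over RWC anchored at the published
class-level means (WW/MS/SS) of the reference campaign, with narrow
transition bands at the RWC 60 and 80 class boundaries. Anchoring at the
class means makes the printed class statistics the configured truth — in
particular the WW→MS fold of mean g_m (~3.3–3.5) and the ~20 % g_s
reduction. The pooled through-origin cubic g_m(g_s) is available as an
alternative coupling (`gm_mode="cubic"`), but it cannot reproduce the
printed class-mean folds (it gives ~2.0–2.3), so it is not the default.

Per observation, the forward model solves the supply–demand system and
generates electron transport consistently with the variable-J inversion,
J_f = 4(A+R_d)(C_c+2Γ*)/(C_c−Γ*), so the whole chain is exactly
invertible: a noiseless campaign recovers g_m, Vcmax, C_i*, R_d and α·β
to machine precision, and the acceptance machinery verifies ≤ 1e-6.

Noise is additive Gaussian on the measured channels only (A, g_s, F_s,
F_m′, RWC) — instrument error, not biological scatter — and C_i is
recomputed from the noisy A and g_s as an open system would. Defaults:
σ_A = 0.25 µmol m⁻² s⁻¹, σ_gs = 0.015 mol m⁻² s⁻¹, σ_F = 5 instrument
units on ~2000, σ_RWC = 1 %. The σ magnitudes were calibrated so the
simulated class-level dispersions match the reference campaign's printed
± values; the well-watered g_m cells are the binding constraint (the
variable-J estimator amplifies channel noise there), and below
σ_A ≈ 0.15 a fluorescence-noise floor dominates, so exact per-genotype
matching is impossible — magnitudes agree across σ_A ∈ [0.15, 0.3].
What the generator does *not* emulate: leaf-to-leaf biological variation
(printed A_N dispersions are slightly wider than simulated ones for this
reason), RuBP-regeneration limitation at high CO2, temperature drift, and
non-Gaussian instrument artefacts. Passing recovery tests therefore
demonstrates correctness of the estimation chain under the stated
instrument model, not robustness to every feature of real data.

Study-design defaults follow the emulated campaign: 12 A/C_i setpoints
(50 → 1500 µmol mol⁻¹ including 380), Laisk sub-curves at PPFD 50/150/300
over six C_a levels 250 → 50 with four replicate sub-curves per
irradiance, an 11-point low-O2 calibration series, four steady-state
readings per leaf-day, and heat-killed-leaf records defining a linear
cuvette-leak line A_leak = k0 + k1·C_a that is added to the measured A of
the steady-state and A/C_i protocols and removed by the pipeline's leak
stage. The rapid g_m(C_i) response uses a gamma-shaped template
g_m(C_i) = g_peak·[(C_i/C_p)·e^{1−C_i/C_p}]^s with C_p = 300 and
s = 1.35, chosen to place the peak in the 200–400 µmol mol⁻¹ window and
give a ~16-fold peak-to-plateau decline at the C_i realised at the
highest setpoint (~1370); each curve point solves the fixed-point system
in which g_m depends on the realised C_i.

A campaign is fully determined by its seed: identical seeds give
byte-identical record tables (fixed float formatting), different seeds
change only the noise draws.

## Pipeline

Stage order: leak correction → Laisk (Γ*, R_d per genotype) → α·β
calibration (which needs R_d, hence after Laisk) → per-point variable-J
g_m → day-level jackknife estimates → Vcmax fits per genotype-day →
limitation partition (raw + WW-normalized, the WW reference being each
genotype's first valid day) → class summaries and empirical regressions
(quadratic g_s(RWC), logarithmic A_N(g_m), through-origin cubic
g_m(g_s)). Stage failures halt with the stage name and offending record
IDs. A JSON manifest (versions, options, fitted constants) plus the seed
reproduces a run byte-identically.

Summary statistics: the coefficient of variation defaults to SD/mean;
an SE-based variant is selectable because published tables sometimes
label their dispersion column S.E. while printing c.v. values consistent
with dispersion/mean. RWC classes are WW [80, 100], MS [60, 80),
SS [40, 60), below 40 out-of-range, with boundary values assigned to the
wetter class. Cells with fewer than two observations are reported as
missing, never imputed.

## Numerical choices and degenerate inputs

- Quadratic root selection: smaller root, stable evaluation; solutions
  must give C_c > 0 or the state is reported infeasible.
- Conservation (A = g_s,CO2(C_a−C_i) = g_m(C_i−C_c)) holds to 1e-9
  relative for every solver output and is property-tested.
- The closed-form Vcmax fit is compared against iterative oracles; note
  that near the optimum the least-squares *objective* is flatter than
  double precision can resolve at the 1e-10 level, so the iterative
  oracle for noisy data finds the root of the analytic gradient by
  bracketing rather than minimising the objective value.
- Fluorescence with F_s > F_m′ is a data error (failed saturating pulse)
  and is reported, not clipped; readers flag such rows with line numbers
  and drop them only in lenient mode.
- Degenerate leaf-water samples (TW = DW) and non-positive conductances
  raise immediately.

## Test problem sizes

The default verification sizes — 21-day, 4-genotype campaigns (~6000
records), 500-replicate Monte-Carlo ensembles, 1000 random solver draws —
were chosen to give stable statistics while keeping the full suite and
the acceptance script each within a few seconds of runtime. Estimator
bias ensembles are evaluated at the pooled well-watered and mild-stress
class states; the severe-stress chain bias (~1–2 %, an input-bias effect
described above) is reported alongside rather than asserted.

## Known limitations

- Variable-J g_m above ~0.5 mol m⁻² s⁻¹ is mean-biased under noise even
  with the jackknife; trust medians and interval summaries there.
- The C_i-basis Vcmax is an apparent value; use `basis="cc"` when a
  credible C_c is available.
- L_S/L_M are a two-way partition: biochemical impairment is folded into
  the mesophyll/non-stomatal component by construction.
- The generator's trajectories are class-anchored templates; per-day
  dehydration dynamics between the anchor classes are interpolation, not
  data.
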