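# Methods

## The transient-ramp measurement model

A steady-flow tubular reactor yields one residence time per experiment.
Decelerating the total flow linearly during a run sweeps residence time
continuously, so a single ramp with periodic online sampling produces a
whole concentration–residence-time profile. The package models this
campaign as follows.

**Velocity and thermal expansion.** The mean tube velocity during a ramp
is u(t) = β(T)(u₀ − α_u t), where α_u is the (velocity-unit)
deceleration and β(T) = 1 + α_v(T₁ − T₀) corrects for the volumetric
thermal expansion of the solvent between ambient T₀ and the reactor
temperature T₁. For ethanol the default α_v = 1.1 × 10⁻³ K⁻¹ (a
literature value near ambient; configurable, since only the functional
form of β is prescribed by the rig model). β multiplies the velocity —
and hence shortens residence times at high temperature — but the inlet
concentrations are kept at their pumped (ambient) values; the package
treats expansion purely as a flow effect, the same convention used on
the rig it emulates.

**Residence time.** A fluid element exiting at clock time t has resided
τ_res satisfying β·∫_{t−τ}^{t} Q(t′) dt′ = V with Q(t′) held at the
pre-ramp value for t′ < 0 (elements that entered during the steady
hold). For linear Q this is a quadratic; the implementation solves for
the *entry time* and takes the root on the physical branch (entry before
the flow would stall), which coincides with the smaller positive τ root
of the τ-form quadratic. When α = 0 this reduces exactly to τ = V/(βQ).
The closed form is unit-tested against bisection on a dense quadrature
of the sweep integral (1 000 random draws, < 10⁻⁶ s).

**Batch-element assumption.** Each exiting element is modelled as a
closed batch reacting for τ_res at the ramp temperature and inlet
composition. For an ideal plug-flow element with constant inlet
composition and temperature this is *exact*: the element's chemistry
depends only on its age, not on its velocity history, so no separate
"high-fidelity" integration along the velocity history is provided —
it would reproduce the same numbers. What the assumption does ignore is
axial dispersion (elements exchanging material), which is treated
separately and deliberately as a *bias analysis* rather than folded into
the forward model (below).

## Reaction network and kinetics

The built-in scheme is the SNAr reaction of 2,4-difluoronitrobenzene
(1) with pyrrolidine (2) in ethanol: parallel substitution to the
*ortho* (3) and *para* (4) mono-adducts and over-reaction of either to
the bis-adduct (5); all four steps are second order (first order in the
aromatic component and in the amine), the motif that wins the shipped
discrimination test. Rates use the reference-temperature Arrhenius form
k(T) = k_ref·exp[−(Eₐ/R)(1/T − 1/T_ref)], T_ref = 363.15 K, which
reports k inside the studied range and strongly decorrelates k and Eₐ
compared to the pre-exponential form. Reference parameters (k_ref in
M⁻¹ s⁻¹ / Eₐ in kJ mol⁻¹): 0.579/33.3, 0.0270/35.3, 0.00865/38.9,
0.0163/44.8 for steps 1–4.

The amine stoichiometry ν (molecules of pyrrolidine consumed per
substitution event) defaults to 1; whether a second equivalent is
sequestered as the hydrofluoride salt is chemically plausible but not
settled, so ν = 2 is configurable. The ODEs conserve the aromatic core
C₁+C₃+C₄+C₅ and the amine combination C₂ + ν(C₃+C₄+2C₅) — property
tests require both to < 10⁻⁹ M on random parameter draws.

Integration uses LSODA with rtol 10⁻⁸, atol 10⁻¹⁰ M. Concentrations are
never clipped inside the right-hand side (the rate law maps negative
round-off to zero rate); clipping to zero happens only on output. The
adaptive solution is cross-checked against a fixed-step classical RK4
oracle at Δτ = 10⁻³ s (< 10⁻⁶ M over 120 s) and against the
pseudo-first-order closed form at large amine excess.

**Default campaign conditions.** Substrate inlet concentration
C₁,₀ = 0.1 M (delivered as a 0.4 M stock at a fixed 25 % flow fraction;
the true campaign value is not in the public record, and 0.1 M is a
typical mesoscale screening concentration — it sets the absolute scale
of the profiles but not the identifiability structure). Amine stock
2.0 M, pump split solved per ramp to hit equivalents 1.5/4/7.
Temperatures 30/60/90/120 °C. Flow 10 → 1.5 mL min⁻¹ at
0.836 mL min⁻², injections every 2 min from ramp onset: 6 per ramp,
72 points, residence times ≈ 0.45–2 min.

## Noise model

HPLC repeatability is emulated as independent Gaussian noise with
sd = max(relative_sd·C, absolute_sd), truncated at zero, defaults 2 %
relative with a 10⁻⁴ M floor — a conventional surrogate; no published
error model exists for the emulated instrument. The generator is
seed-deterministic and bit-reproducible. What it does *not* emulate:
injection carry-over, drift, calibration error correlated across
species, or the short-τ transients that make points below ≈0.5 min
unusable on a real rig (the default schedule simply never samples
them). Passing recovery tests on this generator therefore demonstrates
correctness of the estimator under its stated assumptions, not
robustness to structured instrument error.

## Global fitting

All species at all injections enter one least-squares problem with equal
absolute weights (a relative-weighting flag exists); by default the
residual uses the four aromatic species, matching what an HPLC assay
measures. Optimisation is Levenberg–Marquardt (lmfit/MINPACK) over
log k_ref (positivity by construction, bounds 10⁻⁶–10³ M⁻¹ s⁻¹) and
linear Eₐ (bounds 0–200 kJ mol⁻¹), tolerances xtol = ftol = 10⁻¹⁰. The
recommended two-stage protocol first fits the four rate constants on the
90 °C ramps — where the model is exactly independent of Eₐ — then
refines all 8 parameters globally; tests confirm it reaches the same
optimum as a direct global fit and that multistart refits agree.

Uncertainty is the linearised covariance s²(JᵀJ)⁻¹ at the optimum
(s² = SSE/dof), mapped to the natural scale by the delta method
(SE(k) = k·SE(ln k)) with Student-t 95 % half-widths. A Monte-Carlo
calibration test (25 replicate noisy campaigns on a reduced
3-temperature × 2-equivalents design, chosen to keep the suite fast)
checks the empirical scatter of k₁ against the mean reported SE within
a factor 1.5. With data at a single temperature equal to T_ref the
Jacobian column for Eₐ is identically zero; the covariance is then
singular and the uncertainty request raises an identifiability error by
design. R² = 1 − SSE/SStot with SStot about the grand mean of all
measured concentrations pooled across species (stated convention;
R² values from other poolings are not comparable).

Rate-order discrimination refits each candidate motif (orders 0/1/2 in
either reactant, applied uniformly across steps — a superset of any
plausible mechanistic shortlist) and ranks by SSE and by AICc computed
from the least-squares likelihood.

## Dispersion analysis

Dimensionless groups: Re = ρud_t/μ, Sc = μ/(ρD_m),
De = Re·√(d_t/d_c), and the coil-dispersion correlating group
De·Sc^0.5. The coil *winding* diameter d_c has no credible default (it
is often confused with the tube ID) and is a required input for
Dean-number work; everything else runs without it.

**Taylor–Aris.** D_s = D_m + κ·d_t²u²/(192·D_m), with κ ∈ (0, 1] the
coil-to-straight-tube dispersion ratio (Dean vortices improve radial
mixing, so κ < 1 in coils). The shipped κ(De·Sc^0.5) table is an
approximate, clearly-labelled log-log digitization of the literature
trend and is user-replaceable; nothing quantitative in the package
depends on its exact values except through self-consistent round trips.

**Closed-vessel conversion.** The first-order dispersed-plug-flow
solution 1 − X = 4a·e^{(1−a)/(2N)} / [(1+a)² − (1−a)²e^{−a/N}],
a = √(1+4kτN), written in overflow-safe form. N = D_s/(uL) is called
`dispersion_number` throughout because it is the *reciprocal* of the
conventional Péclet number — the literature this implements labels it
Pe, an ambiguity worth being explicit about. Limits are tested: N → 0
recovers plug flow 1 − e^{−kτ}, N → ∞ the perfectly mixed kτ/(1+kτ);
the quadratic small-N series for a agrees with the exact solution to
O(N²).

**Rate-constant bias.** A plug-flow analysis of dispersed data
under-estimates k. The package evaluates the fractional bias as
ε = −κ·Da_r / 250 with Da_r = k·d_t²/D_m, i.e. ε/(κk) = −500 % · s for
a 1 mm tube in ethanol (D_m = 0.8 × 10⁻⁹ m² s⁻¹) — the published
closed-form evaluation for this geometry, pinned by a unit test. Note
a first-principles small-dispersion expansion of the closed-vessel
solution combined with the straight-tube Taylor–Aris coefficient gives
a denominator of 192 (≈30 % larger bias); the package keeps the
published constant as the default but exposes `bias_denominator` so
users can adopt the theoretical value. Either way the qualitative
content is identical and property-tested: ε ≤ 0 always, |ε| increasing
in κ, k and d_t²/D_m, and u cancels at leading order.

**F-curve.** κ is estimated from a measured step response by fitting
the small-dispersion closed-vessel model F(θ) = ½·erfc[(1−θ)/(2√(Nθ))]
for N and converting D_s = N·u·L to κ against the straight-tube
Taylor–Aris value. At the 6-min reference operating point N ≤ 0.012
for all κ ≤ 1, well inside the regime where all boundary-condition
variants of the dispersion model coincide, so the analytic form is
adequate for both generation and fitting; round-trip tests recover
κ ∈ {0.05, 0.15, 0.31, 1.0} to < 3 %. A front sharper than the
sampling grid returns κ ≈ 0 with an under-resolution warning.

**Campaign report.** Per profile, the substitutions are lumped to the
pseudo-first-order k₁₂ = (k₁+k₂)·C₂,₀ (valid at amine excess) and the
over-reactions to k₃₄ = (k₃+k₄)·C₂,₀; ε is evaluated at the profile's
mean velocity with a single conservative κ (default 0.15). Profiles
whose reacting-component concentration range is below 5 % of C₁,₀
(fully converted, or unreacted) cannot inform the corresponding rate
constant and are masked rather than reported.

## Problem sizes and determinism

The default test suite runs the full 12-ramp campaign once for the
recovery/acceptance checks and uses reduced designs (isothermal 90 °C,
or 3 temperatures × 2 equivalents) for the expensive repeated fits:
discrimination, multistart, and the 25-campaign Monte-Carlo
calibration. All stochastic tests and artifacts are seeded;
regenerating any table with the same config and seed is bit-identical,
and every CSV/JSON artifact embeds a short hash of the fully resolved
configuration.

## Known limitations

- The dispersion bias is a first-order (small-N) estimate for a
  *first-order* reaction applied to lumped pseudo-first-order constants;
  it is a diagnostic, not a correction, and is unreliable once
  |ε| ≳ 50 % (a warning fires).
- The forward model omits axial dispersion, pump pulsation, pressure
  effects and within-ramp temperature transients; the short-τ regime
  (< 0.5 min) where such transients dominate on real rigs is simply not
  sampled by the default schedule.
- The κ correlation table is approximate and for orientation only.
- Solvent physical properties are constants (25 °C ethanol defaults);
  temperature-dependent property tables must be supplied by the user if
  they matter at the hot end of a campaign.
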