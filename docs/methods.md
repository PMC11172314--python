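# Methods

This note documents the models implemented in `abskit`, the defaults they
use, the synthetic-data generators that stand in for raw instrument output,
and the numerical choices made where the underlying procedures were
genuinely open.

## Binodal curves (`abskit.binodal`)

The solubility boundary of an aqueous biphasic system in the
(X = non-IL wt%, Y = IL wt%) plane is modelled with the three-parameter
Merchuck curve

    Y = A · exp(B·X^0.5 − C·X³).

A literal polynomial variant `Y = A·(B·X^0.5 − C·X³)` is kept behind
`form="literal"` because some sources typeset the equation without the
exponential; it cannot produce sigmoidal binodals and is not the default.
Fitting is plain least squares in wt% coordinates (molality-axis diagrams
are a coordinate conversion of the fitted curve, never a refit) over a
deterministic multi-start grid of (B, C) magnitudes and sign patterns with
Levenberg–Marquardt refinement (lmfit); the best candidate by RSS wins, so
repeated fits of the same data are bit-identical. Mixtures are classified
biphasic when their IL content exceeds the curve at their X by more than
1e-6 wt% — a purely numerical tolerance, far below the ±1e-4 g gravimetric
resolution of cloud-point titration.

## Tie-lines (`abskit.tielines`)

A biphasic mixture (Xm, Ym) with IL-rich phase-mass fraction α (IL-rich
phase mass over total mixture mass — note some ATPS literature uses the
top-phase fraction instead; that convention is the complement 1−α and is
never applied silently here) splits into two endpoints that both lie on the
binodal and close the lever rule on each axis. Substituting the X mass
balance `X_IL = (Xm − (1−α)·X_non)/α` into the Y balance reduces the
four-equation system to a single equation in `X_non`. That root is found by
scanning the admissible interval `[Xm, min(Xm/(1−α), 100)]` (the non-IL-rich
phase is richer in the second phase former, and X_IL must stay ≥ 0) for a
sign change and polishing with Brent's method at machine tolerance. This
was chosen over a damped Newton iteration on the 2-unknown system because
the 1-D reduction is exact, deterministic, and globally convergent wherever
a physical solution exists; a Newton scheme needs damping and bracket
restarts to achieve the same. Solutions with any coordinate outside
[0, 100] wt%, coincident endpoints (mixture effectively on the binodal) or
back-substitution residuals above 1e-8 are rejected with diagnostics. The
IL-rich endpoint is identified as the one with larger Y; tie-line length is
the Euclidean distance in wt% units and the slope ΔY/ΔX (a vertical
tie-line reports an infinite-slope sentinel with a flag).

## Extraction efficiency (`abskit.partition`)

%EE = 100·m_ILrp/(m_ILrp + m_non-ILrp) is always referenced to the IL/FIL-
rich phase, so %EE(a,b) + %EE(b,a) = 100 exactly and "which phase is
enriched" is a derived label (%EE ≥ 50) rather than a sign convention.
Replicate uncertainty is the SD over per-replicate %EE values (the assay is
replicated as whole experiments, not as per-phase error models) and is
reported only for ≥ 2 replicates. Concentration quantification uses an OLS
calibration line with inverse prediction that refuses to extrapolate more
than 10% beyond the calibrated concentration range.

## MST binding (`abskit.binding`)

Serial dilutions follow conc_i = start/ratio^i (16 points, ratio 2 by
default; a 16-point series from 100 mM ends at 3.0518×10⁻³ mM). The bound
fraction of the labeled target uses the exact 1:1 quadratic mass-action
solution rather than the hyperbola L/(L+Kd): the target here (0.41 μM) is
far below every fitted Kd, where the two agree to <0.1%, but the quadratic
is correct in all regimes and matches the semantics of vendor "Kd model"
fits. The fit estimates (Kd, f_unbound, f_bound) by Levenberg–Marquardt
with the two plateaus free (MST normalisation fixes the scale of Fnorm, not
the plateaus); Kd standard errors come from the Jacobian. Capillaries above
50 mM ligand are excluded before fitting (fluorescence inhomogeneity at
high surfactant-IL concentration); at least 8 points spanning ≥ 2 decades
are required.

Binding is declared only when the response amplitude *expressed over the
measured concentration range* — |f_bound − f_unbound| times the span of the
fitted bound fraction across the titrated ligand range — exceeds 3× the
residual SD. Using the expressed amplitude, not the raw plateau difference,
matters: on a flat series the optimiser can push Kd far outside the
titrated range, making the bound fraction nearly constant and the plateau
difference an unidentifiable noise amplifier. The 3σ threshold is this
package's own operational criterion for the qualitative call "no binding
detected".

## DSC two-state fitting (`abskit.dsc`)

A two-state unfolding equilibrium with van't Hoff enthalpy ΔH (kJ/mol) and
midpoint Tm gives K(T) = exp((ΔH/R)(1/Tm − 1/T)) (Kelvin internally,
Celsius at every interface), unfolded fraction fu = K/(1+K) and excess heat
capacity

    Cp_exc(T) = s · ΔH²/(R T²) · K/(1+K)² = s · ΔH · dfu/dT,

so the peak area is s·ΔH and its maximum sits at Tm to first order. The
single amplitude factor `s` absorbs the instrument's (unstated) signal
normalisation, which is why Tm and ΔH are invariant to signal units. This
functional form is our reconstruction of the scaled two-state model that
commercial DSC software fits; reports label it as such. Derived quantities
use ΔS = ΔH/Tm and ΔG(T) = ΔH − T·ΔS, which vanishes at Tm by construction.

Baseline removal fits a cubic (default) polynomial to points outside an
exclusion window — argmax ± 8 °C on the first pass, re-centred once on the
fitted Tm — and subtracts it everywhere. Fitting requires a peak exceeding
3× the off-peak noise SD and ≥ 50 grid points; Tm is initialised at the
signal argmax and ΔH from the height/area ratio (height = s·ΔH²/4RT²,
area = s·ΔH). Multi-transition scans fit a sum of k ≤ 4 components jointly,
initialised from detected local maxima (topped up with an even spread when
fewer than k peaks are resolvable), and report AICc against the (k−1)-
component alternative.

## Activity (`abskit.activity`)

Lysozyme activity is the OLS slope of A450 vs time over the full 5-minute
window (no automatic linear-range selection — the assay monitors a fixed
window), with r² < 0.9 flagged as nonlinear decay. Relative activity is
100 × mean sample slope / mean reference slope, clipped at 0 for
non-decaying samples; the reference must itself decay. Replicate SD is
taken over all sample/reference slope pairings.

## Synthetic data (`abskit.simulate`)

Every generator draws from one seeded numpy Generator and reproduces the
generating model exactly at zero noise, giving each analysis stage a
forward-construction oracle. Defaults represent the study conditions:

- **Binodal**: 20 points, x log-uniform on [0.1, 25] wt%, Gaussian y-noise
  of 0.5 wt% SD (generous relative to ±1e-4 g gravimetry; chosen so noisy-
  fit consistency is tested under visible scatter).
- **Partition**: protein mass split by the true %EE, converted to per-phase
  concentrations through the phase volumes, with 2% CV multiplicative
  lognormal concentration noise, in triplicate.
- **Titration**: 16-point 1:1 dilution, target 4.1×10⁻⁴ mM (0.41 μM;
  a methods section elsewhere states 0.4 μM — the 0.41 value is used and
  the discrepancy is immaterial since target ≪ Kd), plateaus
  f_unbound = 1.0 and f_bound = 1.5 (Fnorm is normalised to initial
  fluorescence, so O(1) levels with a 0.5 amplitude), Gaussian noise
  SD 0.02 in Fnorm units (≈ 4% of the amplitude). A no-binding mode
  collapses the amplitude to zero.
- **Thermogram**: 20–90 °C grid at 0.1 °C, sum of two-state components on a
  polynomial baseline plus Gaussian noise. The single-transition default
  ΔH is 440 kJ/mol (literature calorimetric value for hen lysozyme). For
  the three-transition scenario (components 3.3 °C apart) the per-component
  ΔH is set to 1500 kJ/mol so the components appear as three distinct local
  maxima, as sharp cooperative transitions of protein–aggregate complexes
  do; with lysozyme-like 440 kJ/mol peaks (FWHM ≈ 4RTm²/ΔH ≈ 9 °C) the
  triplet would merge into one hump.
- **Activity**: linear traces, reference slope −1×10⁻³ absorbance/s from a
  0.7 start (full clearing over the 5-minute window), noise SD 0.005,
  triplicate.

What the generators do **not** emulate: real cloud-point titrations scatter
along the titration path rather than vertically; MST capillaries have
concentration-dependent noise and photobleaching drift; DSC baselines can
drift nonpolynomially and transitions can be kinetically scan-rate
dependent; turbidity decays saturate as substrate depletes. Passing
recovery tests therefore demonstrates correctness of the estimators under
their stated noise models, not robustness to every instrument artefact.

## Problem sizes

Stochastic recovery checks use 200 replicates for titration and binodal
fits, 50 for single thermograms and 100 random tie-line constructions —
enough for stable medians from sub-second fits while keeping the whole
suite fast.

## Known limitations

- The binodal form is empirical; no temperature dependence, no alternative
  four-parameter variants, no plait-point estimation.
- Tie-lines assume the fitted binodal is exact; binodal fit error is not
  propagated into endpoint uncertainty.
- The Kd confidence interval is a Jacobian-based standard error, comparable
  to but not an exact reimplementation of vendor dispersion estimates.
- The DSC fit is equilibrium two-state; kinetic (scan-rate-dependent)
  unfolding and absolute heat-capacity calibration are out of scope.
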