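# Methods

## Physical model

### Kinematics and constants

Electrons are treated fully relativistically: β² = 1 − (E₀/(E+E₀))²,
γ₀ = E/E₀ + 1, λ = hc/√(E(E+2E₀)), with hc = 1239.842 eV·nm,
E₀ = 511 keV, and a_H = 0.0529 nm. At 3 MeV λ = 0.357 pm, in agreement
with the 0.36 pm design value quoted for the column optics to two
significant figures.

### Elastic scattering

The Wentzel screened-Rutherford differential cross-section in the first
Born approximation, with Thomas–Fermi screening radius
R = a_H·Z^(−1/3). Its characteristic angle (the median of the
solid-angle-weighted distribution) is available in closed form,
θ_el = λ/(2πR); the numerical median on the fine grid agrees with the
closed form to a few parts in 10⁴, the residual coming from the [0, π]
normalisation and the sin θ weight. For water the sampling distribution
is the stoichiometric sum σ_O(θ) + 2σ_H(θ); the *tabulated*
characteristic angle uses Z = 8 (oxygen), which is the convention that
reproduces the reference table (the hydrogen share pulls the molecular
median about 7 % lower — both numbers are available).

### Inelastic scattering

The printed source equation for the inelastic angular form is
typographically corrupted; we adopt the canonical Lenz/Bethe form

    dσ_inel/dΩ ∝ Zλ⁴γ₀²·[1 − (1 + (θ²+θ_E²)/θ₀²)⁻²]/(θ²+θ_E²)²,

with θ₀ the elastic screening angle λ/(2πR) and
θ_E = (ΔE/E)(E+E₀)/(E+2E₀), ΔE = 39.3 eV per event. This reproduces the
reference θ_inel at 300 keV within 6 %, but sits 15–22 % below the
reference values at 1–30 MeV. The discrepancy cannot be removed within
this model family: for *any* angular form parameterised by the two
scales (θ_E, θ₀), the ratio median/√(θ_E·θ₀) is a function of
ln(θ₀/θ_E) alone, and that logarithm is nearly identical at 300 keV
(4.99) and 10 MeV (5.25) while the reference medians imply ratios of
0.83 and 1.12. We therefore keep the canonical form and report the
residual rather than distorting the model. Downstream quantities are
insensitive at the relevant level: θ_eff combines θ_inel with weight
0.75 against 0.25·θ_el, so a 20 % θ_inel deficit moves θ_eff by ≲4 %.

Energy loss is not propagated into the kinematics (ΔE/E ≤ 10⁻⁴ above
1 MeV); ΔE enters only through θ_E.

### Totals and rates

The default total-cross-section mode enforces σ_inel = 3σ_el, the ratio
appropriate for light-element (C/N/O) targets and the one used both by
the transport and by θ_eff. A diagnostic "formula" mode evaluates the
printed closed form 1.5×10⁻⁶·√Z/β²·ln(2/θ_c) with the 110 % molecular
scaling; its prefactor is not dimensionally annotated in the source, so
the output is treated as nm² and excluded from exact comparisons.
Per-length rates are K_i = σ_i·n with n the molecular number density
from the mass density (30.8 molecules/nm³ for ice at 0.92 g/cm³). These
reproduce the ~1 μm inelastic mean free path at 10 MeV within 5 %
without any tuning, which is the model constant the broadening law uses.

## Monte Carlo transport

Slice stepping with dt = 0.5 nm: a per-slice categorical draw
(elastic / inelastic / none) with P_i = K_i·dt, followed by an
inverse-CDF polar-angle draw on the graded grid (0.001 mrad bins below
0.6 mrad, then 0.01/0.1/1/10 mrad bins up to π) with linear in-bin
interpolation. The guard (K_el+K_inel)·dt < 0.1 keeps the Bernoulli
step faithful to the underlying Poisson process at the <1 % per-MFP
level; a direct exponential free-path sampler is provided and is
statistically indistinguishable in the tests (two-sample KS).

Geometry. The physical default `full_3d` samples a uniform azimuth and
rotates the direction vector exactly (at mrad angles this agrees with
small-angle addition to <10⁻⁶ relative, and stays valid for the rare
large-angle event). The `planar_2d` mode models the single transverse
cross-section through the beam: each event deflects the in-plane angle
by θ·cos φ, the projection of the 3D deflection, which makes the planar
run the exact marginal of the 3D one. A ±θ convention was rejected —
it overstates lateral growth by √2 relative to what a beam cross-section
observes.

Bookkeeping. Electrons are never absorbed. Five mutually exclusive
history channels partition the ensemble at every recorded depth
(unscattered, single elastic, multiple elastic, ≥1 inelastic, and
"undetected" once the trajectory angle has exceeded the detector
half-angle, 10 mrad by default; the cut is configurable since the source
does not state one). The beam radius at depth t is the smallest disc
(interval in planar mode) about the optic axis containing 68 % of all
electrons at that depth — the empirical 0.68 quantile with the
`inverted_cdf` convention, so the excluded 32 % tail cannot move it.
Whether undetected electrons should be excluded from the disc is not
specified by the source; both modes are implemented, "all" is the
default. Snapshots are recorded every 100 slices (50 nm) to bound
memory; per-slice recording is available.

The probe enters as independent per-axis Gaussians at the waist
(σ = 1 nm per axis, σ′ = 1 mrad — "RMS size of a nanometre" is read as
per-axis) ballistically back-propagated to the surface, x ← x − t_f·x′.

## Broadening budget and calibration

σ_tot(t)² = σ_AB(t)² + σ_EC² + σ_SB(t)² with σ_AB = |t−t_f|·α,
σ_EC = 1.0 nm (constant; an override accepts the optics-module waist),
and σ_SB = a·e^(b·t/MFP) + c, MFP = 1 μm. Budgets are evaluated on 1000
uniform depth points; the curves are smooth, so the grid max is within
0.1 % of the true max.

Calibration. The scattering-only residual of an MC profile is
√max(r68² − σ_AB² − σ_EC², 0) (negative values clamped to zero); the
quadrature decomposition itself dictates this subtraction, which the
source leaves implicit. Least squares (`scipy.optimize.least_squares`)
fits a, c and a single proportionality k with b_j = k·θ_eff,j shared
across energies (a per-energy option exists). Fit windows follow the
source: ≤1 μm at 0.3 MeV, ≤4 μm at 3 MeV, ≤5 μm at 10 MeV (closed upper
bounds). On this package's own 10 MeV run the fit recovers
k ≈ 1.08×10³, consistent with the published b ≅ 10³·θ_eff, and
a + c ≈ 0, i.e. no scattering broadening at zero depth once the waist is
subtracted.

Benchmark assembly. The published constants round to a ≅ 1 nm with
c ≅ 0 — numerically equal to σ_EC. That means the published σ_SB carries
the waist floor inside it; assembling the full three-term quadrature
with those constants would count the waist twice and force an
irreducible −29 % deviation at t → 0 against any MC beam that contains
the waist once. The MC/analytic benchmark therefore compares the MC
radius against √(σ_AB² + σ_SB²) when using the published constants; with
that reading the 10 MeV/8 μm comparison agrees to ~11 % everywhere.
Resolution budgets and the optimiser keep the full three-term quadrature
(there the extra 1 nm² is conservative and negligible at the
worst-depth maximum).

Energy optimiser. Minimum grid energy (default grid 3, 10, 15, 20, 30,
100 MeV) whose worst-depth σ_tot with the probe focused at T/2 meets the
tolerance (default 10 nm). Note that at T = 20 μm the geometric term
alone reaches (T/2)·α = 10 nm, so the 10 nm goal there is meaningful
only with a modest margin; with a 10 % margin the least sufficient grid
energy is 30 MeV, and no grid energy meets a 5 nm goal.

## Optics and dose

Waist components as quoted: σ_d = 0.61λ/α, σ_s = C_s α³/4,
σ_c = C_c α·(ΔE/E), σ_emit = ε_geo/α (ε_geo defined as the waist
size–divergence product; ε_geo = ε_n/γ₀). λ always comes from the
kinematics rather than a hard-coded 0.36 pm, keeping the budget valid
over the 3–10 MeV tuning range. No alternative aberration-coefficient
conventions are offered. The quoted minimum δ_th = 0.52 nm at
α = 0.6 mrad reflects component-wise rounding (√(0.37²+0.01²+0.36²) =
0.516); the unrounded quadrature sum is 0.511 at the scan optimum
α ≈ 0.61 mrad. The source quotes both a 100 eV energy spread and
ΔE/E = 3.3×10⁻⁵, consistent only at 3 MeV; the dimensionless value is
primary. At 10 MeV (spread 100 eV, ε_geo = ε_n/γ₀) the waist at the
demagnified operating point comes out 1.0 nm within 10 %, closing the
loop with the σ_EC constant; at 3 MeV the chromatic term with the fixed
3.3×10⁻⁵ spread makes the achievable waist ~1.3–1.6 nm, so the 1 nm
σ_EC is nominal there.

Dose-limited resolution uses δ = 2·SNR/(C·√(DQE·F·D_c)) — the only
reading of the (corrupted) printed expression that reproduces both
quoted values — with the per-image fluence of 2 e⁻/Å² as the default
D_c; the tilt-series total (100 e⁻/Å²) is exposed as a constant but the
two quoted resolutions (1.5 nm at C = 0.4, 6.0 nm at C = 0.1) follow
from the per-image value. Contrast is |ρ_f − ρ_b|/ρ_b.

## What the tests do and do not show

The stochastic tests run the same generator-free configurations the
study states — 10⁴ electrons, dt = 0.5 nm, waist 1 nm/1 mrad — at
reduced thicknesses (0.1–1 μm) for the distributional properties and at
the full 8 μm/16,000-slice scale for the MC/analytic benchmark; seeded
RNGs make every assertion reproducible, with multiplicity-aware binomial
bounds where many correlated depths are checked at once. Passing them
shows internal consistency of the transport with its input
cross-sections and with the analytic budget — not agreement with
experimental beam profiles: the model has no energy loss tracking, no
Mott/spin corrections, no solid-state structure factors, and a single
mean energy loss instead of a loss spectrum.

## Known limitations

- The Lenz/Bethe inelastic medians sit 15–22 % below the reference
  table above 1 MeV (see above); θ_eff, the quantity that matters
  downstream, is affected at the ≲4 % level.
- The enforced σ_inel = 3σ_el ratio is a light-element approximation;
  the formula mode's absolute inelastic scale is dimensionally
  uncertain and used for diagnostics only.
- Transport assumes a homogeneous material; adapting to other materials
  scales the rates by mass density (and stoichiometry), not by a full
  per-element inelastic model.
- Dose and beam-size budgets are proxies; feature resolvability in real
  tomograms (CTF, detector MTF, reconstruction) is out of scope.
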