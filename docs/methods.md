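# Methods

## Forward model

The dielectric core uses the convention ε* = ε₀ε_r − j·σ/ω with ω = 2πf
and ε₀ = 8.854×10⁻¹² F/m.  Cells are single-shell spheres only: a
cytoplasm core (ε_cyt, σ_cyt) inside one membrane shell.  The membrane is
parameterised by its specific capacitance C_m (F/m²) and conductance G_m
(S/m²); the fixed thickness d = 5 nm only converts these to shell material
properties (ε_mem = C_m·d/ε₀, σ_mem = G_m·d) and is never fitted — the
spectra constrain the thickness-normalised quantities, not d itself.
Nucleated (multi-shell) geometries, spheroidal eccentricity and
field-gradient computation are out of scope; the spherical assumption is
also used for all surface-area conversions, which for near-spherical
suspended cells changes whole-cell values by far less than the biological
spread.

The suspending medium defaults to ε_r = 78 (aqueous); its conductivity is
an experimental input (10 mS/m for the standard iso-osmotic medium, up to
800 mS/m in the high-conductivity platelet conditions).

Crossover frequencies (sign changes of Re[f_CM]) are located by a dense
4000-point logarithmic scan followed by Brent refinement; a spectrum whose
maximum |Re[f_CM]| is below 10⁻⁹ is treated as everywhere-zero (cell
indistinguishable from medium) and reports no crossovers.

## Inverse problem

Fits minimise squared residuals between a measured spectrum and
α·Σ_k w_k·Re[f_CM,k(f)] using Levenberg–Marquardt (lmfit/MINPACK).
Design choices, all of which matter in practice:

* **Log-space parameters.**  C_m, G_m, σ_cyt, radius and the scale α are
  fitted as log₁₀ values: they are strictly positive and plausible ranges
  span decades.  ε_cyt is fitted linearly within bounds.
* **Radius fixed.**  The radius comes from an independent optical
  measurement (typically the mean of ~100 cells) and is fixed by default;
  it can be freed per `FitConfig.free`.
* **Default free parameters** per population: C_m, G_m, σ_cyt, ε_cyt,
  plus one global α; mixture weights are free for K > 1.
* **Bounds as physical priors.**  Default bounds restrict the search to
  living-cell ranges (C_m 1–100 mF/m², G_m 0.01–2×10⁵ S/m², σ_cyt
  0.01–2.5 S/m, ε_cyt 20–150, α 10⁻⁶–10⁶).  This is not cosmetic: a
  20-point spectrum determines a single-shell cell only up to a discrete
  *swapped-interface* ambiguity — a nearly insulating, high-permittivity
  core inside a highly conductive membrane reproduces the same two
  dispersions essentially exactly within the instrument band.  The bounds
  select the physical branch.
* **Multi-start.**  `n_restarts` initial guesses are drawn log-uniformly
  within bounds from a seeded generator; the first start uses
  bound-midpoints (or user-supplied `initial` values).  Best final
  residual wins; ties go to the first found.
* **Stall polishing.**  These objectives have long, curved, extremely
  ill-conditioned valleys (sloppy C_m/G_m/α combinations) on which MINPACK
  terminates prematurely.  Three escapes are layered: iterated restarts
  from the incumbent (which reset MINPACK's internal scaling), a
  warm-started profile walk that steps each free parameter in fixed
  increments while re-optimising the rest, and single coordinate jumps
  followed by full refits.  Only fully re-optimised improvements are
  accepted, so the procedure cannot leave the feasible region or accept a
  worse fit.  On noiseless synthetic spectra this combination recovers
  all generating parameters of every shipped preset to ≤10⁻⁶ relative.
* **Weights on the simplex.**  Mixture weights use fixed-anchor logits
  (w_k = e^{l_k}/Σe^{l_j}, l_1 ≡ 0), keeping Σw_k = 1 exactly so that the
  global scale α remains identifiable.  Recovered components are reported
  in ascending σ_cyt so populations are comparable across runs; if two
  recovered components agree in every parameter within 1 % the result is
  flagged `weight_degenerate` (their individual weights carry no
  information).
* **Weighting.**  Unweighted least squares by default; inverse-variance
  weights when the spectrum carries per-point standard deviations.
* **Goodness of fit** for spectra is the squared Pearson correlation
  between data and model — the convention used for instrument spectra —
  not 1 − SSres/SStot.

### Identifiability at realistic noise

With 3 % additive noise on a 20-point spectrum of a low-conductance cell
(G_m ≈ 25 S/m²), C_m and σ_cyt are recovered to a few per cent but G_m and
ε_cyt are weakly identifiable: G_m·r is orders of magnitude below the
medium conductivity, so its imprint on the spectrum is tiny, and the
ε_cyt-sensitive high-frequency dispersion is only partially inside the
1 kHz–45 MHz band.  Tests and acceptance checks therefore assert recovery
of the well-identified parameters (C_m, σ_cyt); G_m and ε_cyt require
noiseless data (where they are recovered exactly) or heavy averaging.

The 90/10 mixture benchmark reflects its source procedure: fifteen
replicate spectra at 1 % noise are averaged before decomposition, the two
populations share C_m and ε_cyt (the minority is the majority parameter
set with σ_cyt reduced by 85 % and G_m halved), and the distinguishing
parameters (σ_cyt, G_m per component), the weights and α are free.  Under
these conditions the majority weight is recovered within ±0.01–0.05 across
seeds.

## Interleaved high-resolution spectra

For n points log-spaced over [f_min, f_max] split across c chips, the chip
shift factor is (adjacent-point ratio)^(1/c); chip k carries the base grid
multiplied by factor^k, and the merged grids form one uniformly log-spaced
grid of n·c points.  Twenty points over 1 kHz–40 MHz with five chips give
the factor 1.118 (a 45 MHz span gives 1.119; the planner takes the span as
input).  Merging collapses duplicate frequencies to their mean with a
warning.  On synthetic data, fits of 20-point and interleaved 100-point
spectra agree to the fitter tolerance — consistent with ~5 points/decade
resolving dispersions that each take about a decade to complete.

## Well densitometry

Ten equal-radial-width annuli partition the well disc (pixel-centre
membership, half-open bins); per-ring relative areas follow the
(2k−1)/n² annulus pattern, so the outermost of ten rings holds 19 % of the
disc.  The polarisability index is

    index = Σ_k s_k · a_k · slope_k · T

where slope_k is the least-squares slope of fractional absorbance
(I_k(0) − I_k(t))/I_k(0) over the analysis window of length T, a_k is the
ring's relative area, and s_k is +1 for the outer five rings, −1 for the
inner five.  Using *absorbance* (not raw intensity) makes the stated sign
convention hold under attenuation imaging: cells accumulating at the wall
(positive DEP) raise outer-ring absorbance and give a positive index.
The index is the fitted net change over the window, so in the linear
regime it doubles when the window doubles; the standard window is 10 s,
beyond which the response saturates as cells reach the boundaries.

### Simulator

The seeded simulator emulates what the instrument sees, not its optics:
particles start uniformly over the disc and advect radially with
v(ρ) = v₀·Re[f_CM]·ρ/R — the simplest axisymmetric profile vanishing on
the axis — with reflecting boundaries and ten Euler substeps per 1 s
frame.  v₀ defaults to 0.005·R/s so that even |Re[f_CM]| = 1 displaces
cells by ≤5 % of the well radius over the standard window, keeping the
response in its linear regime.  Frames are Beer–Lambert attenuation of a
unit background; each particle deposits a Gaussian optical-depth footprint
(σ = 1.5 px, peak depth 0.05), and a wall margin of 2σ keeps footprints
inside the disc so total absorbance is conserved while cells move.
Everything derives from one `numpy` generator seed and is bit-reproducible.

What the simulator does *not* model: meniscus and ambient-light artefacts,
electrode ageing, Brownian motion, cell size dispersion, vertical motion,
and the exact intensity-to-force scaling of the real reader.  The index is
therefore proportional, not equal, to the instrument's; passing tests show
internal consistency of the image pipeline (sign, linearity, ~±10 %
proportionality to Re[f_CM], and closure of the image → spectrum →
parameter loop for C_m and σ_cyt within 10 % when three replicate wells
are averaged per frequency), not equivalence to hardware.

## Whole-cell conversions

C_whole = C_m·4πr² and G_whole = G_m·4πr² (and their inverses) are exact
products; specific membrane resistance is (1/G_m)·10 in kΩ·cm².  Note an
internal inconsistency of the benchmark numbers themselves: G_m = 25 S/m²
at r = 6.5 µm gives 13.3 nS and 0.40 kΩ·cm², versus the printed 11.3 nS
and 0.45 kΩ·cm²; the conversions here are exact and the discrepancy is
treated as source rounding (the consistency test allows 10 %).  Report
output rounds to 2–3 significant figures; full precision is kept
internally.

## Cosinor rhythm analysis

y(t) = M + A·cos(2πt/τ + φ) with τ fixed (taken from behavioural
actigraphy; ultradian periods of 1.47–1.55 h in the blood-sampling design
of 9 points over 4 h).  The model is linearised to M + β·cos ωt + γ·sin ωt
and solved by ordinary least squares; A = √(β²+γ²) ≥ 0 and
φ = atan2(−γ, β) wrapped to [0, 2π).  Goodness of fit is the *non-linear*
r² = 1 − SSres/SStot — deliberately different from the Pearson r² used for
spectra, and reported as NaN for zero-variance series.  Known property:
on noisy data the amplitude estimate is positively biased (Â > 0 even for
A = 0); tests check this qualitatively.  The counterphase check wraps the
acrophase difference to (−π, π] and flags |Δφ| > π/2; it requires equal
fixed periods.  Sampling designs shorter than one period produce a warning
rather than an error.

## Synthetic data

`generate_spectrum` adds Gaussian noise with sd equal to a fraction of the
peak |response| (default 3 %, a calibration chosen so that 15-replicate
averages fit with r² > 0.99 under the standard conditions); zero noise
reproduces the forward model bit-for-bit.  `generate_rhythm_series`
defaults to the 30-minute/4-hour blood-sampling design.  Presets ship the
benchmark parameter sets (Jurkat majority and damaged minority, platelets
in 200/400/800 mS/m media, RBC, HL-1); where only whole-cell values are
reported the specific values are back-computed through 4πr² and the
presets file labels them synthetic, as it does the assumed HL-1 radius.
All generators are bit-reproducible under fixed seeds.

## Problem sizes used in tests and the acceptance script

Spectra are 20 points (1 kHz–45 MHz, 5/decade) with 15 replicates where
averaging is exercised; mixtures use 2 components; well simulations use
500–2000 particles in a 128×128 px frame (60 px well radius), 10-s
sequences at 1 frame/s, with 3 replicate wells per frequency for the full
image-to-parameter round trip; rhythm series use 9 points.  These match
the instrument's actual operating scales, so nothing is scaled down from
the real protocol except the number of Monte-Carlo repetitions in
property tests.
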