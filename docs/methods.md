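# Methods

This note documents the models behind `protonwet`, the conventions and
numerical choices, and what the synthetic data do and do not establish.

## Pristine Bragg curve and the MLIC readout

The reference beam is modelled as the classic analytic depth dose of a
monoenergetic proton beam: a power-law stopping term plus a fluence-loss
term,

    d(z) = (R − z)^(−0.435) + k · (R − z)^(0.565),   z < R,

convolved with a Gaussian of width `straggling_sigma_mm` to represent range
straggling (and any detector blurring). The convolution is done numerically
on a 0.01 mm grid; the −0.435 singularity is integrable, so exact cell
integrals of both power terms are used before filtering, which keeps the
convolution accurate near the peak. The closed-form parabolic-cylinder
expression of the same model is analytically equivalent but numerically
unusable far from the peak (the e^(−ζ²/4) and D_ν(−ζ) factors under- and
overflow at entrance depths where ζ ≈ 80), which is why the convolved form
was chosen.

Two calibrations pin the model to its parameters: the plateau weight `k` is
solved by bisection so that entrance signal / peak signal equals
`plateau_entrance_ratio` (default 0.30; values below ≈0.24 are unreachable
for this peak shape and are rejected), and the depth axis is shifted so the
distal R80 sits exactly at `nominal_range_mm`. The default range, 259 mm, is
the water range of a 200 MeV beam; the default straggling width, 3 mm, is
about 1.2 % of that range, typical for this energy.

Detector convention: chamber `i` is centred at `(i + 0.5) · pitch`, with 180
chambers at 2 mm pitch by default (span 360 mm). Device insertion is an
exact depth shift: `signal(z) = pristine(z + WET)`. This neglects the extra
scattering and straggling a real device adds — a deliberate approximation,
adequate for thin low-density devices, and the property that gives the
synthetic data an exact ground truth. Chamber noise is independent
multiplicative Gaussian with coefficient of variation `noise_cv` (default
0.005, i.e. 0.5 %); identical seeds give bit-identical curves.

## WET estimation and its resolution

R80/R90 are defined as the most distal depths where the linearly
interpolated signal falls to 80 %/90 % of the curve maximum (fractions of
the maximum, the standard proton-range convention). Scanning from the deep
end over decreasing segments makes the extraction immune to spurious shallow
dips. WET is the mean of the R80 and R90 shifts between reference and
sample curve.

Linear interpolation of a σ = 3 mm sigmoidal falloff sampled at 2 mm is not
exact: each threshold carries a curvature bias of up to ≈0.2 mm, largest
when the shift is an odd multiple of half the pitch and zero when the shift
is a whole pitch. The biases at 80 % and 90 % have opposite signs (the two
levels sit on opposite sides of the falloff inflection), so their average —
precisely the quantity the method reports — is accurate to better than
0.07 mm noiseless, and to ≈0.1 mm (1 σ) per measurement with 1 % chamber
noise. Tests assert exactly these bounds. A negative WET (sample ranging
deeper than reference) warns but is returned, so swapped inputs are
detectable in QA use. An optional moving-average smoother is available but
off by default.

## TPS side: calibration and ray tracing

Calibration is two-stage piecewise linear, HU → mass density and density →
RSP, mirroring the clinical pathway; a direct HU → RSP table is accepted at
load time. Out-of-domain HU clamps to the end nodes (TPS-like behaviour and
safer than extrapolation). The bundled default curve has air / lung /
adipose / water / soft-bone / bone nodes with representative values; it is a
package fixture, not measured data.

Radiological path length uses exact Siddon voxel traversal: parametric
crossings with all grid planes, each inter-crossing segment attributed to
the voxel containing its midpoint. World coordinates follow
`origin + (index + 0.5) · spacing`, axis order (z, y, x), lengths in mm.
The TPS WET of a device restricts the sum to mask voxels; thickness is the
in-mask geometric length of the same ray, by default perpendicular to the
device surface through each marked location (the line orientation is
configurable). `n_repeats` averages repeated evaluations, optionally with
perpendicular ray jitter to emulate manual repeat measurements.

Comparison convention: %Δ = 100·(SPR_TPS − SPR_meas)/SPR_meas and
WET error = (SPR_TPS − SPR_meas)·thickness. For the bundled reference table
the per-device %Δ values are per-location means and are carried as given;
recomputing the ratio from the aggregate SPR columns can differ in the last
printed digit.

## Density override and dose recalculation

The override scales RSP inside the device contour by SPR_meas/SPR_TPS.
Ratio (not additive) scaling is used because stopping power is very nearly
proportional to density for a fixed material; working in RSP space unifies
the CT-number-override and density-override pathways of commercial systems.
After the override, a TPS re-measurement through the device returns the
measured SPR to machine precision.

Dose is recalculated with a deterministic broad-beam engine. Per beam, the
grid is resampled into a beam frame whose last axis is the travel direction
(90° multiples are exact index permutations; other angles use bilinear
resampling; the axial grid must be square), WEPL is the cumulative RSP sum
along that axis, and the dose is an analytic SOBP:

* unit plateau on [range − modulation, range];
* distal raised-cosine ramp scaled so the 80 %–20 % distance equals
  `distal_falloff_mm` (default 4 mm; total ramp 2.44 × falloff, zero beyond
  range + 3 × falloff);
* proximal raised-cosine ramp-up over `proximal_ramp_mm` (default 10 mm).

Each beam is confined to a lateral aperture: the CTV projected along the
beam axis, dilated by `aperture_margin_mm` (default 6 mm). Without an
aperture a divergence-free broad beam would irradiate the whole grid and
conformity/OAR metrics would be meaningless. No lateral scatter, penumbra
or beam divergence is modelled: this engine is a declared surrogate for
Monte-Carlo/pencil-beam TPS engines, adequate for range-shift arithmetic
(the pullback of the distal edge equals the WEPL change upstream, verified
to 0.2 mm on 1 mm grids) but not for absolute dosimetry.

Plans are generated to cover the CTV: per beam, SOBP range = ray-traced WEPL
to the CTV distal edge + 4 mm, modulation reaching 4 mm proximal of the
proximal edge, equal weights unless specified.

Robustness follows the common 12-scenario recipe: six cardinal setup shifts
(±x, ±y, ±z at the setup uncertainty, default 3 mm) crossed with two range
scales (1 ± 3.5 %), plus the nominal. Shifts are applied in the room frame
(patient grid resampled by +s, apertures fixed to the beams, dose resampled
back by −s); range scales multiply the whole RSP grid.

## DVH metrics and statistics

V95, max and mean dose use exact voxel counts; D95 is the exact order
statistic (largest dose received by ≥95 % of voxels, via sorting — the
binned cumulative DVH is for plotting only). The RTOG conformity index is
the prescription-isodose volume over the CTV volume, counted over the whole
grid. Worst case over scenarios is the per-metric extremum: minimum for
V95/D95/mean/conformity, maximum for max dose (scenario-level, not
voxel-wise). Max dose is the maximum voxel dose, with no small-volume
surrogate. Beam-specific coverage assumes equal beam weights and evaluates
each beam's dose against prescription/n_beams.

The Wilcoxon signed-rank test drops zero differences, assigns average ranks
to ties, and reports W = min(W⁺, W⁻) with a two-sided p. For n ≤ 25 the
p-value is exact: the null distribution of W⁺ over all 2ⁿ sign assignments
is built by dynamic programming over doubled ranks (halved ranks from ties
stay integral). Beyond 25 a normal approximation with continuity and tie
correction is used. The exact branch is verified against full enumeration
for all n ≤ 10 and against an independent implementation.

## Synthetic study conditions, sizes, and what they show

The device loop uses slabs ≥4 voxels thick (1 mm resolution across the
slab), three marked locations by default, and the detector above. The
patient-like case is a water cylinder (radius 70 mm) in a 192 × 192 × 32 mm
grid at 2 mm voxels, a 16 mm-radius spherical CTV, spherical OARs placed
proximal and distal along the posterior beam, and a cushion slab against
the posterior surface traversed by the 180° beam of a two-beam plan; the
range-pullback check uses a 1 mm axial grid to resolve sub-millimetre
shifts. These sizes keep the full test suite and the acceptance script in
the minutes range while leaving every assertion's tolerance dominated by
the method, not the grid.

What the synthetic data do **not** emulate: heterogeneous real anatomy,
device-induced scatter and straggling growth, contouring uncertainty,
pencil-beam spot structure, or inter-fraction variation. Passing tests
therefore establish the correctness of the analysis chain — range
extraction, calibration arithmetic, ray tracing, override algebra, DVH and
statistics — and the direction and scale of override effects (proximal OAR
dose up, distal OAR dose down, CTV coverage nearly unchanged for sub-mm WET
errors), not clinical effect sizes for real patients.

## Degenerate inputs and error behaviour

Truncated curves (no distal crossing) raise a range-not-found error; a
flat-zero curve is rejected at construction. Rays missing the grid or the
device mask warn and return zero (a zero thickness then raises). Empty
override masks warn and no-op. Empty structure masks, non-monotone
calibration tables, mismatched mask/phantom grids, and all-zero Wilcoxon
differences raise distinct, named errors. All randomness flows from
explicit seeds; identical configs reproduce identical reports byte for
byte.

## Known limitations

* The dose engine's proximal ramp rises from zero rather than from a
  physical entrance-dose level; OAR effects proximal of the ramp start are
  therefore not represented.
* Oblique (non-90°-multiple) beams use bilinear resampling, which slightly
  blurs material edges; the shipped study geometries use cardinal angles.
* The broad-beam aperture is a hard edge: no penumbra.
* `hu_for_rsp` inverts the calibration by dense sampling; on flat curve
  segments it returns the shallowest matching HU.
* Wilcoxon p-values for n > 25 are asymptotic (with continuity and tie
  corrections), as in standard practice.
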