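# Methods

This note documents the models implemented in `flickerscope`, the
assumptions behind them, the tunable parameters with their defaults, what
the synthetic-data generators do and do not emulate, and the numerical and
design choices made where the procedure was genuinely open.

## 1. Contours and conventions

A cell contour is stored in polar form about its centroid on a strictly
uniform angle grid `θ_j = 2πj/N` (N = 720 for bright-field fields, 1024 for
high-speed videos), with radii in meters. The mean radius `R0` is the
angular mean of `R(θ)` and the fluctuation profile is `h(θ) = R − R0`. The
equivalent radius `R_eq = √(A/π)` is kept as a separate field: `R0` is the
fluctuation reference, `R_eq` the area-equivalent disk radius.

**Periodic smoothing.** Boundary samples are irregular in angle, so
resampling uses a periodic least-squares trigonometric fit with `degree`
harmonics (12 for fields, 18 for videos). This is the package's reading of
a "degree-12/18" periodic polynomial fit: periodicity is structural, the
harmonic count plays the role of the degree, and the residual RMS at the
boundary samples is reported on every contour (typically ≤ 0.25 px on
digitized disks). A consequence is that angular content above the harmonic
cutoff is removed by construction; all analyses here use modes well below
it.

**Fourier convention.** Mode amplitudes are `h_n = (1/N) Σ_j h(θ_j)
e^(−inθ_j)`; one-sided powers `|h_n|²` for n = 1 … N/2 are reported, and the
convention identifier is stamped on every spectrum and output CSV. The
effective tension depends on this convention and is therefore a
comparative, not absolute, quantity.

## 2. Segmentation and acceptance filtering

Frames are Gaussian-denoised (σ = 2 px), affinely normalized to [0, 1], and
binarized at a global Otsu threshold with the dark class taken as cells
(bright-field rims are dark; a polarity flag covers other optics). Otsu is
implemented directly — 256-bin between-class-variance maximization with
ties broken toward the lowest threshold — because downstream tests pin the
tie-break exactly; splits falling inside a run of empty histogram bins are
genuine ties (identical pixel partitions). Binarized components are
hole-filled and labeled with 8-connectivity.

Each candidate component is evaluated in raster order of its centroid
against, in order:

1. **border** — bounding box within `border_margin` (default 1 px) of the
   frame edge;
2. **focus** — rim sharpness below `focus_metric_min`. Sharpness is the
   99th-percentile Sobel gradient magnitude inside the component (units of
   normalized intensity per pixel, default minimum 0.05–0.06). A
   contrast-based focus test was rejected during design: a rim shallow
   enough to fail a contrast threshold is also too shallow to fall below
   the global Otsu threshold, so defocused cells would vanish instead of
   being rejected with a reason. Gradient sharpness separates sharp
   (~0.1 px⁻¹) from defocused (~0.03 px⁻¹) rims by ~3×;
3. **aggregate** — convex-hull solidity < 0.9, or circularity failure
   combined with an oversized equivalent radius. Overlapping-disk clumps
   are nearly convex (solidity 0.88–0.95), so solidity alone is fragile;
   an aggregate of in-window cells is however necessarily both non-circular
   and oversized, which the combined test detects with wide margins. No
   splitting is attempted — aggregates are discarded;
4. **circularity** — `C = 4πA/P² < 0.9` (P is the Crofton perimeter of the
   filled component). The linear form `C_lin = 2πR_eq/P` is also computed
   and reported; `C_lin² = C` algebraically, so the two conventions rank
   cells identically and the config records which one gates. Note that a
   moderate ellipse (axis ratio 1.5) has C ≈ 0.94 and passes the 0.9
   threshold; the threshold starts rejecting near axis ratio ~1.8;
5. **size** — equivalent radius outside `radius_window` (default
   [7, 8] µm). The window is a configuration default: it matches the
   acquisition convention under which the binarized rim band (trough plus
   outer halo) of a discocyte projection lands in that range, and is not a
   claim about bare discocyte radii.

Every rejection is logged with the first failing reason; an empty accepted
set is a valid outcome.

**Contour refinement.** Accepted components are converted to contours about
their darkness-weighted centroid. When an intensity level is supplied
(normally the Otsu threshold), the boundary is the sub-pixel iso-intensity
contour of the frame — the outer crossing of the dark rim — which reduces
pixelation error by roughly 4× versus the binary mask boundary; star-convex
validity is enforced by checking the radius is single-valued per angular
bin (crescents and other multi-valued shapes raise an error).

**Video tracking.** Each frame of a high-speed stack must segment to
exactly one candidate component; its contour is extracted at 1024 angles
about the instantaneous centroid, so rigid drift cancels by construction
(residual < 0.1 px for 0.5 px/frame planted drift). The fluctuation field
is `h(θ, t) = R(θ, t) − ⟨R(θ, t)⟩_t`; the per-angle time-mean subtraction
makes per-angle means exactly zero and removes a `~2τ_c/T_rec` fraction of
the true variance for records of length `T_rec` (≈ 2% at the default
simulation parameters, counted as part of the measurement conditions).

## 3. Ensemble tension

The population of accepted discocyte contours at one time point is treated
as an ensemble proxy for temporal fluctuations of a single cell (valid for
stationary, homogeneous populations; used strictly comparatively). The
ensemble spectrum is the arithmetic per-mode mean of single-cell spectra;
the effective lateral tension inverts the mode-3 power by default, with a
band option {2, 3, 4} since the tension-dominated regime is not a single
exact mode. Averaging powers before inverting is the default; inverting per
cell and averaging tensions is available but not default (the former
weights cells by information content under the exponential power law).
Mode 1 is the translation mode and is refused. No bending-modulus fit or
mode-crossover analysis is attempted: the package stays in the
tension-dominated long-wavelength regime.

## 4. Time-resolved descriptors

Each per-angle series is analyzed independently:

- `k_eff = k_BT/⟨h²⟩_t` with the population divisor T;
- MSD over all overlapping pairs; `D` from a through-origin least-squares
  fit of `2Dτ` over the first `msd_fit_lags` lags (default 10, i.e. 5 ms at
  2000 fps). The window must sit in the linear MSD regime: the fit has a
  relative bias of about `ω τ̄/2` (≈ 6% at ω = 30 s⁻¹), reported alongside
  as a residual-based quality flag;
- `γ = k_BT/D`, `ω_c = k_eff D/k_BT`, `τ_c = 1/ω_c`;
- volatility: SDs over 0.5 s windows placed every 0.25 s (stride reading of
  "0.25 s overlap"; partial trailing windows discarded), then the SD of
  that window-SD sequence. It is offset-invariant, scales linearly with
  amplitude, and is documented as a comparative non-stationarity marker
  only.

Per-cell aggregation uses the **median** across angle series (robust to
dead angles; the aggregator was not otherwise constrained). Degenerate
(zero-variance) angles are dropped and counted; a cell with more than half
its angles degenerate is flagged unusable. γ, ω_c, τ_c are derived from the
aggregated k_eff and D, so the Einstein identity `γ·D = k_BT` is exact per
record.

## 5. Hemolysis readout

Blank reads are averaged per wavelength and subtracted before the Harboe
combination `H = 167.2·A415′ − 83.6·A380′ − 83.6·A450′`; hemolysis is
`100·H_sample/H_lysis`. The weights and the LOD multiplier (3.3) are
configuration defaults labeled as such. The LOD pools the per-wavelength
read SDs over all blank replicates (≥ 2 reads each), propagates them
through the Harboe weights in quadrature, and expresses 3.3 × the
propagated SD as a percent of full lysis. Negative blank-corrected values
are reported as-is with `below_lod = True`, never clipped: sub-LOD
fluctuations are uninterpretable, not zero.

## 6. Statistics

Kruskal–Wallis across all groups, then planned two-sided Mann–Whitney U
pairs: exact null when both groups have ≤ 8 tie-free values, otherwise the
normal approximation with tie correction. Labels are a pure function of p
with the trend band inclusive at its lower edge (0.05 ≤ p < 0.1). No
multiple-testing correction by default (a Holm option exists). Quartiles
use linear interpolation; the IQR value depends on this rule, hence it is
fixed and stated. All reporting is within-run/within-condition; no
population-level inference is emitted. The mechanical plane (ω_c against
k_eff per cell) carries a purely descriptive OLS line whose slope equals
`D/k_BT` when diffusivity is shared across cells.

## 7. Synthetic data: what it emulates, and what it does not

- **Field scenes** render each cell as a dark radial Gaussian trough
  (depth 0.6 of background, width 0.4 µm) on a bright background with
  additive Gaussian noise; interior pallor, point-spread functions and
  phase optics are not modeled — only the outer rim drives segmentation.
  The default 9-cell fixture plants 5 defect-free cells (7.0 µm trough
  radius, so the binarized band's R_eq ≈ 7.6 µm sits mid-window) and four
  defects: border-touching, a three-lobe aggregate (rim separation
  1.95·R + 0.85 µm keeps the lobes overlapping yet non-convex), a
  defocused cell (rim width 1.8 µm), and an area-preserving axis-ratio-2
  ellipse. Each planted cell carries its expected accept/reject outcome
  and reason in the manifest.
- **Angle dynamics** are independent stationary Ornstein–Uhlenbeck series
  per angle, simulated with the exact discrete update
  `h_{k+1} = h_k e^(−ωΔt) + ξ √(Var_st (1 − e^(−2ωΔt)))` from a stationary
  draw — no Euler discretization bias — with defaults k₀ = 3 µN/m,
  γ₀ = 0.1 µg/s (ω₀ = 30 s⁻¹, ~38 nm amplitude at 310.15 K), 2000 fps,
  6000 frames. Angular correlations are deliberately absent (each series is
  analyzed independently downstream); mode-correlated statics come from
  the ensemble generator, and a band-limited mode-OU helper exists for
  ergodicity tests. Real RBC flickering contains active, non-thermal
  contributions; none are simulated, so recovery tests validate the
  estimators under the equilibrium model, not the biology.
- **Static ensembles** draw independent complex mode amplitudes with
  `E|h_n|² = k_BT/(2πnσ₀)` over a mode band (default {2, 3, 4}); h is real
  by construction and carries no n = 0 component.
- **Videos** render a fluctuation field as a dark rim per frame with
  optional rigid drift. Sub-pixel tracking recovers planted variance within
  ~5% when the field is band-limited below the harmonic cutoff; fields that
  are white in angle lose variance to the cutoff by construction, which is
  a property of any band-limited contour representation.
- **Absorbance records** encode a planted hemolysis level exactly in their
  noise-free part, with Gaussian read noise of stated SD; no spectral
  cross-talk beyond what blank correction removes.

Consequently, passing tests demonstrate correctness of the estimators and
pipeline mechanics under known ground truth at 37 °C; they do not
demonstrate robustness to optical artifacts, active membrane noise,
non-discocyte morphologies, or donor variability.

## 8. Problem sizes and numerical choices

Simulated test problems are scaled for desk-class reproducibility: 64
angles stand in for 1024 in recovery tests (per-angle analyses are
independent, so this changes only averaging width), rendered test videos
use 150–200 frames with volatility windows scaled in proportion, and
ensemble sizes of 30–3000 cells bracket the Monte-Carlo convergence of the
tension estimate. Default temperature is 310.15 K with
k_B = 1.380649 × 10⁻²³ J/K. Pixel coordinates are 0-based; angles live on
[0, 2π); connectivity is 8-way; all generator outputs are pure functions of
their seed.

## 9. Known limitations

- σ_eff and the viscoelastic descriptors are effective, convention-bound
  quantities — not absolute material constants; comparisons are valid only
  within a fixed acquisition/analysis configuration.
- The harmonic-fit reading of the contour smoothing step removes angular
  content above the cutoff; analyses at modes approaching N/2 would need a
  different representation.
- The aggregate test assumes clumps of roughly window-sized cells; an
  aggregate of strongly undersized cells could evade the oversize clause
  (it would still fail circularity, with that reason).
- Exact Mann–Whitney p-values require tie-free samples; tied small samples
  fall back to the tie-corrected normal approximation.
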