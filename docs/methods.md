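# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `ktmese`. Everything quantitative below is recomputed by the
test suite or by `scripts/acceptance.py`; nothing is asserted that the code
does not itself measure.

## Signal model

A multi-echo spin-echo (MESE) train samples transverse decay at echo times
TE_k = k·ESP. With ideal 180° refocusing the echo tops follow
S_k = exp(−TE_k/T2) (the CPMG limit). With reduced refocusing angles —
used here to cut RF power at 3 T: 175° for the first pulse, 145° for the
second, 110° thereafter — a large fraction of the signal traverses
stimulated-echo pathways (stored along z between pulses and recalled
later), so the echo train decays *more slowly* than exp(−TE/T2) and a
mono-exponential fit would overestimate T2.

The extended phase graph (EPG) recursion models this exactly. The
magnetisation is expanded in configuration states F⁺(k), F⁻(k), Z(k) over
integer dephasing orders; each echo period applies, in order: relaxation
over ESP/2, a unit dephasing shift (ideal crusher), the refocusing rotation
(about +x, after a 90° excitation about +y, i.e. CPMG phase conditions),
relaxation and dephasing over the second ESP/2, and reads the echo as F(0).
Transmit-field inhomogeneity enters as a scale `b1_scale` on the refocusing
angles only. Truncating at `n_echoes + 2` dephasing orders is exact (a
tested invariant), so the recursion over a whole train is O(n_echoes²) per
tissue and is vectorised over pixels.

Validation is two-fold and implemented independently of the recursion:
the CPMG limit agrees with the closed form to machine precision across
T2 ∈ [20, 2000] ms, and arbitrary schedules agree with a brute-force
isochromat ensemble (2000 spins on a uniform intravoxel phase grid,
explicit 3×3 rotations) to < 10⁻¹² — far inside the 10⁻³ budget we allow
for ensemble discretisation.

Assumptions: on-resonance excitation, ideal crushers, no slice-profile
integration, no B0 off-resonance, no magnetisation transfer or diffusion
weighting. Tissue T1 is not fitted; a fixed default of 1500 ms (typical
renal cortex at 3 T) is used everywhere and is configurable. Repetition
time enters only as a global saturation factor 1 − exp(−(TR − TE_max)/T1):
the high-resolution protocol is respiratory-gated with effectively full
recovery (TR treated as infinite), the breath-hold protocol uses
TR = 1125 ms.

## Protocols

Two stock protocols are built in. High-resolution: 384 × 384 over a 384 mm
field of view, ESP 7.8 ms, TE up to 234 ms → 30 echoes. Breath-hold:
128 × 128, ESP 13 ms, TE up to 182 ms → 14 echoes, TR 1125 ms. Both use
the reduced-flip schedule above and a nominal 9× k-t acceleration, five
slices of 4.5 mm with 1.0 mm gap. The echo counts follow from the printed
TE range as TE_max/ESP.

## k-t sampling and echo merging

Each echo frame samples `max(center_lines + 1, floor(n_pe / R))`
phase-encode lines: a fully sampled centre band (default 8 lines around DC)
plus an evenly spaced comb over the remaining lines. For the
high-resolution matrix this gives 42 of 384 lines per frame — a net factor
of 9.14, i.e. the nominal 9×. The comb offset advances by a fixed stride
between frames, with the stride chosen coprime to the comb cycle
(≈ 0.382 × cycle, a golden-ratio fraction) so that consecutive frames are
complementary and the offsets scatter rather than sweep. One comb cycle
spans ⌈spacing⌉ frames; for the 30-echo high-resolution train (cycle 12)
the union of any cycle of frames covers every phase encode. The 14-echo
breath-hold train cannot cover its 20-frame cycle: 6 comb lines × 14 frames
< 120 non-centre lines, so 36 of 128 lines are never sampled in any frame.
This is a direct arithmetic consequence of the per-frame line budget and
shapes the reconstruction design below. Line-budget quantisation also
bounds how closely the net factor can track the nominal one (e.g. at
n_pe = 128 the realisable factors jump from 10.7 to 12.8 around R = 11);
the masks realise the floor-rule budget exactly and the tests assert the
quantisation-aware bound.

Echo merging is realised as windowed view sharing: a line missing in frame
t is borrowed from the nearest frame within ±`window` (default 2) where it
was acquired, ties resolving to the earlier echo. Shared entries carry
provenance flags (a shared-line mask and a source-frame map); acquired
lines are never overwritten.

## Reconstruction (k-t FOCUSS with a PC temporal basis)

Pixel decay curves across echoes lie close to a low-dimensional manifold,
so the echo series is represented as x = q Bᵀ where B holds `n_pc_kept`
(default 4) temporal principal components learned, uncentred, from the
fully sampled centre band of the same acquisition (self-calibration; for
phantom-like data the 4-component representation error is ~10⁻⁵). The
solver minimises

    ‖v − M F (q Bᵀ)‖² + λ‖W⁻¹(q − q_pred)‖²

by FOCUSS iterations: W = (|q_prev|)^p with p = 0.5 (ℓ1-like support
promotion), each inner problem solved by warm-started conjugate gradients
(default 60 steps) on the normal equations, over `n_outer` = 3 reweighting
passes with the regularisation annealed from 10λ to λ (λ_rel default 10⁻⁴,
scaled by the operator norm). The recorded data residuals are
non-increasing across passes (enforced by keeping the better iterate). A
final hard data-consistency step re-inserts all measured samples, which
makes the fully sampled, λ = 0 case reproduce the direct inverse FFT
exactly. With coil sensitivity maps the forward operator includes
sensitivity weighting; uniform maps reduce to the single-coil path to
10⁻¹⁰.

Two design choices respond to the sampling regimes:

* **Prediction anchor.** The penalty is anchored at q_pred — the
  zero-filled estimate with missing lines filled by their per-line temporal
  average, sharpened by decay-compensated view sharing (below). When the
  mask covers every line at least once (high-resolution regime) the classic
  zero anchor is used instead: q_pred ≡ 0 there recovers standard FOCUSS,
  which measures slightly better. The anchor switches automatically on
  whether never-sampled lines exist. Without the anchor, content on the
  36 never-sampled breath-hold lines shrinks toward zero, which shows up as
  a regression of lesion contrast toward the global decay (long-T2 lesions
  biased short and vice versa).
* **Merging into the data term.** Borrowed lines are rescaled by the ratio
  of the two frames' decay amplitudes before entering the (soft) data term.
  Because the readout axis is fully sampled, the compensation is applied
  column-wise in hybrid (x, k_y) space using decay curves from the
  centre-band low-resolution images, which locally adapts the scale to the
  tissue mix along each readout column. The final data-consistency step
  uses truly acquired samples only, so borrowed neighbour-echo data can
  never override measurements.

Defaults were fixed by convergence studies on the noiseless 9× phantom:
fewer CG steps or passes leave the solver visibly unconverged (NRMSE ~0.07
at 30 CG / 2 passes vs ~0.045 at the defaults), while further iterations
change the result by < 10⁻³. Reconstruction quality is reported as NRMSE
of the *magnitude* echo series, which is what the downstream magnitude-only
fit consumes; on the 128 × 128 test grid with the 30-echo train at 9× the
defaults give ≈ 0.045 against 0.19 for zero filling.

## T2 fitting

Each pixel's magnitude decay is matched against a dictionary of EPG echo
trains on a log-spaced T2 grid (30–3000 ms, 200 points → 2.3% spacing) ×
a transmit-scale grid B1 ∈ {0.80 … 1.20, step 0.05}, all atoms
L2-normalised; the best atom maximises the normalised inner product, which
equals least-squares residual minimisation at the optimal amplitude and is
a single blocked matrix product for the whole image. The amplitude is
reported in proton-density units via the stored raw atom norms. Matching is
exactly equivalent to exhaustive per-atom residual minimisation (tested on
random crops); noiseless recovery is exact up to grid quantisation
(≤ 1.2%).

Noise handling: the background σ is estimated robustly from the four
image-corner patches (Rayleigh median), pixels with first-echo magnitude
below 3σ are invalidated, and magnitudes are Rician-corrected as
√max(m² − 2σ², 0) before matching (default on). At SNR 30 with the
30-echo train the median absolute T2 error over [50, 250] ms is ≈ 1.8%
(simulated at nominal transmit and fitted with B1 fixed accordingly; the
joint B1 search adds ≈ 0.2 percentage points of noise-driven error).
Magnitude-only fitting is a stated limitation: below SNR ≈ 20 the residual
Rician bias grows.

Synthetic T2-weighted images are generated from the fitted maps as
amplitude · exp(−TE_synth/T2) (invalid pixels → 0), so any echo-time
contrast can be produced without further acquisition.

## ROI metrics and diameters

Histogram metrics over the valid pixels of a single-slice ROI: sample
median; Pearson kurtosis m₄/m₂² (a Gaussian histogram sits at 3 — chosen
over excess kurtosis because normal-cortex reference values in this
application cluster at ≈ 3.3–3.4); skewness m₃/m₂^1.5; central moments with
denominator n, matching common imaging ROI tools bit-for-bit. ROIs need at
least 10 valid pixels; zero-variance ROIs are an error. When ROIs are
derived from phantom compartment labels they are eroded by one pixel,
mirroring manual ROI placement clear of boundaries where partial-volume and
reconstruction edge effects dominate. The largest diameter is the
max-Feret diameter: the maximum pairwise pixel-centre distance in mm,
computed on convex-hull vertices (exact, since the diameter of a set is
attained on its hull) with a brute-force fallback for degenerate masks;
in-plane only.

## Cohort statistics

The Shapiro–Wilk test (3 ≤ n ≤ 5000) gates the analysis; the skewed,
small-n T2 metrics fail it, so comparisons are nonparametric throughout.
Kruskal–Wallis H uses the standard tie correction; Dunn's post-hoc z for
groups i, j is (r̄_i − r̄_j)/√((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i+1/n_j))
with two-sided normal p-values Bonferroni-multiplied over all reported
pairs (capped at 1) — the default of common biostatistics packages. For
two groups the omnibus p equals the tie-corrected asymptotic Mann–Whitney
p (tested to 10⁻⁹). Subtype comparisons include the normal-cortex
reference region as a group and exclude groups with n < 2 from the rank
tests. Protocol agreement uses Bland–Altman bias ± 1.96·SD (sample SD) of
paired differences plus Spearman correlation with average-rank ties; the
Spearman p-value is an exact permutation count for n ≤ 9 and the t
approximation otherwise (adequate at cohort scale). α = 0.05 two-sided;
grade trends report per-grade medians in ascending grade order per
protocol.

## Synthetic data

**Phantom.** A 2-D abdominal-style slice: body ellipse (soft tissue,
T2 ≈ 70 ms), kidney with cortex rim (110 ms) and medullary core (140 ms),
and one circular lesion, default 56 mm (the emulated cohort's median
tumour size). Proton density is 1 inside tissue, 0 outside; T1 is uniform
1500 ms. Per-pixel T2 textures are drawn through a Gaussian copula — a
smoothed latent Gaussian field (correlation length 6 mm) mapped through
the compartment's quantile function — because real tissue heterogeneity is
regional (septa, necrosis, haemorrhage), not pixel-wise white noise. The
quantile transform preserves each compartment's marginal distribution
exactly; the spatial correlation does lower the *sample* kurtosis of a
single lesion (≈ 2.5 for the Gaussian oncocytoma preset at the default
size, vs 3 asymptotically) by reducing the effective sample size.

Lesion presets (per-pixel T2 marginals): papillary RCC log-normal with
median 51 ms (tight, σ_log 0.12); oncocytoma Gaussian 141 ± 25 ms
(near-Gaussian, lowest heterogeneity); chromophobe Gaussian 150 ± 28 ms;
clear cell RCC right-skewed log-normal with grade-dependent medians
209 / 151 / 106 ms (grades 2/3/4, σ_log 0.22); eosinophilic/oncocytic RCC a
two-component mixture (70 ± 12 and 195 ± 22 ms, 45:55) giving the clear
two-region demarcation that subtype shows. `scripts/calibrate_presets.py`
recomputes the realised statistics from the generator so these constants
stay reproducible.

**k-space simulation.** Echo images are built pixel-wise from the EPG
train scaled by proton density, Fourier transformed (centred, orthonormal),
and complex Gaussian noise is added in k-space with magnitude-σ equal to
mean |first-echo image| / SNR; the mask zeroes unsampled entries. All
generators are pure functions of (parameters, seed).

**Cohort generator.** One record per lesion per protocol, no imaging:
27 tumours (9 oncocytomas — seven patients, two bilateral; 1 e/oRCC;
2 chromophobe; 3 papillary; 12 clear cell with grades 2/5/4 split 2/3/4
plus one ungraded) and one cortex reference per subject. Between-lesion
medians are log-normal per subtype (pRCC 51 ms σ 0.15; RO 141 ms σ 0.33,
matching its wide observed range ≈ 97–251 ms; chRCC 150 σ 0.2; ccRCC grade
medians 209/151/106 σ 0.2; cortex 110 σ 0.07); kurtosis/skewness draws are
lowest for RO and cortex (≈ 3.4) and highest for the e/oRCC, clipped to the
Pearson bound kurtosis ≥ 1 + skew². Diameters are log-normal with median
56 mm (σ_log 0.33), shared between protocols. The breath-hold record of
each lesion applies multiplicative log-scale jitter (σ 0.12) to the median
and additive jitter to kurtosis (σ 0.8) and skewness (σ 0.35), emulating
good-but-imperfect inter-protocol agreement (median Spearman r ≈ 0.86
across replicates); zero jitter makes the protocols identical, a tested
degenerate case.

Across 200 seeded replicates the generated cohorts reproduce the
qualitative findings they are calibrated to: papillary RCC has the lowest
subtype median in ~100%, the clear-cell grade medians decrease 2→3→4 in
~96%, and the pRCC-vs-oncocytoma Dunn comparison is significant in ~81%
with median adjusted p ≈ 0.012.

## Problem sizes

The default phantom grid is 128 × 128 (the breath-hold matrix); the
384 × 384 high-resolution matrix is available through the protocol/grid
options. Reconstruction benchmarks run the 30-echo train on the 128 grid;
end-to-end recovery runs the breath-hold protocol at 9×, SNR 30. Cohort
statistics use 200 seeded replicates; the isochromat oracle uses 2000
spins; Monte-Carlo histogram checks use 10⁵ draws.

## Known limitations

* **Breath-hold coverage floor.** At the breath-hold line budget, 36 of 128
  phase encodes are never sampled; whole-image NRMSE cannot go below ≈ 0.09
  there regardless of solver. Median-based ROI statistics are robust to
  this, but long-T2 lesions (clear cell grade-2 preset, 209 ms) still show
  a reproducible ≈ −17% median bias at breath-hold 9×. Notably this
  mirrors the behaviour reported for the real accelerated acquisition,
  whose breath-hold medians sit 12–18% below the high-resolution values for
  the same long-T2 lesions; we document rather than tune it away.
* Magnitude-only fitting accepts residual Rician bias below SNR ≈ 20, and
  dictionary quantisation limits T2 precision to ~1% per pixel.
* The phantom is geometric (ellipses and a disc) with spatially correlated
  but stationary texture; it exercises the algorithm chain, not anatomical
  realism — no respiratory motion, no partial-volume mixtures at interfaces
  beyond pixelation, single 2-D slice, single-coil by default. Passing the
  end-to-end tests therefore demonstrates algorithmic correctness and
  self-consistency under the stated noise model, not clinical performance.
* The cohort generator draws lesion-level metrics directly from calibrated
  distributions; it preserves the study's statistical structure
  (composition, orderings, agreement), not any patient-level covariance
  beyond the modelled protocol jitter. Its bimodal e/oRCC *texture* preset
  is platykurtic at the pixel level even though the e/oRCC *cohort* preset
  has the highest lesion-level kurtosis — the former feeds imaging tests,
  the latter the statistics, and the two are calibrated independently.
* B1 is fitted as a dictionary dimension but the simulator transmits at
  nominal B1; spatially varying transmit fields are not modelled.
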