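# ktmese — accelerated multi-echo spin-echo T2 mapping for renal tumours

Quantitative T2 mapping turns the qualitative contrast of T2-weighted MRI
into per-pixel relaxation times that can be compared within and between
patients — a promising readout for discriminating renal tumour subtypes
(oncocytoma, chromophobe / papillary / clear cell RCC) and clear cell
WHO/ISUP grades, where median T2 falls with grade and histogram
heterogeneity metrics (kurtosis, skewness) track intratumoural structure.
Acquiring a full multi-echo spin-echo (MESE) train at diagnostic resolution
is, however, prohibitively slow, so the method simulated here accelerates it
~9× by undersampling a different set of phase-encode lines at every echo
time (k-t undersampling), sharing acquired lines between neighbouring echo
frames (echo merging), and refocusing with reduced flip angles
(175°–145°–110°–110°–…) to tame RF power deposition.

`ktmese` is a self-contained, tested implementation of that whole chain for
researchers who want to study, stress-test or extend the method without
scanner data:

* **EPG signal model** — the extended phase graph recursion over
  configuration states (F⁺, F⁻, Z) gives exact echo-train amplitudes
  including the stimulated-echo pathways created by reduced refocusing
  angles, validated to machine precision against closed-form CPMG decay and
  a brute-force isochromat ensemble.
* **k-t sampling and echo merging** — interleaved undersampling masks with a
  fully sampled centre band (nominal 9×: 42 of 384 lines per echo frame),
  plus provenance-flagged, decay-compensated view sharing.
* **k-t FOCUSS reconstruction** — iteratively reweighted least squares with
  a temporal principal-component basis self-calibrated from the centre
  band: solves ‖v − M F (q Bᵀ)‖² + λ‖W⁻¹(q − q_pred)‖² with W = |q|^½,
  conjugate-gradient inner solves and a final hard data-consistency step.
* **Dictionary T2 fitting** — per-pixel matching of magnitude decays against
  EPG atoms on a (T2, B1) grid, with Rician noise-floor correction; plus
  synthetic T2-weighted image generation from the fitted maps.
* **ROI and cohort analysis** — median / Pearson kurtosis / skewness of
  lesion histograms, max-Feret diameters, Shapiro–Wilk gating,
  Kruskal–Wallis with Dunn's Bonferroni-corrected post-hoc z tests, and
  Bland–Altman + Spearman protocol agreement.
* **Synthetic ground truth** — digital kidney phantoms (cortex / medulla /
  lesion with subtype-specific T2 distributions) and lesion cohorts with the
  statistical structure of a 24-patient renal-tumour study, so every stage
  is testable end to end with no download.

## Worked example

Simulate a papillary-RCC phantom, acquire it with the breath-hold protocol
(128 × 128, 14 echoes at 13 ms spacing, 9× k-t undersampling, SNR 30),
reconstruct, fit, and compare recovered ROI medians to the ground truth:

```python
from ktmese import run_phantom_pipeline

res = run_phantom_pipeline("bh", snr=30.0, seed=0, lesion_subtype="pRCC")
for name, rec in res.recovered.items():
    print(f"{name:8s} true {res.ground_truth[name]:6.1f} ms   "
          f"fitted {rec['median_t2_ms']:6.1f} ms   n={rec['n_pixels']}")
```

```
cortex   true  110.8 ms   fitted  102.3 ms   n=685
medulla  true  141.7 ms   fitted  138.2 ms   n=489
lesion   true   50.6 ms   fitted   54.8 ms   n=223
```

All three compartments recover their median T2 within ±10% despite the 9×
undersampling — the short-T2 papillary lesion (~51 ms) stays clearly
separated from cortex (~110 ms) and medulla (~140 ms).

Cohort-level statistics run in milliseconds without imaging:

```python
from ktmese import CohortSpec, generate_cohort, kruskal_dunn

df = generate_cohort(CohortSpec(seed=1))
hr = df[df.protocol == "high_res"]
print(hr[hr.subtype != "cortex"].groupby("subtype")["median_t2_ms"]
      .median().round(1))
groups = {s: g["median_t2_ms"].to_numpy()
          for s, g in hr.groupby("subtype") if len(g) >= 2}
pair = kruskal_dunn(groups).pair("pRCC", "RO")
print(f"pRCC vs RO: z = {pair.z:.2f}, adjusted p = {pair.p_adjusted:.4f}")
```

```
RO        158.0
ccRCC     125.2
chRCC     151.6
e/oRCC    107.4
pRCC       53.0
pRCC vs RO: z = 3.99, adjusted p = 0.0007
```

Papillary RCC shows the lowest median T2 of the subtypes, and the Dunn
post-hoc comparison against oncocytoma is significant after Bonferroni
correction — the qualitative pattern the synthetic cohort is calibrated to.

A command-line pipeline wraps the same stages
(`ktmese simulate | reconstruct | fit | roi | cohort | stats | run-all`):

```bash
ktmese run-all --seed 0 --protocol bh --out out/
ktmese run-all --cohort-only --seed 0 --out out/   # statistics only, seconds
```

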