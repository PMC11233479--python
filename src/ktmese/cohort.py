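"""Synthetic lesion cohorts with the statistical structure of a renal-tumour
T2-mapping study.

The generator emits one lesion-metric record per lesion per protocol
(high-resolution and breath-hold), drawing each lesion's "true" metrics from
between-lesion subtype presets and then applying a protocol-level
multiplicative jitter that emulates the imperfect-but-good agreement between
the two acquisitions.  The default composition mirrors the emulated study:
9 oncocytomas (seven patients, two with bilateral lesions), 1 eosinophilic/
oncocytic RCC, 2 chromophobe RCCs, 3 papillary RCCs and 12 clear cell RCCs
(grades 2/3/4 split 2/5/4 plus one ungraded), with a cortex reference region
per subject.

Between-lesion T2 medians are log-normal: pRCC centred at 51 ms (tight),
RO at 141 ms with a wide spread (its observed range spans roughly
97–251 ms), ccRCC grade-dependent at 209/151/106 ms, cortex at 110 ms.
Within-lesion heterogeneity (kurtosis/skewness) is lowest for RO and cortex
(near-Gaussian, ≈ 3.4) and highest for the bimodal e/oRCC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .roi import LesionRecord, records_to_frame

__all__ = ["SubtypePreset", "CohortSpec", "generate_cohort", "default_cohort_spec"]


@dataclass(frozen=True)
class SubtypePreset:
    """Between-lesion distributions of the per-lesion metrics (one subtype)."""

    median_t2_ms: float      # log-normal median
    sigma_log: float         # log-normal spread of the median across lesions
    kurtosis_mean: float
    kurtosis_sd: float
    skewness_mean: float
    skewness_sd: float


SUBTYPE_COHORT_PRESETS: dict[str, SubtypePreset] = {
    "pRCC": SubtypePreset(51.0, 0.15, 4.5, 0.8, 0.8, 0.40),
    "RO": SubtypePreset(141.0, 0.33, 3.4, 0.35, 0.2, 0.25),
    "chRCC": SubtypePreset(150.0, 0.20, 4.5, 0.8, 0.6, 0.30),
    "e/oRCC": SubtypePreset(120.0, 0.10, 7.0, 1.0, 1.3, 0.30),
    "cortex": SubtypePreset(110.0, 0.07, 3.4, 0.30, 0.3, 0.25),
}

CCRCC_GRADE_MEDIANS = {2: 209.0, 3: 151.0, 4: 106.0}
CCRCC_SIGMA_LOG = 0.20


def _ccrcc_preset(grade: int) -> SubtypePreset:
    return SubtypePreset(
        CCRCC_GRADE_MEDIANS[grade],
        CCRCC_SIGMA_LOG,
        4.3 + 0.4 * (grade - 2),
        0.8,
        0.5 + 0.25 * (grade - 2),
        0.30,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Composition and calibration of one synthetic cohort."""

    n_ro: int = 9            # 7 patients, 2 bilateral second lesions
    n_eorcc: int = 1
    n_chrcc: int = 2
    n_prcc: int = 3
    ccrcc_grades: tuple[int | None, ...] = (2, 2, 3, 3, 3, 3, 3, 4, 4, 4, 4, None)
    include_cortex: bool = True
    diameter_median_mm: float = 56.0
    diameter_sigma_log: float = 0.33
    protocol_jitter: float = 0.12     # log-scale jitter of BH vs High-res medians
    kurtosis_jitter: float = 0.8      # additive jitter of BH kurtosis
    skewness_jitter: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_ro, self.n_eorcc, self.n_chrcc, self.n_prcc)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if sum(counts) + len(self.ccrcc_grades) == 0:
            raise ValueError("at least one lesion is required")

    @property
    def n_lesions(self) -> int:
        return (
            self.n_ro + self.n_eorcc + self.n_chrcc + self.n_prcc
            + len(self.ccrcc_grades)
        )


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    return CohortSpec(seed=seed)


def _clip_kurtosis(kurt: float, skew: float) -> float:
    # Pearson inequality: kurtosis >= 1 + skewness²
    return max(kurt, 1.0 + skew**2 + 0.05)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort; returns a tidy lesion-record table (both protocols).

    Deterministic per ``spec.seed``.  The breath-hold row of each lesion is
    the high-resolution row under multiplicative (median) and additive
    (kurtosis/skewness) jitter; diameters are shared.  With all jitters set
    to zero the two protocols agree exactly.
    """
    if spec.n_lesions == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(spec.seed)

    lesions: list[tuple[str, SubtypePreset, int | None]] = []
    lesions += [("RO", SUBTYPE_COHORT_PRESETS["RO"], None)] * spec.n_ro
    lesions += [("e/oRCC", SUBTYPE_COHORT_PRESETS["e/oRCC"], None)] * spec.n_eorcc
    lesions += [("chRCC", SUBTYPE_COHORT_PRESETS["chRCC"], None)] * spec.n_chrcc
    lesions += [("pRCC", SUBTYPE_COHORT_PRESETS["pRCC"], None)] * spec.n_prcc
    for g in spec.ccrcc_grades:
        preset = _ccrcc_preset(g) if g is not None else _ccrcc_preset(3)
        lesions.append(("ccRCC", preset, g))
    if spec.include_cortex:
        # one normal-cortex reference region per subject (two bilateral RO
        # lesions and one synchronous ccRCC share their subjects' kidneys)
        n_subjects = max(spec.n_lesions - 3, 1)
        lesions += [("cortex", SUBTYPE_COHORT_PRESETS["cortex"], None)] * n_subjects

    records: list[LesionRecord] = []
    px_hr, px_bh = 1.0, 3.0  # mm, in-plane
    for i, (subtype, preset, grade) in enumerate(lesions):
        median_hr = float(
            np.exp(rng.normal(np.log(preset.median_t2_ms), preset.sigma_log))
        )
        skew_hr = float(rng.normal(preset.skewness_mean, preset.skewness_sd))
        kurt_hr = _clip_kurtosis(
            float(rng.normal(preset.kurtosis_mean, preset.kurtosis_sd)), skew_hr
        )
        diameter = float(
            np.exp(rng.normal(np.log(spec.diameter_median_mm), spec.diameter_sigma_log))
        )
        if subtype == "cortex":
            diameter = float(np.exp(rng.normal(np.log(45.0), 0.15)))

        median_bh = median_hr * float(np.exp(rng.normal(0.0, spec.protocol_jitter)))
        skew_bh = skew_hr + float(rng.normal(0.0, spec.skewness_jitter))
        kurt_bh = _clip_kurtosis(
            kurt_hr + float(rng.normal(0.0, spec.kurtosis_jitter)), skew_bh
        )

        area_mm2 = np.pi * (diameter / 2.0) ** 2
        for protocol, median, kurt, skew, px in (
            ("high_res", median_hr, kurt_hr, skew_hr, px_hr),
            ("bh", median_bh, kurt_bh, skew_bh, px_bh),
        ):
            records.append(
                LesionRecord(
                    subject_id=f"S{i:03d}",
                    lesion_id=f"L{i:03d}",
                    subtype=subtype,
                    protocol=protocol,
                    median_t2_ms=median,
                    kurtosis=kurt,
                    skewness=skew,
                    diameter_mm=diameter,
                    n_pixels=max(int(area_mm2 / px**2), 1),
                    who_isup_grade=grade,
                )
            )
    return records_to_frame(records)
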