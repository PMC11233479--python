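"""Acquisition protocol definitions for accelerated multi-echo spin-echo T2 mapping.

Two stock protocols are provided:

* ``high_res`` — a respiratory-gated high-resolution variant
  (384 × 384 matrix, ESP 7.8 ms, 30 echoes, TE up to 234 ms, effectively
  full T1 recovery between excitations);
* ``bh`` — a single-breath-hold variant (128 × 128 matrix, ESP 13 ms,
  14 echoes, TE up to 182 ms, TR 1125 ms).

Both use a reduced refocusing flip-angle schedule 175°–145°–110°–110°–…
(first pulse 175°, second 145°, all subsequent 110°) and a nominal 9×
k-t acceleration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = [
    "AcquisitionProtocol",
    "reduced_flip_schedule",
    "high_res_protocol",
    "bh_protocol",
    "get_protocol",
]


def reduced_flip_schedule(n_echoes: int) -> list[float]:
    """Refocusing schedule 175°, 145°, then 110° for every later echo."""
    if n_echoes < 1:
        raise ValueError("n_echoes must be >= 1")
    base = [175.0, 145.0]
    return base[:n_echoes] + [110.0] * max(0, n_echoes - 2)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing, flip-angle and matrix parameters of one multi-echo spin-echo scan.

    Echo times form the arithmetic progression ``esp, 2*esp, ..., n_echoes*esp``.
    ``tr_ms = inf`` means full longitudinal recovery between excitations.
    """

    name: str
    esp_ms: float
    n_echoes: int
    tr_ms: float
    refoc_schedule_deg: tuple[float, ...]
    matrix: tuple[int, int]  # (n_readout, n_phase_encode)
    fov_mm: float = 384.0
    n_slices: int = 5
    slice_thickness_mm: float = 4.5
    gap_mm: float = 1.0
    acceleration: float = 9.0
    excitation_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.esp_ms <= 0:
            raise ValueError("esp_ms must be positive")
        if self.n_echoes < 1:
            raise ValueError("n_echoes must be >= 1")
        if len(self.refoc_schedule_deg) != self.n_echoes:
            raise ValueError(
                f"refocusing schedule length {len(self.refoc_schedule_deg)} "
                f"!= n_echoes {self.n_echoes}"
            )
        if any(not (0.0 < a <= 180.0) for a in self.refoc_schedule_deg):
            raise ValueError("refocusing angles must lie in (0, 180] degrees")
        if self.acceleration < 1:
            raise ValueError("acceleration must be >= 1")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive (use inf for full recovery)")

    @property
    def echo_times_ms(self) -> list[float]:
        return [(k + 1) * self.esp_ms for k in range(self.n_echoes)]

    @property
    def te_max_ms(self) -> float:
        return self.n_echoes * self.esp_ms

    @property
    def pixel_spacing_mm(self) -> tuple[float, float]:
        n_ro, n_pe = self.matrix
        return (self.fov_mm / n_ro, self.fov_mm / n_pe)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["refoc_schedule"] = list(d.pop("refoc_schedule_deg"))
        d["te_min"] = self.esp_ms
        d["esp"] = d.pop("esp_ms")
        d["te_max"] = self.te_max_ms
        d["tr"] = None if math.isinf(self.tr_ms) else d["tr_ms"]
        d.pop("tr_ms")
        d["matrix"] = list(d["matrix"])
        d["slices"] = d.pop("n_slices")
        d["thickness_mm"] = d.pop("slice_thickness_mm")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        esp = float(d["esp"])
        if "n_echoes" in d:
            n_echoes = int(d["n_echoes"])
        else:
            n_echoes = int(round(float(d["te_max"]) / esp))
        tr = d.get("tr")
        schedule = d.get("refoc_schedule") or reduced_flip_schedule(n_echoes)
        return cls(
            name=str(d.get("name", "custom")),
            esp_ms=esp,
            n_echoes=n_echoes,
            tr_ms=math.inf if tr in (None, "inf") else float(tr),
            refoc_schedule_deg=tuple(float(a) for a in schedule),
            matrix=tuple(int(x) for x in d.get("matrix", (128, 128))),
            fov_mm=float(d.get("fov_mm", 384.0)),
            n_slices=int(d.get("slices", 5)),
            slice_thickness_mm=float(d.get("thickness_mm", 4.5)),
            gap_mm=float(d.get("gap_mm", 1.0)),
            acceleration=float(d.get("acceleration", 9.0)),
            excitation_deg=float(d.get("excitation_deg", 90.0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AcquisitionProtocol":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "AcquisitionProtocol":
        return cls.from_dict(json.loads(text))


def high_res_protocol() -> AcquisitionProtocol:
    """High-resolution protocol: 384×384, TE 7.8:7.8:234 (30 echoes), TR ≈ ∞."""
    n_echoes = 30  # 234 / 7.8
    return AcquisitionProtocol(
        name="high_res",
        esp_ms=7.8,
        n_echoes=n_echoes,
        tr_ms=math.inf,
        refoc_schedule_deg=tuple(reduced_flip_schedule(n_echoes)),
        matrix=(384, 384),
    )


def bh_protocol() -> AcquisitionProtocol:
    """Breath-hold protocol: 128×128, TE 13:13:182 (14 echoes), TR 1125 ms."""
    n_echoes = 14  # 182 / 13
    return AcquisitionProtocol(
        name="bh",
        esp_ms=13.0,
        n_echoes=n_echoes,
        tr_ms=1125.0,
        refoc_schedule_deg=tuple(reduced_flip_schedule(n_echoes)),
        matrix=(128, 128),
    )


_PRESETS = {"high_res": high_res_protocol, "bh": bh_protocol}


def get_protocol(name: str) -> AcquisitionProtocol:
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown protocol {name!r}; choose from {sorted(_PRESETS)}")
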