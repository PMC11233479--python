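"""k-t undersampling masks and echo-merging (view sharing) for MESE trains.

Each echo image is undersampled along the phase-encode direction with a
different line pattern, so that complementary information accumulates across
the echo train (nominal 9× acceleration).  A fully sampled centre band is kept
in every echo frame: it trains the temporal principal-component basis and
initialises the iterative reconstruction.

Echo merging shares acquired k-space lines between nearby echo frames
(windowed view sharing).  Shared entries are provenance-flagged so downstream
stages know which data are native to a frame and which were borrowed from a
neighbouring echo time.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor

import numpy as np

__all__ = ["KtMask", "MergePlan", "generate_kt_mask", "merge_echoes"]

_SCHEMES = ("interleaved", "random_uniform")


@dataclass(frozen=True)
class KtMask:
    """Boolean k-t sampling pattern (phase-encode × echo)."""

    mask: np.ndarray  # bool, (n_phase_encode, n_echoes)
    center_lines: int
    seed: int
    scheme: str
    acceleration: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.dtype != bool or m.ndim != 2:
            raise ValueError("mask must be a 2-D boolean array")
        if not m.any(axis=0).all():
            raise ValueError("every echo frame must sample at least one line")

    @property
    def n_phase_encode(self) -> int:
        return self.mask.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.mask.shape[1]

    @property
    def lines_per_frame(self) -> np.ndarray:
        return self.mask.sum(axis=0)

    @property
    def net_acceleration(self) -> float:
        """(n_pe × n_echoes) / number of sampled entries."""
        return self.mask.size / int(self.mask.sum())

    def center_band(self) -> slice:
        n = self.n_phase_encode
        return slice(n // 2 - self.center_lines // 2, n // 2 + self.center_lines // 2)


def _center_indices(n_pe: int, center_lines: int) -> np.ndarray:
    lo = n_pe // 2 - center_lines // 2
    return np.arange(lo, lo + center_lines)


def generate_kt_mask(
    n_phase_encode: int,
    n_echoes: int,
    acceleration: float,
    center_lines: int = 8,
    seed: int = 0,
    scheme: str = "interleaved",
) -> KtMask:
    """Generate the k-t undersampling pattern for one slice.

    The per-frame line budget is ``max(center_lines + 1, floor(n_pe / R))``:
    a fully sampled centre band plus an evenly spaced comb over the remaining
    phase encodes.  In the interleaved scheme the comb offset advances by a
    fixed stride from frame to frame (stride coprime with the comb cycle, so
    consecutive frames sample complementary lines and the union over one comb
    cycle covers every phase encode).  ``random_uniform`` draws the comb lines
    uniformly per frame with equal per-frame counts, reproducibly from
    ``seed``.
    """
    if acceleration < 1:
        raise ValueError("acceleration must be >= 1")
    if acceleration > n_phase_encode:
        raise ValueError("acceleration cannot exceed the number of phase encodes")
    if center_lines % 2 != 0 or center_lines < 0:
        raise ValueError("center_lines must be even and non-negative")
    if center_lines >= 2 * n_phase_encode / acceleration:
        raise ValueError("centre band too wide for the requested acceleration")
    if scheme not in _SCHEMES:
        raise ValueError(f"scheme must be one of {_SCHEMES}")

    lines_per_frame = max(center_lines + 1, floor(n_phase_encode / acceleration))
    lines_per_frame = min(lines_per_frame, n_phase_encode)

    mask = np.zeros((n_phase_encode, n_echoes), dtype=bool)
    center = _center_indices(n_phase_encode, center_lines)
    mask[center, :] = True

    non_center = np.setdiff1d(np.arange(n_phase_encode), center)
    n_comb = lines_per_frame - center_lines
    if n_comb >= non_center.size:
        mask[:, :] = True
        return KtMask(mask, center_lines, seed, scheme, float(acceleration))

    if scheme == "interleaved":
        spacing = non_center.size / n_comb
        cycle = ceil(spacing)
        # golden-ratio-like stride, made coprime with the cycle, scatters the
        # per-frame offsets instead of sweeping them consecutively
        stride = max(1, round(cycle * 0.382))
        while np.gcd(stride, cycle) != 1:
            stride += 1
        for t in range(n_echoes):
            offset = (t * stride) % cycle
            pos = np.floor(offset + np.arange(n_comb) * spacing).astype(int)
            pos = pos[pos < non_center.size]
            mask[non_center[pos], t] = True
    else:
        rng = np.random.default_rng(seed)
        for t in range(n_echoes):
            pick = rng.choice(non_center.size, size=n_comb, replace=False)
            mask[non_center[pick], t] = True

    return KtMask(mask, center_lines, seed, scheme, float(acceleration))


@dataclass(frozen=True)
class MergePlan:
    """View-sharing window for echo merging.

    ``window`` is the maximum echo-frame distance a line may be borrowed
    across; 0 disables sharing.  Ties (a line acquired in both neighbours at
    equal distance) resolve toward the earlier echo.
    """

    window: int = 2
    conflict_rule: str = "nearest_echo_wins"

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.conflict_rule != "nearest_echo_wins":
            raise ValueError("only 'nearest_echo_wins' is supported")


def merge_echoes(kspace: np.ndarray, mask: KtMask, plan: MergePlan):
    """Fill missing k-space lines from the nearest echo frame within a window.

    Parameters
    ----------
    kspace
        Complex array ``(n_readout, n_phase_encode, n_echoes)`` with zeros on
        unsampled entries.
    mask, plan
        The sampling pattern and the sharing window.

    Returns
    -------
    merged : ndarray
        k-space with shared lines filled in; acquired lines are never
        overwritten.
    shared : ndarray of bool, (n_phase_encode, n_echoes)
        True where a line was borrowed.
    source : ndarray of int, (n_phase_encode, n_echoes)
        Echo-frame index each line came from (its own frame for acquired
        lines, −1 where nothing was available within the window).
    """
    if plan.window >= mask.n_echoes:
        raise ValueError("window must be smaller than the number of echoes")
    m = mask.mask
    if kspace.shape[1:] != m.shape:
        raise ValueError("kspace and mask shapes are inconsistent")
    if np.any(np.abs(kspace[:, ~m]) > 0):
        raise ValueError("unsampled k-space entries must be zero")

    merged = kspace.copy()
    n_pe, n_echoes = m.shape
    shared = np.zeros_like(m)
    source = np.where(m, np.arange(n_echoes)[None, :], -1)

    if plan.window == 0:
        return merged, shared, source

    for t in range(n_echoes):
        for line in np.nonzero(~m[:, t])[0]:
            best = -1
            for d in range(1, plan.window + 1):
                # earlier echo wins ties
                for cand in (t - d, t + d):
                    if 0 <= cand < n_echoes and m[line, cand]:
                        best = cand
                        break
                if best >= 0:
                    break
            if best >= 0:
                merged[:, line, t] = kspace[:, line, best]
                shared[line, t] = True
                source[line, t] = best
    return merged, shared, source
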