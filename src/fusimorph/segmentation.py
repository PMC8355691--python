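"""Patient-specific five-segment vessel splitting by cross-sectional area.

The vessel is divided into five contiguous runs of centreline points: two
proximal segments (P2, P1), the annotated aneurysm [a, b], and two distal
segments (D1, D2), all four non-aneurysm segments holding the same number
of points ``s``.

``s`` is found change-point style.  The baseline on the proximal side is
``ps``, the cross-sectional area at the aneurysm start ``a``; on the distal
side it is ``pe``, the area at the aneurysm end ``b``.  Scanning outward
from the aneurysm, the first point whose area deviates from the baseline by
more than the threshold — the sample standard deviation of the areas of the
whole vessel excluding the aneurysm — marks the extent of the adjacent
segment.  A side with no such point contributes the fallback
``default_s = floor(min((a - 1) / 2, (n - b) / 2))``, and ``s`` is the
minimum over both sides and the fallback, so the four segments always fit
inside the vessel.

All indices in this module are 1-based and inclusive, matching how aneurysm
endpoints are annotated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SegmentationInput",
    "SegmentationResult",
    "InsufficientDataError",
    "VesselTooShortError",
    "compute_threshold",
    "default_segment_length",
    "find_s",
    "segment_vessel",
]

#: below this many points per segment the per-segment statistics are meaningless
MIN_SEGMENT_POINTS = 3


class InsufficientDataError(ValueError):
    """Too few non-aneurysm points to estimate the threshold."""


class VesselTooShortError(ValueError):
    """Vessel cannot accommodate four segments of at least the minimum length."""


@dataclass
class SegmentationInput:
    """Area series plus the annotated aneurysm span (1-based, inclusive)."""

    areas: np.ndarray  # (n,) mm^2
    a: int  # aneurysm start index
    b: int  # aneurysm end index

    def __post_init__(self):
        self.areas = np.asarray(self.areas, dtype=float)
        if not (1 < self.a < self.b < self.n):
            raise ValueError(f"need 1 < a < b < n, got a={self.a}, b={self.b}, n={self.n}")

    @property
    def n(self) -> int:
        return len(self.areas)


@dataclass
class SegmentationResult:
    """Five 1-based inclusive index ranges plus the quantities that fixed them."""

    s: int
    threshold: float  # mm^2
    ps: float  # area at aneurysm start, mm^2
    pe: float  # area at aneurysm end, mm^2
    P2: tuple[int, int]
    P1: tuple[int, int]
    A: tuple[int, int]
    D1: tuple[int, int]
    D2: tuple[int, int]

    @property
    def ranges(self) -> dict[str, tuple[int, int]]:
        return {"P2": self.P2, "P1": self.P1, "A": self.A, "D1": self.D1, "D2": self.D2}

    def slices(self) -> dict[str, slice]:
        """0-based slices into per-point arrays, keyed by segment name."""
        return {name: slice(lo - 1, hi) for name, (lo, hi) in self.ranges.items()}

    def report_row(self, identifier: str) -> str:
        cells = [identifier, str(self.s), f"{self.threshold:.8g}", f"{self.ps:.8g}", f"{self.pe:.8g}"]
        for name, (lo, hi) in self.ranges.items():
            cells.append(f"{lo}-{hi}")
        return "\t".join(cells)


def compute_threshold(inp: SegmentationInput) -> float:
    """Sample standard deviation (ddof=1) of areas outside the aneurysm [a, b]."""
    outside = np.r_[inp.areas[: inp.a - 1], inp.areas[inp.b :]]
    if len(outside) < 4:
        raise InsufficientDataError(
            f"only {len(outside)} non-aneurysm points; need at least 4"
        )
    return float(np.std(outside, ddof=1))


def default_segment_length(inp: SegmentationInput) -> int:
    """Fallback segment length ``floor(min((a - 1) / 2, (n - b) / 2))``."""
    s = int(min((inp.a - 1) // 2, (inp.n - inp.b) // 2))
    if s < MIN_SEGMENT_POINTS:
        raise VesselTooShortError(
            f"default segment length {s} is below the minimum {MIN_SEGMENT_POINTS}"
        )
    return s


def find_s(inp: SegmentationInput, threshold: float) -> int:
    """Points per segment from first-exceedance scans against the neck baselines.

    Proximally, indices ``a-1, a-2, ...`` are compared against ``ps`` (the
    area at ``a``); the first index ``i`` with ``|areas[i] - ps| >
    threshold`` yields ``s_prox = a - i``.  The distal scan works
    symmetrically against ``pe``.  The result is the minimum of both sides
    and the fallback length; a side with no exceedance contributes the
    fallback.
    """
    s_default = default_segment_length(inp)
    areas = inp.areas
    ps = areas[inp.a - 1]
    pe = areas[inp.b - 1]

    s_prox = s_default
    for i in range(inp.a - 1, 0, -1):  # 1-based i = a-1 ... 1
        if abs(areas[i - 1] - ps) > threshold:
            s_prox = inp.a - i
            break
    s_dist = s_default
    for i in range(inp.b + 1, inp.n + 1):  # 1-based i = b+1 ... n
        if abs(areas[i - 1] - pe) > threshold:
            s_dist = i - inp.b
            break
    return int(min(s_prox, s_dist, s_default))


def segment_vessel(
    inp: SegmentationInput, threshold_multiplier: float = 1.0
) -> SegmentationResult:
    """Full segmentation: threshold, ``s``, and the five index ranges.

    ``threshold_multiplier`` rescales the area threshold (0.9 / 1.1 for the
    sensitivity protocol) before the scans.
    """
    if threshold_multiplier <= 0:
        raise ValueError("threshold multiplier must be positive")
    threshold = compute_threshold(inp) * threshold_multiplier
    s = find_s(inp, threshold)
    if s < MIN_SEGMENT_POINTS:
        s = MIN_SEGMENT_POINTS
    # s <= default_s guarantees 2s <= a-1 and 2s <= n-b, so the ranges fit
    a, b = inp.a, inp.b
    return SegmentationResult(
        s=s,
        threshold=threshold,
        ps=float(inp.areas[a - 1]),
        pe=float(inp.areas[b - 1]),
        P2=(a - 2 * s, a - s - 1),
        P1=(a - s, a - 1),
        A=(a, b),
        D1=(b + 1, b + s),
        D2=(b + s + 1, b + 2 * s),
    )
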