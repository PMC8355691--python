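"""Per-case geometric feature vectors excluding the aneurysm itself.

Every case is reduced to 382 named features computed from the four
non-aneurysm segments (P2, P1, D1, D2), deliberately using nothing measured
inside the aneurysm span.  The registry enumerates five families:

1. *Segment statistics* — max, mean, sample standard deviation, trapezoidal
   integration against arc length, and total variation ``sum |x_{i+1} -
   x_i|`` of each geometric index over each segment (10 indices x 5
   statistics x 4 segments = 200).
2. *Ratios* — proximal/distal ratios of those statistics for the P1/D1
   ("PD") and P2/D2 ("PD2") pairings, for every index except the
   equivalent diameter, whose ratios are fully redundant with the area
   ratios (9 x 5 x 2 = 90).
3. *Endpoint values* — each index evaluated at the outer endpoint (the
   point farthest from the aneurysm) of each segment (10 x 4 = 40); the
   major-axis endpoint features carry the ``Diameter_normal*`` names.
4. *Endpoint ratios* — PD and PD2 ratios of the endpoint values (9 x 2 =
   18); the diameter pair are ``Ratio_Dpnordnor1`` and ``Ratio_Dpnordnor2``.
5. *Lengths and global distances* — per-segment arc length, chord length
   and tortuosity with PD/PD2/PP2/DD2 ratios and whole-side aggregates
   (30), the neck angle/distance between the tangents at ``a`` and ``b``
   (2), and the end-to-end straight-line and arc-length distances of the
   vessel (2).

Total: 200 + 90 + 40 + 18 + 30 + 2 + 2 = 382.

Feature names follow the ``<Index>_<statistic>_<segment>`` convention, with
P meaning proximal-1 and D distal-1 (so ``Curvature_mean_PD`` is the ratio
of mean curvature between proximal 1 and distal 1, and
``Eccentricity_std_P2`` the standard deviation of eccentricity in
proximal 2).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .centreline import Centreline
from .cross_sections import CrossSectionProfile
from .segmentation import SegmentationResult

__all__ = [
    "FeatureSpec",
    "FeatureRegistry",
    "NeckFeatures",
    "UnreliableFeatureError",
    "default_registry",
    "segment_statistics",
    "ratio_features",
    "endpoint_diameters",
    "neck_features",
    "compute_case_features",
    "build_feature_matrix",
]

STATISTICS = ("max", "mean", "std", "integration", "variation")
SEGMENTS = ("P2", "P", "D", "D2")  # P = proximal 1, D = distal 1
RATIO_PAIRS = {"PD": ("P", "D"), "PD2": ("P2", "D2")}
LENGTH_PAIRS = {"PD": ("P", "D"), "PD2": ("P2", "D2"), "PP2": ("P", "P2"), "DD2": ("D", "D2")}
#: map from segment label to the range key in SegmentationResult
SEGMENT_KEYS = {"P2": "P2", "P": "P1", "D": "D1", "D2": "D2"}

#: geometric indices (per-centreline-point series)
INDICES = (
    "Curvature",
    "Torsion",
    "CrossArea",
    "AreaChangeRate",
    "Eccentricity",
    "Solidity",
    "Extent",
    "MajorAxis",
    "MinorAxis",
    "EquivDiameter",
)
#: indices whose ratio/endpoint-ratio features exist (equivalent diameter is
#: excluded: its ratios duplicate the square root of the area ratios)
RATIO_INDICES = tuple(i for i in INDICES if i != "EquivDiameter")


class UnreliableFeatureError(ValueError):
    """More than half of a segment's points are flagged undefined."""


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    kind: str  # segment_stat | ratio | endpoint | endpoint_ratio | length | neck | global
    index: str  # geometric index or length quantity; "" for neck/global
    segments: tuple  # segment labels involved
    statistic: str  # statistic name, "normal" for point values, "" otherwise


@dataclass
class FeatureRegistry:
    specs: list

    def __len__(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> list:
        return [s.name for s in self.specs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [s.name for s in self.specs],
                "kind": [s.kind for s in self.specs],
                "index": [s.index for s in self.specs],
                "segments": ["+".join(s.segments) for s in self.specs],
                "statistic": [s.statistic for s in self.specs],
            }
        )

    def write_manifest(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _endpoint_name(index: str, segment: str) -> str:
    stem = "Diameter" if index == "MajorAxis" else index
    return f"{stem}_normal{segment}"


def default_registry() -> FeatureRegistry:
    """The default 382-feature registry, in canonical column order."""
    specs: list[FeatureSpec] = []
    for index in INDICES:
        for stat in STATISTICS:
            for seg in SEGMENTS:
                specs.append(
                    FeatureSpec(f"{index}_{stat}_{seg}", "segment_stat", index, (seg,), stat)
                )
    for index in RATIO_INDICES:
        for stat in STATISTICS:
            for pair, segs in RATIO_PAIRS.items():
                specs.append(
                    FeatureSpec(f"{index}_{stat}_{pair}", "ratio", index, segs, stat)
                )
    for index in INDICES:
        for seg in SEGMENTS:
            specs.append(
                FeatureSpec(_endpoint_name(index, seg), "endpoint", index, (seg,), "normal")
            )
    for index in RATIO_INDICES:
        for pair, segs in RATIO_PAIRS.items():
            if index == "MajorAxis":
                name = "Ratio_Dpnordnor1" if pair == "PD" else "Ratio_Dpnordnor2"
            else:
                name = f"{index}_normal_{pair}"
            specs.append(FeatureSpec(name, "endpoint_ratio", index, segs, "normal"))
    for quantity in ("ArcLength", "ChordLength", "Tortuosity"):
        for seg in SEGMENTS:
            specs.append(FeatureSpec(f"{quantity}_{seg}", "length", quantity, (seg,), ""))
        for pair, segs in LENGTH_PAIRS.items():
            specs.append(FeatureSpec(f"{quantity}_{pair}", "length", quantity, segs, ""))
        for side in ("Prox", "Dist"):
            specs.append(FeatureSpec(f"{quantity}_{side}", "length", quantity, (side,), ""))
    specs.append(FeatureSpec("Neck_alpha", "neck", "", ("A",), ""))
    specs.append(FeatureSpec("Neck_d", "neck", "", ("A",), ""))
    specs.append(FeatureSpec("LineDist", "global", "", (), ""))
    specs.append(FeatureSpec("PointDist", "global", "", (), ""))

    names = [s.name for s in specs]
    assert len(names) == len(set(names)), "duplicate feature names in registry"
    assert len(specs) == 382, f"registry holds {len(specs)} features, expected 382"
    return FeatureRegistry(specs)


# ---------------------------------------------------------------------------
# statistic primitives


def segment_statistics(
    series: np.ndarray,
    arc_length: np.ndarray,
    index_range: tuple[int, int],
    defined: np.ndarray | None = None,
) -> dict:
    """Max, mean, sample std, trapezoidal integration and total variation.

    ``index_range`` is 1-based inclusive.  Points flagged undefined (e.g.
    torsion at locally straight spots) are dropped before computing; if
    more than half the segment is flagged an :class:`UnreliableFeatureError`
    is raised.
    """
    lo, hi = index_range
    if hi - lo + 1 < 3:
        raise ValueError(f"segment {index_range} has fewer than 3 points")
    sl = slice(lo - 1, hi)
    x = np.asarray(series, dtype=float)[sl]
    s = np.asarray(arc_length, dtype=float)[sl]
    if defined is not None:
        keep = np.asarray(defined, dtype=bool)[sl]
        if keep.sum() < 0.5 * len(x):
            raise UnreliableFeatureError(
                f"{len(x) - keep.sum()} of {len(x)} points undefined in {index_range}"
            )
        x, s = x[keep], s[keep]
    return {
        "max": float(np.max(x)),
        "mean": float(np.mean(x)),
        "std": float(np.std(x, ddof=1)),
        "integration": float(np.trapezoid(x, s)),
        "variation": float(np.sum(np.abs(np.diff(x)))),
    }


_WARNED_RATIOS: set = set()


def ratio_features(stats_by_segment: dict, index: str | None = None) -> dict:
    """Proximal/distal ratios of segment statistics.

    ``stats_by_segment`` maps segment label to a statistics dict.  Returns
    ``{"<stat>_PD": P/D, "<stat>_PD2": P2/D2, ...}``; a zero denominator
    yields NaN with a warning (the feature is dropped from selection for
    that run).
    """
    out = {}
    for pair, (num_seg, den_seg) in RATIO_PAIRS.items():
        for stat in STATISTICS:
            num = stats_by_segment[num_seg][stat]
            den = stats_by_segment[den_seg][stat]
            if den == 0.0:
                key = f"{index or ''} {stat}_{pair}"
                if key not in _WARNED_RATIOS:
                    _WARNED_RATIOS.add(key)
                    warnings.warn(
                        f"zero denominator in {key} ratio; emitting NaN", stacklevel=2
                    )
                out[f"{stat}_{pair}"] = np.nan
            else:
                out[f"{stat}_{pair}"] = num / den
    return out


def _outer_endpoint(segmentation: SegmentationResult, segment: str) -> int:
    """1-based index of the segment endpoint farthest from the aneurysm."""
    lo, hi = segmentation.ranges[SEGMENT_KEYS[segment]]
    return lo if segment.startswith("P") else hi


def endpoint_diameters(profile: CrossSectionProfile, segmentation: SegmentationResult) -> dict:
    """Major-axis diameter at the outer endpoint of each segment."""
    return {
        _endpoint_name("MajorAxis", seg): float(
            profile.max_diameter[_outer_endpoint(segmentation, seg) - 1]
        )
        for seg in SEGMENTS
    }


@dataclass
class NeckFeatures:
    """Angle (degrees) and distance (mm) between the tangents at a and b."""

    alpha: float
    d: float


def neck_features(centreline: Centreline, a: int, b: int) -> NeckFeatures:
    """Neck geometry from the centreline tangents at the aneurysm endpoints."""
    if centreline.tangent is None:
        raise ValueError("centreline has no tangents; run frenet() first")
    ta = centreline.tangent[a - 1]
    tb = centreline.tangent[b - 1]
    if not (np.all(np.isfinite(ta)) and np.all(np.isfinite(tb))):
        raise ValueError(f"tangent undefined at aneurysm endpoint {a} or {b}")
    cosang = float(np.clip(ta @ tb, -1.0, 1.0))
    alpha = float(np.degrees(np.arccos(cosang)))
    d = float(np.linalg.norm(centreline.points[a - 1] - centreline.points[b - 1]))
    return NeckFeatures(alpha=alpha, d=d)


# ---------------------------------------------------------------------------
# per-case assembly


def _index_series(centreline: Centreline, profile: CrossSectionProfile):
    """Map index name -> (series, defined-mask or None)."""
    return {
        "Curvature": (centreline.curvature, None),
        "Torsion": (centreline.torsion, centreline.frame_defined),
        "CrossArea": (profile.area, None),
        "AreaChangeRate": (profile.area_change_rate, None),
        "Eccentricity": (profile.eccentricity, None),
        "Solidity": (profile.solidity, None),
        "Extent": (profile.extent, None),
        "MajorAxis": (profile.max_diameter, None),
        "MinorAxis": (profile.min_diameter, None),
        "EquivDiameter": (profile.equivalent_diameter, None),
    }


def _segment_lengths(centreline: Centreline, segmentation: SegmentationResult) -> dict:
    arc = centreline.arc_length
    pts = centreline.points
    ranges = dict(segmentation.ranges)
    # whole-side aggregates: proximal = P2+P1, distal = D1+D2
    ranges["Prox"] = (segmentation.P2[0], segmentation.P1[1])
    ranges["Dist"] = (segmentation.D1[0], segmentation.D2[1])
    out = {}
    for label in (*SEGMENTS, "Prox", "Dist"):
        key = SEGMENT_KEYS.get(label, label)
        lo, hi = ranges[key]
        arc_len = float(arc[hi - 1] - arc[lo - 1])
        chord = float(np.linalg.norm(pts[hi - 1] - pts[lo - 1]))
        out[f"ArcLength_{label}"] = arc_len
        out[f"ChordLength_{label}"] = chord
        out[f"Tortuosity_{label}"] = arc_len / chord if chord > 0 else np.nan
    for quantity in ("ArcLength", "ChordLength", "Tortuosity"):
        for pair, (num_seg, den_seg) in LENGTH_PAIRS.items():
            den = out[f"{quantity}_{den_seg}"]
            out[f"{quantity}_{pair}"] = out[f"{quantity}_{num_seg}"] / den if den else np.nan
    return out


def compute_case_features(
    centreline: Centreline,
    profile: CrossSectionProfile,
    segmentation: SegmentationResult,
    registry: FeatureRegistry | None = None,
) -> dict:
    """All registry features for one case, as an ordered name -> value dict."""
    registry = registry or default_registry()
    series = _index_series(centreline, profile)

    stats: dict[str, dict[str, dict[str, float]]] = {}
    for index, (values, defined) in series.items():
        stats[index] = {}
        for seg in SEGMENTS:
            rng = segmentation.ranges[SEGMENT_KEYS[seg]]
            stats[index][seg] = segment_statistics(
                values, centreline.arc_length, rng, defined
            )

    ratios = {
        index: ratio_features(stats[index], index=index) for index in RATIO_INDICES
    }
    lengths = _segment_lengths(centreline, segmentation)
    a, b = segmentation.A
    neck = neck_features(centreline, a, b)
    line_dist = float(np.linalg.norm(centreline.points[-1] - centreline.points[0]))
    point_dist = float(centreline.arc_length[-1] - centreline.arc_length[0])

    values: dict[str, float] = {}
    for spec in registry.specs:
        if spec.kind == "segment_stat":
            values[spec.name] = stats[spec.index][spec.segments[0]][spec.statistic]
        elif spec.kind == "ratio":
            pair = "PD" if spec.segments == ("P", "D") else "PD2"
            values[spec.name] = ratios[spec.index][f"{spec.statistic}_{pair}"]
        elif spec.kind == "endpoint":
            idx = _outer_endpoint(segmentation, spec.segments[0]) - 1
            values[spec.name] = float(series[spec.index][0][idx])
        elif spec.kind == "endpoint_ratio":
            num_seg, den_seg = spec.segments
            num = float(series[spec.index][0][_outer_endpoint(segmentation, num_seg) - 1])
            den = float(series[spec.index][0][_outer_endpoint(segmentation, den_seg) - 1])
            values[spec.name] = num / den if den != 0.0 else np.nan
        elif spec.kind == "length":
            values[spec.name] = lengths[spec.name]
        elif spec.kind == "neck":
            values[spec.name] = neck.alpha if spec.name == "Neck_alpha" else neck.d
        elif spec.kind == "global":
            values[spec.name] = line_dist if spec.name == "LineDist" else point_dist
        else:  # pragma: no cover - registry is closed
            raise ValueError(f"unknown feature kind {spec.kind}")
    return values


def build_feature_matrix(
    cases: list,
    registry: FeatureRegistry | None = None,
) -> tuple[pd.DataFrame, list]:
    """Feature matrix for a cohort.

    ``cases`` is a list of ``(identifier, label, centreline, profile,
    segmentation)`` tuples.  Returns the matrix (columns: identifier,
    label, then the registry features in order) and a list of
    ``(identifier, error)`` pairs for cases whose extraction failed; failed
    cases are reported, never silently dropped.
    """
    registry = registry or default_registry()
    rows = []
    failures = []
    for identifier, label, centreline, profile, segmentation in cases:
        try:
            values = compute_case_features(centreline, profile, segmentation, registry)
        except Exception as exc:  # per-case isolation
            failures.append((identifier, exc))
            warnings.warn(f"feature extraction failed for {identifier}: {exc}", stacklevel=2)
            continue
        rows.append({"identifier": identifier, "label": label, **values})
    matrix = pd.DataFrame(rows, columns=["identifier", "label", *registry.names])
    return matrix, failures
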