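"""Centreline differential geometry.

A vessel centreline is an ordered sequence of 3-D points tracing the lumen
centre from the proximal to the distal end.  This module fits a smooth space
curve through those points and evaluates the quantities every downstream
stage consumes: cumulative arc length, the Frenet-Serret frame (tangent,
normal, binormal unit vectors), curvature ``kappa`` and torsion ``tau``.

Curvature and torsion are computed from spline derivatives::

    kappa = |r' x r''| / |r'|^3
    tau   = (r' x r'') . r''' / |r' x r''|^2

At points where the curve is locally straight (``kappa`` below a configurable
floor) the normal and binormal are undefined; such points are flagged rather
than filled with NaN so that downstream statistics can skip them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import splev, splprep

__all__ = [
    "Centreline",
    "DegenerateInputError",
    "fit_centreline",
    "frenet",
    "read_centreline_table",
]

#: curvature below this value (1/mm) marks a locally straight point where the
#: Frenet normal/binormal (and hence torsion) are undefined
DEFAULT_CURVATURE_FLOOR = 1e-8


class DegenerateInputError(ValueError):
    """Raised for centreline inputs a spline cannot be fitted through."""


@dataclass
class Centreline:
    """A fitted centreline with its differential geometry.

    Attributes
    ----------
    points : (n, 3) float array
        Curve samples in mm, ordered proximal to distal.
    arc_length : (n,) float array
        Cumulative arc length in mm, strictly increasing, 0 at the first
        point, computed by dense quadrature on the fitted spline.
    tangent, normal, binormal : (n, 3) float arrays or None
        Frenet frame unit vectors; ``None`` until :func:`frenet` runs.
        Rows where ``frame_defined`` is False hold zeros.
    curvature, torsion : (n,) float arrays or None
        kappa >= 0 and signed tau in 1/mm; ``None`` until :func:`frenet` runs.
        Torsion is reported as 0 at flagged points.
    frame_defined : (n,) bool array or None
        False where curvature fell below the floor, leaving N, B and tau
        undefined.
    """

    points: np.ndarray
    arc_length: np.ndarray
    tangent: np.ndarray | None = None
    normal: np.ndarray | None = None
    binormal: np.ndarray | None = None
    curvature: np.ndarray | None = None
    torsion: np.ndarray | None = None
    frame_defined: np.ndarray | None = None
    # spline representation: (t, c, k) from splprep plus parameter values
    _tck: tuple = field(default=None, repr=False)
    _u: np.ndarray = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.points)


def _chord_parameter(points: np.ndarray) -> np.ndarray:
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(steps == 0.0):
        i = int(np.flatnonzero(steps == 0.0)[0])
        raise DegenerateInputError(
            f"consecutive centreline points {i} and {i + 1} coincide"
        )
    return np.concatenate([[0.0], np.cumsum(steps)])


def fit_centreline(
    points: np.ndarray,
    smoothing: float = 0.0,
    *,
    spline_order: int = 3,
    quadrature_subdivisions: int = 20,
) -> Centreline:
    """Fit a C2 cubic spline through ordered centreline points.

    Each coordinate is fitted against the chord-length parameter; with
    ``smoothing = 0`` (default) the spline interpolates the input points.
    The curve is re-sampled at the input parameter values, so the returned
    centreline has exactly as many points as the input.  Arc length is
    obtained by trapezoidal quadrature of the spline speed on a grid
    ``quadrature_subdivisions`` times denser than the input.

    Parameters
    ----------
    points : (n, 3) array_like
        Ordered samples, n >= 8, consecutive points distinct.
    smoothing : float
        Non-negative smoothing factor passed to the spline fit
        (sum-of-squared-residuals budget, mm^2).

    Raises
    ------
    DegenerateInputError
        On fewer than 8 points or coincident consecutive points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DegenerateInputError(f"expected (n, 3) points, got {pts.shape}")
    if len(pts) < 8:
        raise DegenerateInputError(f"need at least 8 points, got {len(pts)}")
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")

    u = _chord_parameter(pts)
    tck, _ = splprep(pts.T, u=u, s=smoothing, k=spline_order)

    # dense speed quadrature for arc length; the dense grid contains the
    # input parameters so cumulative sums can be read off exactly at them
    dense = np.unique(
        np.concatenate(
            [np.linspace(u[i], u[i + 1], quadrature_subdivisions + 1) for i in range(len(u) - 1)]
        )
    )
    speed = np.linalg.norm(np.array(splev(dense, tck, der=1)), axis=0)
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(dense))]
    )
    arc = np.interp(u, dense, cum)

    fitted = np.array(splev(u, tck)).T
    return Centreline(points=fitted, arc_length=arc, _tck=tck, _u=u)


def frenet(
    centreline: Centreline,
    curvature_floor: float = DEFAULT_CURVATURE_FLOOR,
) -> Centreline:
    """Populate tangent, normal, binormal, curvature and torsion in place.

    Derivatives are one-sided at the ends (the spline is simply evaluated at
    the boundary parameters; no phantom points are added).  Where curvature
    falls below ``curvature_floor`` the point is flagged: N and B rows are
    zero, torsion is reported as 0 and ``frame_defined`` is False there.

    Returns the same :class:`Centreline` instance for chaining.
    """
    if centreline._tck is None:
        raise ValueError("centreline has no fitted spline; call fit_centreline first")
    tck, u = centreline._tck, centreline._u
    d1 = np.array(splev(u, tck, der=1)).T
    d2 = np.array(splev(u, tck, der=2)).T
    d3 = np.array(splev(u, tck, der=3)).T

    speed = np.linalg.norm(d1, axis=1)
    cross = np.cross(d1, d2)
    cross_norm = np.linalg.norm(cross, axis=1)

    kappa = cross_norm / speed**3
    defined = kappa >= curvature_floor

    tangent = d1 / speed[:, None]
    binormal = np.zeros_like(tangent)
    normal = np.zeros_like(tangent)
    tau = np.zeros(len(u))
    if np.any(defined):
        binormal[defined] = cross[defined] / cross_norm[defined, None]
        normal[defined] = np.cross(binormal[defined], tangent[defined])
        tau[defined] = (
            np.einsum("ij,ij->i", cross[defined], d3[defined])
            / cross_norm[defined] ** 2
        )

    centreline.tangent = tangent
    centreline.normal = normal
    centreline.binormal = binormal
    centreline.curvature = kappa
    centreline.torsion = tau
    centreline.frame_defined = defined
    return centreline


def read_centreline_table(path) -> np.ndarray:
    """Read an ordered x y z centreline table (whitespace or comma delimited).

    Lines starting with ``#`` are comments.  Points are ordered proximal to
    distal, one per row.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise DegenerateInputError(f"malformed centreline row: {line!r}")
            rows.append([float(v) for v in parts[:3]])
    return np.asarray(rows, dtype=float)
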