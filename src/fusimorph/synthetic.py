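"""Synthetic vascular phantoms with known geometry and planted class effects.

The clinical material this analysis is designed for — surface meshes of
vertebral arteries harbouring a fusiform aneurysm, with the aneurysm
start/end annotated on the centreline — cannot be redistributed, so this
module generates stand-in phantoms whose geometry is known analytically:

* a smooth 3-D centreline (an exact helix, or a curve integrated from
  prescribed curvature/torsion profiles via the Frenet-Serret equations),
* near-elliptical cross-sections with controllable area and eccentricity
  series, including a smooth fusiform bulge between the annotated
  endpoints ``a`` and ``b``,
* optionally a watertight triangulated tube surface lofted through the
  elliptical sections.

:func:`make_cohort` draws a labelled cohort (default 37 cases, 12 ruptured)
in which the rupture label shifts a small set of generation knobs so that
the five headline discriminative features of the analysis respond in the
direction the analysis targets: ruptured cases get a smaller proximal/distal
mean-curvature ratio, a smaller distal-2 endpoint diameter, a more variable
eccentricity in proximal 2, a smaller proximal curvature integral and a
larger proximal-2/distal-2 area ratio.  A zeroed effect configuration makes
the two classes exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields
import json
from pathlib import Path

import numpy as np

from .centreline import fit_centreline, frenet

__all__ = [
    "VesselSpec",
    "SyntheticCase",
    "SyntheticCohort",
    "EffectConfig",
    "InvalidSpecError",
    "LoftError",
    "make_centreline",
    "make_profile",
    "make_mesh",
    "make_cohort",
]


class InvalidSpecError(ValueError):
    """Raised for a degenerate or inconsistent vessel specification."""


class LoftError(RuntimeError):
    """Raised when lofting would self-intersect (curvature x radius too large)."""


@dataclass
class VesselSpec:
    """Full recipe for one phantom vessel.

    The annotated aneurysm occupies centreline indices ``[a, b]`` (1-based,
    inclusive).  ``default_s = min((a-1)/2, (n-b)/2)`` is the fallback
    segment length used downstream, so the default ``a=41, b=60, n=100``
    leaves 20 points for each of the four non-aneurysm segments.
    """

    centreline_kind: str = "helix"  # "helix" | "perturbed_spline"
    helix_radius: float = 2.0  # mm
    helix_pitch: float = 1.0  # mm per radian
    n_points: int = 100
    a: int = 41  # aneurysm start index, 1-based
    b: int = 60  # aneurysm end index, 1-based
    base_area: float = 7.0  # mm^2; a ~3 mm calibre artery
    bulge_amplitude: float = 2.5  # peak area multiplier inside [a, b]
    eccentricity_mean: float = 0.45
    eccentricity_sd_proximal2: float = 0.03
    distal_taper: float = 1.0  # multiplicative factor on end-distal diameters
    distal_area_scale: float = 1.0  # multiplicative area factor over the
    # far-distal (D2-like) half of the distal run
    distal_ramp_offset: int = 0  # per-case shift (points) of the far-distal
    # area transition relative to the middle of the distal run
    proximal_end_scale: float = 1.0  # area factor over the first few points
    # (imaging-truncation variability at the proximal end)
    noise_sd: float = 0.0  # relative (multiplicative) area noise
    area_trend: float = 0.0  # total relative area decline proximal -> distal
    # (gentle physiological taper; dominates the change-point threshold)
    seed: int = 0

    # centreline shaping (perturbed_spline kind)
    point_spacing: float = 0.30  # mm of arc between consecutive samples
    proximal_length_factor: float = 1.0  # spacing multiplier proximal of a
    distal_length_factor: float = 1.0  # spacing multiplier distal of b
    curvature_proximal: float = 0.18  # 1/mm level just proximal of the bulge
    curvature_distal: float = 0.18  # 1/mm level just distal of the bulge
    curvature_base: float = 0.0  # far-field level; 0 = geometric mean of the above
    curvature_influence: float = 3.5  # mm of full neck-level plateau
    curvature_decay: float = 3.0  # mm of transition back to the base level
    curvature_wiggle: float = 0.2  # relative amplitude of smooth curvature waves
    curvature_wiggle_asymmetry: float = 0.0  # log-scale proximal/distal wave
    # amplitude imbalance (proximal amp x e^u, distal x e^-u)
    torsion_level: float = 0.05  # 1/mm
    torsion_wave_amplitude: float = 0.0  # 1/mm; smooth torsion oscillation
    # that re-orients the bending plane along the vessel (varies chord
    # shortening at fixed curvature integral)

    # profile shaping
    eccentricity_noise_sd: float = 0.008  # iid eccentricity jitter everywhere
    eccentricity_distal_shift: float = 0.0  # distal-half eccentricity offset
    eccentricity_distal_slope: float = 0.0  # linear eccentricity drift over
    # the distal run (total change from b to the distal end)
    eccentricity_end_drop: float = 0.0  # eccentricity decrease over the tail
    eccentricity_end_window: int = 4  # points over which the end drop acts
    tail_minor_axis_jitter: float = 0.0  # log-sd of per-point minor-axis
    # irregularity over the distal tail (area and eccentricity co-vary so
    # the major axis is preserved)
    taper_window: int | None = None  # points over which the distal taper ramps
    bulge_ramp: int = 5  # points of raised-cosine transition into the bulge

    def validate(self) -> None:
        if not (1 < self.a < self.b < self.n_points):
            raise InvalidSpecError(
                f"need 1 < a < b < n, got a={self.a}, b={self.b}, n={self.n_points}"
            )
        if self.n_points < 40:
            raise InvalidSpecError(f"need n >= 40, got {self.n_points}")
        if self.bulge_amplitude < 1.0:
            raise InvalidSpecError("bulge_amplitude must be >= 1")
        if not (0.0 <= self.eccentricity_mean < 1.0):
            raise InvalidSpecError("eccentricity_mean must be in [0, 1)")
        if self.centreline_kind == "helix":
            if self.helix_radius == 0.0 and self.helix_pitch == 0.0:
                raise InvalidSpecError("helix with R=0 and c=0 is a point")
        elif self.centreline_kind != "perturbed_spline":
            raise InvalidSpecError(f"unknown centreline kind {self.centreline_kind!r}")

    @property
    def resolved_taper_window(self) -> int:
        """End pinch window: concentrated near the distal tip."""
        if self.taper_window is not None:
            return self.taper_window
        return max(3, (self.n_points - self.b) // 6)


@dataclass
class SyntheticCase:
    """One generated phantom with its ground truth and label."""

    identifier: str
    spec: VesselSpec
    points: np.ndarray  # (n, 3) centreline samples, mm
    curvature_true: np.ndarray  # (n,) analytic/prescribed kappa, 1/mm
    torsion_true: np.ndarray  # (n,) analytic/prescribed tau, 1/mm
    area: np.ndarray  # (n,) cross-sectional areas, mm^2
    eccentricity: np.ndarray  # (n,)
    label: str  # "ruptured" | "unruptured"


@dataclass
class SyntheticCohort:
    cases: list[SyntheticCase]
    effect_config: "EffectConfig"
    seed: int

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.cases]

    def write_ground_truth(self, directory) -> None:
        """Per-case ground-truth tables plus a cohort manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for case in self.cases:
            table = directory / f"{case.identifier}_truth.tsv"
            with open(table, "w") as fh:
                fh.write("# index\tx\ty\tz\tarea\teccentricity\n")
                for i in range(len(case.points)):
                    x, y, z = case.points[i]
                    fh.write(
                        f"{i + 1}\t{x:.8g}\t{y:.8g}\t{z:.8g}"
                        f"\t{case.area[i]:.8g}\t{case.eccentricity[i]:.8g}\n"
                    )
        manifest = {
            "seed": self.seed,
            "cases": [
                {"identifier": c.identifier, "label": c.label, "seed": c.spec.seed}
                for c in self.cases
            ],
        }
        with open(directory / "cohort_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)


# ---------------------------------------------------------------------------
# centreline generation


def _spacing_series(spec: VesselSpec) -> np.ndarray:
    """Arc spacing between consecutive samples, with per-side length factors.

    Spacing is ``point_spacing * proximal_length_factor`` proximal of ``a``,
    ``* distal_length_factor`` distal of ``b``, cosine-blended across the
    aneurysm so the series stays smooth.
    """
    n = spec.n_points
    idx = np.arange(n - 1, dtype=float)  # spacing i sits between points i, i+1
    t = np.clip((idx - (spec.a - 1)) / max(spec.b - spec.a, 1), 0.0, 1.0)
    blend = 0.5 * (1.0 - np.cos(np.pi * t))  # 0 proximal -> 1 distal
    factor = spec.proximal_length_factor * (1.0 - blend) + spec.distal_length_factor * blend
    return spec.point_spacing * factor


def _helix_centreline(spec: VesselSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    R, c = spec.helix_radius, spec.helix_pitch
    ds = _spacing_series(spec)
    speed = np.hypot(R, c)  # |dr/dt| for r(t) = (R cos t, R sin t, c t)
    t = np.concatenate([[0.0], np.cumsum(ds / speed)])
    if R == 0.0:
        points = np.c_[np.zeros_like(t), np.zeros_like(t), c * t]
        kappa = np.zeros_like(t)
        tau = np.zeros_like(t)
    else:
        points = np.c_[R * np.cos(t), R * np.sin(t), c * t]
        kappa = np.full_like(t, R / (R**2 + c**2))
        tau = np.full_like(t, c / (R**2 + c**2))
    return points, kappa, tau


def _prescribed_curvature(
    spec: VesselSpec, s: np.ndarray, s_a: float, s_b: float, total: float, rng
) -> np.ndarray:
    """Smooth curvature profile: proximal level -> distal level plus waves.

    ``s_a``/``s_b`` are the arc positions of the aneurysm endpoints.  The
    near-neck levels (``curvature_proximal`` just before ``s_a``,
    ``curvature_distal`` just after ``s_b``) hold over an
    ``curvature_influence``-mm plateau and relax to the far-field base
    level over ``curvature_decay`` mm, so the proximal/distal contrast is a
    neck-local property rather than a whole-vessel one.  Short-wavelength
    waves ride on top; their amplitude scales with the geometric mean of
    the two neck levels, so the waviness carries no proximal/distal
    asymmetry.
    """
    base = spec.curvature_base
    if base <= 0.0:
        base = float(np.sqrt(spec.curvature_proximal * spec.curvature_distal))

    def neck_weight(dist):
        """1 on the plateau, cosine-decaying to 0 beyond it."""
        w = np.zeros_like(dist)
        w[dist <= spec.curvature_influence] = 1.0
        tail = (dist > spec.curvature_influence) & (
            dist <= spec.curvature_influence + spec.curvature_decay
        )
        w[tail] = 0.5 * (
            1.0 + np.cos(np.pi * (dist[tail] - spec.curvature_influence) / spec.curvature_decay)
        )
        return w

    log_level = np.log(base) * np.ones_like(s)
    prox = s <= s_a
    dist = s >= s_b
    wp = neck_weight(s_a - s[prox])
    wd = neck_weight(s[dist] - s_b)
    log_level[prox] += np.log(spec.curvature_proximal / base) * wp
    log_level[dist] += np.log(spec.curvature_distal / base) * wd
    inside = (~prox) & (~dist)
    t = (s[inside] - s_a) / max(s_b - s_a, 1e-9)
    log_level[inside] = (
        np.log(spec.curvature_proximal) * (1 - t) + np.log(spec.curvature_distal) * t
    )
    level = np.exp(log_level)

    wiggle = np.zeros_like(s)
    if spec.curvature_wiggle > 0:
        amp = spec.curvature_wiggle * np.sqrt(
            spec.curvature_proximal * spec.curvature_distal
        ) / 2.0
        for wavelength in (total / 10.0, total / 16.0):
            phase = rng.uniform(0, 2 * np.pi)
            wiggle += amp * np.sin(2 * np.pi * s / wavelength + phase)
        if spec.curvature_wiggle_asymmetry != 0.0:
            t_side = np.clip((s - s_a) / max(s_b - s_a, 1e-9), 0.0, 1.0)
            u = spec.curvature_wiggle_asymmetry
            wiggle = wiggle * np.exp(u * (1.0 - 2.0 * t_side))
    return np.clip(level + wiggle, 0.02, None)


def _frenet_integrate(
    s_nodes: np.ndarray, kappa_fn, tau_fn, substeps: int = 8
) -> np.ndarray:
    """Integrate r' = T, T' = kN, N' = -kT + tB, B' = -tN by RK4.

    Returns curve points at ``s_nodes``.  The frame is re-orthonormalized
    after every step to suppress drift.
    """
    r = np.zeros(3)
    T = np.array([1.0, 0.0, 0.0])
    N = np.array([0.0, 1.0, 0.0])
    B = np.array([0.0, 0.0, 1.0])
    points = [r.copy()]

    def deriv(state, s):
        r_, T_, N_, B_ = state
        k, t = kappa_fn(s), tau_fn(s)
        return (T_, k * N_, -k * T_ + t * B_, -t * N_)

    state = (r, T, N, B)
    for i in range(len(s_nodes) - 1):
        h_total = s_nodes[i + 1] - s_nodes[i]
        h = h_total / substeps
        s = s_nodes[i]
        for _ in range(substeps):
            k1 = deriv(state, s)
            k2 = deriv(tuple(x + 0.5 * h * d for x, d in zip(state, k1)), s + 0.5 * h)
            k3 = deriv(tuple(x + 0.5 * h * d for x, d in zip(state, k2)), s + 0.5 * h)
            k4 = deriv(tuple(x + h * d for x, d in zip(state, k3)), s + h)
            state = tuple(
                x + (h / 6.0) * (d1 + 2 * d2 + 2 * d3 + d4)
                for x, d1, d2, d3, d4 in zip(state, k1, k2, k3, k4)
            )
            s += h
            r_, T_, N_, B_ = state
            T_ = T_ / np.linalg.norm(T_)
            N_ = N_ - (N_ @ T_) * T_
            N_ = N_ / np.linalg.norm(N_)
            B_ = np.cross(T_, N_)
            state = (r_, T_, N_, B_)
        points.append(state[0].copy())
    return np.asarray(points)


def make_centreline(spec: VesselSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate ordered centreline points plus ground-truth curvature/torsion.

    Returns ``(points, kappa, tau)``.  For the helix kind the closed forms
    ``kappa = R / (R^2 + c^2)`` and ``tau = c / (R^2 + c^2)`` hold at every
    point; for the perturbed-spline kind the returned series are the
    prescribed profiles the curve was integrated from.
    """
    spec.validate()
    if spec.centreline_kind == "helix":
        return _helix_centreline(spec)

    rng = np.random.default_rng(spec.seed)
    ds = _spacing_series(spec)
    s_nodes = np.concatenate([[0.0], np.cumsum(ds)])
    total = s_nodes[-1]
    # prescribe on a dense grid, interpolate inside the integrator
    s_dense = np.linspace(0.0, total, 8 * spec.n_points)
    kappa_dense = _prescribed_curvature(
        spec, s_dense, s_nodes[spec.a - 1], s_nodes[spec.b - 1], total, rng
    )
    tau_dense = np.full_like(s_dense, spec.torsion_level)
    if spec.torsion_wave_amplitude != 0.0:
        phase = rng.uniform(0, 2 * np.pi)
        tau_dense = tau_dense + spec.torsion_wave_amplitude * np.sin(
            2 * np.pi * s_dense / (total / 6.0) + phase
        )

    def kappa_fn(s):
        return np.interp(s, s_dense, kappa_dense)

    def tau_fn(s):
        return np.interp(s, s_dense, tau_dense)

    points = _frenet_integrate(s_nodes, kappa_fn, tau_fn)
    kappa = np.interp(s_nodes, s_dense, kappa_dense)
    tau = np.interp(s_nodes, s_dense, tau_dense)
    return points, kappa, tau


# ---------------------------------------------------------------------------
# cross-section profile generation


def _bulge_weight(spec: VesselSpec) -> np.ndarray:
    """Raised-cosine bulge weight in [0, 1]: 0 outside [a, b], 1 at the plateau."""
    n = spec.n_points
    w = np.zeros(n)
    lo, hi = spec.a - 1, spec.b - 1  # 0-based inclusive
    length = hi - lo + 1
    ramp = min(spec.bulge_ramp, max(1, (length - 1) // 2))
    for j in range(length):
        d = min(j, length - 1 - j)
        w[lo + j] = 1.0 if d >= ramp else 0.5 * (1.0 - np.cos(np.pi * d / ramp))
        if length == 1:
            w[lo + j] = 1.0
    # guarantee the plateau value is reached at the centre
    w[lo + (length - 1) // 2] = 1.0
    w[lo + length // 2] = 1.0
    return w


def _taper_scale(spec: VesselSpec) -> np.ndarray:
    """Per-point diameter scale: 1 everywhere, easing to ``distal_taper`` at the end."""
    n = spec.n_points
    scale = np.ones(n)
    window = min(spec.resolved_taper_window, n - spec.b)
    if window <= 0 or spec.distal_taper == 1.0:
        return scale
    start = n - window  # 0-based index where the ramp begins
    j = np.arange(window) + 1
    blend = 0.5 * (1.0 - np.cos(np.pi * j / window))
    scale[start:] = 1.0 + (spec.distal_taper - 1.0) * blend
    return scale


def _far_distal_area_scale(spec: VesselSpec) -> np.ndarray:
    """Area scale reaching ``distal_area_scale`` over the far-distal half.

    The plateau covers the second half of the distal run (the D2-like
    region under the fallback segmentation), entered through a short
    raised-cosine ramp so the area series stays smooth.
    """
    n = spec.n_points
    scale = np.ones(n)
    if spec.distal_area_scale == 1.0:
        return scale
    # plateau onset near the middle of the distal run, jittered per case so
    # the transition has no fixed relation to the segment boundaries
    onset = spec.b + (n - spec.b) // 2 + 2 + spec.distal_ramp_offset
    onset = int(np.clip(onset, spec.b + 4, n - 4))
    ramp = min(4, max(1, onset - spec.b - 1))
    j = np.arange(n - onset + ramp)
    blend = np.clip(j / ramp, 0.0, 1.0)
    blend = 0.5 * (1.0 - np.cos(np.pi * blend))
    scale[onset - ramp :] = 1.0 + (spec.distal_area_scale - 1.0) * blend
    return scale


def _proximal_end_scale(spec: VesselSpec, window: int = 8) -> np.ndarray:
    """Area scale easing from ``proximal_end_scale`` at point 1 back to 1."""
    scale = np.ones(spec.n_points)
    if spec.proximal_end_scale == 1.0:
        return scale
    j = np.arange(window)
    blend = 0.5 * (1.0 + np.cos(np.pi * j / window))  # 1 at the end, -> 0
    scale[:window] = 1.0 + (spec.proximal_end_scale - 1.0) * blend
    return scale


def make_profile(spec: VesselSpec) -> tuple[np.ndarray, np.ndarray]:
    """Target area and eccentricity series for a phantom.

    Area is ``base_area`` outside ``[a, b]``, smoothly raised to
    ``bulge_amplitude * base_area`` inside, scaled by the squared distal
    diameter taper, with optional multiplicative noise.  The eccentricity
    series is rescaled so its sample standard deviation over the proximal-2
    window (the first ``(a-1)//2`` points) equals
    ``eccentricity_sd_proximal2`` exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_points

    area = spec.base_area * (1.0 + (spec.bulge_amplitude - 1.0) * _bulge_weight(spec))
    area = (
        area
        * _taper_scale(spec) ** 2
        * _far_distal_area_scale(spec)
        * _proximal_end_scale(spec)
    )
    if spec.area_trend != 0.0:
        ramp = np.linspace(0.5, -0.5, n)
        area = area * (1.0 + spec.area_trend * ramp)
    if spec.noise_sd > 0:
        area = area * (1.0 + spec.noise_sd * rng.standard_normal(n))

    # eccentricity: case mean + iid jitter + smooth proximal-2 bump + end drop.
    # The bump amplitude is set so the proximal-2 window's total standard
    # deviation (bump plus jitter, in expectation) matches the target; with a
    # zero target the window is held exactly constant.
    ecc = np.full(n, spec.eccentricity_mean)
    eta = spec.eccentricity_noise_sd
    if eta > 0:
        ecc = ecc + eta * rng.standard_normal(n)
    p2 = max(2, (spec.a - 1) // 2)  # proximal-2 window: points 1..p2 (1-based)
    target = spec.eccentricity_sd_proximal2
    if target == 0.0:
        ecc[:p2] = spec.eccentricity_mean
    else:
        bump = np.sin(np.pi * 1.5 * np.arange(p2) / p2 + rng.uniform(0, 2 * np.pi))
        bump = bump - bump.mean()
        bump_sd = bump.std(ddof=1)
        amp = np.sqrt(max(target**2 - eta**2, 0.0))
        if bump_sd > 0:
            ecc[:p2] = ecc[:p2] + bump * (amp / bump_sd)
    if spec.eccentricity_distal_shift != 0.0:
        idx = np.arange(n, dtype=float)
        t = np.clip((idx - (spec.a - 1)) / max(spec.b - spec.a, 1), 0.0, 1.0)
        blend = 0.5 * (1.0 - np.cos(np.pi * t))
        ecc = ecc + spec.eccentricity_distal_shift * blend
    if spec.eccentricity_distal_slope != 0.0:
        drift = np.zeros(n)
        drift[spec.b :] = np.linspace(0.0, spec.eccentricity_distal_slope, n - spec.b)
        ecc = ecc + drift
    if spec.eccentricity_end_drop > 0:
        wnd = min(spec.eccentricity_end_window, n - spec.b)
        j = np.arange(wnd) + 1
        blend = 0.5 * (1.0 - np.cos(np.pi * j / wnd))
        ecc[n - wnd :] = ecc[n - wnd :] - spec.eccentricity_end_drop * blend
    ecc = np.clip(ecc, 0.0, 0.88)
    if spec.tail_minor_axis_jitter > 0:
        # irregular flattening of the distal tail: the minor axis wobbles
        # while the maximum caliber stays put, so area and eccentricity
        # move together at fixed major axis
        wnd = min(8, n - spec.b)
        delta = spec.tail_minor_axis_jitter * rng.standard_normal(wnd)
        ratio2 = (1.0 - ecc[n - wnd :] ** 2) * np.exp(2.0 * delta)
        ratio2 = np.clip(ratio2, 0.05, 1.0)
        area[n - wnd :] = area[n - wnd :] * np.sqrt(
            ratio2 / (1.0 - ecc[n - wnd :] ** 2)
        )
        ecc[n - wnd :] = np.sqrt(1.0 - ratio2)
    return area, ecc


# ---------------------------------------------------------------------------
# mesh lofting


def make_mesh(points: np.ndarray, area: np.ndarray, eccentricity: np.ndarray, sections: int = 48):
    """Loft a watertight triangulated tube through elliptical cross-sections.

    The ellipse at each centreline point has its major axis along the local
    Frenet normal (carried over unchanged through locally straight spots,
    and sign-aligned with the previous ring so the loft cannot twist).  The
    ends are capped with triangle fans.

    Raises
    ------
    LoftError
        If ``curvature * semi_major_axis`` approaches 1 anywhere, which
        would make adjacent rings interpenetrate; the message names the
        first offending centreline index (1-based).
    """
    import trimesh

    points = np.asarray(points, dtype=float)
    area = np.asarray(area, dtype=float)
    ecc = np.asarray(eccentricity, dtype=float)
    if len(points) < 40:
        raise InvalidSpecError("need at least 40 centreline points to loft")
    if np.any(area <= 0):
        raise InvalidSpecError("areas must be positive")

    cl = frenet(fit_centreline(points))
    ratio = np.sqrt(1.0 - ecc**2)
    semi_major = np.sqrt(area / (np.pi * ratio))
    semi_minor = semi_major * ratio

    bad = np.flatnonzero(cl.curvature * semi_major >= 0.95)
    if bad.size:
        raise LoftError(
            f"loft self-intersects at centreline index {bad[0] + 1}: "
            f"curvature x radius = {cl.curvature[bad[0]] * semi_major[bad[0]]:.3f}"
        )

    # propagate a stable frame: reuse the previous normal where undefined,
    # flip to stay aligned (N -> -N, B -> -B preserves handedness)
    n_pts = len(points)
    normals = np.empty((n_pts, 3))
    binormals = np.empty((n_pts, 3))
    prev_n, prev_b = None, None
    for i in range(n_pts):
        if cl.frame_defined[i]:
            ni, bi = cl.normal[i], cl.binormal[i]
            if prev_n is not None and ni @ prev_n < 0:
                ni, bi = -ni, -bi
        elif prev_n is not None:
            ni, bi = prev_n, prev_b
        else:
            t = cl.tangent[i]
            helper = np.array([1.0, 0.0, 0.0])
            if abs(t @ helper) > 0.9:
                helper = np.array([0.0, 1.0, 0.0])
            ni = np.cross(t, helper)
            ni /= np.linalg.norm(ni)
            bi = np.cross(t, ni)
        normals[i], binormals[i] = ni, bi
        prev_n, prev_b = ni, bi

    theta = np.linspace(0.0, 2 * np.pi, sections, endpoint=False)
    rings = (
        points[:, None, :]
        + semi_major[:, None, None] * np.cos(theta)[None, :, None] * normals[:, None, :]
        + semi_minor[:, None, None] * np.sin(theta)[None, :, None] * binormals[:, None, :]
    )
    vertices = rings.reshape(-1, 3)

    faces = []
    for i in range(n_pts - 1):
        base, nxt = i * sections, (i + 1) * sections
        for j in range(sections):
            k = (j + 1) % sections
            faces.append([base + j, nxt + j, nxt + k])
            faces.append([base + j, nxt + k, base + k])
    start_centre = len(vertices)
    end_centre = start_centre + 1
    vertices = np.vstack([vertices, points[0], points[-1]])
    last = (n_pts - 1) * sections
    for j in range(sections):
        k = (j + 1) % sections
        faces.append([start_centre, j, k])  # proximal cap
        faces.append([end_centre, last + k, last + j])  # distal cap
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    mesh.fix_normals()
    return mesh


def write_stl(mesh, path) -> None:
    """Binary little-endian STL with the standard 80-byte header."""
    mesh.export(path, file_type="stl")


# ---------------------------------------------------------------------------
# cohort generation


#: class-independent case-level variability (log-scale sds unless noted);
#: these set how strongly absolute size/level features are diluted relative
#: to the targeted class effects
NUISANCE = {
    "log_kappa_base_sd": 0.18,  # shared far-field curvature level
    "log_spacing_sd": 0.14,  # shared point spacing (overall vessel length)
    "kappa_spacing_corr": -0.8,  # tortuous vessels run shorter between landmarks
    "log_dist_length_sd": 0.30,  # unshared distal length factor
    "log_base_area_sd": 0.15,  # vessel calibre
    "log_prox_end_sd": 0.30,  # proximal-end truncation (area at the first points)
    "ecc_mean_sd": 0.08,
    "ecc_distal_shift": (0.08, 0.20),  # distal eccentricity baseline offset
    "ecc_distal_slope_sd": 0.10,  # class-independent distal ecc drift
    "curvature_wiggle_range": (0.20, 0.60),
    "wiggle_asymmetry_sd": 0.35,
    "torsion_range": (0.01, 0.10),
    "torsion_wave_range": (0.10, 0.50),
    "tail_minor_jitter_range": (0.03, 0.12),
    "area_noise_range": (0.005, 0.015),
    "area_trend_range": (0.20, 0.35),
    "distal_ramp_offset_range": (-6, 7),
    "ecc_noise_range": (0.008, 0.030),
}


@dataclass
class EffectConfig:
    """Class-conditional generation knobs.

    Each knob is ``(ruptured_mean, unruptured_mean, sd)``; per-case values
    are drawn from the class-specific normal.  The defaults plant effects
    on the five headline features, in the direction the analysis targets, while leaving
    sibling features dominated by class-independent nuisance variation; see
    the methods note for the calibration rationale.
    """

    log_curv_prox_shift: tuple = (-0.20, 0.0, 0.06)
    log_curv_dist_shift: tuple = (0.10, 0.0, 0.06)
    log_prox_length: tuple = (-0.24, 0.0, 0.05)
    log_area_d2: tuple = (-0.40, 0.0, 0.10)  # far-distal area scale (P2/D2 ratio)
    log_distal_taper: tuple = (np.log(0.88), np.log(0.98), 0.08)
    ecc_end_drop: tuple = (0.40, 0.02, 0.08)
    ecc_sd_p2: tuple = (0.085, 0.032, 0.014)

    @classmethod
    def null(cls) -> "EffectConfig":
        """Zero planted effects: both classes draw from the pooled mean."""
        cfg = cls()
        kwargs = {}
        for f in dataclass_fields(cls):
            r, u, sd = getattr(cfg, f.name)
            m = 0.5 * (r + u)
            kwargs[f.name] = (m, m, sd)
        return cls(**kwargs)

    def draw(self, knob: str, label: str, rng) -> float:
        r, u, sd = getattr(self, knob)
        mu = r if label == "ruptured" else u
        return float(rng.normal(mu, sd))


def make_cohort(
    n_cases: int = 37,
    n_ruptured: int = 12,
    effect_config: EffectConfig | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Draw a labelled cohort of perturbed-spline phantoms.

    Case-level nuisance parameters (vessel calibre, curvature level,
    segment spacing, noise amplitudes, aneurysm extent) are drawn
    identically for both classes; only the :class:`EffectConfig` knobs are
    class-conditional.  Identical seeds reproduce the cohort bit for bit.
    """
    if n_ruptured >= n_cases:
        raise InvalidSpecError("n_ruptured must be smaller than n_cases")
    cfg = effect_config if effect_config is not None else EffectConfig()
    rng = np.random.default_rng(seed)

    labels = ["ruptured"] * n_ruptured + ["unruptured"] * (n_cases - n_ruptured)
    cases = []
    width = max(2, len(str(n_cases)))
    for idx, label in enumerate(labels):
        case_seed = int(rng.integers(2**31))
        n = 100
        a = int(np.clip(41 + round(rng.normal(0.0, 2.5)), 33, 47))
        b = int(np.clip(a + 19 + round(rng.normal(0.0, 2.5)), a + 12, 68))

        nz = NUISANCE
        # tortuosity and inter-landmark run length co-vary negatively across
        # subjects: strongly curved vessels cover less straight-line span, so
        # the sampled run between anatomical landmarks is shorter
        sk, ss, rho = nz["log_kappa_base_sd"], nz["log_spacing_sd"], nz["kappa_spacing_corr"]
        z1, z2 = rng.standard_normal(2)
        log_kappa_base = np.log(0.18) + sk * z1
        spacing = float(np.exp(np.log(0.30) + ss * (rho * z1 + np.sqrt(1 - rho**2) * z2)))
        log_dist_length = rng.normal(0.0, nz["log_dist_length_sd"])

        spec = VesselSpec(
            centreline_kind="perturbed_spline",
            n_points=n,
            a=a,
            b=b,
            base_area=float(np.exp(rng.normal(np.log(7.0), nz["log_base_area_sd"]))),
            bulge_amplitude=float(rng.uniform(1.8, 3.2)),
            eccentricity_mean=float(
                np.clip(rng.normal(0.45, nz["ecc_mean_sd"]), 0.05, 0.75)
            ),
            eccentricity_sd_proximal2=float(
                max(0.002, cfg.draw("ecc_sd_p2", label, rng))
            ),
            distal_taper=float(np.exp(cfg.draw("log_distal_taper", label, rng))),
            distal_area_scale=float(np.exp(cfg.draw("log_area_d2", label, rng))),
            distal_ramp_offset=int(rng.integers(*nz["distal_ramp_offset_range"])),
            proximal_end_scale=float(np.exp(rng.normal(0.0, nz["log_prox_end_sd"]))),
            noise_sd=float(rng.uniform(*nz["area_noise_range"])),
            area_trend=float(rng.uniform(*nz["area_trend_range"])),
            seed=case_seed,
            point_spacing=spacing,
            proximal_length_factor=float(np.exp(cfg.draw("log_prox_length", label, rng))),
            distal_length_factor=float(np.exp(log_dist_length)),
            curvature_base=float(np.exp(log_kappa_base)),
            curvature_proximal=float(
                np.exp(log_kappa_base + cfg.draw("log_curv_prox_shift", label, rng))
            ),
            curvature_distal=float(
                np.exp(log_kappa_base + cfg.draw("log_curv_dist_shift", label, rng))
            ),
            curvature_wiggle=float(rng.uniform(*nz["curvature_wiggle_range"])),
            curvature_wiggle_asymmetry=float(rng.normal(0.0, nz["wiggle_asymmetry_sd"])),
            torsion_level=float(rng.uniform(*nz["torsion_range"])),
            torsion_wave_amplitude=float(rng.uniform(*nz["torsion_wave_range"])),
            eccentricity_noise_sd=float(rng.uniform(*nz["ecc_noise_range"])),
            eccentricity_distal_shift=float(
                np.clip(rng.normal(*nz["ecc_distal_shift"]), -0.25, 0.35)
            ),
            eccentricity_distal_slope=float(
                np.clip(rng.normal(0.0, nz["ecc_distal_slope_sd"]), -0.35, 0.35)
            ),
            tail_minor_axis_jitter=float(rng.uniform(*nz["tail_minor_jitter_range"])),
            eccentricity_end_drop=float(max(0.0, cfg.draw("ecc_end_drop", label, rng))),
        )
        points, kappa, tau = make_centreline(spec)
        area, ecc = make_profile(spec)
        cases.append(
            SyntheticCase(
                identifier=f"case{idx + 1:0{width}d}",
                spec=spec,
                points=points,
                curvature_true=kappa,
                torsion_true=tau,
                area=area,
                eccentricity=ecc,
                label=label,
            )
        )
    return SyntheticCohort(cases=cases, effect_config=cfg, seed=seed)
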