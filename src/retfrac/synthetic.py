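"""Synthetic inputs with known ground truth.

Four generator families, each deterministic under a fixed seed:

* ``sierpinski_mask`` — an exactly self-similar triangle raster whose
  box-counting dimension is log 3 / log 2 = 1.58496, the analytic oracle
  for the monofractal estimator.
* ``cascade_measure`` — a deterministic four-weight multiplicative cascade
  on the unit square whose generalized dimensions have the closed form
  D_q = log2(sum_i p_i^q) / (1 - q), the oracle for the multifractal
  pipeline.
* ``vessel_phantom`` — a fundus-like grayscale image (bright background
  with a smooth gradient and Gaussian noise, dark vessels of known
  centerline, width and class around an optic disc) plus its ground-truth
  mask and per-vessel truth table.  Vessel centerlines are straight lines
  and circular arcs only, so width and chord/arc tortuosity are analytic.
* ``cohort_sim`` — per-patient feature tables drawn from group-wise
  Gaussians whose default means/SDs are the study cohort's descriptive
  statistics, with a configurable near-perfect correlation between the
  capacity dimension and the singularity-spectrum maximum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .roi import OpticDisc

__all__ = [
    "CascadeSpec",
    "VesselSpec",
    "PhantomSpec",
    "CohortSpec",
    "sierpinski_mask",
    "cascade_measure",
    "cascade_dq_analytic",
    "vessel_phantom",
    "default_phantom_spec",
    "cohort_sim",
    "TABLE_MEANS",
]


# ---------------------------------------------------------------------------
# analytic fractal rasters

def sierpinski_mask(order: int, size: int | None = None) -> np.ndarray:
    """Deterministic Sierpinski-triangle occupancy raster.

    The base raster has side 2**order and exactly 3**order foreground unit
    cells (pixel (i, j) is set iff ``i & j == 0``); ``size`` upscales each
    unit cell by ``size // 2**order``.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    base = 2**order
    if size is None:
        size = base
    if size < base:
        raise ValueError(f"size {size} too small for order {order} (needs >= {base})")
    i = np.arange(base)
    mask = (i[:, None] & i[None, :]) == 0
    cell = size // base
    if cell > 1:
        mask = np.kron(mask, np.ones((cell, cell), dtype=bool))
    return mask


@dataclass(frozen=True)
class CascadeSpec:
    """Four quadrant weights (summing to 1) applied recursively ``depth`` times."""

    weights: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    depth: int = 9
    seed: int | None = None  # set to shuffle weight placement per cell

    def __post_init__(self) -> None:
        if len(self.weights) != 4 or any(w < 0 for w in self.weights):
            raise ValueError("need four nonnegative weights")
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def cascade_measure(spec: CascadeSpec) -> np.ndarray:
    """Multiplicative cascade measure on a 2^depth x 2^depth raster, mass 1.

    Deterministic placement tiles the weights as [[w0, w1], [w2, w3]] at
    every level; with a seed, the four weights are shuffled independently in
    each subdivided cell (a randomised cascade with the same D_q).
    """
    w = np.asarray(spec.weights, dtype=float)
    rng = np.random.default_rng(spec.seed) if spec.seed is not None else None
    m = np.ones((1, 1))
    for _ in range(spec.depth):
        n = m.shape[0]
        if rng is None:
            tile = np.tile(w.reshape(2, 2), (n, n))
        else:
            perms = np.array([rng.permutation(4) for _ in range(n * n)])
            cells = w[perms].reshape(n, n, 2, 2)
            tile = cells.transpose(0, 2, 1, 3).reshape(2 * n, 2 * n)
        m = np.kron(m, np.ones((2, 2))) * tile
    return m


def cascade_dq_analytic(weights, q) -> np.ndarray:
    """Closed-form D_q of the four-weight cascade: log2(sum p^q)/(1-q);
    the q = 1 limit is the entropy -sum p log2 p."""
    p = np.asarray([w for w in weights if w > 0], dtype=float)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    out = np.empty(q.shape)
    for i, qi in enumerate(q):
        if abs(qi - 1.0) < 1e-9:
            out[i] = -np.sum(p * np.log2(p))
        else:
            out[i] = np.log2(np.sum(p**qi)) / (1.0 - qi)
    return out if out.size > 1 else out  # always an array


# ---------------------------------------------------------------------------
# fundus-like vessel phantoms

@dataclass(frozen=True)
class VesselSpec:
    """One phantom vessel: a straight segment or a circular arc.

    Straight: ``p0`` -> ``p1`` (row, col).  Arc: ``center`` (row, col),
    ``radius`` and angle range ``theta0`` -> ``theta1`` (radians, traversed
    counterclockwise in (row, col) convention).
    """

    kind: str  # "straight" | "arc"
    width_px: float = 6.0
    vessel_class: str = "unknown"
    contrast: float = 90.0
    p0: tuple[float, float] | None = None
    p1: tuple[float, float] | None = None
    center: tuple[float, float] | None = None
    radius: float | None = None
    theta0: float = 0.0
    theta1: float = math.pi

    def __post_init__(self) -> None:
        if self.width_px < 1:
            raise ValueError("vessel width must be >= 1 px")
        if self.kind == "straight" and (self.p0 is None or self.p1 is None):
            raise ValueError("straight vessel needs p0 and p1")
        if self.kind == "arc" and (self.center is None or self.radius is None):
            raise ValueError("arc vessel needs center and radius")
        if self.kind not in ("straight", "arc"):
            raise ValueError(f"unknown vessel kind {self.kind!r}")

    def chord_arc_ratio(self) -> float:
        """Analytic chord/arc tortuosity of the centerline."""
        if self.kind == "straight":
            return 1.0
        theta = abs(self.theta1 - self.theta0)
        if theta <= 0:
            return 1.0
        return float(abs(2 * math.sin(theta / 2) / theta))

    def centerline(self, step: float = 0.25) -> np.ndarray:
        """Densely sampled centerline points (row, col)."""
        if self.kind == "straight":
            p0, p1 = np.asarray(self.p0), np.asarray(self.p1)
            n = max(int(np.hypot(*(p1 - p0)) / step), 2)
            t = np.linspace(0, 1, n)[:, None]
            return p0 + t * (p1 - p0)
        theta = np.linspace(
            self.theta0,
            self.theta1,
            max(int(abs(self.theta1 - self.theta0) * self.radius / step), 2),
        )
        cr, cc = self.center
        return np.column_stack(
            [cr + self.radius * np.sin(theta), cc + self.radius * np.cos(theta)]
        )

    def distance_field(self, shape: tuple[int, int]) -> np.ndarray:
        """Distance from every pixel centre to the centerline (analytic)."""
        rr = np.arange(shape[0], dtype=float)[:, None]
        cc = np.arange(shape[1], dtype=float)[None, :]
        if self.kind == "straight":
            p0 = np.asarray(self.p0, dtype=float)
            v = np.asarray(self.p1, dtype=float) - p0
            vv = v @ v
            t = ((rr - p0[0]) * v[0] + (cc - p0[1]) * v[1]) / vv
            t = np.clip(t, 0.0, 1.0)
            return np.hypot(rr - (p0[0] + t * v[0]), cc - (p0[1] + t * v[1]))
        cr, ccen = self.center
        dr, dc = rr - cr, cc - ccen
        ang = np.arctan2(dr, dc)  # matches (sin, cos) parametrisation
        # bring angle into the traversed range, handling wrap-around
        t0, t1 = sorted((self.theta0, self.theta1))
        two_pi = 2 * math.pi
        in_range = ((ang - t0) % two_pi) <= (t1 - t0)
        radial = np.abs(np.hypot(dr, dc) - self.radius)
        ends = self.centerline()[[0, -1]]
        d_ends = np.minimum(
            np.hypot(rr - ends[0, 0], cc - ends[0, 1]),
            np.hypot(rr - ends[1, 0], cc - ends[1, 1]),
        )
        return np.where(in_range, radial, d_ends)


@dataclass(frozen=True)
class PhantomSpec:
    """A fundus-like phantom: geometry, contrast, gradient and noise."""

    shape: tuple[int, int] = (256, 256)
    disc_center: tuple[float, float] = (128.0, 128.0)
    disc_radius_px: float = 20.0
    vessels: tuple[VesselSpec, ...] = ()
    background_level: float = 200.0
    gradient_amplitude: float = 10.0
    noise_sd: float = 2.0
    seed: int = 0


def vessel_phantom(
    spec: PhantomSpec,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, OpticDisc]:
    """Render a phantom: (image, truth mask, truth segment table, disc).

    The truth mask sets pixels whose centre lies strictly within
    ``width/2`` of a vessel centerline, so a straight even-width vessel of
    width w measures exactly w by the 2x-distance-transform rule.  Vessels
    are darker than the background by their ``contrast``.
    """
    rows, cols = spec.shape
    rng = np.random.default_rng(spec.seed)
    rr = np.arange(rows, dtype=float)[:, None]
    cc = np.arange(cols, dtype=float)[None, :]
    img = (
        spec.background_level
        + spec.gradient_amplitude * ((rr / rows) + (cc / cols) - 1.0)
    ) * np.ones((rows, cols))

    truth = np.zeros((rows, cols), dtype=bool)
    d_disc0 = np.hypot(rr - spec.disc_center[0], cc - spec.disc_center[1])
    records = []
    for i, v in enumerate(spec.vessels):
        d = v.distance_field((rows, cols))
        vm = d < (v.width_px / 2.0)
        if (vm & (d_disc0 <= spec.disc_radius_px)).any():
            warnings.warn(f"vessel {i} overlaps the optic disc", stacklevel=2)
        truth |= vm
        img[vm] -= v.contrast
        pts = v.centerline()
        records.append(
            {
                "vessel_id": i,
                "kind": v.kind,
                "vessel_class": v.vessel_class,
                "width_px": v.width_px,
                "chord_arc_ratio": v.chord_arc_ratio(),
                "n_centerline_points": len(pts),
            }
        )

    # bright optic disc, drawn after vessels (the disc region is excluded
    # from every ROI anyway)
    disc = OpticDisc(*spec.disc_center, spec.disc_radius_px)
    in_disc = d_disc0 <= spec.disc_radius_px
    img[in_disc] = spec.background_level + 30.0
    truth[in_disc] = False

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    return img, truth, pd.DataFrame(records), disc


def default_phantom_spec(seed: int = 0) -> PhantomSpec:
    """The default fundus-like phantom: a branching, tapering vessel tree.

    Twelve main vessels (alternating arteriole/venule, widths 6-12 px)
    radiate from an optic disc of radius R = 20 px at the centre of a
    256 x 256 frame, each spawning two child branches (about half the
    parent width) and twigs (3 px), so vessel density falls off from the
    disc hub to the periphery the way a real vascular tree's does — the
    multiscale heterogeneity that multifractal analysis measures.  The fan
    is rotated off the axis/diagonal directions, where strip rasterization
    is degenerate and distance-transform widths jump.  Branch points are
    placed outside the caliber annulus (radii 2R-3R) so the main vessels
    cross it unbroken.
    """
    rng = np.random.default_rng(seed)
    center = np.array([128.0, 128.0])
    R = 20.0
    vessels: list[VesselSpec] = []
    n_main = 12
    for k in range(n_main):
        ang = 2 * math.pi * (k + 0.25) / n_main
        w = float([6, 8, 10, 12][k % 4])
        u = np.array([math.sin(ang), math.cos(ang)])
        p0 = center + 1.5 * R * u
        p1 = center + 5.5 * R * u
        cls = "arteriole" if k % 2 == 0 else "venule"
        vessels.append(
            VesselSpec(kind="straight", p0=tuple(p0), p1=tuple(p1),
                       width_px=w, vessel_class=cls)
        )
        for t, dth in ((0.45, 0.5), (0.7, -0.6)):
            b0 = center + (1.5 + t * 4.0) * R * u
            ang2 = ang + dth + 0.1 * rng.standard_normal()
            u2 = np.array([math.sin(ang2), math.cos(ang2)])
            length = (2.0 - t) * R * 1.4
            b1 = np.clip(b0 + length * u2, 4.0, 251.0)
            vessels.append(
                VesselSpec(kind="straight", p0=tuple(b0), p1=tuple(b1),
                           width_px=max(3.0, w * 0.55), vessel_class="unknown")
            )
            ang3 = ang2 + (0.5 if dth < 0 else -0.5)
            u3 = np.array([math.sin(ang3), math.cos(ang3)])
            c0 = b0 + 0.6 * length * u2
            c1 = np.clip(c0 + 0.5 * length * u3, 4.0, 251.0)
            vessels.append(
                VesselSpec(kind="straight", p0=tuple(c0), p1=tuple(c1),
                           width_px=3.0, vessel_class="unknown")
            )
    return PhantomSpec(
        shape=(256, 256),
        disc_center=tuple(center),
        disc_radius_px=R,
        vessels=tuple(vessels),
        seed=seed,
    )


def caliber_phantom_spec(seed: int = 0) -> PhantomSpec:
    """Caliber phantom: 12 unbranched radial vessels (6 arterioles of
    widths 6-12 px, 6 venules of widths 8-12 px), so no junctions disturb
    the width measurements in the caliber annulus."""
    center = (128.0, 128.0)
    R = 20.0
    art_widths = [6.0, 6.0, 8.0, 8.0, 10.0, 12.0]
    ven_widths = [8.0, 8.0, 10.0, 10.0, 12.0, 12.0]
    vessels: list[VesselSpec] = []
    n_radial = 12
    for k in range(n_radial):
        ang = 2 * math.pi * (k + 0.25) / n_radial
        is_art = k % 2 == 0
        w = art_widths[k // 2] if is_art else ven_widths[k // 2]
        p0 = (center[0] + 1.5 * R * math.sin(ang), center[1] + 1.5 * R * math.cos(ang))
        p1 = (center[0] + 5.5 * R * math.sin(ang), center[1] + 5.5 * R * math.cos(ang))
        vessels.append(
            VesselSpec(kind="straight", p0=p0, p1=p1, width_px=w,
                       vessel_class="arteriole" if is_art else "venule")
        )
    return PhantomSpec(
        shape=(256, 256),
        disc_center=center,
        disc_radius_px=R,
        vessels=tuple(vessels),
        seed=seed,
    )


def tortuosity_phantom_spec(seed: int = 0) -> PhantomSpec:
    """Tortuosity phantom: three semicircles and one straight vessel inside
    the tortuosity annulus; the analytic mean chord/arc ratio is
    (3 * 2/pi + 1) / 4."""
    center = (128.0, 128.0)
    R = 20.0
    arcs = []
    for ang in (0.5, 2.6, 4.7):  # arc anchor directions, radians
        ar = (center[0] + 2.25 * R * math.sin(ang),
              center[1] + 2.25 * R * math.cos(ang))
        arcs.append(
            VesselSpec(kind="arc", center=ar, radius=14.0,
                       theta0=ang, theta1=ang + math.pi, width_px=6.0)
        )
    # tangential chord at radius ~2.25 R
    p0 = (center[0] + 2.25 * R, center[1] - 20.0)
    p1 = (center[0] + 2.25 * R, center[1] + 20.0)
    arcs.append(VesselSpec(kind="straight", p0=p0, p1=p1, width_px=6.0))
    return PhantomSpec(
        shape=(256, 256),
        disc_center=center,
        disc_radius_px=R,
        vessels=tuple(arcs),
        seed=seed,
    )


def default_phantom_suite(seed: int = 0) -> dict[str, PhantomSpec]:
    """The phantom suite: a combined fundus-like phantom plus focused
    caliber and tortuosity phantoms."""
    return {
        "combined": default_phantom_spec(seed),
        "caliber": caliber_phantom_spec(seed),
        "tortuosity": tortuosity_phantom_spec(seed),
    }


# ---------------------------------------------------------------------------
# cohort simulation

#: group-wise (mean, sd) of the cohort feature table: retinal metrics for
#: control / good-collateral / poor-collateral groups, clinical covariates
#: for the stroke groups (controls carry age only).
TABLE_MEANS: dict[str, dict[str, tuple[float, float]]] = {
    "control": {
        "age": (44.3, 10.6),
        "crae_um": (181.4, 15.3),
        "crve_um": (259.1, 25.6),
        "avr": (0.703, 0.042),
        "tortuosity_index": (0.903, 0.011),
        "df": (1.368, 0.038),
        "lacunarity": (0.986, 0.024),
        "d0": (1.660, 0.019),
        "d1": (1.601, 0.019),
        "d2": (1.577, 0.024),
        "curve_asymmetry": (0.361, 0.072),
        "singularity_length": (0.902, 0.078),
        "f_alpha_max": (1.660, 0.019),
    },
    "good": {
        "age": (47.5, 10.4),
        "bmi": (28.5, 4.3),
        "sbp": (145.9, 27.7),
        "hba1c": (5.9, 1.1),
        "mrs_admission": (1.9, 1.3),
        "mrs_discharge": (1.5, 2.1),
        "nihss_admission": (10.1, 5.8),
        "nihss_discharge": (3.9, 4.3),
        "total_cholesterol": (4.62, 0.96),
        "triglycerides": (1.47, 0.62),
        "ldl": (3.08, 0.87),
        "hdl": (0.85, 0.17),
        "crae_um": (182.6, 13.0),
        "crve_um": (276.1, 19.9),
        "avr": (0.664, 0.041),
        "tortuosity_index": (0.891, 0.020),
        "df": (1.392, 0.048),
        "lacunarity": (0.995, 0.023),
        "d0": (1.652, 0.025),
        "d1": (1.590, 0.025),
        "d2": (1.564, 0.025),
        "curve_asymmetry": (0.385, 0.049),
        "singularity_length": (0.934, 0.041),
        "f_alpha_max": (1.652, 0.024),
    },
    "poor": {
        "age": (48.9, 10.5),
        "bmi": (27.5, 3.2),
        "sbp": (143.2, 18.4),
        "hba1c": (7.0, 3.3),
        "mrs_admission": (2.9, 1.6),
        "mrs_discharge": (2.1, 1.7),
        "nihss_admission": (14.7, 5.5),
        "nihss_discharge": (7.5, 5.7),
        "total_cholesterol": (4.70, 1.12),
        "triglycerides": (1.57, 0.68),
        "ldl": (3.06, 0.91),
        "hdl": (0.93, 0.26),
        "crae_um": (189.1, 8.0),
        "crve_um": (275.6, 23.2),
        "avr": (0.690, 0.055),
        "tortuosity_index": (0.889, 0.017),
        "df": (1.384, 0.041),
        "lacunarity": (1.001, 0.028),
        "d0": (1.673, 0.028),
        "d1": (1.609, 0.027),
        "d2": (1.581, 0.027),
        "curve_asymmetry": (0.395, 0.073),
        "singularity_length": (0.933, 0.080),
        "f_alpha_max": (1.674, 0.027),
    },
}


@dataclass(frozen=True)
class CohortSpec:
    """Simulated cohort sizes, group feature distributions and seed.

    Defaults are the study conditions: 21 controls, 20 good- and 15
    poor-collateral stroke patients, group means/SDs from TABLE_MEANS, and
    correlation 0.99 between d0 and f_alpha_max (all other features are
    drawn independently within group).
    """

    n_control: int = 21
    n_good: int = 20
    n_poor: int = 15
    group_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: TABLE_MEANS
    )
    d0_famax_corr: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.d0_famax_corr <= 1.0):
            raise ValueError("correlation must lie in [-1, 1]")
        for grp, feats in self.group_params.items():
            for name, (mu, sd) in feats.items():
                if sd <= 0:
                    raise ValueError(f"{grp}/{name}: sd must be positive")


def cohort_sim(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Simulate a per-patient feature table at the configured group
    distributions.

    d0 and f_alpha_max are drawn jointly (bivariate Gaussian at the
    requested correlation); every other feature is an independent Gaussian
    within its group.  Stroke patients get an ordinal collateral score
    consistent with their class (poor: 0-1, good: 2-3).
    """
    spec = spec or CohortSpec()
    rho = spec.d0_famax_corr
    cov2 = np.array([[1.0, rho], [rho, 1.0]])
    try:
        chol = np.linalg.cholesky(cov2)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation request is not positive definite") from exc

    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    sizes = {"control": spec.n_control, "good": spec.n_good, "poor": spec.n_poor}
    pid = 0
    for grp, n in sizes.items():
        feats = spec.group_params.get(grp, {})
        joint = "d0" in feats and "f_alpha_max" in feats
        for _ in range(n):
            rec: dict = {
                "patient_id": f"P{pid:04d}",
                "group": "control" if grp == "control" else "stroke",
            }
            pid += 1
            if grp == "control":
                rec["collateral_score"] = pd.NA
                rec["collateral_class"] = pd.NA
            else:
                rec["collateral_class"] = grp
                rec["collateral_score"] = int(
                    rng.integers(0, 2) if grp == "poor" else rng.integers(2, 4)
                )
            if joint:
                z = chol @ rng.standard_normal(2)
                mu0, sd0 = feats["d0"]
                mu1, sd1 = feats["f_alpha_max"]
                rec["d0"] = mu0 + sd0 * z[0]
                rec["f_alpha_max"] = mu1 + sd1 * z[1]
            for name, (mu, sd) in feats.items():
                if joint and name in ("d0", "f_alpha_max"):
                    continue
                rec[name] = mu + sd * rng.standard_normal()
            rows.append(rec)
    return pd.DataFrame(rows)
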