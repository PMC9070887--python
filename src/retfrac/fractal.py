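"""Box-counting fractal and multifractal analysis of binary rasters and
nonnegative measures.

Monofractal dimension
    D_f is the least-squares slope of log N(delta) against log(1/delta),
    where N(delta) is the number of boxes of side delta needed to cover the
    foreground.  Box grids are evaluated at several origins (the first at
    the raster origin, the rest seeded pseudo-random in [0, delta)^2) and
    the per-size count aggregated as the minimum over origins — the
    capacity-dimension convention.

Lacunarity
    Gappiness of the raster: for each (delta, origin) the per-box foreground
    pixel counts over all complete boxes give lambda = (sigma/mu)^2, and the
    summary Lambda is the mean of lambda over sizes and origins.

Generalized dimensions
    With box masses m_i normalised to probabilities mu_i, the partition
    function Z(q, eps) = sum_i mu_i^q (empty boxes excluded) gives
    D_q = slope(ln Z vs ln eps) / (q - 1) for q != 1, and the information
    dimension D_1 from the entropy sums sum_i mu_i ln mu_i (the q -> 1
    limit).  D_0, D_1, D_2 are the capacity, information and correlation
    dimensions; for any multifractal D_0 >= D_1 >= D_2.

Singularity spectrum
    tau(q) = (q - 1) D_q; the Hoelder exponent alpha(q) = d tau / d q
    (central differences on the q grid) and f(alpha) = q alpha - tau.
    Derived scalars: alpha_0 = alpha(0); the singularity length
    Delta alpha = alpha_max - alpha_min; the curve asymmetry
    A = (alpha_0 - alpha_min) / (alpha_max - alpha_0) (A > 1: left-skewed,
    dominated by high exponents); and f(alpha)_max, which for a well-behaved
    spectrum approximates D_0.

Defaults mirror the study settings: box sides in a scaled (power-of-two)
series, 10 grid positions, and a q grid from -10 to +10 in steps of 0.1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoxCountCurve",
    "MonofractalResult",
    "PartitionFunction",
    "MultifractalSpectrum",
    "FractalSettings",
    "default_box_sizes",
    "default_q_grid",
    "box_counts",
    "fit_monofractal",
    "lacunarity",
    "partition_function",
    "generalized_dimensions",
    "singularity_spectrum",
    "curve_asymmetry",
    "multifractal_metrics",
]


# ---------------------------------------------------------------------------
# settings

def default_box_sizes(shape: tuple[int, int]) -> tuple[int, ...]:
    """Scaled (power-of-two) box-side series: 16 px up to min(shape)/4.

    The smallest caliber sits at or above the width of the widest vessel so
    that a box reads the local density of the vascular *network*; below
    that scale a binary mask is locally two-dimensional (boxes fall wholly
    inside a vessel trunk) and the moment scaling mixes two regimes, which
    corrupts the high-|q| branches of the spectrum.  Override ``box_sizes``
    for rasters whose structures live at other scales.
    """
    top = min(shape) // 4
    sizes = []
    s = 16
    while s <= top:
        sizes.append(s)
        s *= 2
    if len(sizes) < 3:
        raise ValueError(f"raster {shape} too small for a box-size series")
    return tuple(sizes)


def default_q_grid(q_min: float = -10.0, q_max: float = 10.0,
                   q_step: float = 0.1) -> np.ndarray:
    n = int(round((q_max - q_min) / q_step))
    return np.round(q_min + q_step * np.arange(n + 1), 10)


@dataclass(frozen=True)
class FractalSettings:
    """Box series, grid positions and q grid for the multifractal pipeline."""

    box_sizes: tuple[int, ...] | None = None  # None -> scaled series from shape
    n_grid_offsets: int = 10
    q_min: float = -10.0
    q_max: float = 10.0
    q_step: float = 0.1
    seed: int = 0

    def q_grid(self) -> np.ndarray:
        return default_q_grid(self.q_min, self.q_max, self.q_step)

    def sizes_for(self, shape: tuple[int, int]) -> tuple[int, ...]:
        return self.box_sizes if self.box_sizes else default_box_sizes(shape)


def _offsets_for(delta: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Grid origins in [0, delta)^2; the first is always the raster origin."""
    offs = np.zeros((n, 2), dtype=int)
    if n > 1:
        offs[1:] = rng.integers(0, delta, size=(n - 1, 2))
    return offs


def _box_masses(meas: np.ndarray, delta: int, offset: np.ndarray) -> np.ndarray:
    """Per-box mass grid for a periodically shifted box grid.

    The raster is rolled by the grid offset (toroidal boundary), so every
    grid position tiles the raster with full-size boxes and no edge slivers
    — the offset average stays unbiased at every moment order.  When delta
    does not divide the raster side, the trailing remainder (< delta) is
    dropped after the roll.
    """
    rows, cols = meas.shape
    shifted = np.roll(np.roll(meas, int(offset[0]), axis=0), int(offset[1]), axis=1)
    nr, nc = rows // delta, cols // delta
    sub = shifted[: nr * delta, : nc * delta]
    return sub.reshape(nr, delta, nc, delta).sum(axis=(1, 3))


# ---------------------------------------------------------------------------
# box counting and lacunarity

@dataclass(frozen=True)
class BoxCountCurve:
    box_sizes: tuple[int, ...]
    counts: np.ndarray            # (n_sizes, n_offsets)
    aggregated_counts: np.ndarray  # per-size min over offsets

    def __post_init__(self) -> None:
        if (self.aggregated_counts < 1).any():
            raise ValueError("box counts must be >= 1 for a nonempty raster")


@dataclass(frozen=True)
class MonofractalResult:
    df: float
    r_squared: float
    lacunarity: float = math.nan


def box_counts(
    raster: np.ndarray,
    box_sizes: tuple[int, ...] | None = None,
    n_grid_offsets: int = 10,
    seed: int = 0,
) -> BoxCountCurve:
    """Occupied-box counts N(delta) per box size and grid origin."""
    mask = (np.asarray(getattr(raster, "pixels", raster)) > 0).astype(float)
    if not mask.any():
        raise ValueError("box counting needs a nonempty raster")
    sizes = tuple(box_sizes) if box_sizes else default_box_sizes(mask.shape)
    rng = np.random.default_rng(seed)
    counts = np.zeros((len(sizes), n_grid_offsets), dtype=int)
    for i, delta in enumerate(sizes):
        for j, off in enumerate(_offsets_for(delta, n_grid_offsets, rng)):
            counts[i, j] = int((_box_masses(mask, delta, off) > 0).sum())
    return BoxCountCurve(sizes, counts, counts.min(axis=1))


def _ls_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and r^2 of y on x."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(r2)


def fit_monofractal(curve: BoxCountCurve) -> MonofractalResult:
    """D_f = slope of log N versus log(1/delta) on the aggregated counts."""
    if len(curve.box_sizes) < 3:
        raise ValueError("need at least 3 box sizes for a dimension fit")
    x = np.log(1.0 / np.asarray(curve.box_sizes, dtype=float))
    y = np.log(curve.aggregated_counts.astype(float))
    slope, r2 = _ls_slope(x, y)
    return MonofractalResult(df=slope, r_squared=r2)


def lacunarity(
    raster: np.ndarray,
    box_sizes: tuple[int, ...] | None = None,
    n_grid_offsets: int = 10,
    seed: int = 0,
) -> float:
    """Mean (sigma/mu)^2 of per-box pixel counts over sizes and grid origins.

    Grids are shifted periodically (see :func:`_box_masses`), so every box
    is full-size and a fully filled raster scores exactly 0 at any origin.
    """
    mask = (np.asarray(getattr(raster, "pixels", raster)) > 0)
    if not mask.any():
        raise ValueError("lacunarity needs a nonempty raster")
    rows, cols = mask.shape
    sizes = tuple(box_sizes) if box_sizes else default_box_sizes(mask.shape)
    rng = np.random.default_rng(seed)
    lams: list[float] = []
    for delta in sizes:
        for off in _offsets_for(delta, n_grid_offsets, rng):
            per_box = _box_masses(mask.astype(float), delta, off)
            mu = per_box.mean()
            if mu == 0:
                warnings.warn(
                    f"no foreground in any complete box at delta={delta}",
                    stacklevel=2,
                )
                continue
            lams.append((per_box.std() / mu) ** 2)
    if not lams:
        raise ValueError("no usable (size, origin) grids for lacunarity")
    return float(np.mean(lams))


def monofractal_metrics(
    raster: np.ndarray,
    settings: FractalSettings | None = None,
) -> MonofractalResult:
    """D_f, fit quality and lacunarity with shared settings."""
    settings = settings or FractalSettings()
    mask = np.asarray(getattr(raster, "pixels", raster))
    sizes = settings.sizes_for(mask.shape)
    curve = box_counts(mask, sizes, settings.n_grid_offsets, settings.seed)
    mono = fit_monofractal(curve)
    lam = lacunarity(mask, sizes, settings.n_grid_offsets, settings.seed)
    return MonofractalResult(df=mono.df, r_squared=mono.r_squared, lacunarity=lam)


# ---------------------------------------------------------------------------
# partition function and generalized dimensions

@dataclass(frozen=True)
class PartitionFunction:
    q_grid: np.ndarray
    eps_grid: np.ndarray
    z: np.ndarray              # (n_q, n_eps), offset-averaged
    entropy_terms: np.ndarray  # (n_eps,), offset-averaged sum mu ln mu
    # direct-moment (reweighted-measure) accumulators, offset-averaged:
    # with mu_hat_i = mu_i^q / sum_j mu_j^q,
    alpha_terms: np.ndarray | None = None  # (n_q, n_eps) sum mu_hat ln mu
    f_terms: np.ndarray | None = None      # (n_q, n_eps) sum mu_hat ln mu_hat


def partition_function(
    raster: np.ndarray,
    q_grid: np.ndarray | None = None,
    eps_grid: tuple[int, ...] | None = None,
    n_grid_offsets: int = 10,
    seed: int = 0,
) -> PartitionFunction:
    """Z(q, eps) = sum of box-probability powers, averaged over grid origins.

    Accepts a binary mask (unit mass per foreground pixel) or a nonnegative
    measure raster.  Grids are shifted periodically (see
    :func:`_box_masses`), so every box is full-size and edge slivers cannot
    inject spurious small masses into the negative-q moments; empty boxes
    are excluded and probabilities renormalised within each grid.
    """
    meas = np.asarray(getattr(raster, "pixels", raster), dtype=float)
    if (meas < 0).any():
        raise ValueError("measure raster must be nonnegative")
    if meas.sum() <= 0:
        raise ValueError("partition function needs positive total mass")
    q = np.asarray(q_grid if q_grid is not None else default_q_grid(), dtype=float)
    if q.size == 0:
        raise ValueError("q grid must be nonempty")
    sizes = tuple(eps_grid) if eps_grid else default_box_sizes(meas.shape)
    rows, cols = meas.shape
    rng = np.random.default_rng(seed)

    from scipy.special import logsumexp

    z = np.zeros((q.size, len(sizes)))
    entropy = np.zeros(len(sizes))
    alpha_terms = np.zeros((q.size, len(sizes)))
    f_terms = np.zeros((q.size, len(sizes)))
    for i, delta in enumerate(sizes):
        z_acc = np.zeros(q.size)
        h_acc = 0.0
        a_acc = np.zeros(q.size)
        f_acc = np.zeros(q.size)
        n_used = 0
        for off in _offsets_for(delta, n_grid_offsets, rng):
            masses = _box_masses(meas, delta, off).ravel()
            masses = masses[masses > 0]
            if masses.size == 0:
                continue
            mu = masses / masses.sum()
            ln_mu = np.log(mu)
            w = np.outer(q, ln_mu)                      # ln mu_i^q
            z_acc += np.exp(w).sum(axis=1)
            h_acc += float(mu @ ln_mu)
            # reweighted measure mu_hat = mu^q / Z(q), computed in log space
            # so the extreme moments do not overflow
            ln_z = logsumexp(w, axis=1, keepdims=True)
            mu_hat = np.exp(w - ln_z)
            a_acc += mu_hat @ ln_mu
            f_acc += (mu_hat * w).sum(axis=1) - ln_z[:, 0]
            n_used += 1
        if n_used == 0:
            raise ValueError(f"no usable grid at eps={delta}")
        z[:, i] = z_acc / n_used
        entropy[i] = h_acc / n_used
        alpha_terms[:, i] = a_acc / n_used
        f_terms[:, i] = f_acc / n_used
    return PartitionFunction(
        q, np.asarray(sizes, dtype=float), z, entropy, alpha_terms, f_terms
    )


@dataclass(frozen=True)
class DqCurve:
    q_grid: np.ndarray
    dq: np.ndarray
    r_squared: np.ndarray


def generalized_dimensions(pf: PartitionFunction) -> DqCurve:
    """D_q from the scaling of ln Z(q, eps) with ln eps.

    For q != 1, D_q is the regression slope divided by (q - 1); at q = 1 the
    entropy sums give D_1 directly (the L'Hopital limit).
    """
    if pf.eps_grid.size < 3:
        raise ValueError("need at least 3 box sizes for the Dq regression")
    ln_eps = np.log(pf.eps_grid)
    dq = np.empty(pf.q_grid.size)
    r2 = np.empty(pf.q_grid.size)
    for i, q in enumerate(pf.q_grid):
        if abs(q - 1.0) < 1e-9:
            slope, rr = _ls_slope(ln_eps, pf.entropy_terms)
            dq[i], r2[i] = slope, rr
        else:
            slope, rr = _ls_slope(ln_eps, np.log(pf.z[i]))
            dq[i], r2[i] = slope / (q - 1.0), rr
    return DqCurve(pf.q_grid, dq, r2)


# ---------------------------------------------------------------------------
# singularity spectrum

@dataclass(frozen=True)
class MultifractalSpectrum:
    q_grid: np.ndarray
    dq: np.ndarray
    tau: np.ndarray
    alpha: np.ndarray
    f_alpha: np.ndarray
    d0: float
    d1: float
    d2: float
    alpha0: float
    alpha_min: float
    alpha_max: float
    singularity_length: float
    asymmetry: float  # NaN when the right branch is flat
    f_alpha_max: float

    def as_dict(self) -> dict[str, float]:
        return {
            "d0": self.d0,
            "d1": self.d1,
            "d2": self.d2,
            "alpha0": self.alpha0,
            "singularity_length": self.singularity_length,
            "curve_asymmetry": self.asymmetry,
            "f_alpha_max": self.f_alpha_max,
        }


def curve_asymmetry(alpha0: float, alpha_min: float, alpha_max: float) -> float:
    """Spectrum asymmetry A = (alpha0 - alpha_min) / (alpha_max - alpha0).

    A = 1: symmetric; A > 1: left-skewed (high exponents dominate);
    A < 1: right-skewed.  NaN when the right branch is flat
    (alpha_max == alpha0), as for an exact monofractal.
    """
    if alpha_max - alpha0 < 1e-9:
        return math.nan
    return (alpha0 - alpha_min) / (alpha_max - alpha0)


def _value_at(q_grid: np.ndarray, values: np.ndarray, q: float) -> float:
    idx = np.argmin(np.abs(q_grid - q))
    if abs(q_grid[idx] - q) > 1e-6:
        return float(np.interp(q, q_grid, values))
    return float(values[idx])


def singularity_spectrum(
    curve: DqCurve, pf: PartitionFunction | None = None
) -> MultifractalSpectrum:
    """Singularity-spectrum scalars of the D_q curve.

    tau(q) = (q-1) D_q.  When the partition function's direct-moment
    accumulators are available, alpha(q) and f(q) come from the scaling of
    the reweighted-measure sums (sum mu_hat ln mu and sum mu_hat ln mu_hat
    against ln eps) — the moment-method estimate, which stays bounded where
    the raw negative-q moments of a sparse raster scale poorly.  Otherwise
    alpha = d tau / d q by central differences and f = q alpha - tau (the
    numerical Legendre transform).  The asymmetry A is undefined (NaN) when
    the spectrum's right branch collapses (alpha_max == alpha_0), as
    happens for an exact monofractal.
    """
    q, dq = curve.q_grid, curve.dq
    if q.size < 3:
        raise ValueError("q grid too small for the spectrum")
    tau = (q - 1.0) * dq
    if pf is not None and pf.alpha_terms is not None:
        ln_eps = np.log(pf.eps_grid)
        alpha = np.empty(q.size)
        f_alpha = np.empty(q.size)
        for i in range(q.size):
            alpha[i], _ = _ls_slope(ln_eps, pf.alpha_terms[i])
            f_alpha[i], _ = _ls_slope(ln_eps, pf.f_terms[i])
    else:
        alpha = np.gradient(tau, q)
        f_alpha = q * alpha - tau

    d0 = _value_at(q, dq, 0.0)
    d1 = _value_at(q, dq, 1.0)
    d2 = _value_at(q, dq, 2.0)
    alpha0 = _value_at(q, alpha, 0.0)
    a_min, a_max = float(alpha.min()), float(alpha.max())
    delta_alpha = a_max - a_min
    asym = curve_asymmetry(alpha0, a_min, a_max)
    if math.isnan(asym):
        warnings.warn("flat right branch: curve asymmetry undefined", stacklevel=2)
    return MultifractalSpectrum(
        q_grid=q,
        dq=dq,
        tau=tau,
        alpha=alpha,
        f_alpha=f_alpha,
        d0=d0,
        d1=d1,
        d2=d2,
        alpha0=alpha0,
        alpha_min=a_min,
        alpha_max=a_max,
        singularity_length=delta_alpha,
        asymmetry=asym,
        f_alpha_max=float(f_alpha.max()),
    )


def multifractal_metrics(
    raster: np.ndarray, settings: FractalSettings | None = None
) -> MultifractalSpectrum:
    """Full multifractal pipeline on a mask or measure raster."""
    settings = settings or FractalSettings()
    meas = np.asarray(getattr(raster, "pixels", raster), dtype=float)
    pf = partition_function(
        meas,
        settings.q_grid(),
        settings.sizes_for(meas.shape),
        settings.n_grid_offsets,
        settings.seed,
    )
    return singularity_spectrum(generalized_dimensions(pf), pf)
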