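"""Box counting, lacunarity, generalized dimensions and the spectrum."""

import math
import warnings

import numpy as np
import pytest

import retfrac as rf
from retfrac import fractal as fr
from retfrac.synthetic import CascadeSpec, cascade_dq_analytic, cascade_measure, sierpinski_mask


# ---------------------------------------------------------------------------
# box counts vs brute force

def _offsets_like_impl(sizes, n, seed):
    """Replicate the documented offset convention: first origin (0,0), the
    rest seeded in [0, delta)^2, drawn per size in order."""
    rng = np.random.default_rng(seed)
    out = {}
    for delta in sizes:
        offs = np.zeros((n, 2), dtype=int)
        if n > 1:
            offs[1:] = rng.integers(0, delta, size=(n - 1, 2))
        out[delta] = offs
    return out


def _brute_force_count(mask, delta, off):
    """Independent oracle: explicit double loop over grid cells on the
    periodically shifted raster."""
    shifted = np.roll(np.roll(mask, off[0], axis=0), off[1], axis=1)
    rows, cols = mask.shape
    n = 0
    for r0 in range(0, (rows // delta) * delta, delta):
        for c0 in range(0, (cols // delta) * delta, delta):
            if shifted[r0 : r0 + delta, c0 : c0 + delta].any():
                n += 1
    return n


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_box_counts_match_brute_force_on_small_rasters(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((32, 32)) < 0.2
    if not mask.any():
        mask[3, 4] = True
    sizes = (2, 3, 4, 5, 8)
    n_off = 4
    curve = fr.box_counts(mask, sizes, n_off, seed=seed)
    offsets = _offsets_like_impl(sizes, n_off, seed)
    for i, delta in enumerate(sizes):
        for j in range(n_off):
            assert curve.counts[i, j] == _brute_force_count(
                mask, delta, offsets[delta][j]
            ), (delta, j)


def test_box_count_basics():
    full = np.ones((64, 64), bool)
    curve = fr.box_counts(full, (8,), 1)
    assert curve.aggregated_counts[0] == 64

    single = np.zeros((64, 64), bool)
    single[10, 17] = True
    curve = fr.box_counts(single, (2, 4, 8, 16), 5)
    assert (curve.counts == 1).all()

    rng = np.random.default_rng(0)
    mask = rng.random((64, 64)) < 0.3
    curve = fr.box_counts(mask, (2, 4, 8, 16), 10)
    assert (np.diff(curve.aggregated_counts) <= 0).all()

    with pytest.raises(ValueError):
        fr.box_counts(np.zeros((8, 8), bool), (2, 4))


# ---------------------------------------------------------------------------
# monofractal fits

def test_monofractal_dimension_of_reference_sets():
    full = np.ones((256, 256), bool)
    assert fr.fit_monofractal(fr.box_counts(full)).df == pytest.approx(2.0, abs=0.02)

    line = np.zeros((256, 256), bool)
    line[100, :] = True
    assert fr.fit_monofractal(fr.box_counts(line)).df == pytest.approx(1.0, abs=0.02)

    sierp = sierpinski_mask(8)
    df = fr.fit_monofractal(fr.box_counts(sierp)).df
    assert df == pytest.approx(math.log(3) / math.log(2), abs=0.03)


def test_monofractal_fit_needs_three_sizes():
    curve = fr.box_counts(np.ones((64, 64), bool), (4, 8), 3)
    with pytest.raises(ValueError):
        fr.fit_monofractal(curve)


# ---------------------------------------------------------------------------
# lacunarity

def test_filled_raster_has_zero_lacunarity():
    assert fr.lacunarity(np.ones((128, 128), bool), (4, 8, 16), 5) == 0.0


def test_lacunarity_translation_robust():
    rng = np.random.default_rng(2)
    base = np.zeros((128, 128), bool)
    base[::8, :] = True  # periodic stripes
    l1 = fr.lacunarity(base, (4, 8, 16), 10)
    l2 = fr.lacunarity(np.roll(base, 3, axis=0), (4, 8, 16), 10)
    assert abs(l1 - l2) < 0.05


def test_sparser_raster_is_gappier():
    rng = np.random.default_rng(3)
    sparse = rng.random((256, 256)) < 0.10
    dense = rng.random((256, 256)) < 0.50
    assert fr.lacunarity(sparse) > fr.lacunarity(dense)


# ---------------------------------------------------------------------------
# partition function and Dq

def test_partition_function_normalisation_and_counts():
    rng = np.random.default_rng(1)
    meas = rng.random((64, 64))
    pf = fr.partition_function(meas, np.array([0.0, 1.0, 2.0]), (4, 8, 16), 5)
    # Z(1, eps) = 1 exactly (mass normalisation)
    assert np.allclose(pf.z[1], 1.0, atol=1e-12)
    # Z(0, eps) = nonempty-box count of its grids (all boxes occupied here)
    assert np.allclose(pf.z[0], [(64 // d) ** 2 for d in (4, 8, 16)])


def test_uniform_mass_over_k_boxes_closed_form():
    """Uniform mass on k boxes gives Z(q) = k^(1-q)."""
    meas = np.zeros((32, 32))
    meas[:16, :16] = 1.0
    meas[:16, 16:] = 1.0
    meas[16:, :16] = 1.0
    meas[16:, 16:] = 1.0  # uniform over the 4 quadrants (and all of space)
    q = np.array([-2.0, 0.0, 0.5, 2.0, 3.0])
    pf = fr.partition_function(meas, q, (16,), 1)
    assert np.allclose(pf.z[:, 0], 4.0 ** (1 - q))


def test_partition_function_input_validation():
    with pytest.raises(ValueError):
        fr.partition_function(np.zeros((32, 32)), np.array([0.0]), (4, 8, 16))
    with pytest.raises(ValueError):
        fr.partition_function(np.ones((32, 32)), np.array([]), (4, 8, 16))
    with pytest.raises(ValueError):
        fr.partition_function(-np.ones((32, 32)), np.array([0.0]), (4, 8, 16))


def test_cascade_generalized_dimensions_match_closed_form(cascade_default):
    """Deterministic cascade: D_q within 0.02 of log2(sum p^q)/(1-q) for
    q in [-5, 5]."""
    q = np.round(np.arange(-5.0, 5.01, 0.5), 10)
    # a measure has structure at every dyadic scale, so the oracle uses the
    # full scale range (the 16-px default floor is a vessel-mask choice)
    pf = fr.partition_function(cascade_default, q, (4, 8, 16, 32, 64, 128), 10, 0)
    dq = fr.generalized_dimensions(pf)
    analytic = cascade_dq_analytic((0.4, 0.3, 0.2, 0.1), q)
    assert np.abs(dq.dq - analytic).max() < 0.02


def test_uniform_square_has_flat_spectrum():
    meas = np.ones((256, 256))
    q = np.round(np.arange(-5.0, 5.01, 0.5), 10)
    dq = fr.generalized_dimensions(fr.partition_function(meas, q, None, 10, 0))
    assert np.abs(dq.dq - 2.0).max() < 0.05


def test_dq_nonincreasing_on_cascades():
    """D_q is nonincreasing in q for multiplicative cascades, including
    randomised placements."""
    for spec in (CascadeSpec(), CascadeSpec(seed=11), CascadeSpec((0.5, 0.25, 0.15, 0.1), 8, seed=3)):
        meas = cascade_measure(spec)
        s = fr.multifractal_metrics(meas)
        assert (np.diff(s.dq) <= 1e-6).all()
        assert s.d0 >= s.d1 >= s.d2


# ---------------------------------------------------------------------------
# singularity spectrum

def test_monofractal_spectrum_is_degenerate():
    """A filled square: Delta-alpha ~ 0, f(alpha)max ~ 2, asymmetry NaN."""
    with pytest.warns(UserWarning):
        s = fr.multifractal_metrics(np.ones((256, 256)))
    assert s.singularity_length == pytest.approx(0.0, abs=1e-6)
    assert s.f_alpha_max == pytest.approx(2.0, abs=0.02)
    assert math.isnan(s.asymmetry)


def test_asymmetry_formula():
    """alpha_min 1.0, alpha_0 1.6, alpha_max 1.8 -> A = 3 (left-skewed)."""
    assert fr.curve_asymmetry(1.6, 1.0, 1.8) == pytest.approx(3.0)
    assert math.isnan(fr.curve_asymmetry(1.8, 1.0, 1.8))


def test_cascade_spectrum_scalars(cascade_default):
    """Singularity length within 10% of the analytic width over q in
    [-10, 10] (about 1.97 for these weights); f(alpha)max = D0."""
    s = fr.multifractal_metrics(cascade_default)
    # analytic alpha at the grid ends
    def alpha_at(qv):
        p = np.array([0.4, 0.3, 0.2, 0.1])
        w = p**qv / np.sum(p**qv)
        return float(-(w @ np.log2(p)))
    width = alpha_at(-10.0) - alpha_at(10.0)
    assert s.singularity_length == pytest.approx(width, rel=0.10)
    assert abs(s.f_alpha_max - s.d0) < 0.02
    assert s.alpha_min < s.alpha0 < s.alpha_max


def test_multifractal_metrics_deterministic(cascade_default):
    s1 = fr.multifractal_metrics(cascade_default)
    s2 = fr.multifractal_metrics(cascade_default)
    assert np.array_equal(s1.dq, s2.dq)
    assert s1.as_dict() == s2.as_dict()


def test_vessel_mask_spectrum_is_ordered(phantom_suite, segmented_suite):
    """On the fundus-like phantom (truth and segmented): D0 >= D1 >= D2 and
    f(alpha)max approximates D0."""
    _, _, truth, _, disc = phantom_suite["combined"]
    roi3 = rf.rasterize_roi(rf.make_roi3(disc), disc, truth.shape)
    for mask in (truth & roi3, segmented_suite["combined"] & roi3):
        s = fr.multifractal_metrics(mask.astype(float))
        assert s.d0 >= s.d1 >= s.d2
        assert s.singularity_length >= 0
        assert abs(s.f_alpha_max - s.d0) < 0.02


def test_metrics_translation_robust(phantom_suite):
    """A 3-px shift of the mask changes D0/D1 by < 2% (grid-offset
    averaging)."""
    _, _, truth, _, _ = phantom_suite["combined"]
    s1 = fr.multifractal_metrics(truth.astype(float))
    s2 = fr.multifractal_metrics(np.roll(truth, 3, axis=1).astype(float))
    assert abs(s2.d0 - s1.d0) / s1.d0 < 0.02
    assert abs(s2.d1 - s1.d1) / s1.d1 < 0.02
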