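"""Shared fixtures: rendered phantoms, cascade measures, segmented masks.

Expensive artifacts are session-scoped so the suite renders and segments
each phantom once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import retfrac as rf
from retfrac import synthetic as syn


@pytest.fixture(scope="session")
def phantom_suite():
    """name -> (spec, image, truth mask, truth table, disc) for the suite."""
    out = {}
    for name, spec in syn.default_phantom_suite(seed=0).items():
        img, truth, table, disc = syn.vessel_phantom(spec)
        out[name] = (spec, img, truth, table, disc)
    return out


@pytest.fixture(scope="session")
def segmented_suite(phantom_suite):
    """name -> segmented VesselMask pixels, default parameters."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, (_, img, _, _, _) in phantom_suite.items():
            out[name] = rf.segment_vessels(img).pixels
    return out


@pytest.fixture(scope="session")
def cascade_default():
    """Deterministic four-weight cascade measure, weights (.4,.3,.2,.1), depth 9."""
    return syn.cascade_measure(syn.CascadeSpec())


@pytest.fixture(scope="session")
def study_cohort():
    """Simulated cohort at the study group sizes and feature distributions."""
    return syn.cohort_sim(syn.CohortSpec(seed=0))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
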