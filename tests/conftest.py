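"""Shared fixtures: small solved cases reused across test modules."""

import warnings

import numpy as np
import pytest

import ectplan as ep

# thin-wall clamp warnings are expected at coarse test resolutions
warnings.filterwarnings("ignore", message="vessel wall")


@pytest.fixture(scope="session")
def ect10_4_coarse():
    """ECT 10 mm / 4 electrodes, vessel-free, 1.5 mm grid: scene + envelope."""
    scene = ep.build_simplified_scene(10, spacing=1.5)
    sc = ep.rasterize_electrodes(scene, ep.place_electrodes(scene, "ECT", 10, 4))
    plan = ep.make_pulse_plan(4, *ep.TABLE_VOLTAGES[("ECT", 10, 4)])
    env = ep.solve_sequence(sc, plan)
    return sc, plan, env


@pytest.fixture(scope="session")
def tiny_ect_scene():
    """Very coarse ECT 10 mm scene for optimizer tests (fast solves)."""
    scene = ep.build_simplified_scene(10, spacing=2.5, padding=8.0)
    return ep.rasterize_electrodes(scene, ep.place_electrodes(scene, "ECT", 10, 4))


@pytest.fixture(scope="session")
def patient_scene():
    """Coarse synthetic patient-like scene shared by study tests."""
    return ep.build_patient_like_scene(0, spacing=2.5, padding=8.0)
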