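"""Shared fixtures: phantoms and end-to-end pipeline runs.

Expensive end-to-end runs are session-scoped so acceptance, refinement,
and pipeline tests share one execution per phantom condition.
"""

from __future__ import annotations

import numpy as np
import pytest

from cinelv.config import RunConfig
from cinelv.phantom import PhantomSpec, default_suite, generate
from cinelv.pipeline import run_segment


def circle_nodes(cx: float, cy: float, r: float, n: int = 80) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])


def small_spec(**overrides) -> PhantomSpec:
    """A reduced phantom for fast unit/tuning tests (not the study suite)."""
    defaults = dict(
        name="small",
        rows=72,
        cols=72,
        n_slices=4,
        n_frames=8,
        pixel_spacing_mm=(2.0, 2.0),
        slice_spacing_mm=8.0,
        edv_target_ml=60.0,
        wall_thickness_ed_mm=9.0,
        wall_thickness_es_mm=12.0,
        seed=7,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def _suite_spec(name: str) -> PhantomSpec:
    return next(s for s in default_suite() if s.name == name)


def _run(name: str):
    stack, truth = generate(_suite_spec(name))
    result, report = run_segment(stack, RunConfig())
    return stack, truth, result, report


@pytest.fixture(scope="session")
def baseline_run():
    return _run("baseline")


@pytest.fixture(scope="session")
def outflow_run():
    return _run("outflow_longaxis")


@pytest.fixture(scope="session")
def detached_run():
    return _run("detached_papillary")


@pytest.fixture(scope="session")
def attached_run():
    return _run("attached_papillary")


@pytest.fixture(scope="session")
def small_run():
    stack, truth = generate(small_spec())
    result, report = run_segment(stack, RunConfig())
    return stack, truth, result, report


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
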