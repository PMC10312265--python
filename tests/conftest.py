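"""Shared fixtures: a session-wide cache of preset simulations.

Most acceptance-level checks interrogate the same handful of named
conditions; running each condition once per session keeps the suite fast.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

import spindleloop as sl


@pytest.fixture(scope="session")
def preset_cache():
    """Callable returning (PresetRun, wall-clock seconds), memoized on
    (name, dt, frozen overrides)."""
    cache: dict = {}

    def get(name, dt=5e-4, config_overrides=None):
        key = (name, dt, repr(sorted((config_overrides or {}).items())))
        if key not in cache:
            t0 = time.perf_counter()
            run = sl.run_preset(name, dt=dt, config_overrides=config_overrides)
            cache[key] = (run, time.perf_counter() - t0)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def anchor_runs(preset_cache):
    """The ten single-loop reference conditions, simulated once."""
    names = [
        "fig2b", "fig3a", "fig3b", "fig3c", "fig5a", "fig5b",
        "fig6a", "fig6b", "fig6c", "fig6d",
    ]
    return {name: preset_cache(name)[0] for name in names}


@pytest.fixture(scope="session")
def mixing_runs(preset_cache):
    names = [
        "fig7a", "fig7b", "fig7c",
        "fig8a", "fig8b", "fig8c", "fig8d", "fig8_baseline",
        "fig9a", "fig9b", "fig9c",
    ]
    return {name: preset_cache(name)[0] for name in names}


def stacked_map(run) -> np.ndarray:
    return np.concatenate(
        [run.result.traces[p] for p in sorted(run.result.traces)], axis=0
    )


@pytest.fixture(scope="session")
def small_circuit():
    """A small (N=40) default-wired circuit for structural/dynamics tests."""
    cfg = sl.default_config(N=40)
    return sl.build_circuit(cfg)
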