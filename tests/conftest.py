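"""Shared fixtures: tabulated parameters and a memoized run cache.

Qualitative whole-run checks share one reduced discretization (96 x 24
cells, 20 s steps) that resolves the ~100 um drug boundary layer with
~40 wall-clustered cells while keeping a 10 h run to a few seconds;
several tests reuse the same runs through the session-scoped cache.
"""

from __future__ import annotations

import pytest

import tumordrugsim as td

FAST = td.Numerics(nr_i=96, nz=24, dt_s=20.0, t_end_h=10.0,
                   output_every_s=1800.0, refinement=3.0, ode_substep_s=2.0)


@pytest.fixture(scope="session")
def params() -> td.ModelParameters:
    return td.ModelParameters()


@pytest.fixture(scope="session")
def internal(params) -> td.InternalParameters:
    return td.to_internal_units(params)


@pytest.fixture(scope="session")
def fast_numerics() -> td.Numerics:
    return FAST


@pytest.fixture(scope="session")
def run_cache(params):
    """Memoized simulation runner shared by the whole session.

    ``cache(S, T_h, mode, **kwargs)`` runs (or reuses) a 10 h reduced-
    grid simulation with a single rectangular pulse.
    """
    results: dict = {}

    def cache(S: float, T_h: float, mode: str = "bistable",
              numerics: td.Numerics = FAST, **kwargs) -> td.SimResult:
        key = (S, T_h, mode, numerics, tuple(sorted(kwargs.items())))
        if key not in results:
            results[key] = td.run_pulse(params, numerics, S, T_h, mode,
                                        **kwargs)
        return results[key]

    return cache


@pytest.fixture(scope="session")
def baseline_bistable(run_cache):
    return run_cache(1.0, 1.5, "bistable")


@pytest.fixture(scope="session")
def baseline_monostable(run_cache):
    return run_cache(1.0, 1.5, "monostable")
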