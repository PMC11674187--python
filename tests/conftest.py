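"""Shared fixtures; expensive simulations are memoized per session."""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Memoized heavy runs (shared between property and acceptance tests)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def cell_run(cell_type: int, conc_uM: float, pre_beats: int | None = None,
             dt: float = 0.005):
    """Paced endo/epi/mid cell under the reproduction configuration.

    ``pre_beats=None`` uses the full reproduction pre-pacing (300 beats);
    smaller values are used by directional/refinement checks.
    """
    from cardioblock.cell_model import cenobamate, paced_run, reproduction_setup

    params, pacing = reproduction_setup(cell_type)
    if pre_beats is not None:
        from dataclasses import replace

        pacing = replace(pacing, pre_beats=pre_beats)
    return paced_run(params, cenobamate(), conc_uM, pacing, dt=dt)


@lru_cache(maxsize=None)
def strand_run(g_j: float, conc_uM: float, n_cells: int = 50, duration: float = 350.0):
    from cardioblock.cell_model import cenobamate
    from cardioblock.strand import StrandConfig, simulate_strand

    cfg = StrandConfig(n_cells=n_cells, g_j=g_j, variant="cipa", pre_beats=30)
    return simulate_strand(cfg, cenobamate(), conc_uM, duration=duration)


@lru_cache(maxsize=None)
def markov_sweeps(protocol_name: str, conc_uM: float, k_ib_inv: float | None = None):
    """Markov-model sweep sets at the drug's fixture rates.

    ``k_ib_inv`` overrides the inactivated-state unblock rate while keeping
    the rate sum k_ib*[D] + k_ib_inv fixed at the fixture value 1/4.0 ms^-1
    (used to probe the trapping-dominant regime).
    """
    from cardioblock.protocols import build_protocol
    from cardioblock.synth import NavMarkovParams, simulate_markov_trace

    rate_sum_i = 1.0 / 4.0
    if k_ib_inv is None:
        k_ib_inv = rate_sum_i / (1.0 + 98.44 / 272.5083)
    k_ib = (rate_sum_i - k_ib_inv) / 98.44
    params = NavMarkovParams(
        tau_i=2.47, tau_r=3.81,
        k_ob=0.00215, k_ob_inv=0.189, k_ib=k_ib, k_ib_inv=k_ib_inv,
        drug_conc=conc_uM,
    )
    proto = build_protocol(protocol_name)
    return simulate_markov_trace(params, proto, dt=0.005), proto, params


@pytest.fixture(scope="session")
def nav_standard_control():
    return markov_sweeps("nav_standard", 0.0)


@pytest.fixture(scope="session")
def udb_control():
    return markov_sweeps("nav_udb", 0.0)


def udb_peak_seqs(sweeps, proto, condition):
    from cardioblock.trace_analysis import udb_peak_sequences

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return udb_peak_sequences(sweeps, proto, condition=condition)
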