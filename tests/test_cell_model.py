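"""Single-cell model: blocked-state ODE, current scaling, drug application,
charge bookkeeping and solver behaviour (fast checks; the APD90/Q_net
reproduction runs live in the acceptance suite)."""

import numpy as np
import pytest

from cardioblock.cell_model import (
    IDX,
    ORdParameters,
    PacingSpec,
    apply_drug,
    cenobamate,
    db_dt,
    i_na,
    initial_state,
    paced_run,
    qnet,
)


@pytest.fixture(scope="module")
def mid_ap_state():
    """A state frozen mid-upstroke (gates partially open) for algebra checks."""
    y = initial_state()
    y[IDX["v"]] = -20.0
    y[IDX["m"]] = 0.7
    y[IDX["hf"]] = y[IDX["hs"]] = 0.4
    y[IDX["j"]] = 0.5
    y[IDX["hsp"]] = 0.3
    y[IDX["jp"]] = 0.45
    y[IDX["CaMKt"]] = 0.01
    y[IDX["cass"]] = 5e-4
    return y


def test_db_dt_zero_without_drug_or_block(mid_ap_state):
    assert db_dt(mid_ap_state, cenobamate(), 0.0) == 0.0


def test_db_dt_steady_state_matches_two_term_ratio(mid_ap_state):
    """At frozen gates, b* = sum(on)/(sum(on)+sum(off)) zeroes db/dt."""
    drug = cenobamate()
    conc = 170.0
    y = mid_ap_state.copy()
    y[IDX["b"]] = 0.0
    on = db_dt(y, drug, conc)  # = sum(on) when b = 0
    y[IDX["b"]] = 1.0
    off = -db_dt(y, drug, conc)  # = sum(off) when b = 1
    b_star = on / (on + off)
    y[IDX["b"]] = b_star
    assert abs(db_dt(y, drug, conc)) < 1e-10


def test_db_dt_symmetric_rates_collapse_to_single_site(mid_ap_state):
    """With equal open/inactivated rates the conformation weighting cancels."""
    from dataclasses import replace

    drug = cenobamate()
    sym = replace(drug, k_ib=drug.k_ob, k_ib_inv=drug.k_ob_inv)
    y = mid_ap_state.copy()
    y[IDX["b"]] = 0.2
    m3 = y[IDX["m"]] ** 3
    conc = 100.0
    expected = m3 * (drug.k_ob * conc * (1 - 0.2) - drug.k_ob_inv * 0.2)
    assert db_dt(y, sym, conc) == pytest.approx(expected, rel=1e-12)


def test_i_na_scales_linearly_in_blocked_fraction(mid_ap_state):
    p = ORdParameters()
    y = mid_ap_state.copy()
    y[IDX["b"]] = 0.0
    full = i_na(y, p)
    assert full < 0.0  # inward at -20 mV
    y[IDX["b"]] = 1.0
    assert i_na(y, p) == 0.0
    y[IDX["b"]] = 0.5
    assert i_na(y, p) == pytest.approx(0.5 * full, rel=1e-12)


def test_apply_drug_identity_at_zero_concentration():
    p = ORdParameters(cell_type=0)
    ct0, dv0 = apply_drug(p, cenobamate(), 0.0)
    ct_ref, _ = apply_drug(p, None, 0.0)
    np.testing.assert_array_equal(ct0, ct_ref)
    assert np.all(dv0 == 0.0)


def test_apply_drug_half_block_and_inal_scale():
    drug = cenobamate()
    p = ORdParameters()
    ct_ref, _ = apply_drug(p, None, 0.0)
    ct, _ = apply_drug(p, drug, 509.75)  # at the I_CaL IC50
    assert ct[3] / ct_ref[3] == pytest.approx(0.5)
    ct, _ = apply_drug(p, drug, 170.0)
    assert ct[1] / ct_ref[1] == pytest.approx(1.0 / (1.0 + 170.0 / 46.5), rel=1e-12)
    # fast INa conductance is never statically scaled
    assert ct[0] == ct_ref[0]


def test_apply_drug_missing_channel_is_configuration_error():
    from cardioblock.dose_response import DrugModel

    incomplete = DrugModel(name="x", channels={"IKr": (1000.0, 1.0)})
    with pytest.raises(KeyError, match="lacks a potency"):
        apply_drug(ORdParameters(), incomplete, 10.0)


def test_short_run_is_deterministic_and_b_bounded():
    drug = cenobamate()
    pac = PacingSpec(cycle_length=500.0, pre_beats=2, record_beats=1)
    a = paced_run(ORdParameters(), drug, 170.0, pac)
    b = paced_run(ORdParameters(), drug, 170.0, pac)
    np.testing.assert_array_equal(a.voltage.sweeps, b.voltage.sweeps)
    assert 0.0 <= a.final_state[IDX["b"]] <= 1.0


def test_no_drug_path_has_zero_blocked_state():
    pac = PacingSpec(cycle_length=500.0, pre_beats=1, record_beats=1)
    y0 = initial_state()
    y0[IDX["b"]] = 0.7  # stale block must clear on the drug-free path
    res = paced_run(ORdParameters(), None, 0.0, pac, initial=y0)
    assert res.final_state[IDX["b"]] == 0.0


def test_gating_and_concentration_ranges_after_pacing():
    pac = PacingSpec(cycle_length=1000.0, pre_beats=3, record_beats=1)
    res = paced_run(ORdParameters(cell_type=1), cenobamate(), 170.0, pac)
    y = res.final_state
    gate_names = ("m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp", "a",
                  "iF", "iS", "ap", "iFp", "iSp", "d", "ff", "fs", "fcaf",
                  "fcas", "jca", "ffp", "fcafp", "xrf", "xrs", "xs1", "xs2",
                  "xk1", "b")
    for n in gate_names:
        assert 0.0 <= y[IDX[n]] <= 1.0, n
    for n in ("nai", "ki", "cai", "cansr", "cajsr"):
        assert y[IDX[n]] > 0.0, n


def test_qnet_bookkeeping_and_quadrature():
    """Q_net equals the sum of its six per-current integrals, and the
    recorded-grid trapezoid agrees with a refined recording."""
    pac = PacingSpec(cycle_length=1000.0, pre_beats=3, record_beats=1)
    res = paced_run(ORdParameters(), None, 0.0, pac, record_interval=0.1)
    q = qnet(res)
    assert q.qnet == pytest.approx(sum(q.components.values()), rel=1e-10)
    fine = paced_run(ORdParameters(), None, 0.0, pac, record_interval=0.02)
    assert abs(qnet(fine).qnet - q.qnet) < 1e-3


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        ORdParameters(cell_type=3)
    with pytest.raises(ValueError):
        PacingSpec(record_beats=0)
    with pytest.raises(KeyError):
        apply_drug(ORdParameters(scale={"GFoo": 2.0}), None, 0.0)
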