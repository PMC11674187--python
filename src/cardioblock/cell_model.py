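"""Human ventricular cardiomyocyte model (O'Hara–Rudy 2011) with
state-dependent Na+ channel drug block.

The baseline is the published O'Hara–Rudy dynamic (ORd) 2011 model with its
endocardial, epicardial and midmyocardial parameter sets.  Drug pharmacology
enters two ways:

* fast I_Na carries a dynamic blocked-state occupancy ``b`` obeying a
  first-order ODE whose on/off rates are weighted by the instantaneous
  open-conformation probability (m^3 x availability) for the open-state
  rates k_ob / k_ob_inv and by the m^3-weighted non-available complement for
  the inactivated-state rates k_ib / k_ib_inv; the current is scaled by
  (1 - b);
* late I_Na, I_CaL, I_Kr and I_Ks are scaled statically by the Hill pore
  block factor 1/(1 + [D]/IC50) with their per-channel potencies.

Numerics: fixed-step integration with Rush–Larsen exponential updates for
all gating variables (including ``b``), forward Euler for voltage,
concentrations and CaMK, at dt = 0.005 ms by default.  The per-beat
torsade-risk metric Q_net integrates I_NaL + I_CaL + I_Kr + I_Ks + I_K1 +
I_to over one pacing cycle (uC/uF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from cardioblock.dose_response import DrugModel
from cardioblock.traces import SweepSet

__all__ = [
    "ORdParameters",
    "PacingSpec",
    "SimulationResult",
    "QnetResult",
    "initial_state",
    "apply_drug",
    "db_dt",
    "i_na",
    "paced_run",
    "qnet",
    "STATE_NAMES",
    "cenobamate",
]

ENDO, EPI, MID = 0, 1, 2

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1",
    "Jrelnp", "Jrelp", "CaMKt", "b",
)
N_STATE = len(STATE_NAMES)
IDX = {n: i for i, n in enumerate(STATE_NAMES)}

# Dutta et al. CiPA conductance recalibration (optional variant)
_CIPA_SCALE = {"GNaL": 2.661, "Gto": 0.95, "PCa": 1.007, "GKr": 1.013, "GKs": 1.87, "GK1": 1.698}


@dataclass(frozen=True)
class ORdParameters:
    """Cell type, model variant and optional conductance rescalings."""

    cell_type: int = ENDO  # 0 endo | 1 epi | 2 mid
    variant: str = "base"  # base ORd 2011 | cipa recalibration
    g_na: float = 75.0  # mS/uF
    scale: dict = field(default_factory=dict)  # extra multipliers by name

    def __post_init__(self) -> None:
        if self.cell_type not in (ENDO, EPI, MID):
            raise ValueError("cell_type must be 0 (endo), 1 (epi) or 2 (mid)")
        if self.variant not in ("base", "cipa"):
            raise ValueError("variant must be 'base' or 'cipa'")
        if self.g_na < 0:
            raise ValueError("conductances must be >= 0")


@dataclass(frozen=True)
class PacingSpec:
    """Pacing protocol: cycle length, stimulus, pre-pacing and recorded beats."""

    cycle_length: float = 2000.0  # ms (Q_net convention)
    stim_amplitude: float = -80.0  # uA/uF
    stim_duration: float = 0.5  # ms
    pre_beats: int = 200
    record_beats: int = 2

    def __post_init__(self) -> None:
        if self.cycle_length <= 0 or self.stim_duration <= 0:
            raise ValueError("cycle length and stimulus duration must be > 0")
        if self.record_beats < 1:
            raise ValueError("must record at least one beat")
        if self.pre_beats < 0:
            raise ValueError("pre_beats must be >= 0")


# ---------------------------------------------------------------------------
# Parameter packing
# ---------------------------------------------------------------------------
# ct vector layout (per-cell-type maximal conductances and flags):
#  0 GNa  1 GNaL  2 Gto  3 PCa  4 GKr  5 GKs  6 GK1  7 Gncx  8 Pnak  9 GKb
# 10 jrel_scale  11 jup_scale  12 cmdn_scale  13 is_epi
# drug vector layout:
#  0 conc  1 k_ob  2 k_ob_inv  3 k_ib  4 k_ib_inv

_BASE = {"GNa": 75.0, "GNaL": 0.0075, "Gto": 0.02, "PCa": 0.0001, "GKr": 0.046,
         "GKs": 0.0034, "GK1": 0.1908, "Gncx": 0.0008, "Pnak": 30.0, "GKb": 0.003}
_CT_ORDER = ["GNa", "GNaL", "Gto", "PCa", "GKr", "GKs", "GK1", "Gncx", "Pnak", "GKb"]


def _pack_celltype(params: ORdParameters) -> np.ndarray:
    g = dict(_BASE)
    g["GNa"] = params.g_na
    if params.variant == "cipa":
        for k, s in _CIPA_SCALE.items():
            g[k] *= s
    ct = params.cell_type
    jrel_scale = 1.0
    jup_scale = 1.0
    cmdn_scale = 1.0
    is_epi = 0.0
    if ct == EPI:
        g["GNaL"] *= 0.6
        g["Gto"] *= 4.0
        g["PCa"] *= 1.2
        g["GKr"] *= 1.3
        g["GKs"] *= 1.4
        g["GK1"] *= 1.2
        g["Gncx"] *= 1.1
        g["Pnak"] *= 0.9
        g["GKb"] *= 0.6
        jup_scale = 1.3
        cmdn_scale = 1.3
        is_epi = 1.0
    elif ct == MID:
        g["Gto"] *= 4.0
        g["PCa"] *= 2.5
        g["GKr"] *= 0.8
        g["GK1"] *= 1.3
        g["Gncx"] *= 1.4
        g["Pnak"] *= 0.7
        jrel_scale = 1.7
    for k, s in params.scale.items():
        if k not in g:
            raise KeyError(f"unknown conductance {k!r}")
        g[k] *= s
    vec = [g[k] for k in _CT_ORDER] + [jrel_scale, jup_scale, cmdn_scale, is_epi]
    return np.asarray(vec, dtype=np.float64)


def apply_drug(
    params: ORdParameters,
    drug: DrugModel | None,
    concentration: float,
    apply_free_fraction: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve drug effects into packed model parameter vectors.

    Returns ``(ct, drug_vec)``: the cell-type conductance vector with static
    Hill pore-block scaling applied to I_NaL, I_CaL, I_Kr and I_Ks, and the
    Nav state-rate vector driving the dynamic blocked state.  Fast I_Na is
    never statically scaled — it is handled exclusively through ``b``.
    With ``apply_free_fraction`` the unbound concentration
    ``free_fraction x concentration`` is used throughout.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    ct = _pack_celltype(params)
    if drug is None or concentration == 0.0:
        return ct, np.zeros(5)
    conc = concentration * (drug.free_fraction if apply_free_fraction else 1.0)
    for key, ct_idx in (("INaL", 1), ("ICaL", 3), ("IKr", 4), ("IKs", 5)):
        if key not in drug.channels:
            raise KeyError(f"drug {drug.name!r} lacks a potency entry for {key}")
        ct[ct_idx] *= drug.scale_factor(key, conc)
    drug_vec = np.asarray(
        [conc, drug.k_ob, drug.k_ob_inv, drug.k_ib, drug.k_ib_inv], dtype=np.float64
    )
    return ct, drug_vec


def cenobamate() -> DrugModel:
    """Default multichannel potency / Nav kinetics set for cenobamate.

    Apparent IC50s: peak I_Na 87.6, late I_Na 46.5, I_CaL 509.75, I_Kr 1869
    (regulatory value), I_Ks 1336.1 uM, all with unitary Hill coefficient;
    MRH state rates from the use-dependent block analysis; C_max 170 uM,
    human plasma free fraction 0.4.
    """
    return DrugModel(
        name="cenobamate",
        channels={
            "INa_peak": (87.6, 1.0),
            "INaL": (46.5, 1.0),
            "ICaL": (509.75, 1.0),
            "IKr": (1869.0, 1.0),
            "IKs": (1336.1, 1.0),
        },
        k_ob=0.00215,
        k_ob_inv=0.189,
        k_ib=0.0006698,
        k_ib_inv=0.18252,
        c_max=170.0,
        free_fraction=0.4,
    )


def reproduction_setup(cell_type: int = ENDO) -> tuple[ORdParameters, PacingSpec]:
    """Reference configuration for the APD90/Q_net results: CiPA-recalibrated
    conductances, 2000 ms cycle length, -80 uA/uF x 0.5 ms stimulus, 300
    pre-pacing beats, two recorded beats."""
    return (
        ORdParameters(cell_type=cell_type, variant="cipa"),
        PacingSpec(cycle_length=2000.0, stim_amplitude=-80.0, stim_duration=0.5,
                   pre_beats=300, record_beats=2),
    )


def initial_state() -> np.ndarray:
    """Quiescent initial conditions (model is paced to steady state from here)."""
    y = np.zeros(N_STATE)
    y[IDX["v"]] = -87.0
    y[IDX["nai"]] = 7.0
    y[IDX["nass"]] = 7.0
    y[IDX["ki"]] = 145.0
    y[IDX["kss"]] = 145.0
    y[IDX["cai"]] = 1.0e-4
    y[IDX["cass"]] = 1.0e-4
    y[IDX["cansr"]] = 1.2
    y[IDX["cajsr"]] = 1.2
    for n in ("hf", "hs", "j", "hsp", "jp", "hL", "hLp", "iF", "iS", "iFp",
              "iSp", "ff", "fs", "fcaf", "fcas", "jca", "ffp", "fcafp", "xk1"):
        y[IDX[n]] = 1.0
    return y


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------

_R = 8314.0
_T = 310.0
_F = 96485.0
_L = 0.01
_RAD = 0.0011
_VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
_AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
_ACAP = 2.0 * _AGEO
_VMYO = 0.68 * _VCELL
_VNSR = 0.0552 * _VCELL
_VJSR = 0.0048 * _VCELL
_VSS = 0.02 * _VCELL

_NAO = 140.0
_CAO = 1.8
_KO = 5.4


@njit(cache=True)
def _exp_update(x, x_inf, tau, dt):
    return x_inf + (x - x_inf) * math.exp(-dt / tau)


@njit(cache=True)
def _step(y, dt, ct, drug, istim):
    """Advance the state one dt; returns (INa, INaL, Ito, ICaL, IKr, IKs, IK1)."""
    v = y[0]
    nai = y[1]; nass = y[2]; ki = y[3]; kss = y[4]
    cai = y[5]; cass = y[6]; cansr = y[7]; cajsr = y[8]

    GNa = ct[0]; GNaL = ct[1]; Gto = ct[2]; PCa = ct[3]; GKr = ct[4]
    GKs = ct[5]; GK1 = ct[6]; Gncx = ct[7]; Pnak = ct[8]; GKb = ct[9]
    jrel_scale = ct[10]; jup_scale = ct[11]; cmdn_scale = ct[12]; is_epi = ct[13]

    # CaMK
    KmCaMK = 0.15
    CaMKt = y[40]
    CaMKb = 0.05 * (1.0 - CaMKt) / (1.0 + 0.0015 / cass)
    CaMKa = CaMKb + CaMKt
    dCaMKt = 0.05 * CaMKb * (CaMKb + CaMKt) - 0.00068 * CaMKt
    fp = 1.0 / (1.0 + KmCaMK / CaMKa)  # CaMK-phosphorylated fraction

    vfrt = v * _F / (_R * _T)
    vffrt = v * _F * _F / (_R * _T)
    ENa = (_R * _T / _F) * math.log(_NAO / nai)
    EK = (_R * _T / _F) * math.log(_KO / ki)
    PKNa = 0.01833
    EKs = (_R * _T / _F) * math.log((_KO + PKNa * _NAO) / (ki + PKNa * nai))

    # ---- INa (fast) ----
    mss = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77) + 8.552 * math.exp(-(v + 77.42) / 5.955))
    m = _exp_update(y[9], mss, tm, dt)
    hss = 1.0 / (1.0 + math.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285) + 6.149 * math.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * math.exp(-(v + 17.95) / 28.05) + 0.3343 * math.exp((v + 5.730) / 56.66))
    hf = _exp_update(y[10], hss, thf, dt)
    hs = _exp_update(y[11], hss, ths, dt)
    h = 0.99 * hf + 0.01 * hs
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * math.exp(-(v + 100.6) / 8.281) + 0.3052 * math.exp((v + 0.9941) / 38.45))
    jgate = _exp_update(y[12], jss, tj, dt)
    hssp = 1.0 / (1.0 + math.exp((v + 89.1) / 6.086))
    hsp = _exp_update(y[13], hssp, 3.0 * ths, dt)
    hp = 0.99 * hf + 0.01 * hsp
    jp = _exp_update(y[14], jss, 1.46 * tj, dt)

    m3 = m * m * m
    avail = (1.0 - fp) * h * jgate + fp * hp * jp

    # dynamic drug block of fast INa
    b = y[41]
    conc = drug[0]
    if conc > 0.0:
        on = m3 * (avail * drug[1] + (1.0 - avail) * drug[3]) * conc
        off = m3 * (avail * drug[2] + (1.0 - avail) * drug[4])
        tot = on + off
        if tot > 1.0e-12:
            b = _exp_update(b, on / tot, 1.0 / tot, dt)
    else:
        b = 0.0
    INa = (1.0 - b) * GNa * (v - ENa) * m3 * avail

    # ---- INaL ----
    mLss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    mL = _exp_update(y[15], mLss, tm, dt)
    hLss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    hL = _exp_update(y[16], hLss, 200.0, dt)
    hLssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    hLp = _exp_update(y[17], hLssp, 600.0, dt)
    INaL = GNaL * (v - ENa) * mL * ((1.0 - fp) * hL + fp * hLp)

    # ---- Ito ----
    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (
        1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
        + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814))
    )
    a = _exp_update(y[18], ass, ta, dt)
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    if is_epi > 0.5:
        delta_epi = 1.0 - 0.95 / (1.0 + math.exp((v + 70.0) / 5.0))
    else:
        delta_epi = 1.0
    tiF = 4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0) + 0.08004 * math.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05) + 1.780e-8 * math.exp((v + 114.1) / 8.079))
    tiF *= delta_epi
    tiS *= delta_epi
    AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    iF = _exp_update(y[19], iss, tiF, dt)
    iS = _exp_update(y[20], iss, tiS, dt)
    i_gate = AiF * iF + AiS * iS
    assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
    ap = _exp_update(y[21], assp, ta, dt)
    dti_develop = 1.354 + 1.0e-4 / (math.exp((v - 167.4) / 15.89) + math.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    iFp = _exp_update(y[22], iss, dti_develop * dti_recover * tiF, dt)
    iSp = _exp_update(y[23], iss, dti_develop * dti_recover * tiS, dt)
    ip = AiF * iFp + AiS * iSp
    Ito = Gto * (v - EK) * ((1.0 - fp) * a * i_gate + fp * ap * ip)

    # ---- ICaL / ICaNa / ICaK ----
    dss = 1.0 / (1.0 + math.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    dgate = _exp_update(y[24], dss, td, dt)
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0) + 0.0045 * math.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (3.5e-5 * math.exp(-(v + 5.0) / 4.0) + 3.5e-5 * math.exp((v + 5.0) / 6.0))
    ff = _exp_update(y[25], fss, tff, dt)
    fs = _exp_update(y[26], fss, tfs, dt)
    f = 0.6 * ff + 0.4 * fs
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * math.exp(-(v - 4.0) / 7.0) + 0.04 * math.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * math.exp(-v / 3.0) + 0.00012 * math.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    fcaf = _exp_update(y[27], fcass, tfcaf, dt)
    fcas = _exp_update(y[28], fcass, tfcas, dt)
    fca = Afcaf * fcaf + (1.0 - Afcaf) * fcas
    jca = _exp_update(y[29], fcass, 75.0, dt)
    ffp = _exp_update(y[31], fss, 2.5 * tff, dt)
    fp_gate = 0.6 * ffp + 0.4 * fs
    fcafp = _exp_update(y[32], fcass, 2.5 * tfcaf, dt)
    fcap = Afcaf * fcafp + (1.0 - Afcaf) * fcas
    km2n = jca * 1.0
    anca = 1.0 / (1000.0 / km2n + (1.0 + 0.002 / cass) ** 4)
    nca = y[30]
    if km2n > 1.0e-12:
        nca = _exp_update(nca, anca * 1000.0 / km2n, 1.0 / km2n, dt)
    if vfrt > 1.0e-7 or vfrt < -1.0e-7:
        e2 = math.exp(2.0 * vfrt)
        e1 = math.exp(vfrt)
        PhiCaL = 4.0 * vffrt * (cass * e2 - 0.341 * _CAO) / (e2 - 1.0)
        PhiCaNa = vffrt * (0.75 * nass * e1 - 0.75 * _NAO) / (e1 - 1.0)
        PhiCaK = vffrt * (0.75 * kss * e1 - 0.75 * _KO) / (e1 - 1.0)
    else:
        # v -> 0 limit of the GHK flux
        PhiCaL = 2.0 * _F * (cass - 0.341 * _CAO)
        PhiCaNa = _F * 0.75 * (nass - _NAO)
        PhiCaK = _F * 0.75 * (kss - _KO)
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    gate_n = dgate * (f * (1.0 - nca) + jca * fca * nca)
    gate_p = dgate * (fp_gate * (1.0 - nca) + jca * fcap * nca)
    ICaL = (1.0 - fp) * PCa * PhiCaL * gate_n + fp * PCap * PhiCaL * gate_p
    ICaNa = (1.0 - fp) * PCaNa * PhiCaNa * gate_n + fp * PCaNap * PhiCaNa * gate_p
    ICaK = (1.0 - fp) * PCaK * PhiCaK * gate_n + fp * PCaKp * PhiCaK * gate_p

    # ---- IKr ----
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869) + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355) + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))
    Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    xrf = _exp_update(y[33], xrss, txrf, dt)
    xrs = _exp_update(y[34], xrss, txrs, dt)
    xr = Axrf * xrf + (1.0 - Axrf) * xrs
    rkr = 1.0 / ((1.0 + math.exp((v + 55.0) / 75.0)) * (1.0 + math.exp((v - 10.0) / 30.0)))
    IKr = GKr * math.sqrt(_KO / 5.4) * xr * rkr * (v - EK)

    # ---- IKs ----
    xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80) + 0.001292 * math.exp(-(v + 210.0) / 230.0))
    xs1 = _exp_update(y[35], xs1ss, txs1, dt)
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0) + 0.0193 * math.exp(-(v + 66.54) / 31.0))
    xs2 = _exp_update(y[36], xs1ss, txs2, dt)
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    IKs = GKs * KsCa * xs1 * xs2 * (v - EKs)

    # ---- IK1 ----
    xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * _KO + 144.59) / (1.5692 * _KO + 3.8115)))
    txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36) + math.exp((v + 236.8) / 69.33))
    xk1 = _exp_update(y[37], xk1ss, txk1, dt)
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * _KO) / 9.493))
    IK1 = GK1 * math.sqrt(_KO) * rk1 * xk1 * (v - EK)

    # ---- INaCa (myoplasmic and subspace) ----
    kna1 = 15.0; kna2 = 5.0; kna3 = 88.12
    kasymm = 12.5; wna = 6.0e4; wca = 6.0e4; wnaca = 5.0e3
    kcaon = 1.5e6; kcaoff = 5.0e3
    qna = 0.5224; qca = 0.1670
    hca = math.exp(qca * vfrt)
    hna = math.exp(qna * vfrt)
    KmCaAct = 150.0e-6
    zca = 2.0

    # myoplasmic component
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + _NAO / kna3 * (1.0 + 1.0 / hna)
    h8 = _NAO / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + _NAO / kna1 * (1.0 + _NAO / kna2)
    h11 = _NAO * _NAO / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * _CAO * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    s = x1 + x2 + x3 + x4
    E1 = x1 / s; E2 = x2 / s; E3 = x3 / s; E4 = x4 / s
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_i = 0.8 * Gncx * allo * (JncxNa + zca * JncxCa)

    # subspace component
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    s = x1 + x2 + x3 + x4
    E1 = x1 / s; E2 = x2 / s; E3 = x3 / s; E4 = x4 / s
    allo_ss = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo_ss * (JncxNa + zca * JncxCa)

    # ---- INaK ----
    k1p = 949.5; k1m = 182.4; k2p = 687.2; k2m = 39.4
    k3pn = 1899.0; k3m = 79300.0; k4pn = 639.0; k4m = 40.0
    Knai = 9.073 * math.exp(-0.1550 * vfrt / 3.0)
    Knao = 27.78 * math.exp((1.0 + 0.1550) * vfrt / 3.0)
    Kki = 0.5; Kko = 0.3582
    MgADP = 0.05; MgATP = 9.8; Kmgatp = 1.698e-7
    H = 1.0e-7; eP = 4.2; Khp = 1.698e-7; Knap = 224.0; Kxkur = 292.0
    P = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
    na_i_t = (1.0 + nai / Knai) ** 3
    k_i_t = (1.0 + ki / Kki) ** 2
    na_o_t = (1.0 + _NAO / Knao) ** 3
    k_o_t = (1.0 + _KO / Kko) ** 2
    a1 = k1p * (nai / Knai) ** 3 / (na_i_t + k_i_t - 1.0)
    b1 = k1m * MgADP
    a2 = k2p
    b2 = k2m * (_NAO / Knao) ** 3 / (na_o_t + k_o_t - 1.0)
    a3 = k3pn * (_KO / Kko) ** 2 / (na_o_t + k_o_t - 1.0)
    b3 = k3m * P * H / (1.0 + MgATP / Kmgatp)
    a4 = k4pn * MgATP / Kmgatp / (1.0 + MgATP / Kmgatp)
    b4 = k4m * (ki / Kki) ** 2 / (na_i_t + k_i_t - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    s = x1 + x2 + x3 + x4
    E1 = x1 / s; E2 = x2 / s; E3 = x3 / s; E4 = x4 / s
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    INaK = Pnak * (JnakNa + JnakK)

    # ---- background and pump currents ----
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    IKb = GKb * xkb * (v - EK)
    if vfrt > 1.0e-7 or vfrt < -1.0e-7:
        e1 = math.exp(vfrt)
        e2 = math.exp(2.0 * vfrt)
        INab = 3.75e-10 * vffrt * (nai * e1 - _NAO) / (e1 - 1.0)
        ICab = 2.5e-8 * 4.0 * vffrt * (cai * e2 - 0.341 * _CAO) / (e2 - 1.0)
    else:
        INab = 3.75e-10 * _F * (nai - _NAO)
        ICab = 2.5e-8 * 2.0 * _F * (cai - 0.341 * _CAO)
    IpCa = 0.0005 * cai / (0.0005 + cai)

    # ---- fluxes ----
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8) * jrel_scale
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    Jrelnp = _exp_update(y[38], Jrel_inf, tau_rel, dt)
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8) * jrel_scale
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    Jrelp = _exp_update(y[39], Jrel_infp, tau_relp, dt)
    fJrelp = fp
    Jrel = (1.0 - fJrelp) * Jrelnp + fJrelp * Jrelp

    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    Jleak = 0.0039375 * cansr / 15.0
    Jup = ((1.0 - fp) * Jupnp + fp * Jupp) * jup_scale - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # ---- concentration updates ----
    Itot_na = INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab
    dnai = -Itot_na * _ACAP / (_F * _VMYO) + JdiffNa * _VSS / _VMYO
    dnass = -(ICaNa + 3.0 * INaCa_ss) * _ACAP / (_F * _VSS) - JdiffNa
    dki = -(Ito + IKr + IKs + IK1 + IKb + istim - 2.0 * INaK) * _ACAP / (_F * _VMYO) + JdiffK * _VSS / _VMYO
    dkss = -ICaK * _ACAP / (_F * _VSS) - JdiffK
    cmdnmax = 0.05 * cmdn_scale
    Bcai = 1.0 / (1.0 + cmdnmax * 0.00238 / (0.00238 + cai) ** 2 + 0.07 * 0.0005 / (0.0005 + cai) ** 2)
    dcai = Bcai * (
        -(IpCa + ICab - 2.0 * INaCa_i) * _ACAP / (2.0 * _F * _VMYO)
        - Jup * _VNSR / _VMYO + Jdiff * _VSS / _VMYO
    )
    Bcass = 1.0 / (1.0 + 0.047 * 0.00087 / (0.00087 + cass) ** 2 + 1.124 * 0.0087 / (0.0087 + cass) ** 2)
    dcass = Bcass * (
        -(ICaL - 2.0 * INaCa_ss) * _ACAP / (2.0 * _F * _VSS) + Jrel * _VJSR / _VSS - Jdiff
    )
    dcansr = Jup - Jtr * _VJSR / _VNSR
    Bcajsr = 1.0 / (1.0 + 10.0 * 0.8 / (0.8 + cajsr) ** 2)
    dcajsr = Bcajsr * (Jtr - Jrel)

    Itot = (INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
            + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + istim)

    # ---- commit ----
    y[0] = v - dt * Itot
    y[1] = nai + dt * dnai
    y[2] = nass + dt * dnass
    y[3] = ki + dt * dki
    y[4] = kss + dt * dkss
    y[5] = cai + dt * dcai
    y[6] = cass + dt * dcass
    y[7] = cansr + dt * dcansr
    y[8] = cajsr + dt * dcajsr
    y[9] = m; y[10] = hf; y[11] = hs; y[12] = jgate; y[13] = hsp; y[14] = jp
    y[15] = mL; y[16] = hL; y[17] = hLp
    y[18] = a; y[19] = iF; y[20] = iS; y[21] = ap; y[22] = iFp; y[23] = iSp
    y[24] = dgate; y[25] = ff; y[26] = fs; y[27] = fcaf; y[28] = fcas
    y[29] = jca; y[30] = nca; y[31] = ffp; y[32] = fcafp
    y[33] = xrf; y[34] = xrs; y[35] = xs1; y[36] = xs2; y[37] = xk1
    y[38] = Jrelnp; y[39] = Jrelp
    y[40] = CaMKt + dt * dCaMKt
    y[41] = b

    return INa, INaL, Ito, ICaL, IKr, IKs, IK1


@njit(cache=True)
def _run_beats(y, n_beats, cl, stim_amp, stim_dur, dt, ct, drug,
               rec_every, rec_v, rec_cur):
    """Pace n_beats; record V each rec_every steps (and the six Q_net
    currents) into rec_v / rec_cur when their length is non-zero."""
    steps_per_beat = int(round(cl / dt))
    stim_steps = int(round(stim_dur / dt))
    k = 0
    n_rec = rec_v.shape[0]
    for beat in range(n_beats):
        for s in range(steps_per_beat):
            istim = stim_amp if s < stim_steps else 0.0
            INa, INaL, Ito, ICaL, IKr, IKs, IK1 = _step(y, dt, ct, drug, istim)
            if n_rec > 0:
                step_idx = beat * steps_per_beat + s
                if step_idx % rec_every == 0:
                    j = step_idx // rec_every
                    if j < n_rec:
                        rec_v[j] = y[0]
                        rec_cur[j, 0] = INaL
                        rec_cur[j, 1] = ICaL
                        rec_cur[j, 2] = IKr
                        rec_cur[j, 3] = IKs
                        rec_cur[j, 4] = IK1
                        rec_cur[j, 5] = Ito
                        k = j + 1
    return k


# ---------------------------------------------------------------------------
# Python-level operations
# ---------------------------------------------------------------------------

def db_dt(state: np.ndarray, drug: DrugModel, concentration: float) -> float:
    """Rate of change of the blocked-state occupancy b at the given state.

    Both the open-state term (weighted by the open probability
    m^3 x availability) and the inactivated-state term (weighted by the
    m^3-scaled non-available complement) drive binding at k*[D]*(1-b) and
    unbinding at k_inv*b.
    """
    v = state[IDX["v"]]
    m3 = state[IDX["m"]] ** 3
    CaMKt = state[IDX["CaMKt"]]
    cass = state[IDX["cass"]]
    CaMKb = 0.05 * (1.0 - CaMKt) / (1.0 + 0.0015 / cass)
    fp = 1.0 / (1.0 + 0.15 / (CaMKb + CaMKt))
    h = 0.99 * state[IDX["hf"]] + 0.01 * state[IDX["hs"]]
    hp = 0.99 * state[IDX["hf"]] + 0.01 * state[IDX["hsp"]]
    avail = (1.0 - fp) * h * state[IDX["j"]] + fp * hp * state[IDX["jp"]]
    b = state[IDX["b"]]
    on = m3 * (avail * drug.k_ob + (1.0 - avail) * drug.k_ib) * concentration
    off = m3 * (avail * drug.k_ob_inv + (1.0 - avail) * drug.k_ib_inv)
    return on * (1.0 - b) - off * b


def i_na(state: np.ndarray, params: ORdParameters) -> float:
    """Fast Na+ current (uA/uF) at the given state, scaled by (1 - b)."""
    v = state[IDX["v"]]
    nai = state[IDX["nai"]]
    ena = (_R * _T / _F) * math.log(_NAO / nai)
    m3 = state[IDX["m"]] ** 3
    CaMKt = state[IDX["CaMKt"]]
    cass = state[IDX["cass"]]
    CaMKb = 0.05 * (1.0 - CaMKt) / (1.0 + 0.0015 / cass)
    fp = 1.0 / (1.0 + 0.15 / (CaMKb + CaMKt))
    h = 0.99 * state[IDX["hf"]] + 0.01 * state[IDX["hs"]]
    hp = 0.99 * state[IDX["hf"]] + 0.01 * state[IDX["hsp"]]
    avail = (1.0 - fp) * h * state[IDX["j"]] + fp * hp * state[IDX["jp"]]
    return (1.0 - state[IDX["b"]]) * params.g_na * (v - ena) * m3 * avail


QNET_CURRENTS = ("INaL", "ICaL", "IKr", "IKs", "IK1", "Ito")


@dataclass
class QnetResult:
    """Per-beat net charge of the six Q_net currents (uC/uF)."""

    qnet: float
    components: dict
    beat_index: int


@dataclass
class SimulationResult:
    """Recorded beats of a paced run."""

    voltage: SweepSet  # one sweep per recorded beat
    currents: np.ndarray  # (n_rec_total, 6) at the recording interval
    record_interval: float  # ms
    apd90: list  # per recorded beat, ms
    final_state: np.ndarray
    pacing: PacingSpec
    concentration: float
    steady: bool  # |ΔAPD90| of last two beats < 0.1 ms

    @property
    def final_apd90(self) -> float:
        return self.apd90[-1]


def paced_run(
    params: ORdParameters,
    drug: DrugModel | None = None,
    concentration: float = 0.0,
    pacing: PacingSpec = PacingSpec(),
    dt: float = 0.005,
    record_interval: float = 0.1,
    initial: np.ndarray | None = None,
    apply_free_fraction: bool = False,
) -> SimulationResult:
    """Pace the (drug-extended) cell to steady state and record final beats.

    ``pacing.pre_beats`` beats are integrated without recording, then
    ``pacing.record_beats`` beats are recorded at ``record_interval`` ms.
    APD90 is measured per recorded beat from the maximum-dV/dt take-off to
    90% repolarization toward the pre-stimulus diastolic potential.
    """
    from cardioblock.trace_analysis import ap_metrics

    ct, drug_vec = apply_drug(params, drug, concentration, apply_free_fraction)
    y = initial_state() if initial is None else initial.copy()
    empty_v = np.empty(0)
    empty_c = np.empty((0, 6))
    if pacing.pre_beats > 0:
        _run_beats(
            y, pacing.pre_beats, pacing.cycle_length, pacing.stim_amplitude,
            pacing.stim_duration, dt, ct, drug_vec, 1, empty_v, empty_c,
        )
    rec_every = max(1, int(round(record_interval / dt)))
    steps_per_beat = int(round(pacing.cycle_length / dt))
    n_rec = (steps_per_beat * pacing.record_beats + rec_every - 1) // rec_every
    rec_v = np.empty(n_rec)
    rec_cur = np.empty((n_rec, 6))
    _run_beats(
        y, pacing.record_beats, pacing.cycle_length, pacing.stim_amplitude,
        pacing.stim_duration, dt, ct, drug_vec, rec_every, rec_v, rec_cur,
    )
    if not np.all(np.isfinite(rec_v)):
        raise FloatingPointError("solver blow-up: non-finite membrane potential")
    dt_rec = rec_every * dt
    per_beat = steps_per_beat // rec_every
    sweeps = rec_v[: per_beat * pacing.record_beats].reshape(pacing.record_beats, per_beat)
    vtrace = SweepSet(
        sample_interval=dt_rec, sweeps=sweeps, signal_kind="voltage", units="mV",
        protocol_ref="paced_run",
    )
    # the stimulus sits at t=0 of each sweep, so the diastolic reference is
    # the first sample (end-diastole of the preceding beat)
    metrics = [
        ap_metrics(vtrace, [0.0], sweep_index=bi, rp_window_ms=5.0)[0]
        for bi in range(pacing.record_beats)
    ]
    apd = []
    for bi, mm in enumerate(metrics):
        if not mm.captured or not np.isfinite(mm.apd90):
            apd.append(float("nan"))
        else:
            apd.append(mm.apd90)
    steady = (
        len(apd) >= 2
        and np.isfinite(apd[-1])
        and np.isfinite(apd[-2])
        and abs(apd[-1] - apd[-2]) < 0.1
    )
    return SimulationResult(
        voltage=vtrace,
        currents=rec_cur,
        record_interval=dt_rec,
        apd90=apd,
        final_state=y,
        pacing=pacing,
        concentration=concentration,
        steady=steady,
    )


def qnet(result: SimulationResult, beat_index: int = -1) -> QnetResult:
    """Per-beat Q_net: trapezoidal integral of the six currents (uC/uF)."""
    n_beats = result.voltage.n_sweeps
    per_beat = result.voltage.n_samples
    bi = beat_index % n_beats
    sl = slice(bi * per_beat, (bi + 1) * per_beat)
    cur = result.currents[sl]
    if cur.shape[0] < per_beat:
        raise ValueError("incomplete beat in the recording")
    dt_s = result.record_interval / 1000.0  # ms -> s so the integral is uC/uF
    comps = {
        name: float(np.trapezoid(cur[:, k], dx=dt_s))
        for k, name in enumerate(QNET_CURRENTS)
    }
    return QnetResult(qnet=float(sum(comps.values())), components=comps, beat_index=bi)
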