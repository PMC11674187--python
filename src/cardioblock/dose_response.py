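"""Potency estimation: Hill-type fractional block, single-point IC50 with
control correction, and multi-concentration Hill fits.

The single-point route is the primary estimator for screening data: given the
mean fractional inhibition f measured at one concentration C (after
subtracting the mean inhibition seen in time-matched vehicle controls, i.e.
rundown), the apparent IC50 under a Hill curve with coefficient n_H is

    IC50 = C * ((1 - f) / f)^(1/n_H).

The control correction is a plain subtraction of the mean control inhibition;
no rescaling by (1 - control) is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InhibitionPoint",
    "DoseResponseFit",
    "DrugModel",
    "fractional_block",
    "ic50_single_point",
    "fit_hill",
    "NoMeasurableBlockError",
    "SaturationError",
]


class NoMeasurableBlockError(ValueError):
    """Net inhibition <= 0: potency not estimable."""


class SaturationError(ValueError):
    """Net inhibition >= 1: block saturated, potency not estimable."""


@dataclass(frozen=True)
class InhibitionPoint:
    """One concentration-inhibition observation (fraction in [0, 1])."""

    concentration: float  # uM
    fractional_inhibition: float
    n_cells: int = 1
    dispersion: float = 0.0  # SD of the fraction

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not (0.0 <= self.fractional_inhibition <= 1.0):
            raise ValueError("fractional inhibition must lie in [0, 1]")


@dataclass(frozen=True)
class DoseResponseFit:
    ic50: float  # uM
    n_h: float
    ic50_stderr: float | None = None
    n_h_stderr: float | None = None
    method: str = "single_point"  # single_point | hill_fit

    def __post_init__(self) -> None:
        if self.ic50 <= 0 or self.n_h <= 0:
            raise ValueError("IC50 and n_H must be > 0")


@dataclass
class DrugModel:
    """Per-channel potencies plus Nav state-specific blocking kinetics.

    ``channels`` maps channel keys (INa_peak, INaL, ICaL, IKr, IKs) to
    (IC50 uM, n_H).  The four Nav rates parameterize the dynamic blocked
    state of the cell model; C_max is the maximal effective therapeutic
    plasma concentration, free_fraction the unbound plasma fraction.
    """

    name: str = "drug"
    channels: dict[str, tuple[float, float]] = field(default_factory=dict)
    k_ob: float = 0.0  # uM^-1 ms^-1
    k_ob_inv: float = 0.0  # ms^-1
    k_ib: float = 0.0  # uM^-1 ms^-1
    k_ib_inv: float = 0.0  # ms^-1
    c_max: float = 170.0  # uM
    free_fraction: float = 1.0

    def __post_init__(self) -> None:
        for ch, (ic50, n_h) in self.channels.items():
            if ic50 <= 0 or n_h <= 0:
                raise ValueError(f"channel {ch}: IC50 and n_H must be > 0")
        if not (0.0 < self.free_fraction <= 1.0):
            raise ValueError("free_fraction must lie in (0, 1]")
        for r in ("k_ob", "k_ob_inv", "k_ib", "k_ib_inv"):
            if getattr(self, r) < 0:
                raise ValueError(f"{r} must be >= 0")

    def ic50(self, channel: str) -> float:
        try:
            return self.channels[channel][0]
        except KeyError:
            raise KeyError(
                f"drug {self.name!r} has no potency entry for channel {channel!r}"
            ) from None

    def scale_factor(self, channel: str, concentration: float) -> float:
        """Static pore-block conductance multiplier 1 - fractional_block."""
        ic50, n_h = self.channels[channel]
        return 1.0 - fractional_block(concentration, ic50, n_h)

    # -- YAML round trip --------------------------------------------------
    def to_yaml(self, path) -> None:
        import yaml

        doc = {
            "name": self.name,
            "channels": {k: {"ic50_uM": v[0], "n_h": v[1]} for k, v in self.channels.items()},
            "nav_rates": {
                "k_ob": self.k_ob,
                "k_ob_inv": self.k_ob_inv,
                "k_ib": self.k_ib,
                "k_ib_inv": self.k_ib_inv,
            },
            "c_max_uM": self.c_max,
            "free_fraction": self.free_fraction,
        }
        with open(path, "w") as f:
            yaml.safe_dump(doc, f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DrugModel":
        import yaml

        with open(path) as f:
            doc = yaml.safe_load(f)
        rates = doc.get("nav_rates", {})
        return cls(
            name=doc.get("name", "drug"),
            channels={
                k: (float(v["ic50_uM"]), float(v.get("n_h", 1.0)))
                for k, v in doc.get("channels", {}).items()
            },
            k_ob=float(rates.get("k_ob", 0.0)),
            k_ob_inv=float(rates.get("k_ob_inv", 0.0)),
            k_ib=float(rates.get("k_ib", 0.0)),
            k_ib_inv=float(rates.get("k_ib_inv", 0.0)),
            c_max=float(doc.get("c_max_uM", 170.0)),
            free_fraction=float(doc.get("free_fraction", 1.0)),
        )


def fractional_block(concentration, ic50: float, n_h: float = 1.0):
    """Hill fractional block 1 / (1 + (IC50/C)^n_H), with the C=0 limit 0.

    Accepts scalars or arrays; strictly increasing in concentration and
    strictly decreasing in IC50.
    """
    if ic50 <= 0:
        raise ValueError("IC50 must be > 0")
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    with np.errstate(divide="ignore"):
        f = np.where(c > 0, 1.0 / (1.0 + (ic50 / np.where(c > 0, c, 1.0)) ** n_h), 0.0)
    return float(f) if np.isscalar(concentration) else f


def ic50_single_point(
    concentration: float,
    inhibition_drug: float,
    inhibition_control: float = 0.0,
    n_h: float = 1.0,
) -> DoseResponseFit:
    """Apparent IC50 from one concentration, with rundown control correction.

    Net inhibition f = inhibition_drug - inhibition_control (plain
    subtraction); IC50 = concentration * ((1 - f)/f)^(1/n_H).
    """
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    f = inhibition_drug - inhibition_control
    if f <= 0:
        raise NoMeasurableBlockError(
            f"net inhibition {f:.4g} <= 0: no measurable block at {concentration} uM"
        )
    if f >= 1:
        raise SaturationError(f"net inhibition {f:.4g} >= 1: saturated block")
    ic50 = concentration * ((1.0 - f) / f) ** (1.0 / n_h)
    return DoseResponseFit(ic50=ic50, n_h=n_h, method="single_point")


def fit_hill(
    points: list[InhibitionPoint],
    fix_n_h: float | None = None,
) -> DoseResponseFit:
    """Weighted least-squares Hill fit of inhibition vs. concentration.

    Weights are 1/SD^2 where per-point dispersion is available (unit weights
    otherwise).  Requires >= 3 distinct non-zero concentrations, or >= 2 when
    n_H is fixed; a single point with fixed n_H reduces to the closed-form
    single-point estimator.
    """
    import lmfit

    pts = [p for p in points if p.concentration > 0]
    concs = sorted({p.concentration for p in pts})
    need = 2 if fix_n_h is not None else 3
    if len(concs) == 1 and fix_n_h is not None:
        p = pts[0]
        return ic50_single_point(p.concentration, p.fractional_inhibition, n_h=fix_n_h)
    if len(concs) < need:
        raise ValueError(
            f"need >= {need} distinct non-zero concentrations, got {len(concs)}"
        )
    y = np.array([p.fractional_inhibition for p in pts])
    if np.all(y <= 0):
        raise ValueError("all-zero inhibition: IC50 not identifiable")
    if np.all(y >= 1):
        raise ValueError("all-saturated inhibition: IC50 not identifiable")
    c = np.array([p.concentration for p in pts])
    sd = np.array([p.dispersion for p in pts])
    w = np.where(sd > 0, 1.0 / np.maximum(sd, 1e-12), 1.0)

    model = lmfit.Model(lambda conc, ic50, n_h: fractional_block(conc, ic50, n_h))
    params = model.make_params()
    # start at the interpolated half-block concentration
    guess = float(np.interp(0.5, np.clip(y, 0, 1), c, left=c.min(), right=c.max()))
    params["ic50"].set(value=max(guess, 1e-6), min=1e-9)
    params["n_h"].set(value=fix_n_h or 1.0, min=0.05, vary=fix_n_h is None)
    res = model.fit(y, params, conc=c, weights=w)
    return DoseResponseFit(
        ic50=float(res.params["ic50"].value),
        n_h=float(res.params["n_h"].value),
        ic50_stderr=(
            float(res.params["ic50"].stderr) if res.params["ic50"].stderr else None
        ),
        n_h_stderr=(
            float(res.params["n_h"].stderr)
            if (fix_n_h is None and res.params["n_h"].stderr)
            else None
        ),
        method="hill_fit",
    )
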