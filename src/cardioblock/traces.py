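"""Sweep-set container for multi-sweep patch-clamp traces, with HDF5/CSV I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SweepSet"]

_ALLOWED_UNITS = {"pA", "pA/pF", "mV", "uA/uF"}


@dataclass
class SweepSet:
    """Uniformly sampled multi-sweep recording.

    ``sweeps`` is an array of shape (n_sweeps, n_samples); all sweeps share
    one sample interval (ms).  ``signal_kind`` distinguishes current from
    voltage traces, ``units`` labels the sample values and ``protocol_ref``
    names the protocol that produced the recording.
    """

    sample_interval: float  # ms
    sweeps: np.ndarray  # (n_sweeps, n_samples)
    signal_kind: str = "current"  # current | voltage
    units: str = "pA"
    protocol_ref: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if self.signal_kind not in ("current", "voltage"):
            raise ValueError(f"unknown signal_kind {self.signal_kind!r}")
        if self.units not in _ALLOWED_UNITS:
            raise ValueError(f"units must be one of {sorted(_ALLOWED_UNITS)}")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[1]

    @property
    def time(self) -> np.ndarray:
        """Sample times in ms from sweep start."""
        return np.arange(self.n_samples) * self.sample_interval

    def copy(self) -> "SweepSet":
        return SweepSet(
            sample_interval=self.sample_interval,
            sweeps=self.sweeps.copy(),
            signal_kind=self.signal_kind,
            units=self.units,
            protocol_ref=self.protocol_ref,
            meta=dict(self.meta),
        )

    # -- I/O --------------------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=self.time)
            d = f.create_dataset("sweeps", data=self.sweeps)
            d.attrs["sample_interval_ms"] = self.sample_interval
            d.attrs["signal_kind"] = self.signal_kind
            d.attrs["units"] = self.units
            d.attrs["protocol"] = self.protocol_ref

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "SweepSet":
        import h5py

        with h5py.File(path, "r") as f:
            d = f["sweeps"]
            return cls(
                sample_interval=float(d.attrs["sample_interval_ms"]),
                sweeps=d[...],
                signal_kind=str(d.attrs["signal_kind"]),
                units=str(d.attrs["units"]),
                protocol_ref=str(d.attrs["protocol"]),
            )

    def to_csv(self, path: str | Path) -> None:
        """Long-format CSV: columns sweep, time_ms, value."""
        n_sw, n_s = self.sweeps.shape
        df = pd.DataFrame(
            {
                "sweep": np.repeat(np.arange(n_sw), n_s),
                "time_ms": np.tile(self.time, n_sw),
                "value": self.sweeps.ravel(),
            }
        )
        with open(path, "w") as f:
            f.write(
                f"# signal_kind={self.signal_kind} units={self.units} "
                f"protocol={self.protocol_ref} sample_interval_ms={self.sample_interval}\n"
            )
            df.to_csv(f, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SweepSet":
        meta: dict[str, str] = {}
        with open(path) as f:
            header = f.readline()
            if header.startswith("#"):
                for tok in header[1:].split():
                    k, _, v = tok.partition("=")
                    meta[k] = v
                df = pd.read_csv(f)
            else:
                f.seek(0)
                df = pd.read_csv(f)
        n_sw = int(df["sweep"].max()) + 1
        sweeps = df["value"].to_numpy().reshape(n_sw, -1)
        dt = float(meta.get("sample_interval_ms", df["time_ms"].iloc[1] - df["time_ms"].iloc[0]))
        return cls(
            sample_interval=dt,
            sweeps=sweeps,
            signal_kind=meta.get("signal_kind", "current"),
            units=meta.get("units", "pA"),
            protocol_ref=meta.get("protocol", ""),
        )
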