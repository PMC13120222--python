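"""Shared containers for leaf-cuvette VOC recordings.

A recording couples a leaf enclosed in a flow-through cuvette to a
PTR-TOF-MS sampling the outlet air.  Each trace holds 1 Hz environment
columns (PPFD, leaf temperature, CO2, molar flow, net assimilation)
alongside per-channel VOC mixing ratios in nmol mol^-1, stored in columns
named ``chi_<m/z>`` (e.g. ``chi_69.070`` for protonated isoprene).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

CHANNEL_PREFIX = "chi_"

#: mandatory / optional environment columns of a tidy trace file
TIME_COLUMN = "time_s"
ENV_COLUMNS = ("ppfd", "t_leaf_c", "co2_umol_mol", "q_flow_umol_s", "a_net")


def channel_column(mz: float) -> str:
    """Column name for a VOC channel at monoisotopic ion mass ``mz`` (Da)."""
    return f"{CHANNEL_PREFIX}{mz:.3f}"


def column_mz(name: str) -> float:
    """Inverse of :func:`channel_column`."""
    if not name.startswith(CHANNEL_PREFIX):
        raise ValueError(f"not a channel column: {name!r}")
    return float(name[len(CHANNEL_PREFIX):])


@dataclass(frozen=True)
class ChamberGeometry:
    """Cuvette flow geometry used by the mass balance.

    Parameters
    ----------
    q_flow_umol_s
        Molar air flow through the cuvette (µmol s^-1).
    a_leaf_m2
        Enclosed leaf area (m^2).
    n_chamber_umol
        Molar content of the chamber headspace (µmol).  Zero means the
        headspace equilibrates instantaneously (static mass balance).
    chi_in
        Inlet mixing ratio (nmol mol^-1), either a scalar applied to all
        channels or a mapping from channel column name to value.
    """

    q_flow_umol_s: float = 500.0
    a_leaf_m2: float = 6.0e-4
    n_chamber_umol: float = 0.0
    chi_in: float | Mapping[str, float] = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.q_flow_umol_s) and self.q_flow_umol_s > 0):
            raise ValueError("q_flow_umol_s must be finite and > 0")
        if not (math.isfinite(self.a_leaf_m2) and self.a_leaf_m2 > 0):
            raise ValueError("a_leaf_m2 must be finite and > 0")
        if not (math.isfinite(self.n_chamber_umol) and self.n_chamber_umol >= 0):
            raise ValueError("n_chamber_umol must be finite and >= 0")

    @property
    def residence_time_s(self) -> float:
        """Headspace turnover time τ = n_chamber / Q (s)."""
        return self.n_chamber_umol / self.q_flow_umol_s

    def inlet(self, channel: str | None = None) -> float:
        """Inlet mixing ratio for ``channel`` (nmol mol^-1)."""
        if isinstance(self.chi_in, Mapping):
            if channel is None:
                raise ValueError("per-channel chi_in requires a channel name")
            return float(self.chi_in.get(channel, 0.0))
        return float(self.chi_in)


@dataclass
class LeafTrace:
    """One leaf × treatment recording on a common 1 Hz time base."""

    trace_id: str
    data: pd.DataFrame
    geometry: ChamberGeometry = ChamberGeometry()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if TIME_COLUMN not in self.data.columns:
            raise ValueError(f"trace {self.trace_id!r} lacks a {TIME_COLUMN} column")
        t = np.asarray(self.data[TIME_COLUMN], dtype=float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError(
                f"trace {self.trace_id!r}: {TIME_COLUMN} must be strictly increasing"
            )

    @property
    def time_s(self) -> np.ndarray:
        return np.asarray(self.data[TIME_COLUMN], dtype=float)

    @property
    def dt_s(self) -> float:
        t = self.time_s
        if t.size < 2:
            return float("nan")
        return float(np.median(np.diff(t)))

    @property
    def channel_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith(CHANNEL_PREFIX)]

    @property
    def channel_mz(self) -> list[float]:
        return [column_mz(c) for c in self.channel_columns]

    @property
    def has_ppfd(self) -> bool:
        return "ppfd" in self.data.columns

    def chi(self, mz: float, atol: float = 5e-4) -> np.ndarray:
        """Mixing-ratio series (nmol mol^-1) of the channel nearest ``mz``."""
        for col in self.channel_columns:
            if abs(column_mz(col) - mz) <= atol:
                return np.asarray(self.data[col], dtype=float)
        raise KeyError(f"trace {self.trace_id!r} has no channel at m/z {mz}")
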