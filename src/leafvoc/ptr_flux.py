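"""Channel registry, drift-tube bookkeeping and cuvette mass-balance fluxes.

The PTR-TOF-MS reports each VOC as a protonated ion at an exact m/z; this
module maps those channels onto compounds and biosynthetic groups, converts
outlet-air mixing ratios into leaf-area-normalised emission rates via the
cuvette mass balance

    E = Q * (chi_out - chi_in) / A        [nmol m^-2 s^-1]

(Q molar flow in µmol s^-1, chi in nmol mol^-1, A leaf area in m^2), applies
empty-chamber blank correction, and sums compound fluxes into six
biosynthetic groups (isoprene, LOX/GLV products, reactive carbonyls,
methanol, short-chain organic acids, ethanol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import constants

from .core import ChamberGeometry, LeafTrace, column_mz

GROUPS = ("isoprene", "lox", "carbonyls", "methanol", "acids", "ethanol")

#: single-member groups whose group flux equals the member flux
SINGLE_MEMBER_GROUPS = ("isoprene", "methanol", "ethanol")


@dataclass(frozen=True)
class ChannelDef:
    """One PTR-TOF-MS channel: ion mass -> compound -> biosynthetic group."""

    mz: float
    ion_formula: str
    compound: str
    group: str
    k_rate: float | None = None  # proton-transfer rate constant, optional
    note: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mz) and self.mz > 0):
            raise ValueError("mz must be finite and > 0")
        if self.group not in GROUPS:
            raise ValueError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )


# Default channel table. The printed ion formula for m/z 45.034 is
# inconsistent with protonated acetaldehyde (C2H5O+); the registry keys on
# the m/z and keeps the formula as printed, with the discrepancy noted.
DEFAULT_CHANNELS: tuple[ChannelDef, ...] = (
    ChannelDef(69.070, "C5H9+", "isoprene", "isoprene"),
    ChannelDef(99.080, "C6H11O+", "hexenals", "lox"),
    ChannelDef(101.096, "C6H13O+", "hexanal_hexenols", "lox"),
    ChannelDef(143.107, "C8H15O2+", "hexenyl_acetate", "lox"),
    ChannelDef(87.080, "C5H11O+", "pentanal_1-penten-3-ol", "lox"),
    ChannelDef(45.034, "C2H2O+", "acetaldehyde", "carbonyls",
               note="formula as printed; inconsistent with protonated acetaldehyde"),
    ChannelDef(59.049, "C3H7O+", "propanal_acetone", "carbonyls"),
    ChannelDef(73.065, "C4H9O+", "butanal_mek", "carbonyls"),
    ChannelDef(71.049, "C4H7O+", "mvk_macr", "carbonyls"),
    ChannelDef(75.045, "C3H7O2+", "hydroxyacetone", "carbonyls"),
    ChannelDef(59.014, "C2H3O2+", "glyoxal", "carbonyls"),
    ChannelDef(73.028, "C3H5O2+", "methylglyoxal", "carbonyls"),
    ChannelDef(33.034, "CH5O+", "methanol", "methanol"),
    ChannelDef(47.013, "CH3O2+", "formic_acid", "acids"),
    ChannelDef(61.028, "C2H5O2+", "acetic_acid", "acids"),
    ChannelDef(47.049, "C2H7O+", "ethanol", "ethanol"),
)


class ChannelRegistry:
    """m/z → compound → group lookup with a configurable match tolerance.

    The default tolerance of ±0.01 Da keeps the near-isobars
    47.013 (formic acid) / 47.049 (ethanol) and
    59.014 (glyoxal) / 59.049 (propanal/acetone) distinguishable.
    """

    def __init__(self, channels: Iterable[ChannelDef] | None = None,
                 match_tolerance: float = 0.01):
        if match_tolerance <= 0:
            raise ValueError("match_tolerance must be > 0")
        self.channels: tuple[ChannelDef, ...] = tuple(
            DEFAULT_CHANNELS if channels is None else channels
        )
        self.match_tolerance = float(match_tolerance)
        mzs = sorted(c.mz for c in self.channels)
        for a, b in zip(mzs, mzs[1:]):
            if b - a <= self.match_tolerance:
                raise ValueError(
                    f"registry m/z {a} and {b} are not distinguishable at "
                    f"±{self.match_tolerance} Da"
                )
        compounds = [c.compound for c in self.channels]
        if len(set(compounds)) != len(compounds):
            raise ValueError("duplicate compound labels in registry")
        self._by_compound = {c.compound: c for c in self.channels}

    def __iter__(self):
        return iter(self.channels)

    def __len__(self) -> int:
        return len(self.channels)

    def by_compound(self, compound: str) -> ChannelDef:
        try:
            return self._by_compound[compound]
        except KeyError:
            raise KeyError(f"compound {compound!r} absent from registry") from None

    def members(self, group: str) -> tuple[ChannelDef, ...]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
        return tuple(c for c in self.channels if c.group == group)

    def match(self, mz: float) -> ChannelDef | None:
        """Nearest registry entry within tolerance, None if unassigned.

        Raises if two entries both lie within tolerance (ambiguous).
        """
        hits = [c for c in self.channels if abs(c.mz - mz) <= self.match_tolerance]
        if len(hits) > 1:
            hits.sort(key=lambda c: abs(c.mz - mz))
            raise ValueError(
                f"ambiguous m/z {mz}: within ±{self.match_tolerance} Da of both "
                f"{hits[0].compound} ({hits[0].mz}) and {hits[1].compound} ({hits[1].mz})"
            )
        return hits[0] if hits else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"mz": c.mz, "ion_formula": c.ion_formula, "compound": c.compound,
                 "group": c.group, "k_rate": c.k_rate, "note": c.note}
                for c in self.channels
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, match_tolerance: float = 0.01
                 ) -> "ChannelRegistry":
        df = pd.read_csv(path)
        required = {"mz", "ion_formula", "compound", "group"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"registry file {path} lacks columns {sorted(missing)}")
        chans = [
            ChannelDef(
                mz=float(r.mz), ion_formula=str(r.ion_formula),
                compound=str(r.compound), group=str(r.group),
                k_rate=None if "k_rate" not in df.columns or pd.isna(r.k_rate)
                else float(r.k_rate),
                note="" if "note" not in df.columns or pd.isna(r.note) else str(r.note),
            )
            for r in df.itertuples()
        ]
        return cls(chans, match_tolerance=match_tolerance)


DEFAULT_REGISTRY = ChannelRegistry()


@dataclass(frozen=True)
class DriftConditions:
    """PTR drift-tube operating point; E/N is always recomputed, never stored."""

    u_drift_v: float = 600.0
    p_drift_mbar: float = 2.5
    t_drift_c: float = 60.0
    l_drift_cm: float = 9.3  # instrument constant

    def __post_init__(self) -> None:
        for name in ("u_drift_v", "p_drift_mbar", "t_drift_c", "l_drift_cm"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.u_drift_v < 0:
            raise ValueError("u_drift_v must be >= 0")
        if self.p_drift_mbar <= 0 or self.l_drift_cm <= 0:
            raise ValueError("p_drift_mbar and l_drift_cm must be > 0")
        if self.t_drift_c <= -273.15:
            raise ValueError("t_drift_c must be above absolute zero")


def compute_reduced_field(dc: DriftConditions) -> float:
    """Reduced electric field E/N of the drift tube, in Townsend.

    E = U/L (V cm^-1); N = p/(k_B T) (cm^-3); 1 Td = 1e-17 V cm^2.
    """
    e_field = dc.u_drift_v / dc.l_drift_cm  # V/cm
    n_density = (dc.p_drift_mbar * 100.0) / (
        constants.k * (dc.t_drift_c + 273.15)
    ) * 1e-6  # cm^-3
    return e_field / n_density / 1e-17


def round_reduced_field(en_td: float) -> float:
    """E/N rounded to the nearest ten Td (the conventional reporting grain)."""
    return float(round(en_td / 10.0) * 10.0)


@dataclass
class FluxSeries:
    """Leaf-area-normalised emission rate of one compound (nmol m^-2 s^-1)."""

    compound: str
    group: str | None
    time_s: np.ndarray
    flux: np.ndarray
    blank_corrected: bool = False
    has_negative: bool = False
    source_id: str = ""
    blank_id: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.flux = np.asarray(self.flux, dtype=float)
        if self.time_s.shape != self.flux.shape:
            raise ValueError("time_s and flux must share a shape")
        self.has_negative = bool(np.any(self.flux < 0))


def flux_conversion_factor(geom: ChamberGeometry) -> float:
    """Emission per unit outlet enrichment: (nmol m^-2 s^-1) / (nmol mol^-1)."""
    return 1e-6 * geom.q_flow_umol_s / geom.a_leaf_m2


def mixing_ratio_to_flux(
    chi_out: np.ndarray,
    chi_in: float | np.ndarray,
    geom: ChamberGeometry,
    time_s: np.ndarray | None = None,
    dynamic: bool = False,
) -> np.ndarray:
    """Cuvette mass balance on raw arrays.

    ``dynamic=True`` adds the headspace storage term (n_chamber/A)·dchi/dt,
    which removes the washout lag when the chamber molar content is known.
    """
    chi_out = np.asarray(chi_out, dtype=float)
    chi_in_arr = np.asarray(chi_in, dtype=float)
    if chi_in_arr.ndim > 0 and chi_in_arr.shape != chi_out.shape:
        raise ValueError("chi_in series must share the chi_out time base")
    flux = flux_conversion_factor(geom) * (chi_out - chi_in_arr)
    if dynamic:
        if geom.n_chamber_umol <= 0:
            return flux
        if time_s is None:
            raise ValueError("dynamic flux needs the time base")
        time_s = np.asarray(time_s, dtype=float)
        if time_s.shape != chi_out.shape:
            raise ValueError("time base must share the chi_out shape")
        dchi_dt = np.gradient(chi_out, time_s)
        flux = flux + 1e-6 * geom.n_chamber_umol / geom.a_leaf_m2 * dchi_dt
    return flux


def flux_from_mixing_ratio(
    chi_out: np.ndarray,
    chi_in: float | np.ndarray,
    geom: ChamberGeometry,
    time_s: np.ndarray | None = None,
    compound: str = "",
    group: str | None = None,
    dynamic: bool = False,
    source_id: str = "",
) -> FluxSeries:
    """Convert an outlet mixing-ratio series into a :class:`FluxSeries`."""
    chi_out = np.asarray(chi_out, dtype=float)
    if time_s is None:
        time_s = np.arange(chi_out.size, dtype=float)
    flux = mixing_ratio_to_flux(chi_out, chi_in, geom, time_s=time_s,
                                dynamic=dynamic)
    return FluxSeries(compound=compound, group=group, time_s=time_s, flux=flux,
                      source_id=source_id)


def blank_correct(
    sample: np.ndarray,
    blank: np.ndarray | float,
    mode: str = "mean",
) -> tuple[np.ndarray, bool]:
    """Subtract an empty-chamber blank from a sample series.

    ``mode="mean"`` (default) subtracts the time-mean of the blank window —
    blanks and samples are not synchronous, so a point-wise subtraction is
    only meaningful for equal-length aligned series (``mode="pointwise"``).
    Negative corrected values are preserved; the returned flag reports them.
    """
    sample = np.asarray(sample, dtype=float)
    blank_arr = np.asarray(blank, dtype=float)
    if mode == "mean":
        corrected = sample - float(np.mean(blank_arr))
    elif mode == "pointwise":
        if blank_arr.shape != sample.shape:
            raise ValueError("pointwise blank correction needs matching shapes")
        corrected = sample - blank_arr
    else:
        raise ValueError(f"unknown blank correction mode {mode!r}")
    return corrected, bool(np.any(corrected < 0))


def blank_correct_flux(series: FluxSeries, blank: FluxSeries,
                       mode: str = "mean") -> FluxSeries:
    corrected, neg = blank_correct(series.flux, blank.flux, mode=mode)
    out = replace(series, flux=corrected, blank_corrected=True,
                  blank_id=blank.source_id or blank.compound)
    out.has_negative = neg
    return out


def map_channels(
    observed_mz: Sequence[float],
    registry: ChannelRegistry = DEFAULT_REGISTRY,
) -> pd.DataFrame:
    """Assign observed m/z values to registry compounds.

    Unmatched channels are labelled ``unassigned``; an observed m/z within
    tolerance of two registry entries raises (naming both candidates).
    """
    rows = []
    for mz in observed_mz:
        hit = registry.match(float(mz))
        rows.append({
            "observed_mz": float(mz),
            "compound": hit.compound if hit else "unassigned",
            "group": hit.group if hit else "unassigned",
            "registry_mz": hit.mz if hit else np.nan,
            "delta_mz": (float(mz) - hit.mz) if hit else np.nan,
        })
    return pd.DataFrame(rows)


def trace_fluxes(
    trace: LeafTrace,
    registry: ChannelRegistry = DEFAULT_REGISTRY,
    blank: LeafTrace | None = None,
    dynamic: bool = False,
) -> dict[str, FluxSeries]:
    """Per-compound fluxes for every assignable channel of a trace.

    With ``blank`` given, the time-mean of the blank trace's matching channel
    replaces the nominal inlet mixing ratio (empty-chamber correction under
    identical conditions); unassigned channels are kept under their m/z label
    with ``group=None`` so that totals are conserved.
    """
    time_s = trace.time_s
    out: dict[str, FluxSeries] = {}
    for col in trace.channel_columns:
        mz = column_mz(col)
        hit = registry.match(mz)
        compound = hit.compound if hit else col
        group = hit.group if hit else None
        chi_out = np.asarray(trace.data[col], dtype=float)
        if blank is not None:
            try:
                chi_ref = float(np.mean(blank.chi(mz)))
            except KeyError:
                raise ValueError(
                    f"blank {blank.trace_id!r} has no channel at m/z {mz} "
                    f"for trace {trace.trace_id!r}"
                ) from None
        else:
            chi_ref = trace.geometry.inlet(col)
        fs = flux_from_mixing_ratio(
            chi_out, chi_ref, trace.geometry, time_s=time_s,
            compound=compound, group=group, dynamic=dynamic,
            source_id=trace.trace_id,
        )
        if blank is not None:
            fs.blank_corrected = True
            fs.blank_id = blank.trace_id
        out[compound] = fs
    return out


def aggregate_groups(
    fluxes: Mapping[str, FluxSeries] | Iterable[FluxSeries],
    registry: ChannelRegistry = DEFAULT_REGISTRY,
) -> dict[str, FluxSeries]:
    """Sum compound fluxes into the six biosynthetic groups.

    Compounds absent from the registry are rejected; all members must share
    one time base. Group flux at each time point is the plain sum of member
    fluxes, so totals are conserved.
    """
    series = list(fluxes.values()) if isinstance(fluxes, Mapping) else list(fluxes)
    if not series:
        return {}
    base = series[0].time_s
    grouped: dict[str, list[FluxSeries]] = {}
    for fs in series:
        if fs.time_s.shape != base.shape or not np.allclose(fs.time_s, base):
            raise ValueError("all member series must share a time base")
        cdef = registry.by_compound(fs.compound)  # raises for unknown compound
        grouped.setdefault(cdef.group, []).append(fs)
    out: dict[str, FluxSeries] = {}
    for group, members in grouped.items():
        total = np.sum([m.flux for m in members], axis=0)
        out[group] = FluxSeries(
            compound=group, group=group, time_s=base.copy(), flux=total,
            blank_corrected=all(m.blank_corrected for m in members),
            source_id=members[0].source_id,
        )
    return out
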