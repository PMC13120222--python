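"""Forward simulator of leaf isoprene/VOC emission and chamber gas exchange.

The isoprene model is a single well-mixed precursor (DMADP) pool S driven by
MEP-pathway supply F under light and drained by isoprene synthase with a
first-order apparent rate constant k:

    dS/dt = F * L(t) - k * S,       I(t) = k * S(t) + E_floor

where L(t) ∈ {0, 1} is the light schedule.  Within any constant-light
segment the solution is the closed form

    S(t) = S_eq + (S_seg0 - S_eq) * exp(-k t),    S_eq = F L / k,

which the simulator evaluates exactly on the sampling grid.  Switching the
light off cuts MEP supply instantaneously and the emission decays as a pure
exponential towards the residual dark floor — the transient that the
downstream decay analysis integrates to recover the pool.

The five non-isoprene VOC groups (LOX/GLV products, reactive carbonyls,
methanol, short-chain organic acids, ethanol) are emitted at steady,
temperature- and CO2-dependent rates given by sigmoidal burst profiles,
emulating near-baseline emission at 25–30 °C and coordinated bursts at the
40 °C thermal limit.  Ethanol uses a sum of two sigmoids to reproduce its
biphasic (two-step) rise.

Chamber gas exchange follows the headspace mass balance

    n * dchi/dt = Q * (chi_in - chi) + I * A

with exact exponential stepping; n = 0 reduces to the static mass balance
chi = chi_in + I*A/Q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import ChamberGeometry, LeafTrace, channel_column
from .ptr_flux import (
    DEFAULT_REGISTRY,
    GROUPS,
    ChannelRegistry,
    flux_conversion_factor,
)

#: CO2 mole fraction above which a treatment counts as "elevated"
ELEVATED_CO2_THRESHOLD = 600.0


@dataclass(frozen=True)
class KineticParams:
    """Isoprene precursor-pool kinetics of one leaf.

    s0_nmol_m2         initial DMADP pool (nmol m^-2)
    f_supply_nmol_m2_s MEP supply flux under light (nmol m^-2 s^-1)
    k_isps_s           apparent IspS first-order rate constant (s^-1)
    e_dark_floor       residual dark emission (nmol m^-2 s^-1)
    """

    s0_nmol_m2: float
    f_supply_nmol_m2_s: float
    k_isps_s: float
    e_dark_floor: float = 0.0

    def __post_init__(self) -> None:
        for name in ("s0_nmol_m2", "f_supply_nmol_m2_s", "k_isps_s",
                     "e_dark_floor"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k_isps_s <= 0:
            raise ValueError("k_isps_s must be > 0")

    @property
    def s_light_steady(self) -> float:
        """Light steady-state pool S* = F/k (nmol m^-2)."""
        return self.f_supply_nmol_m2_s / self.k_isps_s


@dataclass(frozen=True)
class TreatmentCell:
    """One cell of the temperature × CO2 factorial design."""

    t_leaf_c: float
    co2_umol_mol: float
    ppfd_light: float = 1200.0
    replicate_id: int = 0


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise of the 1 Hz mixing-ratio channels.

    ``cv_mult`` is the coefficient of variation of multiplicative Gaussian
    noise (approximating ion-counting statistics at high signal);
    ``sd_add`` is an additive Gaussian floor in nmol mol^-1.
    """

    cv_mult: float = 0.03
    sd_add: float = 0.01

    def __post_init__(self) -> None:
        if self.cv_mult < 0 or self.sd_add < 0:
            raise ValueError("noise parameters must be >= 0")

    def apply(self, chi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cv_mult == 0 and self.sd_add == 0:
            return np.asarray(chi, dtype=float)
        chi = np.asarray(chi, dtype=float)
        out = chi * (1.0 + self.cv_mult * rng.standard_normal(chi.shape))
        return out + self.sd_add * rng.standard_normal(chi.shape)


@dataclass(frozen=True)
class SigmoidComponent:
    amplitude: float          # nmol m^-2 s^-1
    t_mid_c: float            # °C
    scale_c: float            # °C, > 0
    co2_amp_mult: float = 1.0  # amplitude multiplier under elevated CO2


@dataclass(frozen=True)
class BurstParams:
    """Temperature/CO2 response of one VOC group's steady emission."""

    baseline: float
    components: tuple[SigmoidComponent, ...]


# Defaults emulate the observed steady-state magnitudes: isoprene
# 1.5 -> 13.3, LOX ~2.4, carbonyls ~450, methanol 11 -> 36, acids ~15,
# ethanol ~50 nmol m^-2 s^-1 at the 40 °C / 800 ppm extreme.
DEFAULT_BURSTS: dict[str, BurstParams] = {
    "isoprene": BurstParams(1.5, (SigmoidComponent(9.1, 35.5, 1.8, 1.40),)),
    "lox": BurstParams(0.15, (SigmoidComponent(2.2, 38.5, 1.1, 1.27),)),
    "carbonyls": BurstParams(1.0, (SigmoidComponent(440.0, 39.5, 0.9, 1.60),)),
    "methanol": BurstParams(11.0, (SigmoidComponent(26.0, 37.5, 1.0, 1.00),)),
    "acids": BurstParams(0.5, (SigmoidComponent(13.5, 39.0, 1.0, 1.50),)),
    "ethanol": BurstParams(
        0.4,
        (
            SigmoidComponent(2.5, 29.0, 1.0, 0.20),   # moderate rise, CO2-suppressed
            SigmoidComponent(62.0, 40.0, 0.8, 1.60),  # fermentative surge
        ),
    ),
}


def stress_burst_profile(
    group: str,
    t_leaf_c: float,
    co2_umol_mol: float,
    params: BurstParams | None = None,
) -> float:
    """Steady emission rate (nmol m^-2 s^-1) of ``group`` at (T, CO2).

    Monotone non-decreasing in temperature: each component is a rising
    logistic, and amplitudes are non-negative.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    p = DEFAULT_BURSTS[group] if params is None else params
    elevated = co2_umol_mol >= ELEVATED_CO2_THRESHOLD
    value = p.baseline
    for comp in p.components:
        amp = comp.amplitude * (comp.co2_amp_mult if elevated else 1.0)
        value += amp * float(expit((t_leaf_c - comp.t_mid_c) / comp.scale_c))
    return value


def simulate_pool_dynamics(
    params: KineticParams,
    protocol: Sequence[tuple[float, float]],
    dt: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evolve the precursor pool over a piecewise-constant light schedule.

    ``protocol`` is a sequence of ``(duration_s, L)`` segments with
    L ∈ [0, 1] the fractional MEP supply (1 = light, 0 = dark).  Returns
    ``(times, S, I)`` sampled at ``dt``; within each segment the grid values
    equal the closed-form solution exactly.
    """
    if not (math.isfinite(dt) and dt > 0):
        raise ValueError("dt must be finite and > 0")
    if not protocol:
        raise ValueError("protocol must contain at least one segment")
    total = float(sum(d for d, _ in protocol))
    n = int(round(total / dt)) + 1
    times = np.arange(n, dtype=float) * dt
    s = np.empty(n, dtype=float)

    k = params.k_isps_s
    s_seg0 = params.s0_nmol_m2
    seg_start = 0.0
    bounds = []
    for duration, light in protocol:
        if duration < 0 or not (0.0 <= light <= 1.0):
            raise ValueError("protocol segments need duration >= 0 and L in [0, 1]")
        bounds.append((seg_start, seg_start + duration, light))
        seg_start += duration

    for t0, t1, light in bounds:
        s_eq = params.f_supply_nmol_m2_s * light / k
        sel = (times >= t0 - 1e-9) & (times <= t1 + 1e-9)
        tau = times[sel] - t0
        s[sel] = s_eq + (s_seg0 - s_eq) * np.exp(-k * tau)
        # exact pool at the segment boundary, whether or not on the grid
        s_seg0 = s_eq + (s_seg0 - s_eq) * math.exp(-k * (t1 - t0))

    i_emis = k * s + params.e_dark_floor
    return times, s, i_emis


def simulate_chamber(
    i_emis: np.ndarray,
    geom: ChamberGeometry,
    dt: float = 1.0,
    channel: str | None = None,
    chi0: float | None = None,
) -> np.ndarray:
    """Outlet mixing ratio (nmol mol^-1) for an emission series I(t).

    With ``n_chamber = 0`` the static mass balance chi = chi_in + I*A/Q
    applies sample-by-sample; otherwise the headspace integrates the source
    with time constant τ = n_chamber/Q (exact exponential stepping, emission
    held constant within each step).
    """
    i_emis = np.asarray(i_emis, dtype=float)
    chi_in = geom.inlet(channel)
    chi_ss = chi_in + i_emis / flux_conversion_factor(geom)
    tau = geom.residence_time_s
    if tau == 0:
        return chi_ss
    decay = math.exp(-dt / tau)
    chi = np.empty_like(chi_ss)
    chi[0] = chi_ss[0] if chi0 is None else float(chi0)
    for j in range(1, chi.size):
        chi[j] = chi_ss[j] + (chi[j - 1] - chi_ss[j]) * decay
    return chi


def default_kinetics(t_leaf_c: float, co2_umol_mol: float) -> KineticParams:
    """Treatment-level kinetic parameters.

    k_isps is log-linear in 1/T (Arrhenius form) spanning ≈0.015 s^-1 at
    25 °C to ≈0.075 s^-1 at 40 °C; the supply flux follows the isoprene
    burst profile so that the light steady state S* = F/k reproduces the
    treatment-level emission magnitudes.  The leaf starts at S0 = S*.
    """
    k25, k40 = 0.015, 0.075
    t25, t40 = 298.15, 313.15
    b = math.log(k40 / k25) / (1.0 / t25 - 1.0 / t40)
    k = k25 * math.exp(b * (1.0 / t25 - 1.0 / (t_leaf_c + 273.15)))
    f_supply = stress_burst_profile("isoprene", t_leaf_c, co2_umol_mol)
    return KineticParams(
        s0_nmol_m2=f_supply / k,
        f_supply_nmol_m2_s=f_supply,
        k_isps_s=k,
        e_dark_floor=0.02,
    )


def default_a_net(t_leaf_c: float, co2_umol_mol: float) -> float:
    """Net assimilation (µmol CO2 m^-2 s^-1): high at 25 °C (≈30% higher under
    elevated CO2), collapsing to <2 at the 40 °C extreme under ambient CO2."""
    top = 18.2 if co2_umol_mol >= ELEVATED_CO2_THRESHOLD else 14.0
    floor = 1.2
    return top - (top - floor) * float(expit((t_leaf_c - 36.5) / 1.2))


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated leaf, keyed by (treatment, replicate)."""

    trace_id: str
    cell: TreatmentCell
    kinetics: KineticParams
    a_net_true: float
    group_emission: dict[str, float] = field(default_factory=dict)
    warnings: tuple[str, ...] = ()


@dataclass
class ExperimentConfig:
    """Design and generation settings for one simulated experiment.

    Defaults reproduce the study design: 4 temperatures × 2 CO2 levels ×
    6 replicates = 48 leaves, each recorded at 1 Hz through a 300 s light
    hold and a dark tail of max(300 s, 6/k).
    """

    temps_c: tuple[float, ...] = (25.0, 30.0, 35.0, 40.0)
    co2_levels: tuple[float, ...] = (400.0, 800.0)
    replicates: int = 6
    ppfd_light: float = 1200.0
    light_duration_s: float = 300.0
    dark_duration_s: float | None = None  # None -> max(300, 6/k)
    dt_s: float = 1.0
    noise: NoiseModel = NoiseModel()
    geometry: ChamberGeometry = ChamberGeometry(chi_in=0.2)
    kinetics: Callable[[float, float], KineticParams] = default_kinetics
    a_net: Callable[[float, float], float] = default_a_net
    bursts: dict[str, BurstParams] | None = None  # None -> DEFAULT_BURSTS
    replicate_cv_supply: float = 0.15
    replicate_cv_k: float = 0.10
    supply_lag_s: float = 0.0  # optional exponential MEP supply lag at darkening


def _burst(config: ExperimentConfig, group: str, t: float, co2: float) -> float:
    params = None if config.bursts is None else config.bursts.get(group)
    return stress_burst_profile(group, t, co2, params=params)


def simulate_leaf(
    cell: TreatmentCell,
    config: ExperimentConfig,
    rng: np.random.Generator,
    trace_id: str | None = None,
    registry: ChannelRegistry = DEFAULT_REGISTRY,
) -> tuple[LeafTrace, SimTruth]:
    """Simulate one leaf recording plus its ground-truth record."""
    t, co2 = cell.t_leaf_c, cell.co2_umol_mol
    base = config.kinetics(t, co2)
    # biological replicate variability (lognormal, unit median)
    f_supply = base.f_supply_nmol_m2_s * float(
        rng.lognormal(0.0, config.replicate_cv_supply)
    )
    k = base.k_isps_s * float(rng.lognormal(0.0, config.replicate_cv_k))
    kp = KineticParams(
        s0_nmol_m2=f_supply / k,
        f_supply_nmol_m2_s=f_supply,
        k_isps_s=k,
        e_dark_floor=base.e_dark_floor,
    )
    dark = config.dark_duration_s
    if dark is None:
        dark = max(300.0, math.ceil(6.0 / k))
    warnings = []
    if dark < 5.0 / k:
        warnings.append("dark-tail-short")

    if config.supply_lag_s > 0:
        # approximate an exponential supply run-down with short sub-segments
        lag = config.supply_lag_s
        n_sub = max(3, int(round(3 * lag / config.dt_s)))
        sub = 3 * lag / n_sub
        protocol = [(config.light_duration_s, 1.0)]
        for j in range(n_sub):
            protocol.append((sub, math.exp(-(j + 0.5) * sub / lag)))
        protocol.append((dark - 3 * lag, 0.0))
    else:
        protocol = [(config.light_duration_s, 1.0), (dark, 0.0)]

    times, _, i_iso = simulate_pool_dynamics(kp, protocol, dt=config.dt_s)
    n = times.size

    group_truth = {"isoprene": f_supply + kp.e_dark_floor}
    emissions: dict[str, np.ndarray] = {}
    iso_channel = registry.members("isoprene")[0]
    emissions[channel_column(iso_channel.mz)] = i_iso
    for group in GROUPS:
        if group == "isoprene":
            continue
        members = registry.members(group)
        e_group = _burst(config, group, t, co2) * float(
            rng.lognormal(0.0, config.replicate_cv_supply)
        )
        group_truth[group] = e_group
        share = e_group / len(members)
        for m in members:
            emissions[channel_column(m.mz)] = np.full(n, share)

    data = {
        "time_s": times,
        "ppfd": np.where(times < config.light_duration_s, cell.ppfd_light, 0.0),
        "t_leaf_c": np.full(n, t),
        "co2_umol_mol": np.full(n, co2),
        "q_flow_umol_s": np.full(n, config.geometry.q_flow_umol_s),
    }
    a_true = config.a_net(t, co2)
    data["a_net"] = np.full(n, a_true + 0.3 * float(rng.standard_normal()))
    for col, i_emis in emissions.items():
        chi = simulate_chamber(i_emis, config.geometry, dt=config.dt_s,
                               channel=col)
        data[col] = config.noise.apply(chi, rng)

    tid = trace_id or (
        f"leaf_T{t:g}_C{co2:g}_r{cell.replicate_id}"
    )
    trace = LeafTrace(
        trace_id=tid,
        data=pd.DataFrame(data),
        geometry=config.geometry,
        meta={
            "t_leaf_c": t,
            "co2_umol_mol": co2,
            "replicate": cell.replicate_id,
            "ppfd_light": cell.ppfd_light,
            "warnings": list(warnings),
        },
    )
    truth = SimTruth(
        trace_id=tid,
        cell=cell,
        kinetics=kp,
        a_net_true=a_true,
        group_emission=group_truth,
        warnings=tuple(warnings),
    )
    return trace, truth


def simulate_blank(
    t_leaf_c: float,
    co2_umol_mol: float,
    config: ExperimentConfig,
    rng: np.random.Generator,
    duration_s: float = 120.0,
    registry: ChannelRegistry = DEFAULT_REGISTRY,
) -> LeafTrace:
    """Empty-chamber blank trace under one treatment cell's conditions."""
    n = int(round(duration_s / config.dt_s)) + 1
    times = np.arange(n, dtype=float) * config.dt_s
    data = {
        "time_s": times,
        "ppfd": np.zeros(n),
        "t_leaf_c": np.full(n, t_leaf_c),
        "co2_umol_mol": np.full(n, co2_umol_mol),
        "q_flow_umol_s": np.full(n, config.geometry.q_flow_umol_s),
        "a_net": np.zeros(n),
    }
    for cdef in registry:
        col = channel_column(cdef.mz)
        chi = np.full(n, config.geometry.inlet(col))
        data[col] = config.noise.apply(chi, rng)
    tid = f"blank_T{t_leaf_c:g}_C{co2_umol_mol:g}"
    return LeafTrace(
        trace_id=tid,
        data=pd.DataFrame(data),
        geometry=config.geometry,
        meta={"t_leaf_c": t_leaf_c, "co2_umol_mol": co2_umol_mol,
              "blank": True},
    )


def generate_experiment(
    config: ExperimentConfig | None = None,
    seed: int = 0,
    include_blanks: bool = True,
    registry: ChannelRegistry = DEFAULT_REGISTRY,
) -> tuple[list[LeafTrace], list[SimTruth], list[LeafTrace]]:
    """Generate the full factorial experiment.

    Returns ``(traces, truths, blanks)``; the default configuration yields
    4 × 2 × 6 = 48 leaf traces plus one blank per treatment cell.  Reruns
    with the same seed are bit-identical.
    """
    config = config or ExperimentConfig()
    cells = [
        TreatmentCell(t, c, config.ppfd_light, r)
        for t, c, r in product(config.temps_c, config.co2_levels,
                               range(config.replicates))
    ]
    cell_keys = list(product(config.temps_c, config.co2_levels))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cells) + len(cell_keys))
    traces, truths = [], []
    for cell, child in zip(cells, children):
        trace, truth = simulate_leaf(cell, config,
                                     np.random.default_rng(child),
                                     registry=registry)
        traces.append(trace)
        truths.append(truth)
    blanks = []
    if include_blanks:
        for (t, c), child in zip(cell_keys, children[len(cells):]):
            blanks.append(
                simulate_blank(t, c, config, np.random.default_rng(child),
                               registry=registry)
            )
    return traces, truths, blanks
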