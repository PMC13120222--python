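"""Post-illumination isoprene decay analysis.

When the actinic light is shut off, MEP-pathway supply of DMADP ceases and
isoprene emission decays as the pre-existing precursor pool is exhausted.
Two quantities are recovered in vivo from the 1 Hz emission trace:

* the total DMADP pool size S (nmol m^-2), as the area under the decay
  curve above the stable dark baseline, and
* the apparent isoprene synthase rate constant k (s^-1), from the initial
  decay rate.

For a first-order system E(t) = E_dark + (E_ss - E_dark) * exp(-k (t-t_off))
these obey the identity S * k = E_ss - E_dark, which the analysis reports as
a third, consistency estimator of k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import LeafTrace
from .ptr_flux import DEFAULT_REGISTRY, ChannelRegistry, trace_fluxes


class DecayStageError(RuntimeError):
    """Failure of one named stage of the decay analysis chain."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class DecayWindows:
    """Window lengths and the dark-baseline stability criterion.

    ss_window_s               steady-state averaging window before t_off
    initial_window_s          rate-fit window after t_off
    baseline_slope_frac       |slope| threshold, as a fraction of E_ss per s
    baseline_min_duration_s   minimum stable duration of the baseline window
    """

    ss_window_s: float = 60.0
    initial_window_s: float = 10.0
    baseline_slope_frac: float = 0.005
    baseline_min_duration_s: float = 30.0

    def __post_init__(self) -> None:
        for name in ("ss_window_s", "initial_window_s",
                     "baseline_min_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.baseline_slope_frac <= 0:
            raise ValueError("baseline_slope_frac must be > 0")


DEFAULT_WINDOWS = DecayWindows()


@dataclass
class DecayResult:
    """Outcome of one post-illumination decay analysis."""

    trace_id: str
    t_off_s: float
    e_ss: float                  # steady-state emission (nmol m^-2 s^-1)
    e_dark: float                # dark baseline (nmol m^-2 s^-1)
    s_pool_nmol_m2: float        # DMADP pool
    k_loglin_s: float            # primary rate-constant estimate (s^-1)
    k_slope_s: float             # initial-slope estimate (s^-1)
    k_ratio_s: float             # (E_ss - E_dark)/S_pool consistency estimate
    r2_loglin: float
    baseline_start_s: float
    flags: tuple[str, ...] = ()

    @property
    def v_app_nmol_m2_s(self) -> float:
        """Apparent IspS velocity (nmol m^-2 s^-1): the initial decay
        amplitude E_ss - E_dark, reported alongside the rate constant."""
        return self.e_ss - self.e_dark


def detect_transition(trace: LeafTrace, ppfd_frac: float = 0.01) -> float:
    """Time of the light-to-dark transition.

    Primary rule: first sample where PPFD falls below ``ppfd_frac`` of its
    light-phase median.  Fallback (no usable PPFD column): the largest
    single-step drop of the lightly smoothed isoprene channel.
    """
    time_s = trace.time_s
    if trace.has_ppfd:
        ppfd = np.asarray(trace.data["ppfd"], dtype=float)
        peak = np.nanmax(ppfd)
        if peak > 0:
            light_median = float(np.median(ppfd[ppfd > 0.5 * peak]))
            below = np.nonzero(ppfd < ppfd_frac * light_median)[0]
            if below.size == 0:
                raise DecayStageError("detect_transition",
                                      "no dark transition in trace")
            return float(time_s[below[0]])
        raise DecayStageError("detect_transition", "no dark transition in trace")
    # change-point fallback on the isoprene channel
    try:
        iso = trace.chi(DEFAULT_REGISTRY.by_compound("isoprene").mz)
    except KeyError:
        raise DecayStageError("detect_transition",
                              "no PPFD column and no isoprene channel") from None
    return float(_refine_changepoint(time_s, iso))


def _refine_changepoint(time_s: np.ndarray, signal: np.ndarray) -> float:
    """Plateau→exponential change point: coarse matched-filter candidate,
    refined by least-squares template matching over nearby offsets."""
    n = signal.size
    w = 5
    if n < 4 * w:
        raise DecayStageError("detect_transition", "trace too short")
    # coarse: largest drop between adjacent w-sample means
    means = np.convolve(signal, np.ones(w) / w, mode="valid")
    drops = means[w:] - means[:-w]  # right-mean minus left-mean at offset j+w
    j = int(np.argmin(drops))
    c0 = j + w  # candidate index of the first post-transition sample
    noise = 1.4826 * float(np.median(np.abs(np.diff(signal)
                                            - np.median(np.diff(signal)))))
    if -drops[j] < 4 * noise or drops[j] >= 0:
        raise DecayStageError("detect_transition", "no dark transition in trace")

    lo = max(w, c0 - 40)
    plateau = float(np.mean(signal[lo:max(lo + 2, c0 - 2)]))
    floor = float(np.mean(signal[-min(30, n // 4):]))
    # provisional rate constant from the mid-decay log slope
    seg = slice(min(c0 + 2, n - 4), min(c0 + 40, n))
    excess = signal[seg] - floor
    pos = excess > 0
    if np.count_nonzero(pos) >= 3:
        k_hat = -_ls_slope(time_s[seg][pos], np.log(excess[pos]))
        k_hat = min(max(k_hat, 1e-4), 2.0)
    else:
        k_hat = 0.05
    # refine: SSE of the plateau→exponential template over candidate offsets
    best_c, best_sse = c0, math.inf
    fit_lo, fit_hi = max(0, c0 - 3 * w), min(n, c0 + 6 * w)
    t_fit = time_s[fit_lo:fit_hi]
    y_fit = signal[fit_lo:fit_hi]
    for c in range(max(1, c0 - 2 * w), min(n - 1, c0 + 2 * w)):
        tc = time_s[c]
        pred = np.where(
            t_fit < tc, plateau,
            floor + (plateau - floor) * np.exp(-k_hat * (t_fit - tc)),
        )
        sse = float(np.sum((y_fit - pred) ** 2))
        if sse < best_sse:
            best_c, best_sse = c, sse
    return float(time_s[best_c])


def _ls_slope(t: np.ndarray, y: np.ndarray) -> float:
    tc = t - t.mean()
    return float(tc @ (y - y.mean()) / (tc @ tc))


def estimate_steady_state(
    time_s: np.ndarray,
    flux: np.ndarray,
    t_off: float,
    windows: DecayWindows = DEFAULT_WINDOWS,
    drift_tol: float = 0.05,
) -> tuple[float, tuple[str, ...]]:
    """Mean emission over the window just before t_off, plus a drift check.

    A fitted trend exceeding ``drift_tol`` of the mean over the window sets
    the ``steady-state-drift`` flag (not a rejection).
    """
    sel = (time_s >= t_off - windows.ss_window_s) & (time_s < t_off)
    if np.count_nonzero(sel) < 2:
        raise DecayStageError("estimate_steady_state",
                              "ss_window does not fit before t_off")
    t, y = time_s[sel], flux[sel]
    e_ss = float(y.mean())
    flags: tuple[str, ...] = ()
    drift = _ls_slope(t, y) * windows.ss_window_s
    if e_ss != 0 and abs(drift / e_ss) > drift_tol:
        flags = ("steady-state-drift",)
    return e_ss, flags


def estimate_dark_baseline(
    time_s: np.ndarray,
    flux: np.ndarray,
    t_off: float,
    e_ss: float,
    windows: DecayWindows = DEFAULT_WINDOWS,
) -> tuple[float, float, tuple[str, ...]]:
    """Dark baseline E_dark and the time the baseline is first reached.

    E_dark is the mean of the final window of the dark tail (the stable end
    state the protocol runs until).  ``baseline_start`` is the start of the
    earliest window that (a) has |fitted slope| below the criterion and
    (b) has a mean consistent with that floor — within
    max(slope_frac * (E_ss - E_dark), 3 * SEM of the final window).
    If the final window itself is still sloped, or no earlier window
    qualifies, the ``baseline-not-reached`` flag is set.
    """
    dt = float(np.median(np.diff(time_s)))
    sel = time_s >= t_off
    tt, ff = time_s[sel], flux[sel]
    w = max(2, int(round(windows.baseline_min_duration_s / dt)))
    if tt.size < w:
        e_dark = float(ff.mean()) if ff.size else 0.0
        return e_dark, float(tt[0]) if tt.size else t_off, ("baseline-not-reached",)

    f_fin = ff[-w:]
    e_dark = float(f_fin.mean())
    slope_tol = windows.baseline_slope_frac * abs(e_ss)
    flags: list[str] = []
    fin_slope = _ls_slope(tt[-w:], f_fin)
    if abs(fin_slope) > slope_tol:
        flags.append("baseline-not-reached")
        return e_dark, float(tt[-w]), tuple(flags)

    # rolling slope and mean over all windows of width w
    x = np.arange(w) * dt
    xc = x - x.mean()
    sxx = float(xc @ xc)
    slopes = np.convolve(ff, xc[::-1] / sxx, mode="valid")
    means = np.convolve(ff, np.ones(w) / w, mode="valid")
    sem = float(np.std(f_fin, ddof=1)) / math.sqrt(w) if w > 1 else 0.0
    band = max(windows.baseline_slope_frac * abs(e_ss - e_dark), 3.0 * sem)
    ok = (np.abs(slopes) <= slope_tol) & (np.abs(means - e_dark) <= band)
    idx = np.nonzero(ok)[0]
    if idx.size == 0:
        flags.append("baseline-not-reached")
        return e_dark, float(tt[-w]), tuple(flags)
    return e_dark, float(tt[idx[0]]), tuple(flags)


def integrate_pool(
    time_s: np.ndarray,
    flux: np.ndarray,
    t_off: float,
    e_dark: float,
) -> float:
    """DMADP pool (nmol m^-2): trapezoidal integral of (E - E_dark) over the
    dark tail on the native sampling grid, with no clipping of negative
    excursions (they cancel noise in expectation)."""
    sel = time_s >= t_off
    if np.count_nonzero(sel) < 2:
        raise DecayStageError("integrate_pool", "no dark tail to integrate")
    s_pool = float(np.trapezoid(flux[sel] - e_dark, time_s[sel]))
    if s_pool < 0:
        raise DecayStageError(
            "integrate_pool",
            f"negative integral ({s_pool:.3g}); dark baseline overestimated",
        )
    return s_pool


def fit_rate_constant(
    time_s: np.ndarray,
    flux: np.ndarray,
    t_off: float,
    e_dark: float,
    windows: DecayWindows = DEFAULT_WINDOWS,
) -> tuple[float, float, float]:
    """Apparent rate constant from the initial decay window.

    Returns ``(k_slope, k_loglin, r2_loglin)``:

    * ``k_slope``: least-squares line through E(t) over the initial window;
      k = -slope / mean(E - E_dark) over the same window.  For first-order
      kinetics dE/dt = -k (E - E_dark) at every instant, so normalising by
      the window-mean excess makes the line estimator exact up to curvature.
    * ``k_loglin``: -slope of ln(E - E_dark) vs t (primary estimate; robust
      to the exact transition sample).
    """
    sel = (time_s >= t_off) & (time_s < t_off + windows.initial_window_s)
    t, y = time_s[sel], flux[sel]
    excess = y - e_dark
    pos = excess > 0
    if np.count_nonzero(pos) < 3:
        raise DecayStageError("fit_rate_constant", "no decay signal above the "
                              "dark baseline in the initial window")
    mean_excess = float(excess.mean())
    if mean_excess <= 0:
        raise DecayStageError("fit_rate_constant", "no decay signal")
    k_slope = -_ls_slope(t, y) / mean_excess

    tl, yl = t[pos], np.log(excess[pos])
    slope = _ls_slope(tl, yl)
    k_loglin = -slope
    pred = yl.mean() + slope * (tl - tl.mean())
    ss_res = float(np.sum((yl - pred) ** 2))
    ss_tot = float(np.sum((yl - yl.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return k_slope, k_loglin, r2


def analyze_decay(
    trace: LeafTrace,
    windows: DecayWindows = DEFAULT_WINDOWS,
    registry: ChannelRegistry = DEFAULT_REGISTRY,
    blank: LeafTrace | None = None,
    dynamic: bool = False,
) -> DecayResult:
    """Full decay analysis of one trace's isoprene channel.

    Stages: transition detection → steady state → dark baseline → pool
    integration → rate-constant fits.  Any stage failure surfaces as a
    :class:`DecayStageError` carrying the stage name; soft problems travel
    as flags on the result.
    """
    fluxes = trace_fluxes(trace, registry=registry, blank=blank,
                          dynamic=dynamic)
    if "isoprene" not in fluxes:
        raise DecayStageError("analyze_decay", "trace has no isoprene channel")
    fs = fluxes["isoprene"]
    time_s, flux = fs.time_s, fs.flux

    t_off = detect_transition(trace)
    e_ss, ss_flags = estimate_steady_state(time_s, flux, t_off, windows)
    e_dark, baseline_start, base_flags = estimate_dark_baseline(
        time_s, flux, t_off, e_ss, windows
    )
    if e_ss < e_dark:
        raise DecayStageError("analyze_decay",
                              "steady-state emission below dark baseline")
    flags = list(ss_flags) + list(base_flags)
    if "baseline-not-reached" in flags:
        flags.append("truncated-integral")
    s_pool = integrate_pool(time_s, flux, t_off, e_dark)
    k_slope, k_loglin, r2 = fit_rate_constant(time_s, flux, t_off, e_dark,
                                              windows)
    k_ratio = (e_ss - e_dark) / s_pool if s_pool > 0 else float("nan")
    return DecayResult(
        trace_id=trace.trace_id,
        t_off_s=t_off,
        e_ss=e_ss,
        e_dark=e_dark,
        s_pool_nmol_m2=s_pool,
        k_loglin_s=k_loglin,
        k_slope_s=k_slope,
        k_ratio_s=k_ratio,
        r2_loglin=r2,
        baseline_start_s=baseline_start,
        flags=tuple(flags),
    )
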