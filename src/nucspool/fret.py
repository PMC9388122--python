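"""FRET-efficiency computation, fiduciary alignment, and step detection.

FRET efficiency is the proximity ratio E = A / (A + D) after background
subtraction, with low-signal bins masked (NaN).  Ensembles are aligned by a
pure time shift on a fiduciary event -- the high-force rip for cooperative
transitions, the midpoint of a sigmoid fit for noncooperative ones (the
latter realises the gradual-transition alignment; its limiting case on step
traces coincides with rip alignment within one bin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .data import FluorescenceTrace, ForceExtensionTrace
from .traces import wlc_divergence_point
from .wlc import WLCParams

__all__ = [
    "compute_fret",
    "AlignedEnsemble",
    "align_on_rip",
    "align_noncooperative",
    "fret_extension_offset",
    "detect_fluorescence_steps",
    "ejection_delay",
    "EjectionEvent",
    "hinge_onset",
]

DEFAULT_COUNT_FLOOR = 10.0   # photons/bin below which E is masked


def compute_fret(donor, acceptor, background_d: float = 0.0,
                 background_a: float = 0.0,
                 count_floor: float = DEFAULT_COUNT_FLOOR,
                 gamma: float = 1.0) -> np.ndarray:
    """Proximity-ratio FRET efficiency per bin, NaN where signal is too low.

    ``gamma`` optionally corrects for detection-efficiency imbalance
    (E = A / (A + gamma * D)); the default 1.0 is the uncorrected ratio.
    """
    d = np.asarray(donor, dtype=float) - background_d
    a = np.asarray(acceptor, dtype=float) - background_a
    if len(d) != len(a):
        raise ValueError("channels must have equal length")
    d = np.clip(d, 0.0, None)
    a = np.clip(a, 0.0, None)
    total = a + gamma * d
    e = np.full(len(d), np.nan)
    ok = total >= count_floor
    e[ok] = a[ok] / total[ok]
    return np.clip(e, 0.0, 1.0)


def fret_trace(trace: FluorescenceTrace, background_d: float = 0.0,
               background_a: float = 0.0,
               count_floor: float = DEFAULT_COUNT_FLOOR) -> FluorescenceTrace:
    """Return the trace with its ``fret_e`` channel filled in."""
    trace.fret_e = compute_fret(trace.donor_counts, trace.acceptor_counts,
                                background_d, background_a, count_floor)
    return trace


@dataclass
class AlignedEnsemble:
    """FRET traces on a common relative-time axis (t = 0 at the fiduciary)."""

    rel_time: np.ndarray                  # bin centres, s
    matrix: np.ndarray                    # (n_traces, n_bins), NaN outside data
    fiduciary_times: list = field(default_factory=list)
    fiduciary_kind: str = "rip"
    excluded: list = field(default_factory=list)   # indices of dropped traces
    histogram: tuple | None = None        # (H, t_edges, e_edges)

    @property
    def mean_trace(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.matrix, axis=0)

    def build_histogram(self, e_bins: int = 25) -> tuple:
        """2D histogram (relative time x E) of unnormalised counts."""
        n_t = len(self.rel_time)
        dt = self.rel_time[1] - self.rel_time[0]
        t_edges = np.concatenate([self.rel_time - dt / 2,
                                  [self.rel_time[-1] + dt / 2]])
        e_edges = np.linspace(0.0, 1.0, e_bins + 1)
        tt = np.tile(self.rel_time, self.matrix.shape[0])
        ee = self.matrix.ravel()
        ok = ~np.isnan(ee)
        h, _, _ = np.histogram2d(tt[ok], ee[ok], bins=[t_edges, e_edges])
        self.histogram = (h, t_edges, e_edges)
        return self.histogram


def _shift_align(traces, e_list, t0_list, excluded, kind) -> AlignedEnsemble:
    dt = traces[0].dt
    rel_starts = [tr.time[0] - t0 for tr, t0 in zip(traces, t0_list)]
    rel_ends = [tr.time[-1] - t0 for tr, t0 in zip(traces, t0_list)]
    lo, hi = min(rel_starts), max(rel_ends)
    n_bins = int(round((hi - lo) / dt)) + 1
    rel_time = lo + np.arange(n_bins) * dt
    mat = np.full((len(traces), n_bins), np.nan)
    for i, (tr, e, t0) in enumerate(zip(traces, e_list, t0_list)):
        k0 = int(round((tr.time[0] - t0 - lo) / dt))
        mat[i, k0:k0 + len(e)] = e
    ens = AlignedEnsemble(rel_time, mat, list(t0_list), kind, excluded)
    ens.build_histogram()
    return ens


def align_on_rip(traces: list[FluorescenceTrace], rip_times: list,
                 count_floor: float = DEFAULT_COUNT_FLOOR) -> AlignedEnsemble:
    """Shift traces so the high-force rip maps to t = 0.

    Traces without a rip time (None) are excluded and logged in
    ``excluded``.  The shift is the only operation: within-trace timing is
    preserved exactly.
    """
    kept, e_list, t0s, excluded = [], [], [], []
    for i, (tr, t0) in enumerate(zip(traces, rip_times)):
        if t0 is None:
            excluded.append(i)
            continue
        e = compute_fret(tr.donor_counts, tr.acceptor_counts,
                         count_floor=count_floor)
        kept.append(tr)
        e_list.append(e)
        t0s.append(float(t0))
    if not kept:
        raise ValueError("no traces with a rip fiduciary")
    return _shift_align(kept, e_list, t0s, excluded, "rip")


def _sigmoid(t, e0, amp, t0, w):
    z = np.clip(-(t - t0) / w, -500.0, 500.0)
    return e0 - amp / (1.0 + np.exp(z))


def sigmoid_midpoint(time, e) -> tuple[float, float]:
    """Midpoint and width of a decreasing-sigmoid fit to a FRET trace."""
    ok = ~np.isnan(e)
    t, y = time[ok], e[ok]
    if len(y) < 10:
        raise RuntimeError("too few valid bins for a sigmoid fit")
    amp0 = max(y.max() - y.min(), 0.05)
    t0_guess = float(t[np.argmin(np.abs(y - (y.max() - amp0 / 2)))])
    p0 = [float(y.max()), amp0, t0_guess, max((t[-1] - t[0]) / 50, 1e-3)]
    with warnings.catch_warnings():
        # flat traces make the fit degenerate; they are rejected just below
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(_sigmoid, t, y, p0=p0, maxfev=5000)
    e0, amp, t0, w = popt
    if amp < 0.1 or not (t[0] - 1.0 <= t0 <= t[-1] + 1.0):
        raise RuntimeError("no credible FRET decrease found")
    return float(t0), float(abs(w))


def align_noncooperative(traces: list[FluorescenceTrace],
                         count_floor: float = DEFAULT_COUNT_FLOOR
                         ) -> AlignedEnsemble:
    """Align gradual FRET decreases on their sigmoid-fit midpoints.

    Traces whose fit fails (no credible decrease) are excluded and logged.
    """
    kept, e_list, t0s, excluded = [], [], [], []
    for i, tr in enumerate(traces):
        e = compute_fret(tr.donor_counts, tr.acceptor_counts,
                         count_floor=count_floor)
        try:
            t0, _w = sigmoid_midpoint(tr.time, e)
        except RuntimeError:
            excluded.append(i)
            continue
        kept.append(tr)
        e_list.append(e)
        t0s.append(t0)
    if not kept:
        raise ValueError("no traces with a fittable FRET decrease")
    return _shift_align(kept, e_list, t0s, excluded, "sigmoid-midpoint")


def hinge_onset(time: np.ndarray, y: np.ndarray, decreasing: bool = True,
                min_tail: int = 4) -> float | None:
    """Departure point of a flat-then-ramp signal by least-squares hinge fit.

    Scans candidate breakpoints; for each, models y as constant before and
    linear after, and returns the breakpoint time minimising the residual
    sum of squares.  Returns None when no ramp improves on a flat fit.
    """
    ok = ~np.isnan(y)
    t, v = time[ok], y[ok]
    n = len(v)
    if n < min_tail + 5:
        return None
    best, best_cost = None, np.inf
    flat_cost = float(np.sum((v - v.mean()) ** 2))
    for k in range(3, n - min_tail):
        pre = v[:k]
        post = v[k:]
        tp = t[k:] - t[k]
        denom = np.dot(tp, tp)
        slope = np.dot(tp, post - pre.mean()) / denom if denom > 0 else 0.0
        if decreasing and slope >= 0:
            continue
        resid_post = post - pre.mean() - slope * tp
        cost = float(np.sum((pre - pre.mean()) ** 2) + np.sum(resid_post ** 2))
        if cost < best_cost:
            best_cost, best = cost, float(t[k])
    if best is None or best_cost > 0.95 * flat_cost:
        return None
    return best


def fret_extension_offset(pull_trace: ForceExtensionTrace,
                          fluor: FluorescenceTrace,
                          params: WLCParams = WLCParams(),
                          fit_range: tuple = (1.0, 3.0)):
    """Temporal separation of extension divergence and FRET onset.

    Returns ``(extension_divergence, fret_onset, separation)`` where
    ``separation = fret_onset - extension_divergence_time`` (positive when
    the tweezers channel moves first); any undetectable onset yields None
    in its slot and a None separation.
    """
    div = wlc_divergence_point(pull_trace, fit_range=fit_range, params=params)
    e = compute_fret(fluor.donor_counts, fluor.acceptor_counts)
    # restrict the hinge fit to the region up to the transition midpoint:
    # the flat low-E tail after the drop would otherwise dominate the fit
    onset = None
    try:
        t0, w = sigmoid_midpoint(fluor.time, e)
    except RuntimeError:
        t0 = None
    if t0 is not None:
        sel = fluor.time <= t0 + w
        onset = hinge_onset(fluor.time[sel], e[sel], decreasing=True)
        if onset is None:
            onset = t0 - 2.0 * w     # fallback: sigmoid departure point
    if div is None or onset is None:
        return div, onset, None
    _f_div, t_div = div
    return div, onset, float(onset - t_div)


# ---------------------------------------------------------------------------
# fluorescence step detection (photobleaching, dimer ejection)
# ---------------------------------------------------------------------------

@dataclass
class EjectionEvent:
    t_drop: float
    delay_after_rip: float
    n_steps_before: int
    anomalous: bool = False


def _binseg(x: np.ndarray, min_size: int, sensitivity: float,
            offset: int = 0) -> list[int]:
    """Binary segmentation changepoints of a piecewise-constant mean.

    The split penalty is ``sensitivity`` times the segment's *local* noise
    variance (from first differences): shot noise scales with the level, so
    a global estimate would over-segment bright segments or, worse, let a
    long dim tail drag the penalty down.
    """
    n = len(x)
    if n < 2 * min_size:
        return []
    penalty = sensitivity * max(0.5 * float(np.mean(np.diff(x) ** 2)), 1e-6)
    csum = np.cumsum(np.insert(x, 0, 0.0))
    csq = np.cumsum(np.insert(x ** 2, 0, 0.0))

    def sse(i, j):  # [i, j)
        s, s2, m = csum[j] - csum[i], csq[j] - csq[i], j - i
        return s2 - s * s / m

    total = sse(0, n)
    best_k, best_gain = None, 0.0
    for k in range(min_size, n - min_size + 1):
        gain = total - sse(0, k) - sse(k, n)
        if gain > best_gain:
            best_gain, best_k = gain, k
    if best_k is None or best_gain < penalty:
        return []
    left = _binseg(x[:best_k], min_size, sensitivity, offset)
    right = _binseg(x[best_k:], min_size, sensitivity, offset + best_k)
    return sorted(left + [offset + best_k] + right)


def detect_fluorescence_steps(counts: np.ndarray, dt: float = 0.01,
                              min_size: int = 3,
                              sensitivity: float = 50.0) -> list[dict]:
    """Steps in a single fluorescence channel via binary segmentation.

    Returns a list of ``{"time", "level_before", "level_after"}``.  The
    split penalty scales with the shot-noise variance estimated from
    first differences; ``sensitivity`` multiplies it.
    """
    x = np.asarray(counts, dtype=float)
    if len(x) < 2 * min_size:
        return []
    cps = _binseg(x, min_size, sensitivity)
    steps = []
    bounds = [0] + cps + [len(x)]
    for i, k in enumerate(cps):
        lvl_before = float(np.mean(x[bounds[i]:k]))
        lvl_after = float(np.mean(x[k:bounds[i + 2]]))
        steps.append({"time": k * dt, "level_before": lvl_before,
                      "level_after": lvl_after})
    return steps


def ejection_delay(trace: FluorescenceTrace, rip_time: float,
                   sensitivity: float = 50.0) -> EjectionEvent | None:
    """Dimer-ejection event: the terminal fluorescence drop after the rip.

    The drop is the largest downward step; earlier downward steps are
    counted as photobleaching.  Returns None when no drop is found.
    """
    steps = detect_fluorescence_steps(trace.donor_counts, trace.dt,
                                      sensitivity=sensitivity)
    down = [s for s in steps if s["level_after"] < s["level_before"]]
    if not down:
        return None
    drop = min(down, key=lambda s: s["level_after"] - s["level_before"])
    # time axis of the trace, not bin index * dt
    t_drop = float(trace.time[0]) + drop["time"]
    n_before = sum(1 for s in down if s["time"] + trace.time[0] < t_drop)
    delay = t_drop - rip_time
    return EjectionEvent(t_drop, delay, n_steps_before=n_before - 0,
                         anomalous=delay < 0)
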