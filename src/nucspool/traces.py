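"""Detection and quantification of transitions in force-extension traces.

The working coordinate is the *apparent free contour*  L(t) = x(t) / u(F(t)),
with u the WLC relative extension: a pure tether is a flat line in L, a
cooperative rip is a step, a noncooperative transition is a ramp, and spool
rotation appears as slowly varying baseline.  Rips are found as steps in L
by a rolling-median jump statistic; their size is then re-measured in
extension units as the horizontal distance between one-parameter WLC fits to
the flanking segments, evaluated at the rip force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PULLING, RELAXATION, ForceExtensionTrace, SpeciesCall, TransitionEvent
from .wlc import WLCParams, relative_extension_fast

__all__ = [
    "detect_rips",
    "detect_zips",
    "classify_low_force",
    "quantify_low_force",
    "measure_offset_vs_reference",
    "wlc_divergence_point",
    "classify_species",
    "LowForceResult",
]

#: force band of the high-force rip search
HIGH_FORCE_BAND = (8.0, 40.0)
#: force band of the low-force transition
LOW_FORCE_BAND = (2.6, 6.0)
#: baseline WLC fit range, below any transition
BASELINE_RANGE = (0.8, 2.4)
#: post-transition fit range, above the low-force band
POST_LF_RANGE = (6.2, 7.8)


def _u(trace: ForceExtensionTrace, params: WLCParams, force=None,
       smooth: int = 0):
    f = trace.force if force is None else np.asarray(force, dtype=float)
    if smooth > 1:
        # the force ramp is slow and smooth; filtering the force channel
        # before converting to u keeps force noise from leaking several nm
        # into the apparent-contour coordinate at low force
        f = _rolling_median(f, smooth)
    return relative_extension_fast(np.clip(f, 0.05, None), params)


def apparent_contour(trace: ForceExtensionTrace,
                     params: WLCParams = WLCParams()) -> np.ndarray:
    """Extension divided by the WLC relative extension at each sample."""
    return trace.extension / _u(trace, params)


def _fit_contour(trace: ForceExtensionTrace, params: WLCParams,
                 mask: np.ndarray) -> float:
    """Least-squares effective free contour over masked samples (x = u * L)."""
    if mask.sum() < 5:
        raise ValueError("fewer than 5 samples in fit range")
    u = _u(trace, params)[mask]
    x = trace.extension[mask]
    return float(np.dot(u, x) / np.dot(u, u))


def _fit_contour_range(trace, params, f_lo, f_hi):
    return _fit_contour(trace, params, (trace.force >= f_lo) & (trace.force <= f_hi))


def _rolling_median(x: np.ndarray, w: int) -> np.ndarray:
    return pd.Series(x).rolling(w, min_periods=1, center=True).median().to_numpy()


def _step_candidates(l_app: np.ndarray, u: np.ndarray, window: int,
                     min_step_nm: float):
    """Indices where the rolling-median jump of L (in extension units) peaks."""
    n = len(l_app)
    med = _rolling_median(l_app, window)
    jump = np.zeros(n)
    jump[window:-window] = med[2 * window:] - med[:-2 * window] \
        if window * 2 < n else 0.0
    # convert apparent-contour jump to extension units at the local force
    step_ext = jump * u
    candidates = []
    mag = np.abs(step_ext)
    above = mag >= min_step_nm
    i = window
    while i < n - window:
        if above[i]:
            j = i
            while j < n - window and above[j]:
                j += 1
            seg = slice(i, j)
            k = i + int(np.argmax(mag[seg]))
            # refine to the largest single-sample increment nearby
            lo = max(k - window, 1)
            hi = min(k + window, n - 1)
            local = np.abs(np.diff(l_app[lo:hi + 1]))
            k_ref = lo + int(np.argmax(local))
            candidates.append((k_ref, float(step_ext[k])))
            i = j + window
        else:
            i += 1
    return candidates


def _measure_step(trace: ForceExtensionTrace, params: WLCParams, k: int,
                  window: int = 150, gap: int = 10):
    """Delta-x between flanking WLC fits, evaluated at the step force.

    Returns (nan, force) when a flank has too few samples to fit.
    """
    n = len(trace)
    f_rip = float(trace.force[k])
    pre = np.zeros(n, dtype=bool)
    post = np.zeros(n, dtype=bool)
    pre[max(0, k - gap - window):max(0, k - gap)] = True
    post[min(n, k + gap):min(n, k + gap + window)] = True
    if pre.sum() < 5 or post.sum() < 5:
        return float("nan"), f_rip
    l_pre = _fit_contour(trace, params, pre)
    l_post = _fit_contour(trace, params, post)
    u_rip = float(relative_extension_fast(max(f_rip, 0.05), params))
    return (l_post - l_pre) * u_rip, f_rip


def _local_sharpness(l_app: np.ndarray, u: np.ndarray, k: int) -> float:
    """Extension jump across a few samples around k.

    A cooperative rip is instantaneous at the sampling rate, so the medians
    immediately before/after the candidate differ by the full step; a
    noncooperative ramp moves only a fraction of a nanometre per sample and
    scores near zero.  The smaller-magnitude of a narrow (3-sample) and a
    wide (8-sample) median jump is used: the narrow one rejects ramps, the
    wide one rejects single-sample noise spikes.
    """
    jumps = []
    for half in (3, 8):
        lo = max(0, k - half)
        hi = min(len(l_app), k + 1 + half)
        if k - lo < 2 or hi - (k + 1) < 2:
            return 0.0
        jumps.append(float((np.median(l_app[k + 1:hi])
                            - np.median(l_app[lo:k])) * u[k]))
    return min(jumps, key=abs)


def detect_rips(trace: ForceExtensionTrace, min_step_nm: float = 5.0,
                window: int = 25, force_band: tuple = HIGH_FORCE_BAND,
                params: WLCParams = WLCParams()) -> list[TransitionEvent]:
    """Cooperative unwrapping rips on a pulling trace, ordered by time.

    Each event's delta-x is measured between WLC fits to the flanking
    segments evaluated at the rip force; events smaller than ``min_step_nm``
    or outside ``force_band`` are dropped.
    """
    if len(trace) < 2 * window + 2:
        raise ValueError("trace shorter than detection window")
    u = _u(trace, params, smooth=51)
    l_app = trace.extension / u
    events = []
    for k, _rough in _step_candidates(l_app, u, window, min_step_nm):
        if _local_sharpness(l_app, u, k) < 0.7 * min_step_nm:
            continue                  # gradual ramp, not a cooperative step
        dx, f_rip = _measure_step(trace, params, k)
        if not np.isfinite(dx) or dx < min_step_nm:   # rips increase extension
            continue
        if force_band is not None and not (force_band[0] <= f_rip <= force_band[1]):
            continue
        events.append(TransitionEvent("cooperative", "unwrap", f_rip, dx,
                                      float(trace.time[k])))
    return sorted(events, key=lambda e: e.t_event)


def detect_zips(trace: ForceExtensionTrace, min_step_nm: float = 5.0,
                window: int = 25, force_band: tuple = (0.5, 15.0),
                params: WLCParams = WLCParams()) -> list[TransitionEvent]:
    """Cooperative rewrapping zips on a relaxation trace (extension drops)."""
    if len(trace) < 2 * window + 2:
        raise ValueError("trace shorter than detection window")
    u = _u(trace, params, smooth=51)
    l_app = trace.extension / u
    events = []
    for k, _rough in _step_candidates(l_app, u, window, min_step_nm):
        if _local_sharpness(l_app, u, k) > -0.7 * min_step_nm:
            continue
        dx, f_zip = _measure_step(trace, params, k)
        if not np.isfinite(dx) or dx > -min_step_nm:  # zips decrease extension
            continue
        if force_band is not None and not (force_band[0] <= f_zip <= force_band[1]):
            continue
        events.append(TransitionEvent("cooperative", "rewrap", f_zip, -dx,
                                      float(trace.time[k])))
    return sorted(events, key=lambda e: e.t_event)


@dataclass
class LowForceResult:
    kind: str                    # cooperative | noncooperative | mixed | absent
    delta_x: float               # nm, total excess gained across the band
    force: float                 # pN, transition midpoint (half-excess force)
    hopping: bool
    steps: list[TransitionEvent]


def quantify_low_force(trace: ForceExtensionTrace,
                       force_band: tuple = LOW_FORCE_BAND,
                       params: WLCParams = WLCParams(),
                       step_threshold: float = 5.0,
                       noncoop_threshold: float = 5.0) -> LowForceResult:
    """Classify and measure the low-force transition of a pulling trace.

    The total transition size is the horizontal distance between WLC fits
    below (baseline) and above (post) the band, evaluated at the half-excess
    force.  Cooperative steps inside the band are detected separately; the
    noncooperative share is the remainder.
    """
    if trace.direction != PULLING:
        raise ValueError("low-force classification requires a pulling trace")
    f = trace.force
    if f.min() > force_band[0] or f.max() < POST_LF_RANGE[1]:
        raise ValueError("trace does not cover the low-force band")
    l_pre = _fit_contour_range(trace, params, *BASELINE_RANGE)
    l_post = _fit_contour_range(trace, params, *POST_LF_RANGE)
    u = _u(trace, params)
    # half-excess force: where the excess vs baseline reaches half its final value
    band = (f >= force_band[0]) & (f <= force_band[1] + 0.5)
    excess = _rolling_median(trace.extension - u * l_pre, 21)
    total_gap = (l_post - l_pre)
    f_mid = float(f[band][np.argmin(np.abs(excess[band] - 0.5 * total_gap
                                           * u[band]))]) if band.any() else np.nan
    u_mid = float(relative_extension_fast(max(f_mid, 0.05), params))
    delta_x = total_gap * u_mid

    steps = detect_rips(trace, min_step_nm=step_threshold, force_band=force_band,
                        params=params)
    # cooperative share from a *local* jump (medians over ~20 samples either
    # side): flanking WLC fits would absorb any adjacent noncooperative ramp
    # into the step and hide a mixed transition
    l_app = trace.extension / u
    coop_dx = 0.0
    for e in steps:
        k = int(np.searchsorted(trace.time, e.t_event))
        lo, hi = max(0, k - 20), min(len(l_app), k + 21)
        if k - lo > 5 and hi - k > 5:
            coop_dx += float((np.median(l_app[k + 3:hi])
                              - np.median(l_app[lo:k - 2])) * u[k])
        else:
            coop_dx += e.delta_x
    noncoop_dx = delta_x - coop_dx
    hopping = _hopping_flag(trace, params, force_band)
    if delta_x < 3.0:
        kind = "absent"
    elif steps and noncoop_dx >= noncoop_threshold:
        kind = "mixed"
    elif steps:
        kind = "cooperative"
    elif delta_x >= noncoop_threshold:
        kind = "noncooperative"
    else:
        kind = "absent"
    return LowForceResult(kind, float(delta_x), f_mid, hopping, steps)


def classify_low_force(trace: ForceExtensionTrace,
                       force_band: tuple = LOW_FORCE_BAND,
                       params: WLCParams = WLCParams()) -> str:
    """Kind of the low-force transition: cooperative/noncooperative/mixed/absent."""
    return quantify_low_force(trace, force_band, params).kind


def _hopping_flag(trace, params, force_band, min_alternations: int = 3,
                  min_gap_nm: float = 6.0) -> bool:
    """>= 3 alternations of a two-state apparent-contour residual in the band."""
    f = trace.force
    band = (f >= force_band[0]) & (f <= force_band[1])
    if band.sum() < 20:
        return False
    l_band = _rolling_median(apparent_contour(trace, params)[band], 7)
    hi, lo = np.percentile(l_band, [85, 15])
    if hi - lo < min_gap_nm:
        return False
    mid = 0.5 * (hi + lo)
    dead = 0.25 * (hi - lo)
    # hysteresis: a ramp crosses the dead band once, a telegraph many times
    state, alternations = None, 0
    for v in l_band:
        if v > mid + dead:
            s = 1
        elif v < mid - dead:
            s = 0
        else:
            continue
        if state is not None and s != state:
            alternations += 1
        state = s
    return alternations >= min_alternations


def measure_offset_vs_reference(trace_a: ForceExtensionTrace,
                                trace_b: ForceExtensionTrace,
                                force_range: tuple = (32.0, 38.0),
                                params: WLCParams = WLCParams()) -> float:
    """Mean extension displacement of a relative to b over ``force_range``.

    Positive when a is longer.  Exactly antisymmetric under argument swap.
    """
    for tr in (trace_a, trace_b):
        if tr.force.min() > force_range[0] or tr.force.max() < force_range[1]:
            raise ValueError("trace does not cover the requested force range")
    l_a = _fit_contour_range(trace_a, params, *force_range)
    l_b = _fit_contour_range(trace_b, params, *force_range)
    grid = np.linspace(force_range[0], force_range[1], 50)
    u = relative_extension_fast(grid, params)
    return float(np.mean(u) * (l_a - l_b))


def wlc_divergence_point(trace: ForceExtensionTrace,
                         fit_range: tuple = (1.0, 3.0),
                         k_sigma: float = 3.0, sustained_s: float = 0.05,
                         params: WLCParams = WLCParams()):
    """First sustained departure of the trace from its low-force WLC baseline.

    Returns ``(force, time)`` of the first excursion beyond ``k_sigma`` times
    the baseline residual SD lasting at least ``sustained_s`` seconds, or
    ``None`` if the trace never diverges.
    """
    # the force ramp is slow: smooth the force channel before converting to u,
    # otherwise force noise leaks ~10 nm of apparent extension noise at low force
    f = _rolling_median(trace.force, 101)
    fit_mask = (f >= fit_range[0]) & (f <= fit_range[1])
    u = relative_extension_fast(np.clip(f, 0.05, None), params)
    if fit_mask.sum() < 5:
        raise ValueError("baseline fit range not covered")
    l_fit = float(np.dot(u[fit_mask], trace.extension[fit_mask])
                  / np.dot(u[fit_mask], u[fit_mask]))
    resid = trace.extension - u * l_fit
    # fast-noise scale from first differences; slow baseline curvature excluded
    sigma = float(np.std(np.diff(resid[fit_mask])) / np.sqrt(2.0))
    resid_s = _rolling_median(resid, 21)
    n_sust = max(1, int(round(sustained_s / trace.dt)))
    after = np.flatnonzero(f > fit_range[1])
    if len(after) == 0:
        return None
    above = np.abs(resid_s) > k_sigma * sigma
    run = 0
    for i in range(after[0], len(resid)):
        run = run + 1 if above[i] else 0
        if run >= n_sust:
            j = i - n_sust + 1
            # refine the onset: walk back to where the smoothed residual
            # last sat within 2 sigma of the baseline (1 sigma would chase
            # slow baseline creep far below the true onset)
            while j > after[0] and np.abs(resid_s[j - 1]) > 2.0 * sigma:
                j -= 1
            return float(f[j]), float(trace.time[j])
    return None


def classify_species(pull_trace: ForceExtensionTrace,
                     reference_dna: ForceExtensionTrace | None = None,
                     params: WLCParams = WLCParams()) -> SpeciesCall:
    """Assign a pulling trace to nucleosome / hexasome / tetrasome / bare DNA.

    Rules: nucleosome = low-force transition + high-force rip; hexasome =
    single 12-37 pN rip without a low-force transition; tetrasome = single
    low-force transition (hopping allowed) without a high-force rip; bare
    DNA = no events (and ~zero offset vs the reference when given).
    """
    rips = detect_rips(pull_trace, params=params)
    low = quantify_low_force(pull_trace, params=params)
    offset = None
    if reference_dna is not None:
        offset = measure_offset_vs_reference(reference_dna, pull_trace,
                                             params=params)
    has_low = low.kind != "absent"
    has_rip = len(rips) > 0
    ambiguous = False
    if has_low and has_rip:
        label = "nucleosome"
    elif has_rip and not has_low:
        label = "hexasome"
        if not any(12.0 <= e.force <= 37.0 for e in rips):
            ambiguous = True
    elif has_low and not has_rip:
        label = "tetrasome"
    else:
        label = "bareDNA"
        if offset is not None and abs(offset) > 1.5:
            ambiguous = True
    evidence = rips + low.steps
    if has_low and not low.steps:
        evidence.append(TransitionEvent(low.kind, "unwrap", max(low.force, 0.1),
                                        max(low.delta_x, 1e-3), t_event=0.0,
                                        hopping=low.hopping))
    return SpeciesCall(label, evidence, offset, ambiguous)
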