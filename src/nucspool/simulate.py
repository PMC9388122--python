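"""Seeded generator of synthetic fleezers experiments.

Emulates paired force-extension and fluorescence traces of nucleosomes,
hexasomes, tetrasomes and bare DNA over pulling/relaxation cycles, with
ground-truth event logs, so every analysis stage is testable offline.

The two-trap instrument is abstracted to a linear force ramp on the tether
(trap compliance folded into the extension noise).  The emitted extension is

    x(t) = u(F) * (L_construct - seq(t)) + proj(t) + noise,

where ``seq`` is the contour sequestered by the particle and ``proj`` the
axial extension returned by the particle's entry-exit chord.  Particle
states are anchored to the *measured* quantities: the final post-rip state
sequesters 30 bp against the sphere chord (2.3 nm offset vs bare DNA), rip
sizes are drawn from the measured distribution (24.5 +- 1.6 nm for the
nucleosome), and the low-force transition is the spool pathway (rotation
11.3 nm + 27 bp release -> ~19.9 nm at 4 pN), with the rotation phase
*preceding* DNA release so that the tweezers channel diverges before FRET.

Default event distributions (force in pN, delta-x in nm):

=========== =========================== =======================
species      transition                  distribution
=========== =========================== =======================
nucleosome   low force, noncooperative   onset N(3.6, 0.2), end N(4.3, 0.2)  (87%)
nucleosome   low force, cooperative      N(4.1, 0.7), dx N(20.4, 1.5)        (9%)
nucleosome   low force, mixed            N(3.8, 0.2), dx N(20.6, 2.0)        (4%)
nucleosome   high-force rip              N(30.4, 8.3) trunc [8, 40], dx N(24.5, 1.6)
hexasome     single rip                  N(24.6, 3.0) trunc [8, 40], dx N(23.4, 1.1)
tetrasome    low force + hopping         N(4.4, 0.5) trunc [3.2, 5.6], dx N(13.3, 1.7)
=========== =========================== =======================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data import (PULLING, RELAXATION, FluorescenceTrace, ForceExtensionTrace,
                   GroundTruth, TransitionEvent)
from .disassembly import DisassemblyModel, SPECIES
from .spool import SpoolGeometry, chord_axial_rise, chord_length, sphere_chord
from .wlc import WLCParams, relative_extension_fast

__all__ = [
    "GeneratorConfig",
    "CycleResult",
    "generate_cycle",
    "generate_experiment",
    "generate_ejection_trace",
    "generate_bleach_trace",
]

REWRAP_CASES = ("I", "II.1", "II.2a", "II.2b", "III.1", "III.2", "III.3")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic experiment (50 mM KOAc defaults)."""

    handle_bp: int = 5000                  # 2 x 2.5-kb handles
    pulling_speed: float = 100.0           # nm/s
    sampling_rate: float = 1000.0          # Hz, force/extension channels
    fluorescence_rate: float = 100.0       # Hz (10-ms bins)
    force_min: float = 0.5                 # pN
    force_max: float = 40.0                # pN
    force_noise: float = 0.1               # pN, Gaussian SD
    extension_noise: float = 1.0           # nm, Gaussian SD
    wlc: WLCParams = WLCParams()
    geometry: SpoolGeometry = SpoolGeometry()
    # nucleosome low-force transition
    lf_kind_probs: tuple = (0.87, 0.09, 0.04)     # noncooperative, cooperative, mixed
    lf_onset: tuple = (3.6, 0.2)
    lf_end: tuple = (4.3, 0.2)
    lf_coop_force: tuple = (4.1, 0.7)
    lf_coop_dx: tuple = (20.4, 1.5)
    lf_rotation_fraction: float = 0.4      # share of the ramp that is pure rotation
    # nucleosome high-force rip
    hf_force: tuple = (30.4, 8.3)
    hf_force_band: tuple = (8.0, 40.0)
    hf_dx: tuple = (24.5, 1.6)
    nucleosome_post_rip_bp: int = 30
    # hexasome
    hexasome_force: tuple = (24.6, 3.0)
    hexasome_dx: tuple = (23.4, 1.1)
    hexasome_post_rip_bp: int = 31
    # tetrasome
    tetrasome_force: tuple = (4.4, 0.5)
    tetrasome_force_band: tuple = (3.2, 5.6)
    tetrasome_dx: tuple = (13.3, 1.7)
    tetrasome_release_bp: int = 30
    tetrasome_post_bp: int = 47
    tetrasome_hop_switches: int = 6
    # fluorescence
    fret_construct: str = "none"           # ED1 | INT | ED2 | none
    e_high: float = 0.85
    e_low: float = 0.10
    e_noise: float = 0.03                  # extra SD of E for INT "gaping"
    int_gaping_noise: float = 0.08
    photon_rate: float = 60.0              # photons per 10-ms bin (both channels)
    background_rate: float = 2.0           # per channel per bin
    ejection_delay_mean: float = 0.113     # s, exponential
    rewrap_case_weights: tuple = (1,) * len(REWRAP_CASES)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.force_noise < 0 or self.extension_noise < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.fret_construct not in ("ED1", "INT", "ED2", "none"):
            raise ValueError(f"unknown FRET construct {self.fret_construct!r}")
        if not self.force_min < self.force_max:
            raise ValueError("force_min must be < force_max")
        if abs(sum(self.lf_kind_probs) - 1.0) > 1e-9:
            raise ValueError("lf_kind_probs must sum to 1")

    @property
    def construct_contour(self) -> float:
        return (self.handle_bp + self.geometry.total_wrap_bp) * self.wlc.rise_per_bp


@dataclass
class CycleResult:
    pull: ForceExtensionTrace
    relax: ForceExtensionTrace
    truth: GroundTruth
    fluor_pull: FluorescenceTrace | None = None
    fluor_relax: FluorescenceTrace | None = None


def _truncnorm(rng, mean, sd, lo=None, hi=None):
    """Rejection-sampled truncated normal (bounds are loose; cheap)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if (lo is None or x >= lo) and (hi is None or x <= hi):
            return float(x)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


# ---------------------------------------------------------------------------
# particle state schedules
# ---------------------------------------------------------------------------

@dataclass
class _Schedule:
    """Piecewise-linear (force -> sequestered contour, chord projection)."""

    f_knots: list = field(default_factory=list)
    seq_knots: list = field(default_factory=list)
    proj_knots: list = field(default_factory=list)

    def add(self, f, seq, proj):
        self.f_knots.append(f)
        self.seq_knots.append(seq)
        self.proj_knots.append(proj)

    def seq(self, force):
        return np.interp(force, self.f_knots, self.seq_knots)

    def proj(self, force):
        return np.interp(force, self.f_knots, self.proj_knots)

    @property
    def initial(self):
        return self.seq_knots[0], self.proj_knots[0]

    @property
    def final(self):
        return self.seq_knots[-1], self.proj_knots[-1]


_STEP = 1e-6  # pN, knot separation used to encode a discontinuity


def _u(config: GeneratorConfig, force):
    return relative_extension_fast(force, config.wlc)


def _rotation_total(config: GeneratorConfig) -> float:
    g = config.geometry
    core = g.total_wrap_bp - g.low_force_release_bp
    return chord_length(g, core) + chord_axial_rise(g, core)


def _nucleosome_schedule(config: GeneratorConfig, rng, truth: GroundTruth) -> _Schedule:
    g, rise = config.geometry, config.wlc.rise_per_bp
    # final (post-rip) state: 30 bp on the sphere chord -> ~2.3 nm offset
    seq_f = config.nucleosome_post_rip_bp * rise
    proj_f = sphere_chord(g, config.nucleosome_post_rip_bp)
    # high-force rip
    f_rip = _truncnorm(rng, *config.hf_force, *config.hf_force_band)
    dx_rip = _truncnorm(rng, *config.hf_dx, lo=5.0)
    n_rip = round(dx_rip / (rise * float(_u(config, f_rip))))
    seq_p = seq_f + n_rip * rise
    proj_p = proj_f - (dx_rip - n_rip * rise * float(_u(config, f_rip)))
    # low-force transition
    kind = ("noncooperative", "cooperative", "mixed")[
        rng.choice(3, p=np.asarray(config.lf_kind_probs))]
    release = g.low_force_release_bp * rise
    rot = _rotation_total(config)
    seq_0, proj_0 = seq_p + release, proj_p - rot

    s = _Schedule()
    s.add(0.0, seq_0, proj_0)
    if kind == "cooperative":
        f_c = _truncnorm(rng, *config.lf_coop_force, lo=2.8, hi=5.6)
        dx_c = _truncnorm(rng, *config.lf_coop_dx, lo=10.0)
        # single step carrying the full release + rotation; remainder in proj
        proj_step = proj_0 + dx_c - release * float(_u(config, f_c))
        s.add(f_c, seq_0, proj_0)
        s.add(f_c + _STEP, seq_p, proj_step)
        s.add(f_c + 2 * _STEP, seq_p, proj_p)  # residual folded immediately
        truth.lf_onset_force = truth.lf_end_force = f_c
        truth.lf_delta_x = dx_c
        truth.unwrap_start_time = None  # set from time map later
        truth.events.append(TransitionEvent("cooperative", "unwrap", f_c, dx_c,
                                            t_event=0.0))
    else:
        f_on = _truncnorm(rng, *config.lf_onset, lo=3.0, hi=4.2)
        # width floor keeps a drawn "noncooperative" transition resolvable as
        # such at the sampling rate (narrower would be indistinguishable from
        # a rip, making the ground-truth kind label meaningless)
        f_end = _truncnorm(rng, *config.lf_end, lo=f_on + 0.45, hi=5.2)
        f_rot = f_on + config.lf_rotation_fraction * (f_end - f_on)
        core_chord = chord_length(g, g.total_wrap_bp - g.low_force_release_bp)
        if kind == "mixed":
            # sharp step carrying half of the transition, gradual remainder
            s.add(f_on, seq_0, proj_0)
            s.add(f_on + _STEP, seq_0 - release / 2, proj_0 + rot / 2)
            s.add(f_end, seq_p, proj_p)
        else:
            s.add(f_on, seq_0, proj_0)
            s.add(f_rot, seq_0, proj_0 + core_chord)     # rotation first
            s.add(f_end, seq_p, proj_p)                   # release + residual
        dx_lf = release * float(_u(config, (f_on + f_end) / 2)) + rot
        truth.lf_onset_force, truth.lf_end_force = f_on, f_end
        truth.lf_delta_x = dx_lf
        truth.events.append(TransitionEvent(kind, "unwrap", (f_on + f_end) / 2,
                                            dx_lf, t_event=0.0))
    truth.lf_kind = kind
    # plateau then rip
    s.add(f_rip, seq_p, proj_p)
    s.add(f_rip + _STEP, seq_f, proj_f)
    truth.rip_force, truth.rip_delta_x = f_rip, dx_rip
    truth.released_bp = n_rip + g.low_force_release_bp
    truth.events.append(TransitionEvent("cooperative", "unwrap", f_rip, dx_rip,
                                        t_event=0.0))
    s.add(config.force_max + 1.0, seq_f, proj_f)
    return s


def _hexasome_schedule(config: GeneratorConfig, rng, truth: GroundTruth) -> _Schedule:
    g, rise = config.geometry, config.wlc.rise_per_bp
    seq_f = config.hexasome_post_rip_bp * rise
    proj_f = sphere_chord(g, config.hexasome_post_rip_bp)
    f_rip = _truncnorm(rng, *config.hexasome_force, *config.hf_force_band)
    dx_rip = _truncnorm(rng, *config.hexasome_dx, lo=5.0)
    n_rip = round(dx_rip / (rise * float(_u(config, f_rip))))
    seq_0 = seq_f + n_rip * rise
    proj_0 = proj_f - (dx_rip - n_rip * rise * float(_u(config, f_rip)))
    s = _Schedule()
    s.add(0.0, seq_0, proj_0)       # already aligned: no rotation phase
    s.add(f_rip, seq_0, proj_0)
    s.add(f_rip + _STEP, seq_f, proj_f)
    s.add(config.force_max + 1.0, seq_f, proj_f)
    truth.rip_force, truth.rip_delta_x = f_rip, dx_rip
    truth.released_bp = n_rip
    truth.events.append(TransitionEvent("cooperative", "unwrap", f_rip, dx_rip,
                                        t_event=0.0))
    return s


def _tetrasome_schedule(config: GeneratorConfig, rng, truth: GroundTruth) -> _Schedule:
    g, rise = config.geometry, config.wlc.rise_per_bp
    seq_f = config.tetrasome_post_bp * rise
    proj_f = sphere_chord(g, config.tetrasome_post_bp)
    f_t = _truncnorm(rng, *config.tetrasome_force, *config.tetrasome_force_band)
    dx = _truncnorm(rng, *config.tetrasome_dx, lo=6.0)
    release = config.tetrasome_release_bp * rise
    # ~30 bp release plus a rotation share making up the drawn delta-x
    proj_0 = proj_f - (dx - release * float(_u(config, f_t)))
    seq_0 = seq_f + release
    f_on, f_end = f_t - 0.25, f_t + 0.25
    s = _Schedule()
    s.add(0.0, seq_0, proj_0)
    s.add(f_on, seq_0, proj_0)
    s.add(f_end, seq_f, proj_f)
    s.add(config.force_max + 1.0, seq_f, proj_f)
    truth.lf_kind = "noncooperative"
    truth.lf_onset_force, truth.lf_end_force = f_on, f_end
    truth.lf_delta_x = dx
    truth.released_bp = config.tetrasome_release_bp
    truth.events.append(TransitionEvent("noncooperative", "unwrap", f_t, dx,
                                        t_event=0.0, hopping=True))
    return s


def _bare_schedule(config: GeneratorConfig) -> _Schedule:
    s = _Schedule()
    s.add(0.0, 0.0, 0.0)
    s.add(config.force_max + 1.0, 0.0, 0.0)
    return s


_SCHEDULES = {
    "nucleosome": _nucleosome_schedule,
    "hexasome": _hexasome_schedule,
    "tetrasome": _tetrasome_schedule,
}


# ---------------------------------------------------------------------------
# trace synthesis
# ---------------------------------------------------------------------------

def _ramp(config: GeneratorConfig, direction: str):
    """Force ramp and time axis; duration set by the mean pulling speed."""
    u_lo = float(_u(config, config.force_min))
    u_hi = float(_u(config, config.force_max))
    span_nm = config.construct_contour * (u_hi - u_lo)
    duration = span_nm / config.pulling_speed
    n = max(2, int(round(duration * config.sampling_rate)))
    t = np.arange(n) / config.sampling_rate
    if direction == PULLING:
        f = np.linspace(config.force_min, config.force_max, n)
    else:
        f = np.linspace(config.force_max, config.force_min, n)
    return t, f


def _force_to_time(config: GeneratorConfig, t, f, force, direction=PULLING):
    if direction == PULLING:
        return float(np.interp(force, f, t))
    return float(np.interp(force, f[::-1], t[::-1]))


def _emit(config: GeneratorConfig, rng, t, f_true, schedule: _Schedule,
          direction: str, cycle_index: int,
          hop_band: tuple | None = None, hop_truth: dict | None = None
          ) -> ForceExtensionTrace:
    u = _u(config, f_true)
    seq = schedule.seq(f_true)
    proj = schedule.proj(f_true)
    if hop_band is not None:
        # two-state telegraph between pre- and post-transition curves
        lo, hi = hop_band
        band = (f_true >= lo) & (f_true <= hi)
        idx = np.flatnonzero(band)
        if len(idx) > 4:
            n_sw = max(3, hop_truth.get("switches", 6) if hop_truth else 6)
            cuts = np.sort(rng.choice(idx[1:-1], size=min(n_sw, len(idx) - 2),
                                      replace=False))
            state = 0
            seq_pre, proj_pre = schedule.seq(lo - 0.01), schedule.proj(lo - 0.01)
            seq_post, proj_post = schedule.seq(hi + 0.01), schedule.proj(hi + 0.01)
            start = idx[0]
            for cut in list(cuts) + [idx[-1] + 1]:
                sl = slice(start, cut)
                seq[sl] = seq_pre if state == 0 else seq_post
                proj[sl] = proj_pre if state == 0 else proj_post
                state ^= 1
                start = cut
    ext = u * (config.construct_contour - seq) + proj
    ext = ext + rng.normal(0.0, config.extension_noise, size=len(ext))
    f_meas = f_true + rng.normal(0.0, config.force_noise, size=len(f_true))
    return ForceExtensionTrace(t, f_meas, ext, direction=direction,
                               cycle_index=cycle_index)


# ---------------------------------------------------------------------------
# relaxation / rewrapping
# ---------------------------------------------------------------------------

def _relax_schedule(config: GeneratorConfig, rng, start, end, next_species: str,
                    truth: GroundTruth) -> _Schedule:
    """Rewrapping schedule from the pull end state back to next cycle's start.

    The recovered deficit is distributed over 1-3 shortening transitions
    drawn from the observed case menu; zips are steps, noncooperative
    portions are ramps around the low-force band.
    """
    seq_e, proj_e = start
    seq_0, proj_0 = end
    s = _Schedule()       # knots in *increasing* force, evaluated on the way down
    if next_species == "bareDNA" or (seq_0 == seq_e and proj_0 == proj_e):
        s.add(0.0, seq_0, proj_0)
        s.add(config.force_max + 1.0, seq_e, proj_e)
        if next_species != "bareDNA":
            return s
        # full dissociation during relaxation: bare from the top
        s2 = _Schedule()
        s2.add(0.0, 0.0, 0.0)
        s2.add(config.force_max + 1.0, 0.0, 0.0)
        return s2
    weights = np.asarray(config.rewrap_case_weights, dtype=float)
    case = REWRAP_CASES[rng.choice(len(REWRAP_CASES), p=weights / weights.sum())]
    truth.rewrap_case = case
    n_zips = {"I": 1, "II.1": 2, "II.2a": 2, "II.2b": 2,
              "III.1": 3, "III.2": 3, "III.3": 3}[case]
    # zip forces, descending through the relaxation
    if case == "I":
        forces = [rng.uniform(2.0, 3.5)]
    elif case == "II.1":
        forces = [rng.uniform(5.0, 9.0), rng.uniform(2.5, 3.8)]
    elif case == "II.2a":
        forces = sorted([rng.uniform(2.0, 3.8), rng.uniform(2.0, 3.8)], reverse=True)
    elif case == "II.2b":
        forces = [rng.uniform(5.0, 9.0), rng.uniform(2.0, 3.5)]
    else:
        forces = sorted([rng.uniform(4.5, 9.0), rng.uniform(3.0, 4.4),
                         rng.uniform(2.0, 2.9)], reverse=True)
    fractions = rng.dirichlet(np.ones(n_zips) * 3.0)
    dseq = (seq_0 - seq_e) * fractions
    dproj = (proj_0 - proj_e) * fractions
    seq, proj = seq_e, proj_e
    s.add(config.force_max + 1.0, seq_e, proj_e)
    noncoop_last = case in ("II.1", "III.1", "III.2")
    for i, f_z in enumerate(forces):
        is_ramp = noncoop_last and i == n_zips - 1
        if is_ramp:
            s.add(f_z + 0.6, seq, proj)
            seq, proj = seq + dseq[i], proj + dproj[i]
            s.add(max(f_z - 0.6, 0.2), seq, proj)
        else:
            s.add(f_z + _STEP, seq, proj)
            seq, proj = seq + dseq[i], proj + dproj[i]
            s.add(f_z, seq, proj)
            u_z = float(_u(config, f_z))
            dx = abs(dseq[i]) * u_z + abs(dproj[i])
            truth.zip_events.append(TransitionEvent(
                "cooperative", "rewrap", f_z, max(dx, 1e-3), t_event=0.0))
    s.add(0.05, seq_0, proj_0)
    # enforce strictly decreasing force knots (cases can draw close forces)
    for i in range(1, len(s.f_knots)):
        if s.f_knots[i] >= s.f_knots[i - 1]:
            s.f_knots[i] = s.f_knots[i - 1] - 1e-4
    # reverse into increasing-force knot order
    s.f_knots, s.seq_knots, s.proj_knots = (list(x[::-1]) for x in
                                            (s.f_knots, s.seq_knots, s.proj_knots))
    return s


# ---------------------------------------------------------------------------
# fluorescence
# ---------------------------------------------------------------------------

def _fret_profile_pull(config: GeneratorConfig, t_bins, truth: GroundTruth,
                       t_map) -> np.ndarray:
    """FRET efficiency vs time for the pulling phase of the labelled construct."""
    e = np.full(len(t_bins), config.e_high)
    c = config.fret_construct
    if truth.species == "bareDNA" or c == "none":
        return e
    if c in ("ED2", "INT"):
        if truth.rip_time is not None:
            e[t_bins >= truth.rip_time] = config.e_low
            truth.fret_drop_time = truth.rip_time
    elif c == "ED1":
        if truth.lf_kind == "cooperative" and truth.lf_onset_force is not None:
            t_c = t_map(truth.lf_onset_force)
            e[t_bins >= t_c] = config.e_low
            truth.fret_drop_time = t_c
        elif truth.lf_onset_force is not None:
            # FRET follows DNA release: starts only once rotation completes
            t0 = truth.unwrap_start_time
            t1 = t_map(truth.lf_end_force)
            ramp = np.clip((t_bins - t0) / max(t1 - t0, 1e-3), 0.0, 1.0)
            e = config.e_high - (config.e_high - config.e_low) * ramp
            truth.fret_drop_time = t0
    return e


def _fret_profile_relax(config: GeneratorConfig, t_bins, truth: GroundTruth,
                        rng) -> np.ndarray:
    e = np.full(len(t_bins), config.e_low if truth.fret_drop_time is not None
                else config.e_high)
    if truth.fret_drop_time is None or not truth.zip_events:
        return e
    zips = truth.zip_events
    if config.fret_construct == "INT" or len(zips) == 1:
        k = 0                              # INT always recovers at the first zip
    else:
        k = int(rng.integers(0, 2))        # ED1/ED2: first or second zip
    t_rec = zips[k].t_event
    e[t_bins >= t_rec] = config.e_high
    truth.fret_recovery_time = t_rec
    truth.recovery_zip_index = k
    return e


def _emit_fluorescence(config: GeneratorConfig, rng, duration: float,
                       e_profile_fn) -> FluorescenceTrace:
    dt = 1.0 / config.fluorescence_rate
    n = max(2, int(round(duration / dt)))
    t = (np.arange(n) + 0.5) * dt
    e = np.clip(e_profile_fn(t), 0.0, 1.0)
    sigma = (config.int_gaping_noise if config.fret_construct == "INT"
             else config.e_noise)
    e_noisy = np.clip(e + rng.normal(0.0, sigma, n), 0.0, 1.0)
    total = rng.poisson(config.photon_rate, n)
    acceptor = rng.binomial(total, e_noisy)
    donor = total - acceptor
    donor = donor + rng.poisson(config.background_rate, n)
    acceptor = acceptor + rng.poisson(config.background_rate, n)
    return FluorescenceTrace(t, donor.astype(float), acceptor.astype(float))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_cycle(config: GeneratorConfig, species: str, seed: int | None = None,
                   cycle_index: int = 0, next_species: str | None = None,
                   rng: np.random.Generator | None = None) -> CycleResult:
    """One pulling + relaxation cycle for a molecule of the given species."""
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    if next_species is None:
        next_species = species
    truth = GroundTruth(species=species)

    t, f = _ramp(config, PULLING)
    if species == "bareDNA":
        schedule = _bare_schedule(config)
        hop_band = None
    else:
        schedule = _SCHEDULES[species](config, rng, truth)
        hop_band = None
        if species == "tetrasome":
            hop_band = (truth.lf_onset_force, truth.lf_end_force)
    # map event forces to times on the pulling ramp
    t_map = lambda force: _force_to_time(config, t, f, force)
    for ev in truth.events:
        ev.t_event = t_map(ev.force)
    if truth.rip_force is not None:
        truth.rip_time = t_map(truth.rip_force)
    if truth.lf_kind in ("noncooperative", "mixed") and truth.lf_onset_force is not None:
        f_on, f_end = truth.lf_onset_force, truth.lf_end_force
        f_rot = f_on + config.lf_rotation_fraction * (f_end - f_on)
        truth.unwrap_start_time = t_map(f_rot)
    elif truth.lf_kind == "cooperative" and truth.lf_onset_force is not None:
        truth.unwrap_start_time = t_map(truth.lf_onset_force)
    truth.sequestered_contour_nm = schedule.final[0]

    pull = _emit(config, rng, t, f, schedule, PULLING, cycle_index,
                 hop_band=hop_band,
                 hop_truth={"switches": config.tetrasome_hop_switches})

    # relaxation back down, rewrapping toward the next cycle's species
    t_r, f_r = _ramp(config, RELAXATION)
    if next_species == species and species != "bareDNA":
        end_state = _initial_state(config, rng, species)
    elif next_species == "bareDNA":
        end_state = (0.0, 0.0)
    else:
        end_state = _initial_state(config, rng, next_species)
    relax_sched = _relax_schedule(config, rng, schedule.final, end_state,
                                  next_species, truth)
    for ev in truth.zip_events:
        ev.t_event = _force_to_time(config, t_r, f_r, ev.force, RELAXATION)
    relax = _emit(config, rng, t_r, f_r, relax_sched, RELAXATION, cycle_index)

    fluor_pull = fluor_relax = None
    if config.fret_construct != "none":
        duration = t[-1] + 1.0 / config.sampling_rate
        fluor_pull = _emit_fluorescence(
            config, rng, duration,
            lambda tb: _fret_profile_pull(config, tb, truth, t_map))
        fluor_relax = _emit_fluorescence(
            config, rng, duration,
            lambda tb: _fret_profile_relax(config, tb, truth, rng))
    return CycleResult(pull, relax, truth, fluor_pull, fluor_relax)


def _initial_state(config: GeneratorConfig, rng, species: str):
    """Initial (seq, proj) of a fresh particle; draws its own event sizes."""
    probe = GroundTruth(species=species)
    sched = _SCHEDULES[species](config, rng, probe) if species != "bareDNA" \
        else _bare_schedule(config)
    return sched.initial


def generate_experiment(config: GeneratorConfig, model: DisassemblyModel,
                        n_molecules: int, seed: int | None = None,
                        max_cycles: int = 8) -> list[list[CycleResult]]:
    """Full synthetic experiment: per-molecule cycle sequences with traces.

    Species sequences are drawn from the disassembly model; each molecule's
    randomness comes from a child generator spawned deterministically from
    the experiment seed.
    """
    base = config.seed if seed is None else seed
    molecules: list[list[CycleResult]] = []
    for m in range(n_molecules):
        rng = np.random.default_rng([base, m])
        species = "nucleosome"
        cycles: list[CycleResult] = []
        for c in range(max_cycles):
            if species == "bareDNA":
                cycles.append(generate_cycle(config, species, cycle_index=c,
                                             rng=rng))
                break
            nxt = SPECIES[rng.choice(4, p=model.probabilities(species))]
            cycles.append(generate_cycle(config, species, cycle_index=c,
                                         next_species=nxt, rng=rng))
            species = nxt
        molecules.append(cycles)
    return molecules


def generate_ejection_trace(config: GeneratorConfig, rip_time: float,
                            duration: float, seed: int | None = None,
                            level: float = 40.0,
                            rng: np.random.Generator | None = None):
    """Cy3-only intensity trace with a dimer-ejection drop after the rip.

    Returns ``(trace, delay)``: photon counts per 10-ms bin dropping to
    background at ``rip_time + delay``, delay ~ Exp(ejection_delay_mean),
    with enhanced fluctuations between rip and drop.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    dt = 1.0 / config.fluorescence_rate
    n = int(round(duration / dt))
    t = (np.arange(n) + 0.5) * dt
    delay = float(rng.exponential(config.ejection_delay_mean))
    t_drop = rip_time + delay
    rate = np.where(t < t_drop, level, config.background_rate)
    flicker = (t >= rip_time) & (t < t_drop)
    rate = rate * np.where(flicker, rng.uniform(0.6, 1.4, n), 1.0)
    counts = rng.poisson(rate).astype(float)
    return FluorescenceTrace(t, counts, np.zeros(n)), delay


def generate_bleach_trace(config: GeneratorConfig, n_steps: int = 2,
                          duration: float = 4.0, level: float = 25.0,
                          seed: int | None = None,
                          rng: np.random.Generator | None = None):
    """Stepwise photobleaching trace (``n_steps`` dyes), for step counting."""
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    dt = 1.0 / config.fluorescence_rate
    n = int(round(duration / dt))
    t = (np.arange(n) + 0.5) * dt
    bleach_times = np.sort(rng.uniform(0.15 * duration, 0.85 * duration, n_steps))
    dyes = n_steps - np.searchsorted(bleach_times, t, side="right")
    rate = dyes * level + config.background_rate
    counts = rng.poisson(rate).astype(float)
    return FluorescenceTrace(t, counts, np.zeros(n)), bleach_times
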