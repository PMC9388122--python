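"""Spool models of nucleosome unwrapping.

Two complementary geometric models convert measured changes in tether
extension into DNA base pairs:

* the **mechanical unwrapping model**: the nucleosome is a rigid superhelical
  spool (crystal-structure geometry: 147 bp in 1.65 left-handed turns, radius
  4.18 nm, pitch 2.39 nm/turn).  Under tension the spool reorients so that the
  chord between the DNA entry and exit contact points aligns with the pulling
  axis; this rigid-body rotation contributes tether extension *without*
  unwrapping any DNA.
* the **spherical geometric model**: the particle is a sphere of effective
  radius calibrated once against the mechanical model's end state; an
  extension change is the WLC extension of the released contour plus the
  change of the entry-exit chord across the sphere as the wrap shrinks.

Accounting used by the mechanical model (the construction that reproduces the
crystal geometry's observable consequences):

* DNA is mapped linearly to superhelical angle, ``theta(bp) = 2*pi*turns*
  bp/147``.  Chord length and axial rise of a wrapped interval depend only on
  its angular span (screw symmetry).
* During the low-force transition the rotating rigid body is the wrap
  *retained* at the end of the transition (the weak-arm outer stretch,
  27 bp pinned by the FRET dye positions, peels while the body turns).
  Aligning the retained-wrap chord from the zero-force pose contributes its
  full chord length (8.08 nm for the 120-bp core).  The zero-force pose has
  crossed linkers: the tether backtracks axially by the chord's rise along
  the superhelix axis, and recovering that deficit (3.22 nm) accrues as
  residual rotation while the 27 bp unwrap.
* During the high-force rip the spool rotates ~180 deg while unwrapping
  symmetrically from both ends; the rotation is extension-neutral (the
  aligned chord of the 43-bp remainder differs from the 120-bp chord by
  < 0.4 nm), so the rip inverts through the WLC term alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .wlc import WLCParams, bp_from_delta_extension, wlc_extension, wlc_relative_extension

__all__ = [
    "SpoolGeometry",
    "WrapState",
    "AnnotatedPathway",
    "BpEstimate",
    "wrap_path",
    "wrap_tangent",
    "chord_vector",
    "chord_length",
    "chord_axial_rise",
    "rotation_alignment_extension",
    "annotate_low_force",
    "annotate_high_force",
    "end_state_deficit",
    "sphere_chord",
    "sphere_delta_x",
    "sphere_bp_from_delta_x",
    "sphere_bp_remaining_from_offset",
    "calibrate_sphere_radius",
    "with_calibrated_sphere",
    "MEAN_RIP_FORCE",
]

#: mean force of the high-force rip ensemble (pN), the default evaluation
#: point for post-rip geometry
MEAN_RIP_FORCE = 30.4


@dataclass(frozen=True)
class SpoolGeometry:
    """Nucleosome superhelix parameters.

    Defaults are the crystal-structure values; ``effective_sphere_radius`` is
    the one calibrated constant of the spherical model (see
    :func:`calibrate_sphere_radius`).  ``low_force_release_bp`` is the extent
    of the weak-arm release during the low-force transition, pinned by the
    positions of the FRET labels (24-27 bp from the weak-arm entry);
    ``post_rip_wrapped_bp`` is the residual wrap inferred from the post-rip
    offset against bare DNA, reached through a ~13 bp noncooperative release
    that is not resolvable as a discrete event.
    """

    superhelix_radius: float = 4.18       # nm
    superhelix_pitch: float = 2.39        # nm per turn
    total_wrap_bp: int = 147
    total_turns: float = 1.65
    effective_sphere_radius: float = 4.2518  # nm, calibrated (see methods note)
    low_force_release_bp: int = 27
    post_rip_wrapped_bp: int = 30

    def __post_init__(self) -> None:
        if min(self.superhelix_radius, self.superhelix_pitch,
               self.effective_sphere_radius) <= 0:
            raise ValueError("all spool lengths must be > 0")
        if self.total_wrap_bp <= 0 or self.total_turns <= 0:
            raise ValueError("total_wrap_bp and total_turns must be > 0")

    def theta(self, bp) -> np.ndarray | float:
        """Superhelical angle (rad) at a bp offset from the weak-arm entry."""
        return 2.0 * math.pi * self.total_turns * np.asarray(bp, dtype=float) / self.total_wrap_bp


@dataclass(frozen=True)
class WrapState:
    """Wrapped-bp interval of the spool plus its orientation.

    ``orientation`` is either "crossed" (the zero-force pose, linkers crossed
    and emerging oppositely) or "aligned" (entry-exit chord along the pulling
    axis, zero net torque from the force couple).
    """

    bp_wrapped: int
    weak_arm_unwrapped_bp: int = 0
    strong_arm_unwrapped_bp: int = 0
    orientation: str = "crossed"
    total_wrap_bp: int = 147

    def __post_init__(self) -> None:
        if min(self.bp_wrapped, self.weak_arm_unwrapped_bp,
               self.strong_arm_unwrapped_bp) < 0:
            raise ValueError("bp counts must be >= 0")
        if (self.bp_wrapped + self.weak_arm_unwrapped_bp
                + self.strong_arm_unwrapped_bp) != self.total_wrap_bp:
            raise ValueError("wrapped + unwrapped bp must equal total_wrap_bp")
        if self.orientation not in ("crossed", "aligned"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class AnnotatedPathway:
    """Ordered annotation of an unwrapping pathway as a numbered state table."""

    rows: list[dict] = field(default_factory=list)
    released_bp: int | None = None
    remaining_bp: int | None = None

    def add(self, state: int, bp_wrapped: float, rotation_nm: float,
            unwrap_nm: float, force_pn: float) -> None:
        if self.rows and state <= self.rows[-1]["state"]:
            raise ValueError("state labels must be strictly increasing")
        self.rows.append(dict(state=state, bp_wrapped=bp_wrapped,
                              rotation_nm=rotation_nm, unwrap_nm=unwrap_nm,
                              force_pN=force_pn))

    @property
    def total_rotation_nm(self) -> float:
        return float(sum(r["rotation_nm"] for r in self.rows))

    @property
    def total_unwrap_nm(self) -> float:
        return float(sum(r["unwrap_nm"] for r in self.rows))

    @property
    def total_nm(self) -> float:
        return self.total_rotation_nm + self.total_unwrap_nm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["state", "bp_wrapped", "rotation_nm",
                                     "unwrap_nm", "force_pN"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# helical path of the wrapped DNA (body frame)
# ---------------------------------------------------------------------------

def wrap_path(geometry: SpoolGeometry, bp_start: float = 0.0,
              bp_end: float | None = None, n_points: int = 500) -> np.ndarray:
    """Centerline of the wrapped DNA between two bp offsets, shape (n, 3).

    The superhelix is left-handed; z runs along the superhelix axis.
    """
    if bp_end is None:
        bp_end = geometry.total_wrap_bp
    bp = np.linspace(bp_start, bp_end, n_points)
    th = geometry.theta(bp)
    r = geometry.superhelix_radius
    return np.column_stack([
        r * np.cos(th),
        -r * np.sin(th),                      # left-handed
        geometry.superhelix_pitch * th / (2.0 * math.pi),
    ])


def wrap_tangent(geometry: SpoolGeometry, bp: float) -> np.ndarray:
    """Unit tangent of the wrapped DNA path at a bp offset."""
    th = float(geometry.theta(bp))
    r = geometry.superhelix_radius
    t = np.array([
        -r * math.sin(th),
        -r * math.cos(th),
        geometry.superhelix_pitch / (2.0 * math.pi),
    ])
    return t / np.linalg.norm(t)


def chord_vector(geometry: SpoolGeometry, bp_start: float, bp_end: float) -> np.ndarray:
    """Entry-to-exit chord of a wrapped interval, in the body frame."""
    pts = wrap_path(geometry, bp_start, bp_end, n_points=2)
    return pts[1] - pts[0]


def chord_length(geometry: SpoolGeometry, bp_span: float) -> float:
    """Chord length of a wrapped interval; position-independent (screw symmetry)."""
    return float(np.linalg.norm(chord_vector(geometry, 0.0, bp_span)))


def chord_axial_rise(geometry: SpoolGeometry, bp_span: float) -> float:
    """Rise of the chord along the superhelix axis (the crossing deficit)."""
    return float(chord_vector(geometry, 0.0, bp_span)[2])


def _retained_core_bp(state: WrapState, geometry: SpoolGeometry) -> float:
    """Wrap retained through the low-force transition for a given state.

    For states that still hold the weak-arm outer stretch the rotating rigid
    body excludes the imminent ``low_force_release_bp``; after the release the
    wrapped interval is the core itself.
    """
    lo = max(state.weak_arm_unwrapped_bp, geometry.low_force_release_bp)
    hi = state.total_wrap_bp - state.strong_arm_unwrapped_bp
    if hi <= lo:
        raise ValueError("state retains no wrapped core")
    return hi - lo


def rotation_alignment_extension(state_before: WrapState, state_after: WrapState,
                                 geometry: SpoolGeometry = SpoolGeometry(),
                                 force: float | None = None) -> float:
    """Extension gain attributable to spool reorientation alone (nm).

    Pure rotation (bp unchanged, crossed -> aligned) contributes the full
    chord length of the retained core: the chord turns from perpendicular to
    parallel to the pulling axis.  A mixed step (bp released while already
    rotating, states 3 -> 5 of the pathway) contributes the residual rotation that
    recovers the axial crossing deficit of the zero-force pose, i.e. the
    chord's rise along the superhelix axis.  Already-aligned before-states
    with unchanged bp contribute nothing.  ``force`` is unused by the rigid
    geometry and accepted for interface symmetry with the WLC terms.
    """
    if state_after.orientation != "aligned":
        raise ValueError("state_after must be force-aligned; other end poses "
                         "are unreachable under tension")
    core = _retained_core_bp(state_after, geometry)
    if state_before.bp_wrapped == state_after.bp_wrapped:
        if state_before.orientation == "aligned":
            return 0.0
        return chord_length(geometry, core)
    # mixed rotation-while-unwrapping step: crossing recovery
    return chord_axial_rise(geometry, core)


# ---------------------------------------------------------------------------
# pathway annotation
# ---------------------------------------------------------------------------

def annotate_low_force(geometry: SpoolGeometry = SpoolGeometry(),
                       wlc: WLCParams = WLCParams(),
                       force: float = 4.0) -> AnnotatedPathway:
    """States 1-5 of the unwrapping pathway: the low-force transition at ~4 pN.

    Rotation-before-unwrapping (states 2-3), asymmetric release of the
    weak-arm outer stretch with residual rotation (states 3-5).  The total is
    the modelled change in extension of the low-force transition (~20 nm).
    """
    release = geometry.low_force_release_bp
    core = geometry.total_wrap_bp - release
    rot = chord_length(geometry, core)
    residual = chord_axial_rise(geometry, core)
    unwrap = wlc_extension(force, release * wlc.rise_per_bp, wlc)
    path = AnnotatedPathway()
    path.add(1, geometry.total_wrap_bp, 0.0, 0.0, 0.0)
    path.add(2, geometry.total_wrap_bp, 0.0, 0.0, force)
    path.add(3, geometry.total_wrap_bp, rot, 0.0, force)
    path.add(4, geometry.total_wrap_bp - release / 2.0, residual / 2.0,
             unwrap / 2.0, force)
    path.add(5, core, residual / 2.0, unwrap / 2.0, force)
    path.released_bp = release
    path.remaining_bp = core
    return path


def annotate_high_force(geometry: SpoolGeometry = SpoolGeometry(),
                        wlc: WLCParams = WLCParams(),
                        force: float = MEAN_RIP_FORCE,
                        delta_x: float = 24.5) -> AnnotatedPathway:
    """States 5-8 of the unwrapping pathway: the rip and the unresolvable tail.

    The rip releases DNA symmetrically from both ends while the spool rotates
    ~180 deg; the rotation is extension-neutral, so the released bp follow
    from the WLC inversion of ``delta_x`` at the rip force.  The final state
    relaxes by bookkeeping to ``post_rip_wrapped_bp`` (noncooperative release
    not visible as an event).
    """
    start = geometry.total_wrap_bp - geometry.low_force_release_bp
    released = round(bp_from_delta_extension(delta_x, force, wlc))
    if released > start:
        raise ValueError("delta_x implies releasing more DNA than is wrapped")
    remaining = start - released
    tail = remaining - geometry.post_rip_wrapped_bp
    path = AnnotatedPathway()
    path.add(5, start, 0.0, 0.0, force)
    path.add(6, start - released / 2.0, 0.0, delta_x / 2.0, force)
    path.add(7, remaining, 0.0, delta_x / 2.0, force)
    # state 8: noncooperative tail, represented as bookkeeping only
    tail_dx = wlc_extension(force, max(tail, 0) * wlc.rise_per_bp, wlc) if tail > 0 else 0.0
    path.add(8, geometry.post_rip_wrapped_bp, 0.0, tail_dx, force)
    path.released_bp = released
    path.remaining_bp = remaining
    return path


def end_state_deficit(bp_wrapped: float, force: float = MEAN_RIP_FORCE,
                      geometry: SpoolGeometry = SpoolGeometry(),
                      wlc: WLCParams = WLCParams()) -> float:
    """Predicted end-to-end deficit of a partially wrapped particle vs bare DNA.

    The wrapped contour is sequestered (shortening the free DNA by its WLC
    extension at ``force``) but the particle still spans its aligned
    entry-exit chord, which is returned to the tether:

        deficit = wlc_extension(bp * rise, F) - chord(bp)
    """
    return (wlc_extension(force, bp_wrapped * wlc.rise_per_bp, wlc)
            - chord_length(geometry, bp_wrapped))


# ---------------------------------------------------------------------------
# spherical geometric model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BpEstimate:
    """Integer bp estimate with a 1-sigma uncertainty in bp."""

    value: int
    sigma: float

    def __iter__(self):
        return iter((self.value, self.sigma))


def sphere_chord(geometry: SpoolGeometry, bp_wrapped: float,
                 radius: float | None = None) -> float:
    """Entry-exit chord across the effective sphere for a given wrap."""
    r = geometry.effective_sphere_radius if radius is None else radius
    if r == 0.0:
        return 0.0
    arc = bp_wrapped * 0.34  # arc stored on the sphere, nm (B-form contour)
    return 2.0 * r * abs(math.sin(arc / (2.0 * r)))


def sphere_delta_x(released_bp: float, force: float,
                   geometry: SpoolGeometry = SpoolGeometry(),
                   wlc: WLCParams = WLCParams(),
                   wrapped_before: float | None = None) -> float:
    """Predicted extension change for releasing ``released_bp`` off the sphere."""
    if wrapped_before is None:
        wrapped_before = geometry.total_wrap_bp - geometry.low_force_release_bp
    u = wlc_relative_extension(force, wlc)
    return (released_bp * wlc.rise_per_bp * u
            + sphere_chord(geometry, wrapped_before - released_bp)
            - sphere_chord(geometry, wrapped_before))


def sphere_bp_from_delta_x(delta_x: float, force: float,
                           geometry: SpoolGeometry = SpoolGeometry(),
                           wlc: WLCParams = WLCParams(),
                           wrapped_before: float | None = None,
                           delta_x_sd: float = 1.6) -> BpEstimate:
    """Invert the sphere model: integer bp whose predicted delta-x is closest.

    ``delta_x_sd`` (nm) propagates a measurement SD to bp through the local
    WLC slope; the default is the ensemble SD of the high-force rip.
    """
    if delta_x <= 0 or force <= 0:
        raise ValueError("delta_x and force must be > 0")
    if wrapped_before is None:
        wrapped_before = geometry.total_wrap_bp - geometry.low_force_release_bp
    if delta_x > sphere_delta_x(wrapped_before, force, geometry, wlc, wrapped_before):
        raise ValueError("delta_x exceeds the full-release prediction")
    n = np.arange(0, int(wrapped_before) + 1)
    pred = np.array([sphere_delta_x(ni, force, geometry, wlc, wrapped_before)
                     for ni in n])
    best = int(n[np.argmin(np.abs(pred - delta_x))])
    u = wlc_relative_extension(force, wlc)
    return BpEstimate(best, delta_x_sd / (wlc.rise_per_bp * u))


def sphere_bp_remaining_from_offset(offset: float, force: float = MEAN_RIP_FORCE,
                                    geometry: SpoolGeometry = SpoolGeometry(),
                                    wlc: WLCParams = WLCParams(),
                                    offset_sd: float = 0.6) -> BpEstimate:
    """Wrapped bp whose sequestration, net of the sphere chord, equals ``offset``.

    ``offset`` is the end-to-end deficit of the particle curve relative to
    bare DNA at ``force`` (> 30 pN in the measurements).
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    u = wlc_relative_extension(force, wlc)

    def predicted(m: float) -> float:
        return m * wlc.rise_per_bp * u - sphere_chord(geometry, m)

    if offset > predicted(geometry.total_wrap_bp):
        raise ValueError("offset exceeds the full-wrap prediction")
    m = np.arange(0, geometry.total_wrap_bp + 1)
    pred = np.array([predicted(mi) for mi in m])
    best = int(m[np.argmin(np.abs(pred - offset))])
    return BpEstimate(best, offset_sd / (wlc.rise_per_bp * u))


def calibrate_sphere_radius(geometry: SpoolGeometry = SpoolGeometry(),
                            wlc: WLCParams = WLCParams(),
                            anchor_bp: int = 43, anchor_deficit: float = 6.2,
                            force: float = MEAN_RIP_FORCE) -> float:
    """Effective sphere radius from the end-state consistency constraint.

    Solves  2 R sin(anchor_bp * 0.34 / 2R) = wlc_extension(anchor_bp) -
    anchor_deficit,  i.e. the sphere chord of the mechanical-model end state
    must equal the free-contour extension minus the predicted deficit.
    """
    target = wlc_extension(force, anchor_bp * wlc.rise_per_bp, wlc) - anchor_deficit

    def f(r: float) -> float:
        return sphere_chord(geometry, anchor_bp, radius=r) - target

    return float(brentq(f, 1.0, 10.0, xtol=1e-9))


def with_calibrated_sphere(geometry: SpoolGeometry = SpoolGeometry(),
                           wlc: WLCParams = WLCParams()) -> SpoolGeometry:
    """Geometry with ``effective_sphere_radius`` recomputed from the anchor."""
    return replace(geometry,
                   effective_sphere_radius=calibrate_sphere_radius(geometry, wlc))
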