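"""Shared trace and event containers.

All instrument channels are plain numpy arrays wrapped in small dataclasses;
the TSV interchange schema (time_s, force_pN, extension_nm, direction, cycle
[, donor_counts, acceptor_counts]) maps onto these 1:1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PULLING = "pulling"
RELAXATION = "relaxation"


@dataclass
class ForceExtensionTrace:
    """Synchronised force and extension channels at uniform sampling."""

    time: np.ndarray         # s
    force: np.ndarray        # pN
    extension: np.ndarray    # nm
    direction: str = PULLING
    cycle_index: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if not (len(self.time) == len(self.force) == len(self.extension)):
            raise ValueError("channels must have equal length")
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.direction not in (PULLING, RELAXATION):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class FluorescenceTrace:
    """Donor/acceptor photon counts in fixed (10 ms) bins."""

    time: np.ndarray
    donor_counts: np.ndarray
    acceptor_counts: np.ndarray
    fret_e: np.ndarray | None = None   # filled by fret.compute_fret

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.donor_counts = np.asarray(self.donor_counts, dtype=float)
        self.acceptor_counts = np.asarray(self.acceptor_counts, dtype=float)
        if not (len(self.time) == len(self.donor_counts) == len(self.acceptor_counts)):
            raise ValueError("channels must have equal length")
        if np.any(self.donor_counts < 0) or np.any(self.acceptor_counts < 0):
            raise ValueError("photon counts must be >= 0")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class TransitionEvent:
    """A detected (or ground-truth) rip/zip/noncooperative transition."""

    kind: str                 # cooperative | noncooperative | mixed
    direction: str            # unwrap | rewrap
    force: float              # pN at midpoint
    delta_x: float            # nm, always > 0
    t_event: float            # s
    hopping: bool = False

    def __post_init__(self) -> None:
        if self.delta_x <= 0:
            raise ValueError("delta_x must be > 0")
        if self.force <= 0:
            raise ValueError("force must be > 0")
        if self.kind not in ("cooperative", "noncooperative", "mixed"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.direction not in ("unwrap", "rewrap"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class SpeciesCall:
    """Classification of a pulling trace with its supporting evidence."""

    label: str
    evidence: list[TransitionEvent] = field(default_factory=list)
    residual_offset_nm: float | None = None
    ambiguous: bool = False


@dataclass
class GroundTruth:
    """Per-cycle generator ground truth, consistent with the emitted traces."""

    species: str
    events: list[TransitionEvent] = field(default_factory=list)
    zip_events: list[TransitionEvent] = field(default_factory=list)
    rip_force: float | None = None
    rip_delta_x: float | None = None
    rip_time: float | None = None
    released_bp: float = 0.0
    lf_kind: str | None = None          # noncooperative | cooperative | mixed
    lf_onset_force: float | None = None
    lf_end_force: float | None = None
    lf_delta_x: float | None = None
    unwrap_start_time: float | None = None  # first actual bp release (FRET-visible)
    fret_drop_time: float | None = None
    fret_recovery_time: float | None = None
    recovery_zip_index: int | None = None
    ejection_delay: float | None = None
    rewrap_case: str | None = None
    sequestered_contour_nm: float = 0.0
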