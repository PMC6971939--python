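"""Retrospective cardiac binning of acquired events into k-t masks.

Events are assigned to cardiac frames by their time distance to the
preceding ECG R-top ("absolute" binning: a fixed frame duration derived
from the nominal RR interval, not stretched per beat).  Events landing
beyond the nominal cycle — the tail of long heartbeats — are rejected.
Each flow-encoding segment is binned independently.  The resulting
boolean mask over (k_y, k_z, frame, segment), together with its
sample-count companion, defines the support of the undersampling Fourier
operator used by the reconstruction; duplicate acquisitions of the same
(profile, frame, segment) cell are merged by count and averaged later.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .trajectory import N_FLOW_SEGMENTS, SamplingSchedule

__all__ = [
    "CardiacTimeline",
    "BinningConfig",
    "KTMask",
    "REJECTED",
    "assign_frame",
    "assign_frames",
    "build_kt_mask",
    "effective_R",
]

#: sentinel frame index for events that cannot be binned
REJECTED = -1


@dataclass(frozen=True)
class CardiacTimeline:
    """Strictly increasing R-top times (ms) plus the nominal RR interval."""

    r_top_times: np.ndarray
    nominal_rr: float

    def __post_init__(self) -> None:
        t = np.asarray(self.r_top_times, dtype=float)
        object.__setattr__(self, "r_top_times", t)
        if t.size < 2:
            raise ValueError("timeline needs at least 2 R-tops")
        if np.any(np.diff(t) <= 0):
            raise ValueError("R-top times must be strictly increasing")
        if self.nominal_rr <= 0:
            raise ValueError("nominal_rr must be positive")

    @classmethod
    def from_intervals(
        cls, rr_intervals_ms: np.ndarray, nominal_rr: Optional[float] = None, t0: float = 0.0
    ) -> "CardiacTimeline":
        rr = np.asarray(rr_intervals_ms, dtype=float)
        tops = t0 + np.concatenate([[0.0], np.cumsum(rr)])
        return cls(tops, float(nominal_rr if nominal_rr is not None else rr.mean()))


@dataclass(frozen=True)
class BinningConfig:
    """Frame grid for absolute binning.

    ``frame_duration`` defaults to ``nominal_rr / n_card``.  The last
    ``n_discard`` frames systematically receive less data under RR
    variability and are flagged for exclusion from flow-curve analysis
    (they are still reconstructed).
    """

    n_card: int
    frame_duration: float  # ms
    n_discard: int = 2

    def __post_init__(self) -> None:
        if self.n_card < 2:
            raise ValueError("n_card must be >= 2")
        if not 0 <= self.n_discard < self.n_card:
            raise ValueError("n_discard must satisfy 0 <= n_discard < n_card")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive")

    @classmethod
    def from_timeline(
        cls, timeline: CardiacTimeline, n_card: int, n_discard: int = 2
    ) -> "BinningConfig":
        return cls(n_card=n_card, frame_duration=timeline.nominal_rr / n_card,
                   n_discard=n_discard)

    def discard_flags(self) -> np.ndarray:
        """Boolean per-frame flags; True marks an end-diastolic discard frame."""
        flags = np.zeros(self.n_card, dtype=bool)
        if self.n_discard:
            flags[-self.n_discard:] = True
        return flags


def assign_frames(
    t_events: np.ndarray, timeline: CardiacTimeline, config: BinningConfig
) -> np.ndarray:
    """Vectorised absolute binning; returns frame indices with REJECTED = -1.

    frame = floor((t - preceding R-top) / frame_duration), half-open
    interval convention.  Events before the first R-top or with
    frame >= n_card are rejected.
    """
    t = np.asarray(t_events, dtype=float)
    idx = np.searchsorted(timeline.r_top_times, t, side="right") - 1
    valid = idx >= 0
    prev = timeline.r_top_times[np.clip(idx, 0, None)]
    frame = np.floor((t - prev) / config.frame_duration).astype(np.int64)
    frame[~valid] = REJECTED
    frame[frame >= config.n_card] = REJECTED
    return frame


def assign_frame(
    t_event: float, timeline: CardiacTimeline, config: BinningConfig
) -> int:
    """Scalar convenience wrapper around :func:`assign_frames`."""
    return int(assign_frames(np.array([t_event]), timeline, config)[0])


@dataclass
class KTMask:
    """Sampling counts and derived boolean mask over (ky, kz, frame, segment)."""

    counts: np.ndarray  # uint32, shape (n_ky, n_kz, n_card, n_flow)
    n_rejected: int = 0
    discard_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def mask(self) -> np.ndarray:
        return self.counts > 0

    @property
    def shape(self):
        return self.counts.shape

    @property
    def n_accepted(self) -> int:
        return int(self.counts.sum())


def build_kt_mask(
    schedule: SamplingSchedule, timeline: CardiacTimeline, config: BinningConfig
) -> KTMask:
    """Bin all schedule events into a (ky, kz, frame, segment) count volume.

    Each accepted event increments the count at its cell; the boolean
    mask is ``counts > 0``.  Raises if no event overlaps the timeline.
    """
    ky, kz, seg, t = schedule.event_arrays()
    frames = assign_frames(t, timeline, config)
    ok = frames != REJECTED
    if not np.any(ok):
        raise ValueError("schedule and cardiac timeline do not overlap")
    iy = ky[ok] + schedule.matrix_ky // 2
    iz = kz[ok] + schedule.matrix_kz // 2
    counts = np.zeros(
        (schedule.matrix_ky, schedule.matrix_kz, config.n_card, N_FLOW_SEGMENTS),
        dtype=np.uint32,
    )
    np.add.at(counts, (iy, iz, frames[ok], seg[ok]), 1)
    return KTMask(
        counts=counts,
        n_rejected=int((~ok).sum()),
        discard_flags=config.discard_flags(),
    )


def effective_R(mask: KTMask) -> float:
    """Retrospective acceleration: grid size over number of sampled cells."""
    n_true = int(mask.mask.sum())
    if n_true == 0:
        raise ValueError("mask has no sampled entries")
    return mask.mask.size / n_true


def save_mask_nifti(mask: KTMask, path: str, voxel_size: float = 1.0) -> None:
    """Export the sample counts as a 4D integer NIfTI volume.

    Axes are (k_y, k_z, frame, flow segment); useful for inspecting the
    per-frame incoherence of the binned sampling pattern.
    """
    import nibabel as nib
    import numpy as _np

    affine = _np.diag([voxel_size, voxel_size, 1.0, 1.0])
    nib.save(nib.Nifti1Image(mask.counts.astype(_np.int32), affine), path)
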