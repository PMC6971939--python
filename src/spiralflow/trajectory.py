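"""Pseudo-spiral Cartesian sampling-schedule design.

A 4D-flow acquisition subsamples the two phase-encode directions
(k_y, k_z); the readout direction k_x is always fully sampled and is
abstracted away here.  Profiles — (k_y, k_z) coordinate pairs — are laid
out along quadratic spiral arms, ``r(phi) = phi**2`` with ``phi`` running
linearly from 0 to ``2*pi*l``, gridded onto the Cartesian phase-encode
matrix.  Successive arms are rotated by a tiny golden angle, which yields
a variable-density pattern with a fully sampled centre and incoherent
coverage when combined with retrospective cardiac binning.

Every profile is acquired four times in a row (reference + three
velocity-encoding segments) before moving to the next profile, so one
profile occupies 4 TR of scan time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, TextIO, Tuple, Union

import numpy as np

GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0

#: number of flow-encoding segments (1 reference + 3 velocity-encoded)
N_FLOW_SEGMENTS = 4

__all__ = [
    "SpiralParams",
    "SamplingSchedule",
    "AccelerationSpec",
    "tiny_golden_angle",
    "spiral_arm",
    "build_schedule",
    "acceleration_factor",
    "export_profiles",
    "import_profiles",
    "ProfileParseError",
]


def tiny_golden_angle(order: int) -> float:
    """Return the tiny golden angle of the given order, in degrees.

    The sequence ``180 / (tau + order - 1)`` with ``tau`` the golden
    ratio generalises the golden angle 111.25 deg (order 1) to smaller
    increments; order 7 gives the 23.63 deg increment used for rotating
    successive pseudo-spiral arms.
    """
    if not isinstance(order, (int, np.integer)) or order < 1:
        raise ValueError(f"order must be a positive integer, got {order!r}")
    return 180.0 / (GOLDEN_RATIO + order - 1)


@dataclass(frozen=True)
class SpiralParams:
    """Geometry of one pseudo-spiral arm on the phase-encode grid.

    Parameters
    ----------
    matrix_ky, matrix_kz:
        Even phase-encode matrix sizes (number of grid points along
        k_y and k_z).
    n_readouts:
        Number of Cartesian readouts per arm (``n``).
    n_turns:
        Number of spiral turns (``l``).
    angle_increment:
        Arm-to-arm rotation in degrees; defaults to the order-7 tiny
        golden angle (23.63 deg).
    """

    matrix_ky: int
    matrix_kz: int
    n_readouts: int = 100
    n_turns: int = 3
    angle_increment: float = field(default_factory=lambda: tiny_golden_angle(7))

    def __post_init__(self) -> None:
        if self.n_readouts < 2:
            raise ValueError("n_readouts must be >= 2")
        if self.n_turns < 1:
            raise ValueError("n_turns must be >= 1")
        if not 0.0 < self.angle_increment < 360.0:
            raise ValueError("angle_increment must lie in (0, 360) degrees")
        for name in ("matrix_ky", "matrix_kz"):
            m = getattr(self, name)
            if m < 4 or m % 2:
                raise ValueError(f"{name} must be even and >= 4, got {m}")


def _round_half_toward_zero(x: np.ndarray) -> np.ndarray:
    """Nearest-integer rounding with exact halves pulled toward zero."""
    return np.copysign(np.ceil(np.abs(x) - 0.5), x).astype(np.int64)


def spiral_arm(params: SpiralParams, arm_index: int) -> np.ndarray:
    """Grid one pseudo-spiral arm; returns an (n_readouts, 2) int array.

    The angle phi is sampled at ``n_readouts`` uniformly spaced values on
    [0, 2*pi*l] (endpoints included) and the radius follows
    ``r = phi**2``, normalised so that the final point reaches
    ``matrix_ky/2 - 1`` grid units.  The whole arm is rotated by
    ``arm_index * angle_increment`` (accumulated modulo 360 deg).  For
    asymmetric matrices the k_z coordinate is rescaled by the ratio of
    the half-matrix sizes before rounding to the integer grid; rounded
    points falling outside the zero-centred index range are clamped.
    """
    if arm_index < 0:
        raise ValueError("arm_index must be >= 0")
    phi = np.linspace(0.0, 2.0 * np.pi * params.n_turns, params.n_readouts)
    r = phi**2
    r_max = params.matrix_ky / 2 - 1
    r *= r_max / r[-1]
    rot = np.deg2rad((arm_index * params.angle_increment) % 360.0)
    ky = r * np.cos(phi + rot)
    # asymmetric matrices: rescale kz by the ratio of the largest positive
    # indices so the gridded arm spans exactly the valid range on both axes
    kz = r * np.sin(phi + rot) * (params.matrix_kz / 2 - 1) / (params.matrix_ky / 2 - 1)
    iy = _round_half_toward_zero(ky)
    iz = _round_half_toward_zero(kz)
    iy = np.clip(iy, -params.matrix_ky // 2, params.matrix_ky // 2 - 1)
    iz = np.clip(iz, -params.matrix_kz // 2, params.matrix_kz // 2 - 1)
    return np.stack([iy, iz], axis=1)


@dataclass(frozen=True)
class AccelerationSpec:
    """Bookkeeping for the acceleration factor R = N_fully / N_undersampled."""

    n_ky: int
    n_kz: int
    n_card: int
    n_flow: int = N_FLOW_SEGMENTS

    @property
    def n_fully(self) -> int:
        return self.n_ky * self.n_kz * self.n_card * self.n_flow


def acceleration_factor(spec: AccelerationSpec, n_undersampled: int) -> float:
    """Acceleration factor R of an undersampled scan relative to full sampling."""
    if n_undersampled < 1:
        raise ValueError("n_undersampled must be >= 1")
    return spec.n_fully / n_undersampled


@dataclass(frozen=True)
class SamplingSchedule:
    """Acquisition-ordered sampling schedule.

    ``ky``/``kz`` hold one entry per (k_y,k_z)-profile in acquisition
    order.  Each profile expands to four consecutive flow-segment events
    (reference, x, y, z) of one TR each; event timestamps therefore run
    in strict TR steps from scan start.
    """

    ky: np.ndarray
    kz: np.ndarray
    arm_index: np.ndarray
    matrix_ky: int
    matrix_kz: int
    tr: float = 8.9  # ms

    @property
    def n_profiles(self) -> int:
        return len(self.ky)

    @property
    def n_events(self) -> int:
        return self.n_profiles * N_FLOW_SEGMENTS

    def event_arrays(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return per-event (ky, kz, flow_segment, time_ms) arrays."""
        ky = np.repeat(self.ky, N_FLOW_SEGMENTS)
        kz = np.repeat(self.kz, N_FLOW_SEGMENTS)
        seg = np.tile(np.arange(N_FLOW_SEGMENTS), self.n_profiles)
        t = np.arange(self.n_events) * self.tr
        return ky, kz, seg, t

    @property
    def duration_ms(self) -> float:
        return self.n_events * self.tr


def build_schedule(
    params: SpiralParams,
    spec: AccelerationSpec,
    tr: float = 8.9,
    r_target: float = 10.0,
) -> SamplingSchedule:
    """Emit whole spiral arms until the readout budget for R_target is met.

    Arms are appended in tiny-golden-angle order; the schedule stops at
    the first arm for which the total readout count
    (profiles x N_flow) reaches ``N_fully / R_target``, so the realised
    acceleration differs from the target by at most one arm's quantum.
    Fully deterministic.
    """
    if r_target < 1:
        raise ValueError("r_target must be >= 1")
    if spec.n_ky != params.matrix_ky or spec.n_kz != params.matrix_kz:
        raise ValueError("AccelerationSpec matrix must match SpiralParams matrix")
    budget = spec.n_fully / r_target
    ky_parts: List[np.ndarray] = []
    kz_parts: List[np.ndarray] = []
    arm_parts: List[np.ndarray] = []
    n_readouts_total = 0
    arm = 0
    while n_readouts_total < budget:
        pts = spiral_arm(params, arm)
        ky_parts.append(pts[:, 0])
        kz_parts.append(pts[:, 1])
        arm_parts.append(np.full(len(pts), arm, dtype=np.int64))
        n_readouts_total += len(pts) * spec.n_flow
        arm += 1
    return SamplingSchedule(
        ky=np.concatenate(ky_parts),
        kz=np.concatenate(kz_parts),
        arm_index=np.concatenate(arm_parts),
        matrix_ky=params.matrix_ky,
        matrix_kz=params.matrix_kz,
        tr=tr,
    )


class ProfileParseError(ValueError):
    """Raised when a profile text file contains a malformed line."""


def export_profiles(schedule: SamplingSchedule, out: Union[str, TextIO]) -> None:
    """Write the acquisition-ordered profile list as 'ky kz' text lines."""
    lines = [f"{y} {z}" for y, z in zip(schedule.ky, schedule.kz)]
    text = "\n".join(lines) + "\n"
    if hasattr(out, "write"):
        out.write(text)  # type: ignore[union-attr]
    else:
        with open(out, "w", encoding="utf-8") as fh:
            fh.write(text)


def import_profiles(source: Union[str, TextIO, Iterable[str]]) -> np.ndarray:
    """Parse a profile text file back into an (n, 2) integer array.

    Lines starting with '#' and blank lines are ignored.  A line that is
    not exactly two integers raises :class:`ProfileParseError` naming the
    1-based line number.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()  # type: ignore[union-attr]
    elif isinstance(source, str) and "\n" not in source:
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = list(source)
    profiles: List[Tuple[int, int]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ProfileParseError(
                f"line {lineno}: expected two integers, got {raw!r}"
            )
        try:
            profiles.append((int(parts[0]), int(parts[1])))
        except ValueError as exc:
            raise ProfileParseError(
                f"line {lineno}: expected two integers, got {raw!r}"
            ) from exc
    return np.asarray(profiles, dtype=np.int64).reshape(-1, 2)
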