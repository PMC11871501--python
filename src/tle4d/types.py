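"""Core data containers for 4D respiratory studies.

Coordinate convention used throughout the package:

* Patient axes are (LR, AP, SI) — left-right, anterior-posterior,
  superior-inferior — always in millimetres, always in that order.
* A :class:`VoxelMask` stores its occupancy grid with array axis 0 = LR,
  axis 1 = AP, axis 2 = SI.  The ``origin`` is the physical coordinate of
  the *center* of voxel index (0, 0, 0); voxel index ``i`` maps to
  ``origin + i * spacing`` (center-of-voxel semantics, as in NIfTI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Point3D",
    "PhaseSet",
    "MarkerTrack",
    "VoxelMask",
    "FourDStudy",
    "AXIS_NAMES",
]

AXIS_NAMES = ("LR", "AP", "SI")


@dataclass(frozen=True)
class Point3D:
    """A position or displacement in patient axes, in millimetres."""

    lr_mm: float
    ap_mm: float
    si_mm: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError(f"Point3D components must be finite, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.lr_mm, self.ap_mm, self.si_mm], dtype=float)

    @classmethod
    def from_array(cls, a: Iterable[float]) -> "Point3D":
        lr, ap, si = (float(x) for x in a)
        return cls(lr, ap, si)

    def __add__(self, other: "Point3D") -> "Point3D":
        return Point3D.from_array(self.as_array() + other.as_array())

    def __sub__(self, other: "Point3D") -> "Point3D":
        return Point3D.from_array(self.as_array() - other.as_array())

    def __neg__(self) -> "Point3D":
        return Point3D(-self.lr_mm, -self.ap_mm, -self.si_mm)


def _default_phase_labels() -> tuple[str, ...]:
    return tuple(f"{10 * i}%" for i in range(10))


@dataclass(frozen=True)
class PhaseSet:
    """Ordered respiratory phase labels and the index of the reference phase.

    The default is the standard 10-bin phase sorting (0%, 10%, ..., 90%)
    with the 30% phase as the reference (planning) phase.
    """

    labels: tuple[str, ...] = field(default_factory=_default_phase_labels)
    reference_index: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 2:
            raise ValueError("PhaseSet needs at least 2 phases")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"phase labels must be distinct: {self.labels}")
        if not (0 <= self.reference_index < len(self.labels)):
            raise ValueError(
                f"reference_index {self.reference_index} out of range for "
                f"{len(self.labels)} phases"
            )

    @property
    def n_phases(self) -> int:
        return len(self.labels)

    @property
    def reference_label(self) -> str:
        return self.labels[self.reference_index]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown phase label {label!r}; have {self.labels}") from None

    def non_reference_indices(self) -> list[int]:
        return [i for i in range(self.n_phases) if i != self.reference_index]


@dataclass(frozen=True)
class MarkerTrack:
    """One fiducial marker's centroid position at every respiratory phase."""

    marker_id: str
    positions: tuple[Point3D, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(self.positions))

    def as_array(self) -> np.ndarray:
        """Positions as an (n_phases, 3) array in (LR, AP, SI) order."""
        return np.array([p.as_array() for p in self.positions])


@dataclass(frozen=True)
class VoxelMask:
    """A binary structure on a regular axis-aligned voxel grid.

    ``occupancy`` has shape ``shape`` with axes (LR, AP, SI); ``origin`` is
    the physical center of voxel (0, 0, 0) and ``spacing`` the per-axis
    voxel size in mm.
    """

    origin: Point3D
    spacing: tuple[float, float, float]
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if occ.ndim != 3:
            raise ValueError(f"occupancy must be 3-D, got shape {occ.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive on all axes: {self.spacing}")
        if any(n < 1 for n in occ.shape):
            raise ValueError(f"grid shape must be >= 1 on all axes: {occ.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape  # type: ignore[return-value]

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        return self.n_occupied * self.voxel_volume_mm3

    def spacing_array(self) -> np.ndarray:
        return np.array(self.spacing, dtype=float)

    def same_grid(self, other: "VoxelMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_array(), other.spacing_array(), atol=atol)
            and np.allclose(self.origin.as_array(), other.origin.as_array(), atol=atol)
        )

    def occupied_centers_mm(self) -> np.ndarray:
        """Physical coordinates of occupied-voxel centers, shape (n, 3)."""
        idx = np.argwhere(self.occupancy)
        return self.origin.as_array() + idx * self.spacing_array()

    def with_occupancy(self, occ: np.ndarray) -> "VoxelMask":
        return VoxelMask(self.origin, self.spacing, occ)


@dataclass(frozen=True)
class FourDStudy:
    """One patient's 4D study: per-phase GTV masks plus marker tracks.

    Invariants enforced at construction: all masks share one grid, every
    marker track has exactly one position per phase, and there are at
    least two markers (single-marker tracking is out of scope by default).
    """

    patient_id: str
    phases: PhaseSet
    gtv_masks: tuple[VoxelMask, ...]
    markers: tuple[MarkerTrack, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gtv_masks", tuple(self.gtv_masks))
        object.__setattr__(self, "markers", tuple(self.markers))
        n = self.phases.n_phases
        if len(self.gtv_masks) != n:
            raise ValueError(
                f"study {self.patient_id!r}: {len(self.gtv_masks)} masks for {n} phases"
            )
        ref = self.gtv_masks[0]
        for i, m in enumerate(self.gtv_masks[1:], start=1):
            if not ref.same_grid(m):
                raise ValueError(
                    f"study {self.patient_id!r}: mask for phase "
                    f"{self.phases.labels[i]!r} is not on the shared grid"
                )
        if len(self.markers) < 2:
            raise ValueError(
                f"study {self.patient_id!r}: needs >= 2 markers, got {len(self.markers)}"
            )
        ids = [t.marker_id for t in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError(f"study {self.patient_id!r}: duplicate marker ids {ids}")
        for t in self.markers:
            if len(t.positions) != n:
                raise ValueError(
                    f"study {self.patient_id!r}: marker {t.marker_id!r} has "
                    f"{len(t.positions)} positions for {n} phases"
                )

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(t.marker_id for t in self.markers)

    @property
    def reference_mask(self) -> VoxelMask:
        return self.gtv_masks[self.phases.reference_index]

    def marker(self, marker_id: str) -> MarkerTrack:
        for t in self.markers:
            if t.marker_id == marker_id:
                return t
        raise KeyError(
            f"study {self.patient_id!r} has no marker {marker_id!r}; "
            f"have {self.marker_ids}"
        )


def as_point_sequence(points: Sequence[Point3D] | np.ndarray) -> np.ndarray:
    """Coerce a sequence of Point3D (or an (n, 3) array) to an (n, 3) array."""
    if isinstance(points, np.ndarray):
        a = np.asarray(points, dtype=float)
        if a.ndim != 2 or a.shape[1] != 3:
            raise ValueError(f"expected (n, 3) array, got shape {a.shape}")
        return a
    return np.array([p.as_array() for p in points])
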