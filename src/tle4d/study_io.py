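"""Reading and writing 4D study inputs.

A study on disk is a YAML manifest pointing at one volumetric mask file per
respiratory phase (NRRD or NIfTI, mm spacing) and one CSV of fiducial-marker
centroid tracks.  The manifest also declares how the mask file's array axes
map onto the patient (LR, AP, SI) axes — per-direction results make a silent
axis permutation the most dangerous failure mode, so the mapping is never
inferred from headers.

Marker-track CSV schema::

    patient_id,phase_label,marker_id,lr_mm,ap_mm,si_mm
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import yaml

from .types import AXIS_NAMES, FourDStudy, MarkerTrack, PhaseSet, Point3D, VoxelMask

__all__ = [
    "StudyIOError",
    "read_marker_tracks",
    "write_marker_tracks",
    "read_phase_mask",
    "write_phase_mask",
    "mask_centroid",
    "load_study",
    "save_study",
    "apply_axis_mapping",
]

TRACK_COLUMNS = ("patient_id", "phase_label", "marker_id", "lr_mm", "ap_mm", "si_mm")


class StudyIOError(ValueError):
    """Malformed or incomplete study input."""


# ---------------------------------------------------------------------------
# Marker tracks (CSV)
# ---------------------------------------------------------------------------

def read_marker_tracks(
    path: str | Path,
    phases: PhaseSet,
    patient_id: str | None = None,
) -> list[MarkerTrack]:
    """Read fiducial-marker centroid tracks from CSV.

    Every (phase, marker) pair must be present; a missing pair raises
    :class:`StudyIOError` naming the gap, and a non-numeric coordinate
    raises with its row number.  Tracks are returned ordered by marker id
    with positions ordered by ``phases``.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(TRACK_COLUMNS) <= set(reader.fieldnames):
            raise StudyIOError(
                f"{path}: expected columns {TRACK_COLUMNS}, got {reader.fieldnames}"
            )
        positions: dict[tuple[str, str], Point3D] = {}
        patients_seen: set[str] = set()
        for row_no, row in enumerate(reader, start=2):  # row 1 is the header
            pid = row["patient_id"]
            if patient_id is not None and pid != patient_id:
                continue
            patients_seen.add(pid)
            coords = []
            for col in ("lr_mm", "ap_mm", "si_mm"):
                try:
                    coords.append(float(row[col]))
                except (TypeError, ValueError):
                    raise StudyIOError(
                        f"{path} row {row_no}: non-numeric {col}={row[col]!r}"
                    ) from None
            key = (row["marker_id"], row["phase_label"])
            if key in positions:
                raise StudyIOError(
                    f"{path} row {row_no}: duplicate entry for marker "
                    f"{key[0]!r} phase {key[1]!r}"
                )
            positions[key] = Point3D(*coords)
    if len(patients_seen) > 1:
        raise StudyIOError(
            f"{path}: multiple patient_ids {sorted(patients_seen)}; pass patient_id="
        )
    if not positions:
        raise StudyIOError(f"{path}: no rows" + (f" for patient {patient_id!r}" if patient_id else ""))

    marker_ids = sorted({m for m, _ in positions})
    missing = [
        (m, lab)
        for m in marker_ids
        for lab in phases.labels
        if (m, lab) not in positions
    ]
    if missing:
        gaps = ", ".join(f"({m}, {lab})" for m, lab in missing[:5])
        raise StudyIOError(
            f"{path}: missing (marker, phase) pairs: {gaps}"
            + ("..." if len(missing) > 5 else "")
        )
    return [
        MarkerTrack(m, tuple(positions[(m, lab)] for lab in phases.labels))
        for m in marker_ids
    ]


def write_marker_tracks(
    path: str | Path,
    tracks: Sequence[MarkerTrack],
    phases: PhaseSet,
    patient_id: str,
) -> Path:
    """Write marker tracks to CSV with full float precision (repr round-trip)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRACK_COLUMNS)
        for track in tracks:
            for lab, pos in zip(phases.labels, track.positions):
                writer.writerow(
                    [patient_id, lab, track.marker_id,
                     repr(pos.lr_mm), repr(pos.ap_mm), repr(pos.si_mm)]
                )
    return path


# ---------------------------------------------------------------------------
# Phase masks (NRRD / NIfTI)
# ---------------------------------------------------------------------------

def read_phase_mask(path: str | Path) -> VoxelMask:
    """Read a binary structure mask from NRRD or NIfTI.

    Any nonzero voxel is treated as occupied.  The file's array axes are
    taken as-is (axis 0, 1, 2); apply :func:`apply_axis_mapping` afterwards
    if the file axes are not already (LR, AP, SI).
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        affine = img.affine
        rot = affine[:3, :3]
        if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
            raise StudyIOError(
                f"{path}: non-axis-aligned affine; resample before import"
            )
        spacing = np.diag(rot)
        if np.any(spacing <= 0):
            raise StudyIOError(
                f"{path}: non-positive voxel spacing {tuple(spacing)} in affine; "
                "flip to a positive-spacing orientation before import"
            )
        origin = affine[:3, 3]
    elif suffixes.endswith(".nrrd"):
        img = sitk.ReadImage(str(path))
        direction = np.array(img.GetDirection()).reshape(img.GetDimension(), -1)
        if not np.allclose(direction, np.eye(img.GetDimension()), atol=1e-6):
            raise StudyIOError(f"{path}: non-identity direction matrix unsupported")
        # SimpleITK arrays come back (z, y, x); our axis 0 is the file x axis.
        data = np.transpose(sitk.GetArrayFromImage(img))
        spacing = np.array(img.GetSpacing(), dtype=float)
        origin = np.array(img.GetOrigin(), dtype=float)
    else:
        raise StudyIOError(f"{path}: unsupported mask format (use .nrrd, .nii, .nii.gz)")
    if data.ndim != 3:
        raise StudyIOError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return VoxelMask(Point3D.from_array(origin), tuple(spacing), data != 0)


def write_phase_mask(path: str | Path, mask: VoxelMask) -> Path:
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    occ = mask.occupancy.astype(np.uint8)
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.eye(4)
        affine[:3, :3] = np.diag(mask.spacing)
        affine[:3, 3] = mask.origin.as_array()
        nib.save(nib.Nifti1Image(occ, affine), str(path))
    elif suffixes.endswith(".nrrd"):
        img = sitk.GetImageFromArray(np.transpose(occ))
        img.SetSpacing(tuple(float(s) for s in mask.spacing))
        img.SetOrigin(tuple(float(x) for x in mask.origin.as_array()))
        sitk.WriteImage(img, str(path), useCompression=False)
    else:
        raise StudyIOError(f"{path}: unsupported mask format (use .nrrd, .nii, .nii.gz)")
    return path


def apply_axis_mapping(mask: VoxelMask, mapping: Sequence[str]) -> VoxelMask:
    """Permute a mask's array axes so that they become (LR, AP, SI).

    ``mapping`` names the patient axis carried by each *file* axis, e.g.
    ``["AP", "LR", "SI"]`` means file axis 0 is AP.  Identity is
    ``["LR", "AP", "SI"]``.
    """
    mapping = tuple(str(m).upper() for m in mapping)
    if sorted(mapping) != sorted(AXIS_NAMES):
        raise StudyIOError(f"axis mapping must be a permutation of {AXIS_NAMES}: {mapping}")
    # perm[k] = file axis that holds patient axis k
    perm = tuple(mapping.index(name) for name in AXIS_NAMES)
    if perm == (0, 1, 2):
        return mask
    origin = mask.origin.as_array()[list(perm)]
    spacing = tuple(mask.spacing[p] for p in perm)
    return VoxelMask(Point3D.from_array(origin), spacing,
                     np.transpose(mask.occupancy, perm))


def mask_centroid(mask: VoxelMask) -> Point3D:
    """Unweighted mean of occupied-voxel center coordinates, in mm.

    This is the GTV-centroid substrate of the whole analysis: all residuals
    are differences of such centroids.
    """
    if mask.n_occupied == 0:
        raise ValueError("cannot compute the centroid of an empty mask")
    idx_mean = np.argwhere(mask.occupancy).mean(axis=0)
    return Point3D.from_array(mask.origin.as_array() + idx_mean * mask.spacing_array())


# ---------------------------------------------------------------------------
# Study manifests (YAML)
# ---------------------------------------------------------------------------

def load_study(manifest_path: str | Path) -> FourDStudy:
    """Load a complete 4D study from its YAML manifest.

    Manifest keys: ``patient_id``, ``phase_labels``, ``reference_phase``,
    ``mask_paths`` (one per phase label, relative to the manifest),
    ``track_path``, ``axis_mapping`` (optional, default identity).
    """
    manifest_path = Path(manifest_path)
    with manifest_path.open() as fh:
        man = yaml.safe_load(fh)
    for key in ("patient_id", "phase_labels", "reference_phase", "mask_paths", "track_path"):
        if key not in man:
            raise StudyIOError(f"{manifest_path}: manifest missing key {key!r}")
    labels = tuple(str(x) for x in man["phase_labels"])
    ref_label = str(man["reference_phase"])
    if ref_label not in labels:
        raise StudyIOError(
            f"{manifest_path}: reference phase {ref_label!r} not among {labels}"
        )
    phases = PhaseSet(labels, labels.index(ref_label))
    mapping = man.get("axis_mapping", list(AXIS_NAMES))
    base = manifest_path.parent
    mask_paths: Mapping[str, str] = man["mask_paths"]
    masks = []
    for lab in labels:
        if lab not in mask_paths:
            raise StudyIOError(f"{manifest_path}: no mask path for phase {lab!r}")
        masks.append(apply_axis_mapping(read_phase_mask(base / mask_paths[lab]), mapping))
    tracks = read_marker_tracks(base / man["track_path"], phases,
                                patient_id=str(man["patient_id"]))
    return FourDStudy(str(man["patient_id"]), phases, tuple(masks), tuple(tracks))


def save_study(study: FourDStudy, out_dir: str | Path, mask_format: str = "nrrd") -> Path:
    """Write a study's masks, tracks, and manifest under ``out_dir``.

    Returns the manifest path.  ``mask_format`` is ``"nrrd"`` or ``"nii.gz"``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mask_paths = {}
    for lab, mask in zip(study.phases.labels, study.gtv_masks):
        fname = f"{study.patient_id}_phase{lab.rstrip('%')}.{mask_format}"
        write_phase_mask(out_dir / fname, mask)
        mask_paths[lab] = fname
    track_file = f"{study.patient_id}_tracks.csv"
    write_marker_tracks(out_dir / track_file, study.markers, study.phases,
                        study.patient_id)
    manifest = {
        "patient_id": study.patient_id,
        "phase_labels": list(study.phases.labels),
        "reference_phase": study.phases.reference_label,
        "mask_paths": mask_paths,
        "track_path": track_file,
        "axis_mapping": list(AXIS_NAMES),
    }
    manifest_path = out_dir / f"{study.patient_id}_manifest.yaml"
    with manifest_path.open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path
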