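"""Projection of detected disks onto the cord centerline and evaluation.

Detected disks live on the anteriorly shifted curve; the final output labels
the cord itself, so each disk is orthogonally projected onto the centerline
polyline.  Centerline samples between the disk above vertebra n and the disk
below it receive the label n (numeric scheme: 1 = C1 ... 8 = T1 ... 20 = L1);
the stretches rostral of the first disk and caudal of the last disk receive
the adjacent vertebra's index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import Volume
from .levels import disk_name
from .profile import Centerline


@dataclass
class ProjectedDisk:
    """A disk mapped to the cord centerline's arc length."""

    level: int
    arc_mm: float


@dataclass
class LabeledCenterline:
    centerline: Centerline
    labels: np.ndarray  # vertebral index per centerline sample

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.centerline.points):
            raise ValueError("one label per centerline sample required")
        if np.any(np.diff(self.labels) < 0):
            raise ValueError("labels must be non-decreasing rostral to caudal")


def _project_point_to_polyline(
    point: np.ndarray, centerline: Centerline
) -> float:
    """Arc length of the orthogonal foot of ``point`` on the polyline."""
    pts = centerline.points
    a, b = pts[:-1], pts[1:]
    ab = b - a
    seg_len2 = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", point - a, ab) / seg_len2, 0.0, 1.0)
    foot = a + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", point - foot, point - foot)
    i = int(np.argmin(d2))
    seg = centerline.arc_length[i + 1] - centerline.arc_length[i]
    return float(centerline.arc_length[i] + t[i] * seg)


def project_disks(
    disks: list[tuple[int, np.ndarray]], centerline: Centerline
) -> list[ProjectedDisk]:
    """Project disk coordinates (level, xyz mm) onto the centerline.

    The rostral-to-caudal ordering must survive projection; a crossing (two
    disks projecting to the same or inverted arc positions) is an error.
    """
    projected = [
        ProjectedDisk(level=lvl, arc_mm=_project_point_to_polyline(np.asarray(xyz, float), centerline))
        for lvl, xyz in disks
    ]
    for a, b in zip(projected, projected[1:]):
        if b.arc_mm <= a.arc_mm:
            raise ValueError(
                f"projection inverted the disk order: {disk_name(a.level)} at "
                f"{a.arc_mm:.2f} mm vs {disk_name(b.level)} at {b.arc_mm:.2f} mm"
            )
    return projected


def label_centerline(
    centerline: Centerline, projected: list[ProjectedDisk]
) -> LabeledCenterline:
    """Assign a vertebral index to every centerline sample.

    A sample strictly caudal to the disk between vertebrae n and n+1 (and not
    caudal to the next disk) is labeled n+1; samples at or rostral to the
    first disk get the first disk's upper-vertebra label.
    """
    if not projected:
        raise ValueError("need at least one projected disk")
    arcs = np.array([d.arc_mm for d in projected])
    labels = projected[0].level + np.searchsorted(
        arcs, centerline.arc_length, side="left"
    )
    return LabeledCenterline(centerline=centerline, labels=labels.astype(int))


def label_surface(cord_mask: Volume, lc: LabeledCenterline) -> Volume:
    """Label every cord-mask voxel with its nearest centerline sample's label."""
    mask = np.asarray(cord_mask.data) > 0
    if not mask.any():
        raise ValueError("cord mask is empty")
    vox = np.column_stack(np.nonzero(mask))
    world = cord_mask.voxel_to_world(vox)
    _, nearest = cKDTree(lc.centerline.points).query(world)
    out = np.zeros(cord_mask.shape, dtype=np.int16)
    out[mask] = lc.labels[nearest]
    return Volume(data=out, affine=cord_mask.affine)


@dataclass
class EvaluationReport:
    """All-or-nothing labeling accuracy and per-level position errors.

    ``accuracy_pct`` is 100 only if every reference disk level was detected
    and each detected disk lies nearer to its own reference disk than to any
    other (i.e. every vertebra gets its true label); otherwise 0.
    """

    accuracy_pct: float
    abs_error_mm: dict[int, float]

    @property
    def mean_abs_error_mm(self) -> float:
        return float(np.mean(list(self.abs_error_mm.values())))

    @property
    def max_abs_error_mm(self) -> float:
        return float(np.max(list(self.abs_error_mm.values())))


def evaluate(
    detected: list[ProjectedDisk],
    reference_positions_mm: dict[int, float],
) -> EvaluationReport:
    """Score detected disk positions against reference positions.

    ``reference_positions_mm`` maps disk level to arc length on the same
    centerline the detections were projected to.
    """
    det = {d.level: d.arc_mm for d in detected}
    shared = sorted(set(det) & set(reference_positions_mm))
    if not shared:
        raise ValueError("detected and reference level ranges are disjoint")
    ref_levels = sorted(reference_positions_mm)
    ref_pos = np.array([reference_positions_mm[l] for l in ref_levels])
    correct = set(det) >= set(ref_levels)
    for lvl in shared:
        nearest = ref_levels[int(np.argmin(np.abs(ref_pos - det[lvl])))]
        if nearest != lvl:
            correct = False
    errors = {
        lvl: float(abs(det[lvl] - reference_positions_mm[lvl])) for lvl in shared
    }
    return EvaluationReport(
        accuracy_pct=100.0 if correct else 0.0, abs_error_mm=errors
    )
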