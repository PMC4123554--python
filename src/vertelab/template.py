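"""Templates of generic intervertebral disk distances.

A template stores, for each pair of adjacent disks, the mean distance between
them across a set of manually labeled training subjects together with the
across-subject standard deviation.  During detection these generic distances,
rescaled by a subject-specific ratio, predict where the next disk should lie.

A gap is keyed by the numeric index of the upper disk's upper vertebra: the
gap (2, 3) is the distance from the C2-C3 disk to the C3-C4 disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .levels import disk_name, level_index

#: relative SD above which validate_template flags a gap, matching the
#: +/-20% search range used during detection
RELATIVE_SD_REFERENCE = 0.2

TEMPLATE_COLUMNS = ("upper_level", "lower_level", "mean_mm", "sd_mm", "n")


@dataclass
class TemplateGap:
    """Distance between the disk above vertebra pair and the next caudal disk."""

    upper_level: int
    lower_level: int
    mean_mm: float
    sd_mm: float  # NaN when undefined (fewer than 2 subjects)
    n_subjects: int

    def __post_init__(self) -> None:
        if self.lower_level != self.upper_level + 1:
            raise ValueError(
                f"gap {disk_name(self.upper_level)} -> {disk_name(self.lower_level)} "
                "skips a level: lower_level must equal upper_level + 1"
            )
        if not self.mean_mm > 0:
            raise ValueError(
                f"gap {disk_name(self.upper_level)}: mean distance must be positive, "
                f"got {self.mean_mm}"
            )
        if np.isfinite(self.sd_mm) and self.sd_mm < 0:
            raise ValueError(f"gap {disk_name(self.upper_level)}: negative SD")


@dataclass
class DiskTemplate:
    """Ordered, level-contiguous list of generic inter-disk distances."""

    gaps: list[TemplateGap] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gaps:
            raise ValueError("template has no gaps")
        uppers = [g.upper_level for g in self.gaps]
        if any(b != a + 1 for a, b in zip(uppers, uppers[1:])):
            raise ValueError(f"template gaps are not level-contiguous: {uppers}")

    @property
    def first_disk_level(self) -> int:
        return self.gaps[0].upper_level

    @property
    def last_disk_level(self) -> int:
        return self.gaps[-1].lower_level

    @property
    def means(self) -> np.ndarray:
        return np.array([g.mean_mm for g in self.gaps])

    @property
    def min_gap_mm(self) -> float:
        return float(self.means.min())

    def gap_from(self, upper_level: int) -> TemplateGap | None:
        """The gap whose rostral disk is ``upper_level``, or None past the end."""
        i = upper_level - self.first_disk_level
        if 0 <= i < len(self.gaps):
            return self.gaps[i]
        return None

    def span_mm(self, from_level: int, to_level: int) -> float:
        """Sum of generic distances from disk ``from_level`` to disk ``to_level``."""
        if to_level <= from_level:
            raise ValueError("to_level must be caudal to from_level")
        return float(
            sum(
                g.mean_mm
                for g in self.gaps
                if from_level <= g.upper_level < to_level
            )
        )


def build_template(
    labeled_subjects: Sequence[Mapping[int, float]],
) -> DiskTemplate:
    """Build a template from per-subject labeled disk positions.

    Parameters
    ----------
    labeled_subjects : sequence of mappings
        One mapping per subject from disk level (upper-vertebra index) to the
        disk's arc-length position in mm.  Each subject must cover a
        contiguous level range with strictly increasing positions.

    The mean and sample SD (n-1 denominator) of each inter-disk gap are taken
    over the subjects that cover that gap; a gap covered by fewer than two
    subjects gets an undefined (NaN) SD and a warning.
    """
    if len(labeled_subjects) < 1:
        raise ValueError("need at least one labeled subject")
    per_gap: dict[int, list[float]] = {}
    for idx, subject in enumerate(labeled_subjects):
        levels = sorted(int(k) for k in subject)
        if any(b != a + 1 for a, b in zip(levels, levels[1:])):
            raise ValueError(f"subject {idx}: disk levels are not contiguous: {levels}")
        pos = np.array([float(subject[k]) for k in levels])
        if np.any(np.diff(pos) <= 0):
            raise ValueError(
                f"subject {idx}: disk positions are not strictly increasing"
            )
        for u, gap in zip(levels[:-1], np.diff(pos)):
            per_gap.setdefault(u, []).append(float(gap))
    if not per_gap:
        raise ValueError("no subject covers more than one disk")
    gaps = []
    for u in sorted(per_gap):
        vals = per_gap[u]
        if len(vals) < 2:
            warnings.warn(
                f"gap {disk_name(u)} -> {disk_name(u + 1)} covered by "
                f"{len(vals)} subject(s); SD undefined",
                stacklevel=2,
            )
            sd = float("nan")
        else:
            sd = float(np.std(vals, ddof=1))
        gaps.append(
            TemplateGap(
                upper_level=u,
                lower_level=u + 1,
                mean_mm=float(np.mean(vals)),
                sd_mm=sd,
                n_subjects=len(vals),
            )
        )
    return DiskTemplate(gaps=gaps)


def write_template(template: DiskTemplate, path: str | Path) -> None:
    """Write a template as headered CSV (levels as numeric indices)."""
    pd.DataFrame(
        [
            {
                "upper_level": g.upper_level,
                "lower_level": g.lower_level,
                "mean_mm": g.mean_mm,
                "sd_mm": g.sd_mm,
                "n": g.n_subjects,
            }
            for g in template.gaps
        ]
    ).to_csv(path, index=False)


def read_template(path: str | Path) -> DiskTemplate:
    """Read and validate a CSV template file."""
    df = pd.read_csv(path)
    missing = set(TEMPLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"template file {path} missing columns: {sorted(missing)}")
    gaps = []
    for row_number, row in enumerate(df.itertuples(index=False)):
        try:
            gaps.append(
                TemplateGap(
                    upper_level=level_index(row.upper_level),
                    lower_level=level_index(row.lower_level),
                    mean_mm=float(row.mean_mm),
                    sd_mm=float(row.sd_mm),
                    n_subjects=int(row.n),
                )
            )
        except ValueError as exc:
            raise ValueError(f"template file {path}, row {row_number}: {exc}") from exc
    try:
        return DiskTemplate(gaps=gaps)
    except ValueError as exc:
        raise ValueError(f"template file {path}: {exc}") from exc


def validate_template(template: DiskTemplate) -> list[str]:
    """Report (without rejecting) anatomically suspicious template entries.

    Flags gaps that break the expected caudal increase of inter-disk
    distances and gaps whose across-subject SD exceeds 20% of the mean (the
    reference used for the detection search range).
    """
    report: list[str] = []
    for a, b in zip(template.gaps, template.gaps[1:]):
        if b.mean_mm <= a.mean_mm:
            report.append(
                f"gap {disk_name(b.upper_level)} ({b.mean_mm:.1f} mm) does not "
                f"increase over gap {disk_name(a.upper_level)} ({a.mean_mm:.1f} mm)"
            )
    for g in template.gaps:
        if np.isfinite(g.sd_mm) and g.sd_mm > RELATIVE_SD_REFERENCE * g.mean_mm:
            report.append(
                f"gap {disk_name(g.upper_level)}: SD {g.sd_mm:.1f} mm exceeds "
                f"{RELATIVE_SD_REFERENCE:.0%} of the mean ({g.mean_mm:.1f} mm)"
            )
    return report
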