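"""Synthetic spine phantoms with known ground truth.

A phantom is a curved vertebral column (a tube of "body" tissue carrying
raised-cosine disk bumps along its axis) with a spinal cord running 15 mm
posterior to it, embedded in a darker background.  Inter-disk distances
increase caudally.  Optional degradations emulate routine acquisitions: a
low-order multiplicative bias field, additive Gaussian noise, and a
multiplicative signal-dropout slab spanning named vertebral levels (a
metallic-implant-type artifact).  Contrast polarity is switchable: disks are
brighter than vertebral bodies on T2-like images and darker on T1-like
images.

Everything is rendered in RAS world millimetres with the rostral (superior)
end at the top of the field of view; disk positions are expressed as
arc length along the column axis measured from the rostral end, which equals
arc length along the cord centerline (the two curves are translates of each
other).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .io import T1_LIKE, T2_LIKE, Volume
from .levels import disk_name, level_index, level_name
from .profile import Centerline
from .template import DiskTemplate, TemplateGap

# fixed tissue/geometry constants of the phantom (mm and arbitrary units)
BODY_INTENSITY = 100.0
CORD_INTENSITY = 80.0
BACKGROUND_INTENSITY = 10.0
COLUMN_RADIUS_MM = 10.0
CORD_RADIUS_MM = 3.5
CORD_POSTERIOR_OFFSET_MM = 15.0
#: noise SD giving SNR 10 on the vertebral body; also the reference used to
#: convert the disk/body CNR into an absolute contrast for noiseless phantoms
REFERENCE_NOISE_SD = 10.0

#: default disk layout: C2-C3 through T8-T9, gaps growing 1 mm per level
DEFAULT_FIRST_DISK_LEVEL = 2
DEFAULT_FIRST_DISK_MM = 45.0
DEFAULT_GAPS_MM = {u: 16.0 + 1.0 * (u - 2) for u in range(2, 15)}
#: nominal across-subject SD of the default gaps, growing caudally
DEFAULT_GAP_SD_FRACTION = {u: 0.04 + 0.006 * (u - 2) for u in DEFAULT_GAPS_MM}


def default_disk_positions() -> dict[int, float]:
    """Arc-length positions (mm) of the default disks, keyed by disk level."""
    positions = {DEFAULT_FIRST_DISK_LEVEL: DEFAULT_FIRST_DISK_MM}
    for u, gap in sorted(DEFAULT_GAPS_MM.items()):
        positions[u + 1] = positions[u] + gap
    return positions


def default_phantom_template() -> DiskTemplate:
    """The generic-distance template matching the default phantom layout.

    This is a synthetic fixture shipped with the phantom generator, not a
    template measured on subjects; its nominal SDs grow caudally like real
    inter-subject variability does.
    """
    gaps = [
        TemplateGap(
            upper_level=u,
            lower_level=u + 1,
            mean_mm=gap,
            sd_mm=DEFAULT_GAP_SD_FRACTION[u] * gap,
            n_subjects=6,
        )
        for u, gap in sorted(DEFAULT_GAPS_MM.items())
    ]
    return DiskTemplate(gaps=gaps)


@dataclass
class PhantomConfig:
    """Parameters of one synthetic spine volume.

    ``vertebral_contrast`` is the disk/body contrast-to-noise ratio: the
    absolute disk-body intensity difference is ``vertebral_contrast *
    noise_sd`` (or ``vertebral_contrast * REFERENCE_NOISE_SD`` when the
    phantom is noiseless).  ``disk_positions_mm`` maps disk level (upper
    vertebra index) to arc length from the rostral end of the field of view.
    """

    fov_mm: tuple[float, float, float] = (64.0, 96.0, 368.0)
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    disk_positions_mm: dict[int, float] = dataclass_field(
        default_factory=default_disk_positions
    )
    disk_width_mm: float = 4.0
    vertebral_contrast: float = 3.0
    contrast_polarity: str = T2_LIKE
    curvature_amplitude_mm: float = 5.0
    curvature_period_mm: float = 300.0
    bias_field_amplitude: float = 0.2
    noise_sd: float = 10.0
    dropout_levels: frozenset = frozenset()
    dropout_attenuation: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        self.disk_positions_mm = {
            level_index(k): float(v) for k, v in self.disk_positions_mm.items()
        }
        levels = sorted(self.disk_positions_mm)
        if len(levels) < 2:
            raise ValueError("need at least two disks")
        if any(b != a + 1 for a, b in zip(levels, levels[1:])):
            raise ValueError(f"disk levels must be contiguous, got {levels}")
        pos = [self.disk_positions_mm[k] for k in levels]
        if np.any(np.diff(pos) <= 0):
            raise ValueError("disk positions must be strictly increasing caudally")
        if not 0.0 <= self.dropout_attenuation <= 1.0:
            raise ValueError("dropout_attenuation must be in [0, 1]")
        if self.contrast_polarity not in (T1_LIKE, T2_LIKE):
            raise ValueError(f"unknown contrast polarity {self.contrast_polarity!r}")
        self.dropout_levels = frozenset(level_index(l) for l in self.dropout_levels)
        for lvl in sorted(self.dropout_levels):
            if not levels[0] + 1 <= lvl <= levels[-1]:
                raise ValueError(
                    f"dropout level {level_name(lvl)} is not bracketed by the "
                    "simulated disks"
                )

    @property
    def levels(self) -> list[int]:
        return sorted(self.disk_positions_mm)


@dataclass
class GroundTruth:
    """Reference answers for one phantom.

    ``true_disk_positions_mm`` maps disk level to arc length along the cord
    centerline; ``true_labels`` holds the vertebral index of each centerline
    sample; ``cord_mask`` is the binary cord volume the pipeline can extract
    a centerline from.
    """

    true_disk_positions_mm: dict[int, float]
    true_centerline: Centerline
    true_labels: np.ndarray
    cord_mask: Volume


def _column_axis_xy(
    depth_mm: np.ndarray, config: PhantomConfig, fov_xy: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Anteroposterior/mediolateral column-axis position vs rostral depth."""
    a = config.curvature_amplitude_mm
    p = config.curvature_period_mm
    x0 = fov_xy[0] / 2.0
    y0 = fov_xy[1] * 0.625  # leaves room for the cord 15 mm posterior
    xc = x0 + a * np.sin(2.0 * np.pi * depth_mm / p + 1.0)
    yc = y0 + a * np.sin(2.0 * np.pi * depth_mm / (0.75 * p) + 2.5)
    return xc, yc


def generate_phantom(config: PhantomConfig) -> tuple[Volume, GroundTruth]:
    """Render a phantom volume and its ground truth.

    Identical configs (including the seed) give bit-identical volumes.
    """
    nx, ny, nz = (
        int(round(f / v)) for f, v in zip(config.fov_mm, config.voxel_mm)
    )
    dx, dy, dz = config.voxel_mm
    affine = np.diag([dx, dy, dz, 1.0])

    # column axis parameterized by rostral depth; arc length via cumulative
    # chord length on the slice grid
    z_world = np.arange(nz) * dz
    z_top = z_world[-1]
    depth = z_top - z_world[::-1]  # 0 at the rostral (top) slice, increasing
    xc, yc = _column_axis_xy(depth, config, (config.fov_mm[0], config.fov_mm[1]))
    steps = np.sqrt(np.diff(xc) ** 2 + np.diff(yc) ** 2 + dz**2)
    arc = np.concatenate([[0.0], np.cumsum(steps)])  # arc length per depth slice

    levels = config.levels
    disk_s = np.array([config.disk_positions_mm[u] for u in levels])
    margin = config.disk_width_mm
    for u, s in zip(levels, disk_s):
        if s < margin or s > arc[-1] - margin:
            raise ValueError(
                f"disk {disk_name(u)} at {s:.1f} mm does not fit in the "
                f"field of view (column arc length {arc[-1]:.1f} mm)"
            )

    # axial disk-bump profile g(s): raised cosines of FWHM disk_width_mm
    def bump_profile(s: np.ndarray) -> np.ndarray:
        g = np.zeros_like(s)
        for sd in disk_s:
            d = np.abs(s - sd)
            within = d <= config.disk_width_mm
            g[within] += 0.5 * (1.0 + np.cos(np.pi * d[within] / config.disk_width_mm))
        return g

    g_per_depth = bump_profile(arc)
    sign = 1.0 if config.contrast_polarity == T2_LIKE else -1.0
    noise_ref = config.noise_sd if config.noise_sd > 0 else REFERENCE_NOISE_SD
    amplitude = config.vertebral_contrast * noise_ref
    column_value = BODY_INTENSITY + sign * amplitude * g_per_depth

    x_grid = np.arange(nx)[:, None] * dx
    y_grid = np.arange(ny)[None, :] * dy
    data = np.full((nx, ny, nz), BACKGROUND_INTENSITY, dtype=float)
    cord_mask = np.zeros((nx, ny, nz), dtype=np.uint8)
    for slab, k in enumerate(range(nz - 1, -1, -1)):  # rostral to caudal
        r2_col = (x_grid - xc[slab]) ** 2 + (y_grid - yc[slab]) ** 2
        r2_cord = (x_grid - xc[slab]) ** 2 + (
            y_grid - (yc[slab] - CORD_POSTERIOR_OFFSET_MM)
        ) ** 2
        sl = data[:, :, k]
        sl[r2_col <= COLUMN_RADIUS_MM**2] = column_value[slab]
        sl[r2_cord <= CORD_RADIUS_MM**2] = CORD_INTENSITY
        cord_mask[:, :, k] = r2_cord <= CORD_RADIUS_MM**2

    # low-order multiplicative bias field along the superior-inferior axis
    if config.bias_field_amplitude:
        u = 2.0 * z_world / max(z_world[-1], 1e-9) - 1.0
        bias = 1.0 + config.bias_field_amplitude * (0.6 * u + 0.4 * u**2)
        data *= bias[None, None, :]

    # signal-dropout slab across the named vertebral levels
    if config.dropout_levels:
        lo, hi = min(config.dropout_levels), max(config.dropout_levels)
        s_lo = config.disk_positions_mm[lo - 1] - config.disk_width_mm
        s_hi = config.disk_positions_mm[hi] + config.disk_width_mm
        in_slab_depth = (arc >= s_lo) & (arc <= s_hi)
        k_in_slab = (nz - 1) - np.flatnonzero(in_slab_depth)
        data[:, :, k_in_slab] *= 1.0 - config.dropout_attenuation

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        data += rng.normal(0.0, config.noise_sd, size=data.shape)

    volume = Volume(data=data, affine=affine, polarity=config.contrast_polarity)

    # ground-truth cord centerline: same curve as the column axis, shifted
    # 15 mm posteriorly, at 1 mm arc steps
    cord_points = np.column_stack(
        [xc, yc - CORD_POSTERIOR_OFFSET_MM, z_top - depth]
    )
    true_cl = Centerline.from_points(cord_points).resample(1.0)
    # reference disk positions on the cord: the orthogonal foot of each
    # disk's column-axis point on the cord curve — the cord point adjacent
    # to the disk, which is what a human rater marks.  Under curvature this
    # differs by up to a couple of millimetres from the position at equal
    # arc length.
    from .labeling import _project_point_to_polyline

    disk_points = np.column_stack(
        [
            np.interp(disk_s, arc, xc),
            np.interp(disk_s, arc, yc),
            z_top - np.interp(disk_s, arc, depth),
        ]
    )
    disk_cord_s = np.array(
        [_project_point_to_polyline(pt, true_cl) for pt in disk_points]
    )
    labels = levels[0] + np.searchsorted(
        disk_cord_s, true_cl.arc_length, side="left"
    )
    truth = GroundTruth(
        true_disk_positions_mm={u: float(s) for u, s in zip(levels, disk_cord_s)},
        true_centerline=true_cl,
        true_labels=labels.astype(int),
        cord_mask=Volume(data=cord_mask, affine=affine),
    )
    return volume, truth


def level_slab_mean_intensities(
    volume: Volume,
    truth: GroundTruth,
    config: PhantomConfig,
) -> dict[int, float]:
    """Mean column intensity per vertebral level (for artifact checks).

    The level of vertebra ``n`` spans from the disk above it to the disk
    below it; levels at the rostral/caudal ends of the simulated stack are
    skipped.
    """
    nz = volume.shape[2]
    dz = volume.voxel_size[2]
    z_world = np.arange(nz) * dz
    depth = z_world[-1] - z_world[::-1]
    xc, yc = _column_axis_xy(depth, config, (config.fov_mm[0], config.fov_mm[1]))
    steps = np.sqrt(np.diff(xc) ** 2 + np.diff(yc) ** 2 + dz**2)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    x_grid = np.arange(volume.shape[0])[:, None] * volume.voxel_size[0]
    y_grid = np.arange(volume.shape[1])[None, :] * volume.voxel_size[1]

    levels = sorted(truth.true_disk_positions_mm)
    out: dict[int, float] = {}
    for vert in range(levels[0] + 1, levels[-1] + 1):
        s_lo = truth.true_disk_positions_mm[vert - 1]
        s_hi = truth.true_disk_positions_mm[vert]
        vals = []
        for slab, k in enumerate(range(nz - 1, -1, -1)):
            if s_lo <= arc[slab] <= s_hi:
                r2 = (x_grid - xc[slab]) ** 2 + (y_grid - yc[slab]) ** 2
                vals.append(volume.data[:, :, k][r2 <= COLUMN_RADIUS_MM**2])
        out[vert] = float(np.mean(np.concatenate(vals)))
    return out
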