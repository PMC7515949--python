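"""Data model and file IO for dynamic PET volumes, frame timing, atlases and curves.

Conventions
-----------
* Activity concentration is stored in Bq/cc, total activity in Bq.
* All curve operations index time by frame **mid-times** (start + duration/2),
  the usual convention for coarsely framed PET data.
* Images are assumed decay-corrected to injection time by the scanner; this
  toolkit neither applies nor removes decay correction.
* Image, mask and atlas grids are assumed co-registered; no resampling is done.

File formats: NIfTI-1 for 4D images, masks, atlases and parametric maps
(via nibabel); plain TSV for frame timing, curves and tables.  The timing
sidecar is a two-column table ``start_s<TAB>duration_s`` with optional ``#``
comment lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing of a dynamic scan: start and duration of each frame in seconds.

    Frames must be contiguous (each frame starts where the previous one ends),
    non-overlapping and strictly positive in duration; at least 3 frames.
    """

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.ndim != 1 or starts.shape != durations.shape:
            raise ValueError("starts and durations must be 1-D arrays of equal length")
        if len(starts) < 3:
            raise ValueError("a frame schedule needs at least 3 frames")
        if np.any(durations <= 0):
            raise ValueError("frame durations must be strictly positive")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if not np.allclose(starts[1:], starts[:-1] + durations[:-1], rtol=0, atol=1e-6):
            raise ValueError("frames must be contiguous and non-overlapping")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def mids(self) -> np.ndarray:
        """Frame mid-times in seconds."""
        return self.starts + self.durations / 2.0

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def total_duration(self) -> float:
        """Scan length in seconds (end of the last frame)."""
        return float(self.ends[-1])

    def frame_covering(self, t_start: float, t_end: float) -> int:
        """Index of the frame spanning exactly [t_start, t_end); raises if absent."""
        for i, (s, e) in enumerate(zip(self.starts, self.ends)):
            if abs(s - t_start) < 1e-6 and abs(e - t_end) < 1e-6:
                return i
        raise ValueError(f"no frame spans [{t_start}, {t_end}) s")

    @classmethod
    def from_durations(cls, durations, t0: float = 0.0) -> "FrameSchedule":
        durations = np.asarray(durations, dtype=float)
        starts = t0 + np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts, durations)


def reference_mouse_schedule() -> FrameSchedule:
    """The 60-min whole-body mouse framing used as the reference fixture:
    3x30 s, 5x60 s, 5x120 s, 3x180 s, 3x240 s, 4x300 s, 1x240 s (24 frames)."""
    durations = [30] * 3 + [60] * 5 + [120] * 5 + [180] * 3 + [240] * 3 + [300] * 4 + [240]
    return FrameSchedule.from_durations(durations)


@dataclass
class DynamicImage:
    """4D activity-concentration volume (Bq/cc) with voxel geometry and timing.

    ``voxels`` is (nx, ny, nz, n_frames); ``voxel_size`` is in mm.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be a 4D array (x, y, z, frame)")
        if self.voxels.shape[3] != len(self.schedule):
            raise ValueError(
                f"frame count mismatch: image has {self.voxels.shape[3]} frames, "
                f"schedule has {len(self.schedule)}"
            )
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be 3 positive numbers (mm)")
        self.voxel_size = vs

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[3]

    @property
    def voxel_volume_cc(self) -> float:
        """Voxel volume in cc (mm^3 / 1000)."""
        vx, vy, vz = self.voxel_size
        return vx * vy * vz / 1000.0


@dataclass
class LabelAtlas:
    """3D integer label volume aligned to the image grid plus a label->name map."""

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D integer array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = np.rint(self.labels).astype(np.int32)
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    @property
    def name_to_label(self) -> dict[str, int]:
        return {v: k for k, v in self.names.items()}

    def mask_of(self, region: str) -> np.ndarray:
        try:
            lab = self.name_to_label[region]
        except KeyError:
            raise KeyError(f"unknown region name: {region!r}") from None
        return self.labels == lab


@dataclass
class Curve:
    """Time-stamped curve: frame mid-times (s) and values with a unit tag.

    Recognised units: 'Bq', 'Bq/cc', 'percent_id', 'fraction', 'arb'.
    """

    times: np.ndarray
    values: np.ndarray
    unit: str = "arb"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("curve times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def require_unit(self, unit: str) -> None:
        if self.unit != unit:
            raise ValueError(f"expected a curve in {unit!r}, got {self.unit!r}")

    def interpolate(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation inside the support, constant extrapolation outside."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.values)


# --------------------------------------------------------------------------
# Timing sidecar and image IO
# --------------------------------------------------------------------------

def read_schedule(timing_path) -> FrameSchedule:
    """Read a two-column (start_s, duration_s) TSV timing sidecar."""
    timing_path = Path(timing_path)
    if not timing_path.exists():
        raise FileNotFoundError(timing_path)
    rows = np.loadtxt(timing_path, comments="#", ndmin=2)
    if rows.shape[1] != 2:
        raise ValueError("timing sidecar must have two columns: start_s, duration_s")
    return FrameSchedule(rows[:, 0], rows[:, 1])


def write_schedule(schedule: FrameSchedule, timing_path) -> None:
    header = "start_s\tduration_s"
    np.savetxt(
        timing_path,
        np.column_stack([schedule.starts, schedule.durations]),
        fmt="%.12g",
        delimiter="\t",
        header=header,
        comments="# ",
    )


def read_dynamic_image(image_path, timing_path) -> DynamicImage:
    """Load a 4D NIfTI volume and its timing sidecar into a DynamicImage."""
    image_path = Path(image_path)
    if not image_path.exists():
        raise FileNotFoundError(image_path)
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, got {data.ndim}D")
    schedule = read_schedule(timing_path)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DynamicImage(data, voxel_size, schedule)


def write_dynamic_image(image: DynamicImage, image_path, timing_path=None) -> None:
    affine = np.diag(list(image.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(image.voxels, affine), str(image_path))
    if timing_path is not None:
        write_schedule(image.schedule, timing_path)


def read_atlas(atlas_path, names_path) -> LabelAtlas:
    """Load a 3D integer-label NIfTI and a TSV (label, name) table."""
    img = nib.load(str(atlas_path))
    labels = np.asarray(img.dataobj)
    if labels.ndim == 4 and labels.shape[3] == 1:
        labels = labels[..., 0]
    names: dict[int, str] = {}
    for line in Path(names_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("label"):
            continue
        lab, name = line.split("\t")
        names[int(lab)] = name
    return LabelAtlas(labels, names)


def write_atlas(atlas: LabelAtlas, atlas_path, names_path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine), str(atlas_path))
    lines = ["label\tname"] + [f"{k}\t{v}" for k, v in sorted(atlas.names.items())]
    Path(names_path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Curve IO
# --------------------------------------------------------------------------

def write_curve(curve: Curve, path) -> None:
    """Write a curve as TSV with header ``time_s\\tvalue\\tunit`` (12 sig. digits)."""
    lines = ["time_s\tvalue\tunit"]
    for t, v in zip(curve.times, curve.values):
        lines.append(f"{t:.12g}\t{v:.12g}\t{curve.unit}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve(path) -> Curve:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    times, values, unit = [], [], "arb"
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("time_s"):
            continue
        parts = line.split("\t")
        times.append(float(parts[0]))
        values.append(float(parts[1]))
        if len(parts) > 2:
            unit = parts[2]
    return Curve(np.asarray(times), np.asarray(values), unit)


# --------------------------------------------------------------------------
# Whole-body ROI and TAC extraction
# --------------------------------------------------------------------------

def body_mask(image: DynamicImage, threshold_fraction: float = 0.05) -> np.ndarray:
    """Whole-body mask: voxels whose time-summed activity exceeds a fraction of
    the maximum time-summed activity, reduced to the largest connected component.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    summed = image.voxels.sum(axis=3)
    peak = summed.max()
    if peak <= 0:
        raise ValueError("cannot build a body mask from an all-zero image")
    mask = summed > threshold_fraction * peak
    labeled, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
        mask = labeled == (1 + int(np.argmax(sizes)))
    return mask


def whole_body_tac(image: DynamicImage, mask: np.ndarray) -> Curve:
    """Total activity per frame inside a ROI: mean concentration (Bq/cc) times
    ROI volume (cc).  Times are frame mid-times; values in Bq."""
    if mask.shape != image.spatial_shape:
        raise ValueError("mask shape does not match image spatial shape")
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("mask is empty")
    volume_cc = n_vox * image.voxel_volume_cc
    mean_conc = image.voxels[mask].mean(axis=0)
    return Curve(image.schedule.mids, mean_conc * volume_cc, unit="Bq")


def extract_regional_tacs(
    image: DynamicImage, atlas: LabelAtlas, regions: list[str]
) -> dict[str, Curve]:
    """Mean-concentration TAC (Bq/cc) per named atlas region."""
    if atlas.labels.shape != image.spatial_shape:
        raise ValueError("atlas grid does not match image spatial shape")
    out: dict[str, Curve] = {}
    for region in regions:
        m = atlas.mask_of(region)
        if not m.any():
            raise ValueError(f"region {region!r} is empty in the atlas")
        out[region] = Curve(image.schedule.mids, image.voxels[m].mean(axis=0), unit="Bq/cc")
    return out
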