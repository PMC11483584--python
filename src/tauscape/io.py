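"""Core domain types and file I/O.

Volumes are held as 3D arrays in fixed ``(z, y, x)`` axis order with a
per-axis voxel pitch in micrometres.  The physical coordinate of voxel
``i`` along an axis is ``(i + 0.5) * pitch`` (voxel-centre convention),
so the centroid of a single-voxel spot sits at the voxel centre.

Supported on-disk formats: multi-page TIFF and NRRD for volumes, CSV for
spot tables, region-metadata tables, rankings and time-activity curves.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("tauscape")


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a stderr handler with stage tags (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


class TauscapeError(Exception):
    """Base class for package errors."""


class FormatError(TauscapeError):
    """Malformed or unsupported input file."""


class ValidationError(TauscapeError):
    """Input violates a type invariant."""


# --------------------------------------------------------------------------
# Volumes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Volume3D:
    """A 3D non-negative intensity grid with voxel pitch in micrometres.

    Parameters
    ----------
    data
        3D array, axis order (z, y, x).  Stored as float64 regardless of
        the on-disk integer type.
    voxel_pitch_um
        Per-axis (z, y, x) voxel pitch in micrometres, all > 0.
    """

    data: np.ndarray
    voxel_pitch_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValidationError(f"non-3D data: got {data.ndim} dimensions")
        if min(data.shape) < 1:
            raise ValidationError("all volume dimensions must be >= 1")
        if not np.all(np.isfinite(data)):
            raise ValidationError("volume intensities must be finite")
        if data.min() < 0:
            raise ValidationError("volume intensities must be non-negative")
        pitch = tuple(float(p) for p in self.voxel_pitch_um)
        if len(pitch) != 3 or any(p <= 0 for p in pitch):
            raise ValidationError(f"voxel pitch must be three positive values, got {pitch}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_pitch_um", pitch)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_pitch_um))

    def is_isotropic(self, pitch_um: float, rtol: float = 1e-6) -> bool:
        return all(abs(p - pitch_um) <= rtol * pitch_um for p in self.voxel_pitch_um)


def read_volume(path: str, pitch_override: tuple[float, float, float] | None = None) -> Volume3D:
    """Read a TIFF stack or NRRD file into a :class:`Volume3D`.

    Pitch is taken from file metadata; ``pitch_override`` replaces it.
    Reading fails rather than guessing when no pitch is available.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext in (".nrrd", ".nhdr"):
        data, pitch = _read_nrrd(path)
    elif ext in (".tif", ".tiff"):
        data, pitch = _read_tiff(path)
    else:
        raise FormatError(f"unsupported volume format: {path!r} (expected TIFF or NRRD)")
    if pitch_override is not None:
        pitch = tuple(float(p) for p in pitch_override)
    if pitch is None:
        raise FormatError(f"no voxel pitch metadata in {path!r} and no pitch_override given")
    return Volume3D(data=data, voxel_pitch_um=pitch)


def write_volume(volume: Volume3D, path: str) -> None:
    """Write a volume with its pitch metadata (TIFF or NRRD by extension)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".nrrd", ".nhdr"):
        _write_nrrd(volume, path)
    elif ext in (".tif", ".tiff"):
        _write_tiff(volume, path)
    else:
        raise FormatError(f"unsupported volume format: {path!r} (expected TIFF or NRRD)")


def _read_tiff(path):
    import tifffile

    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    if data.ndim != 3:
        raise ValidationError(f"non-3D data in {path!r}: shape {data.shape}")
    pitch = None
    if desc:
        try:
            meta = json.loads(desc)
            if isinstance(meta, dict) and "voxel_pitch_um" in meta:
                pitch = tuple(float(p) for p in meta["voxel_pitch_um"])
        except (json.JSONDecodeError, TypeError):
            pitch = None
    return np.asarray(data, dtype=np.float64), pitch


def _write_tiff(volume, path):
    import tifffile

    meta = json.dumps({"voxel_pitch_um": list(volume.voxel_pitch_um)})
    tifffile.imwrite(path, volume.data, description=meta, photometric="minisblack")


def _read_nrrd(path):
    import SimpleITK as sitk

    img = sitk.ReadImage(path)
    if img.GetDimension() != 3:
        raise ValidationError(f"non-3D data in {path!r}")
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    sx, sy, sz = img.GetSpacing()       # SimpleITK spacing is (x, y, z)
    return np.asarray(data, dtype=np.float64), (float(sz), float(sy), float(sx))


def _write_nrrd(volume, path):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(volume.data)
    pz, py, px = volume.voxel_pitch_um
    img.SetSpacing((px, py, pz))
    sitk.WriteImage(img, path)


# --------------------------------------------------------------------------
# Spots
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TauSpot:
    """One connected suprathreshold component in the filtered tau channel.

    ``centroid_um`` is the intensity-weighted centre in physical (z, y, x)
    coordinates; ``total_intensity`` sums the band-pass (Gaussian-minus-mean)
    values over the component.
    """

    label: int
    centroid_um: tuple[float, float, float]
    total_intensity: float
    volume_vox: int
    volume_um3: float

    def __post_init__(self) -> None:
        if self.volume_vox < 1:
            raise ValidationError(f"spot {self.label}: volume_vox must be >= 1")
        if not self.total_intensity > 0:
            raise ValidationError(f"spot {self.label}: total_intensity must be > 0")


SPOT_COLUMNS = ["label", "z_um", "y_um", "x_um", "total_intensity", "volume_vox", "volume_um3"]


@dataclass
class SpotTable:
    """A set of detected tau deposit spots for one sample."""

    spots: list[TauSpot]
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        labels = [s.label for s in self.spots]
        if len(labels) != len(set(labels)):
            raise ValidationError("spot labels must be unique")

    def __len__(self) -> int:
        return len(self.spots)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s.label, *s.centroid_um, s.total_intensity, s.volume_vox, s.volume_um3)
            for s in self.spots
        ]
        return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def write_spot_table(table: SpotTable, path: str) -> None:
    table.to_frame().to_csv(path, index=False)


def read_spot_table(path: str, sample_id: str | None = None) -> SpotTable:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"malformed spot CSV {path!r}: {exc}") from exc
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"spot CSV {path!r} missing column(s): {', '.join(missing)}")
    spots = [
        TauSpot(
            label=int(r.label),
            centroid_um=(float(r.z_um), float(r.y_um), float(r.x_um)),
            total_intensity=float(r.total_intensity),
            volume_vox=int(r.volume_vox),
            volume_um3=float(r.volume_um3),
        )
        for r in df.itertuples(index=False)
    ]
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    return SpotTable(spots=spots, sample_id=sample_id)


# --------------------------------------------------------------------------
# Atlas
# --------------------------------------------------------------------------

REGION_COLUMNS = ["region_id", "acronym", "medium_group_id", "volume_mm3", "excluded"]


@dataclass
class Atlas:
    """Integer label volume plus region metadata.

    ``regions`` has columns region_id, acronym, medium_group_id,
    volume_mm3 (> 0) and excluded (bool).  Every nonzero label present in
    the grid must appear in the table.  Excluded regions (e.g. ventricular
    systems and fibre tracts, which carry non-specific staining) are
    dropped during spot assignment.
    """

    labels: np.ndarray
    voxel_pitch_um: tuple[float, float, float]
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValidationError("atlas label grid must be 3D")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise ValidationError("atlas labels must be integers")
            labels = np.round(labels).astype(np.int64)
        self.labels = labels
        self.voxel_pitch_um = tuple(float(p) for p in self.voxel_pitch_um)
        missing = [c for c in REGION_COLUMNS if c not in self.regions.columns]
        if missing:
            raise FormatError(f"region table missing column(s): {', '.join(missing)}")
        regions = self.regions.copy()
        regions["region_id"] = regions["region_id"].astype(int)
        regions["medium_group_id"] = regions["medium_group_id"].astype(int)
        regions["excluded"] = regions["excluded"].astype(bool)
        if regions["region_id"].duplicated().any():
            raise ValidationError("duplicate region_id in region table")
        if (regions["volume_mm3"] <= 0).any():
            bad = regions.loc[regions["volume_mm3"] <= 0, "region_id"].tolist()
            raise ValidationError(f"volume_mm3 must be > 0 (region {bad})")
        present = set(np.unique(labels)) - {0}
        known = set(regions["region_id"])
        unknown = sorted(present - known)
        if unknown:
            raise ValidationError(f"unknown label {', '.join(map(str, unknown))} in atlas grid")
        self.regions = regions.reset_index(drop=True)

    @property
    def region_ids(self) -> list[int]:
        return self.regions["region_id"].tolist()

    @property
    def excluded_ids(self) -> set[int]:
        return set(self.regions.loc[self.regions["excluded"], "region_id"])

    def region_volume_mm3(self, region_id: int) -> float:
        row = self.regions.loc[self.regions["region_id"] == region_id, "volume_mm3"]
        if row.empty:
            raise KeyError(f"unknown region {region_id}")
        return float(row.iloc[0])


def read_atlas(label_path: str, region_table_path: str) -> Atlas:
    """Read a label volume (TIFF/NRRD) and region metadata CSV."""
    vol = read_volume(label_path, pitch_override=None)
    regions = pd.read_csv(region_table_path)
    return Atlas(labels=vol.data, voxel_pitch_um=vol.voxel_pitch_um, regions=regions)


def write_atlas(atlas: Atlas, label_path: str, region_table_path: str) -> None:
    vol = Volume3D(data=atlas.labels.astype(np.float64), voxel_pitch_um=atlas.voxel_pitch_um)
    write_volume(vol, label_path)
    atlas.regions.to_csv(region_table_path, index=False)


# --------------------------------------------------------------------------
# Extraction parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtractionParams:
    """Tunable parameters of the tau-deposit extraction.

    Defaults follow the published light-sheet workflow: a small Gaussian
    (sigma 0.83 voxels, FWHM ~16 um at 8.3 um pitch) minus an 83 um mean
    filter; brain mask at 1.5x the global mean intensity eroded ten times;
    spot threshold at 2x the mean intensity outside the brain.
    """

    sigma_small_vox: float = 0.83
    mean_extent_um: float = 83.0
    mask_threshold_factor: float = 1.5
    erosion_iterations: int = 10
    spot_threshold_factor: float = 2.0
    target_pitch_um: float = 8.3
    connectivity: int = 6
    erosion_structure: str = "cross"     # cross (6-connected) | cube (26-connected)
    centroid_mode: str = "weighted"      # weighted (by band-pass value) | geometric

    def __post_init__(self) -> None:
        for name in ("sigma_small_vox", "mean_extent_um", "mask_threshold_factor",
                     "spot_threshold_factor", "target_pitch_um"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.erosion_iterations < 0:
            raise ValidationError("erosion_iterations must be >= 0")
        if self.connectivity not in (6, 26):
            raise ValidationError("connectivity must be 6 or 26")
        if self.erosion_structure not in ("cross", "cube"):
            raise ValidationError("erosion_structure must be 'cross' or 'cube'")
        if self.centroid_mode not in ("weighted", "geometric"):
            raise ValidationError("centroid_mode must be 'weighted' or 'geometric'")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractionParams":
        allowed = {f.name for f in fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ValidationError(f"unknown extraction parameter(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    def replace(self, **kw) -> "ExtractionParams":
        return replace(self, **kw)


# --------------------------------------------------------------------------
# Time-activity curves
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeActivityCurve:
    """Regional PET time-activity curve.

    ``activity_kbq_per_cc`` holds frame-averaged radioactivity; ``dose_kbq``
    and ``body_weight_g`` are needed to express it as a standardized uptake
    value (SUV).
    """

    frame_mid_times_min: np.ndarray
    activity_kbq_per_cc: np.ndarray
    dose_kbq: float
    body_weight_g: float
    region: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_mid_times_min, dtype=np.float64)
        a = np.asarray(self.activity_kbq_per_cc, dtype=np.float64)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValidationError("times and activities must be 1D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("frame mid-times must be strictly increasing")
        if np.any(a < 0):
            raise ValidationError("activities must be >= 0")
        if not self.dose_kbq > 0:
            raise ValidationError("dose_kbq must be > 0")
        if not self.body_weight_g > 0:
            raise ValidationError("body_weight_g must be > 0")
        object.__setattr__(self, "frame_mid_times_min", t)
        object.__setattr__(self, "activity_kbq_per_cc", a)


def write_tac(tac: TimeActivityCurve, path: str) -> None:
    df = pd.DataFrame({
        "mid_time_min": tac.frame_mid_times_min,
        "activity_kbq_per_cc": tac.activity_kbq_per_cc,
    })
    header = f"# dose_kbq={tac.dose_kbq!r} body_weight_g={tac.body_weight_g!r} region={tac.region}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_tac(path: str) -> TimeActivityCurve:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise FormatError(f"TAC file {path!r} missing metadata header line")
        meta = dict(tok.split("=", 1) for tok in first[1:].split())
        df = pd.read_csv(fh)
    for col in ("mid_time_min", "activity_kbq_per_cc"):
        if col not in df.columns:
            raise FormatError(f"TAC file {path!r} missing column {col}")
    return TimeActivityCurve(
        frame_mid_times_min=df["mid_time_min"].to_numpy(),
        activity_kbq_per_cc=df["activity_kbq_per_cc"].to_numpy(),
        dose_kbq=float(meta["dose_kbq"]),
        body_weight_g=float(meta["body_weight_g"]),
        region=meta.get("region", ""),
    )
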