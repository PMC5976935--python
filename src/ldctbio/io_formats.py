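"""Reading and writing CT images and subject rosters.

Axis convention
---------------
Voxel grids are indexed ``(slice, row, col)``.  In-plane pixel spacing is
``(row, col)`` in millimetres.  Area computations downstream depend only on
spacing, never on patient orientation, so no orientation metadata is kept.

Two image formats are supported: DICOM series directories (the reference
path, with the rescale slope/intercept applied on read) and single-file
NIfTI volumes (convenience path for synthetic fixtures, stored directly in
Hounsfield units).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Nominal Hounsfield range is [-1024, 3071] (12-bit CT).  A guard band down
# to -1100 HU accommodates uncalibrated scans whose air level has drifted
# low; such scans are exactly what background normalization corrects.
HU_MIN_NOMINAL = -1024.0
HU_MIN_GUARD = -1100.0
HU_MAX = 3071.0


@dataclass
class CTVolume:
    """A CT intensity grid in Hounsfield units with physical spacing.

    Parameters
    ----------
    voxels : ndarray, shape (slices, rows, cols)
        HU values.  A 2-D array is promoted to a single-slice volume.
    pixel_spacing : (float, float)
        In-plane spacing (row, col) in mm.
    slice_thickness : float
        Slice thickness in mm.
    slice_locations : ndarray or None
        Optional per-slice positions in mm.
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float = 1.0
    slice_locations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[np.newaxis, :, :]
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 2-D or 3-D")
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        self.validate()

    def validate(self) -> None:
        ns, nr, nc = self.voxels.shape
        if nr < 8 or nc < 8:
            raise ValueError(f"in-plane grid must be at least 8x8, got {nr}x{nc}")
        if self.pixel_spacing[0] <= 0 or self.pixel_spacing[1] <= 0:
            raise ValueError("pixel_spacing components must be > 0")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be > 0")
        vmin, vmax = float(self.voxels.min()), float(self.voxels.max())
        if vmin < HU_MIN_GUARD or vmax > HU_MAX:
            raise ValueError(
                f"voxel values [{vmin:.1f}, {vmax:.1f}] outside the representable "
                f"HU range [{HU_MIN_GUARD}, {HU_MAX}]"
            )
        if self.slice_locations is not None and len(self.slice_locations) != ns:
            raise ValueError("slice_locations length must match slice count")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def slice_at(self, index: int) -> "CTVolume":
        """Return a single-slice volume view of slice ``index``."""
        return CTVolume(
            self.voxels[index].copy(),
            self.pixel_spacing,
            self.slice_thickness,
        )

    def with_voxels(self, voxels: np.ndarray) -> "CTVolume":
        return CTVolume(voxels, self.pixel_spacing, self.slice_thickness,
                        None if self.slice_locations is None else np.array(self.slice_locations))


_GENDER_MAP = {
    "male": "male", "m": "male", "1": "male",
    "female": "female", "f": "female", "2": "female",
}
_DEATH_MAP = {
    "alive": "alive", "0": "alive",
    "lung_cancer_death": "lung_cancer_death", "1": "lung_cancer_death",
    "lc_death": "lung_cancer_death",
    "unrelated_death": "unrelated_death", "2": "unrelated_death",
}
_STAGES = ("I", "II", "III", "IV")


@dataclass
class SubjectRecord:
    """One roster row, using the trial master sheet's semantics.

    ``screen_detected`` mirrors the "can scr" column, ``death_lc`` the
    "finaldeathLC" outcome code.  Numeric fields are ``None`` when missing;
    derived fields (``bmi``, ``survival_time``) start unset.
    """

    pid: str
    age: float | None = None
    gender: str | None = None          # "male" / "female"
    height: float | None = None       # m
    weight: float | None = None       # kg
    pkyr: float | None = None         # pack-years
    stage: str | None = None          # "I".."IV" or None
    screen_detected: bool | None = None
    death_lc: str | None = None       # alive / lung_cancer_death / unrelated_death
    candx_days: float | None = None
    fup_days: float | None = None
    copd: bool | None = None
    histology: str | None = None
    bmi: float | None = None
    survival_time: float | None = None
    flags: tuple[str, ...] = ()


#: Default roster column names (the trial master sheet's own headers).
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "pid": "pid",
    "age": "age",
    "gender": "gender",
    "height": "height",
    "weight": "weight",
    "pkyr": "pkyr",
    "stage": "stage",
    "screen_detected": "can scr",
    "death_lc": "finaldeathLC",
    "candx_days": "candx_days",
    "fup_days": "fup_days",
    "copd": "copd",
    "histology": "histology",
}


def _parse_float(value, bad_counter: list[int], positive: bool = False) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        x = float(value)
    except (TypeError, ValueError):
        bad_counter[0] += 1
        return None
    if not np.isfinite(x) or (positive and x <= 0):
        bad_counter[0] += 1
        return None
    return x


def _parse_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    s = str(value).strip().lower()
    if s in ("1", "true", "yes", "y", "t", "1.0"):
        return True
    if s in ("0", "false", "no", "n", "f", "0.0"):
        return False
    return None


def read_roster(path: str | Path, column_map: dict[str, str] | None = None) -> list[SubjectRecord]:
    """Read a roster CSV into :class:`SubjectRecord` objects.

    ``column_map`` maps record field names to CSV header names; defaults to
    the master-sheet names ("can scr", "finaldeathLC", ...).  Unparseable
    numeric fields become missing with a logged count.  A missing pid column
    or duplicated pids are hard errors.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if cmap["pid"] not in df.columns:
        raise ValueError(f"roster is missing the pid column {cmap['pid']!r}")
    pids = df[cmap["pid"]].astype(str)
    if pids.duplicated().any():
        dups = sorted(pids[pids.duplicated()].unique())
        raise ValueError(f"duplicate pid(s) in roster: {dups[:5]}")

    bad = [0]
    records: list[SubjectRecord] = []
    for _, row in df.iterrows():
        def get(fieldname: str):
            col = cmap.get(fieldname)
            return row[col] if col in df.columns else None

        gender_raw = get("gender")
        gender = _GENDER_MAP.get(str(gender_raw).strip().lower()) if gender_raw not in (None, "") else None
        death_raw = get("death_lc")
        death = _DEATH_MAP.get(str(death_raw).strip().lower()) if death_raw not in (None, "") else None
        stage_raw = get("stage")
        stage = None
        if stage_raw not in (None, ""):
            s = str(stage_raw).strip().upper()
            s = {"1": "I", "2": "II", "3": "III", "4": "IV"}.get(s, s)
            stage = s if s in _STAGES else None

        records.append(SubjectRecord(
            pid=str(get("pid")),
            age=_parse_float(get("age"), bad, positive=True),
            gender=gender,
            height=_parse_float(get("height"), bad, positive=True),
            weight=_parse_float(get("weight"), bad, positive=True),
            pkyr=_parse_float(get("pkyr"), bad),
            stage=stage,
            screen_detected=_parse_bool(get("screen_detected")),
            death_lc=death,
            candx_days=_parse_float(get("candx_days"), bad),
            fup_days=_parse_float(get("fup_days"), bad),
            copd=_parse_bool(get("copd")),
            histology=(str(get("histology")) or None) if get("histology") not in (None, "") else None,
        ))
    if bad[0]:
        logger.warning("roster %s: %d unparseable numeric field(s) set to missing", path, bad[0])
    return records


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame with deterministic column order."""
    cols = [f.name for f in fields(SubjectRecord) if f.name != "flags"]
    data = {c: [getattr(r, c) for r in records] for c in cols}
    data["flags"] = [";".join(r.flags) for r in records]
    return pd.DataFrame(data)


def write_roster(records: Sequence[SubjectRecord], path: str | Path,
                 column_map: dict[str, str] | None = None) -> None:
    """Write records as a roster CSV using master-sheet column names."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = records_to_frame(records).drop(columns=["bmi", "survival_time", "flags"])
    df["screen_detected"] = df["screen_detected"].map({True: 1, False: 0})
    df["copd"] = df["copd"].map({True: 1, False: 0})
    df = df.rename(columns=cmap)
    df.to_csv(path, index=False)


def write_table(obj, path: str | Path) -> None:
    """Write any tabular result to CSV with deterministic column order.

    Accepts a DataFrame, a sequence of dataclass instances (e.g.
    :class:`SubjectRecord`), or any object exposing ``to_frame()`` (e.g.
    ``MatchedCohort``, ``ModelResult``).  Values round-trip at full
    precision (shortest-repr float formatting).
    """
    if isinstance(obj, pd.DataFrame):
        df = obj
    elif hasattr(obj, "to_frame"):
        df = obj.to_frame()
    elif isinstance(obj, Iterable):
        items = list(obj)
        if items and isinstance(items[0], SubjectRecord):
            df = records_to_frame(items)
        elif items and dataclasses.is_dataclass(items[0]):
            df = pd.DataFrame([dataclasses.asdict(x) for x in items])
        else:
            df = pd.DataFrame(items, columns=getattr(obj, "columns", None))
            if not items:
                df = pd.DataFrame(columns=[f.name for f in fields(SubjectRecord)])
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Image I/O


def read_ct(path: str | Path, format_hint: str | None = None) -> CTVolume:
    """Read a CT image as a :class:`CTVolume` in Hounsfield units.

    ``path`` may be a DICOM series directory or a NIfTI file
    (``.nii``/``.nii.gz``).  ``format_hint`` ("dicom" or "nifti") overrides
    autodetection.  DICOM stored values are converted to HU with the series'
    rescale slope/intercept; missing spacing metadata and mixed series are
    hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        fmt = "dicom" if path.is_dir() else "nifti"
    if fmt == "dicom":
        return _read_dicom_series(path)
    if fmt == "nifti":
        return _read_nifti(path)
    raise ValueError(f"unknown format hint {fmt!r}")


def _read_dicom_series(directory: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise ValueError(f"no readable DICOM files in {directory}")
    uids = {str(getattr(ds, "SeriesInstanceUID", None)) for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"mixed DICOM series in {directory}: {sorted(uids)}")
    for attr in ("PixelSpacing", "SliceThickness"):
        for ds in datasets:
            if getattr(ds, attr, None) is None:
                raise ValueError(f"DICOM series is missing required attribute {attr}")

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    slices = []
    locations = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
        ipp = getattr(ds, "ImagePositionPatient", None)
        locations.append(float(ipp[2]) if ipp is not None else np.nan)
    first = datasets[0]
    spacing = (float(first.PixelSpacing[0]), float(first.PixelSpacing[1]))
    locs = np.array(locations)
    return CTVolume(
        np.stack(slices),
        pixel_spacing=spacing,
        slice_thickness=float(first.SliceThickness),
        slice_locations=None if np.isnan(locs).any() else locs,
    )


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 2:
        data = data[np.newaxis]
    zooms = img.header.get_zooms()[:3]
    # stored as (slice, row, col) with matching zoom order
    return CTVolume(data, pixel_spacing=(float(zooms[1]), float(zooms[2])),
                    slice_thickness=float(zooms[0]))


def write_nifti(volume: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI, array axes (slice, row, col), HU values."""
    import nibabel as nib

    affine = np.diag([volume.slice_thickness, volume.pixel_spacing[0],
                      volume.pixel_spacing[1], 1.0])
    img = nib.Nifti1Image(volume.voxels.astype(np.float64), affine)
    img.header.set_zooms((volume.slice_thickness,) + volume.pixel_spacing)
    nib.save(img, str(path))


def write_dicom_series(volume: CTVolume, directory: str | Path,
                       intercept: float = -1024.0) -> list[Path]:
    """Write a volume as a minimal single-series DICOM directory.

    Stored values are signed 16-bit with rescale slope 1 and the given
    intercept, so ``stored = HU - intercept``.
    """
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    paths = []
    for i in range(volume.n_slices):
        stored = np.round(volume.voxels[i] - intercept).astype(np.int16)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = pydicom.Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * volume.slice_thickness]
        ds.PixelSpacing = [volume.pixel_spacing[0], volume.pixel_spacing[1]]
        ds.SliceThickness = volume.slice_thickness
        ds.Rows, ds.Columns = stored.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = str(intercept)
        ds.PixelData = stored.tobytes()
        out = directory / f"slice_{i:04d}.dcm"
        ds.save_as(str(out), enforce_file_format=True)
        paths.append(out)
    return paths
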