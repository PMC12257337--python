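"""Reading and writing phantom acquisitions.

A standard large-ACR-phantom series is 11 axial slices (256x256, 250 mm
FOV, 5 mm thick); the LCOD sheets appear on slices 8-11 (1-based).  Volumes
are read either from a DICOM series directory (via pydicom, slices sorted
by through-plane position with instance number as fallback) or from a
NIfTI file (via nibabel).  Intensities are kept in native stored units —
rescale slope/intercept are applied when present — and normalisation
happens downstream in the segmentation stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import AcrLcodError
from .geometry import PhantomLayout

__all__ = [
    "PhantomSlice",
    "PhantomVolume",
    "read_volume",
    "write_volume",
    "write_dicom_series",
    "lcod_slices",
]


@dataclass(frozen=True)
class PhantomSlice:
    """One axial slice: intensities (row 0 at image top) plus pixel spacing."""

    intensities: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_index_1based: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if arr.ndim != 2:
            raise ValueError("slice intensities must be 2-D")
        if not np.isfinite(arr).all():
            raise ValueError("slice intensities must be finite")
        if not all(s > 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel spacings must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def with_intensities(self, arr: np.ndarray) -> "PhantomSlice":
        return replace(self, intensities=arr)


@dataclass(frozen=True)
class PhantomVolume:
    """Ordered stack of :class:`PhantomSlice` with uniform pixel spacing."""

    slices: tuple[PhantomSlice, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "slices", tuple(self.slices))
        if not self.slices:
            raise ValueError("volume must contain at least one slice")
        spacings = {s.pixel_spacing_mm for s in self.slices}
        if len(spacings) > 1:
            raise ValueError(f"non-uniform pixel spacing across slices: {spacings}")
        indices = [s.slice_index_1based for s in self.slices]
        if len(set(indices)) != len(indices):
            raise ValueError("duplicate slice indices")

    @property
    def slice_indices(self) -> tuple[int, ...]:
        return tuple(s.slice_index_1based for s in self.slices)

    @property
    def pixel_spacing_mm(self) -> tuple[float, float]:
        return self.slices[0].pixel_spacing_mm

    def get_slice(self, index_1based: int) -> PhantomSlice:
        for s in self.slices:
            if s.slice_index_1based == index_1based:
                return s
        raise KeyError(f"slice {index_1based} not in volume {self.slice_indices}")

    def has_slice(self, index_1based: int) -> bool:
        return index_1based in self.slice_indices


def _read_dicom_series(path: Path, pixel_spacing=None) -> list[tuple]:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise AcrLcodError(f"no DICOM images found under {path}")
    series_uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(series_uids) > 1:
        raise AcrLcodError(
            f"directory mixes {len(series_uids)} DICOM series; expected one"
        )

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None and len(pos) == 3:
            return (0, float(pos[2]))
        return (1, int(getattr(ds, "InstanceNumber", 0)))

    datasets.sort(key=sort_key)
    out = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        spacing = pixel_spacing
        if spacing is None:
            ps = getattr(ds, "PixelSpacing", None)
            if ps is None:
                raise AcrLcodError(
                    "DICOM PixelSpacing missing; supply a spacing override"
                )
            spacing = (float(ps[0]), float(ps[1]))
        meta = {
            "series_description": str(getattr(ds, "SeriesDescription", "")),
            "instance_number": int(getattr(ds, "InstanceNumber", 0)),
        }
        out.append((arr, tuple(spacing), meta))
    return out


def _read_nifti(path: Path, pixel_spacing=None) -> list[tuple]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise AcrLcodError(f"expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()
    spacing = pixel_spacing or (float(zooms[0]), float(zooms[1]))
    return [
        (np.asarray(data[:, :, k], dtype=float), tuple(spacing), {})
        for k in range(data.shape[2])
    ]


def read_volume(
    path,
    format: str | None = None,
    pixel_spacing: tuple[float, float] | None = None,
    first_slice_index: int = 1,
    layout: PhantomLayout | None = None,
) -> PhantomVolume:
    """Read a phantom acquisition into a :class:`PhantomVolume`.

    Parameters
    ----------
    path
        A DICOM series directory or a NIfTI file.
    format
        ``"dicom-series"`` or ``"volume-file"``; inferred from the path by
        default.
    pixel_spacing
        (row, col) mm override when header spacing is missing or wrong.
    first_slice_index
        1-based phantom index of the first stored slice.  A full ACR series
        starts at 1; a synthetic LCOD-only volume may start at 7.
    """
    layout = layout or PhantomLayout.default()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "dicom-series" if path.is_dir() else "volume-file"
    if format == "dicom-series":
        raw = _read_dicom_series(path, pixel_spacing)
    elif format == "volume-file":
        raw = _read_nifti(path, pixel_spacing)
    else:
        raise ValueError(f"unknown format {format!r}")

    slices = [
        PhantomSlice(arr, spacing, first_slice_index + k, meta)
        for k, (arr, spacing, meta) in enumerate(raw)
    ]
    volume = PhantomVolume(tuple(slices), meta={"source": str(path)})
    needed = layout.lcod_slice_indices_1based
    missing = [i for i in needed if not volume.has_slice(i)]
    if missing:
        raise AcrLcodError(
            f"LCOD slices {missing} not present (volume has "
            f"{volume.slice_indices}); a standard series has 11 slices"
        )
    if len(slices) < 11 and first_slice_index == 1:
        warnings.warn(
            f"series has {len(slices)} slices; a standard ACR series has 11",
            stacklevel=2,
        )
    return volume


def write_volume(volume: PhantomVolume, path) -> Path:
    """Write a volume as an uncompressed float64 NIfTI (bit-exact round trip)."""
    import nibabel as nib

    path = Path(path)
    data = np.stack([s.intensities for s in volume.slices], axis=-1)
    sr, sc = volume.pixel_spacing_mm
    affine = np.diag([sr, sc, 5.0, 1.0])
    img = nib.Nifti1Image(data.astype(np.float64), affine)
    img.header.set_zooms((sr, sc, 5.0))
    nib.save(img, str(path))
    return path


def write_dicom_series(volume: PhantomVolume, directory) -> Path:
    """Write a volume as a minimal uint16 MR DICOM series (for testing/QC).

    Intensities are affinely mapped to uint16 with RescaleSlope/Intercept
    recording the inverse map, so reading the series back recovers values
    to quantisation precision.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    lo = min(float(s.intensities.min()) for s in volume.slices)
    hi = max(float(s.intensities.max()) for s in volume.slices)
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0

    for n, s in enumerate(volume.slices, start=1):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "MR"
        ds.SeriesDescription = "synthetic ACR LCOD"
        ds.InstanceNumber = n
        ds.ImagePositionPatient = [0.0, 0.0, float(s.slice_index_1based) * 5.0]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [s.pixel_spacing_mm[0], s.pixel_spacing_mm[1]]
        ds.SliceThickness = 5.0
        ds.Rows, ds.Columns = s.intensities.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = scale
        ds.RescaleIntercept = lo
        stored = np.round((s.intensities - lo) / scale).astype(np.uint16)
        ds.PixelData = stored.tobytes()
        ds.save_as(directory / f"slice_{n:03d}.dcm", enforce_file_format=True)
    return directory


def lcod_slices(
    volume: PhantomVolume, layout: PhantomLayout | None = None
) -> list[tuple[PhantomSlice, float]]:
    """The four LCOD slices paired with their nominal contrasts (percent)."""
    layout = layout or PhantomLayout.default()
    out = []
    for idx in layout.lcod_slice_indices_1based:
        if not volume.has_slice(idx):
            raise AcrLcodError(f"LCOD slice {idx} missing from volume")
        out.append((volume.get_slice(idx), layout.slice_contrasts_pct[idx]))
    return out
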