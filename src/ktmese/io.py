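"""File formats: HDF5 k-t containers, NIfTI maps and masks, CSV records.

Conventions
-----------
* k-t data live in an HDF5 container with datasets ``/kspace`` (complex),
  ``/mask`` (bool), ``/echo_times_ms`` and optional ``/coil_maps``; protocol
  and mask parameters are stored as attributes, so a file round-trips to an
  identical in-memory object.
* T2 maps and ROI masks are NIfTI volumes; pixel spacing is carried in the
  affine/zooms.  Maps are float32 in ms; companion volumes hold amplitude,
  B1, residual and validity.
* Lesion records append to a comma-separated UTF-8 CSV with units embedded
  in the column names (``median_t2_ms``, ``diameter_mm``).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import T2MapResult
from .recon import KtData
from .roi import RoiMask
from .sampling import KtMask

__all__ = [
    "save_ktdata",
    "load_ktdata",
    "save_t2map",
    "load_t2map",
    "save_nifti_image",
    "load_nifti_image",
    "save_roi_mask",
    "load_roi_mask",
    "append_records_csv",
    "read_records_csv",
    "export_dicom_secondary",
]

RECORD_COLUMNS = [
    "subject_id",
    "lesion_id",
    "subtype",
    "who_isup_grade",
    "protocol",
    "median_t2_ms",
    "kurtosis",
    "skewness",
    "diameter_mm",
    "n_pixels",
]


def _affine(pixel_spacing_mm: tuple[float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = pixel_spacing_mm[0]
    aff[1, 1] = pixel_spacing_mm[1]
    return aff


# -- k-t container ----------------------------------------------------------


def save_ktdata(path: str | Path, ktdata: KtData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=ktdata.kspace)
        f.create_dataset("mask", data=ktdata.mask.mask)
        f.create_dataset("echo_times_ms", data=ktdata.echo_times_ms)
        if ktdata.coil_maps is not None:
            f.create_dataset("coil_maps", data=ktdata.coil_maps)
        f.attrs["center_lines"] = ktdata.mask.center_lines
        f.attrs["seed"] = ktdata.mask.seed
        f.attrs["scheme"] = ktdata.mask.scheme
        f.attrs["acceleration"] = ktdata.mask.acceleration
        f.attrs["protocol_name"] = ktdata.protocol_name


def load_ktdata(path: str | Path) -> KtData:
    with h5py.File(path, "r") as f:
        mask = KtMask(
            mask=f["mask"][()].astype(bool),
            center_lines=int(f.attrs["center_lines"]),
            seed=int(f.attrs["seed"]),
            scheme=str(f.attrs["scheme"]),
            acceleration=float(f.attrs["acceleration"]),
        )
        return KtData(
            kspace=f["kspace"][()],
            mask=mask,
            echo_times_ms=f["echo_times_ms"][()],
            coil_maps=f["coil_maps"][()] if "coil_maps" in f else None,
            protocol_name=str(f.attrs.get("protocol_name", "")),
        )


# -- NIfTI ------------------------------------------------------------------


def save_nifti_image(
    path: str | Path,
    data: np.ndarray,
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
) -> None:
    """Write a 2-D or 3-D float volume (e.g. magnitude echo series x×y×t)."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(pixel_spacing_mm))
    nib.save(img, str(path))


def load_nifti_image(path: str | Path) -> tuple[np.ndarray, tuple[float, float]]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return np.asarray(img.dataobj, dtype=np.float32), (float(zooms[0]), float(zooms[1]))


def save_t2map(path_base: str | Path, t2map: T2MapResult) -> dict[str, Path]:
    """Write T2/amplitude/B1/residual/valid as companion NIfTI volumes.

    ``path_base`` is extended with suffixes; returns the written paths.
    """
    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name.removesuffix(".nii.gz").removesuffix(".nii")
    paths = {}
    for suffix, data in (
        ("t2_ms", t2map.t2_ms),
        ("amplitude", t2map.amplitude),
        ("b1", np.nan_to_num(t2map.b1_scale, nan=0.0)),
        ("residual", np.nan_to_num(t2map.residual, nan=0.0)),
        ("valid", t2map.valid.astype(np.float32)),
    ):
        p = base.parent / f"{stem}_{suffix}.nii.gz"
        save_nifti_image(p, data, t2map.pixel_spacing_mm)
        paths[suffix] = p
    return paths


def load_t2map(path_base: str | Path) -> T2MapResult:
    base = Path(path_base)
    stem = base.name.removesuffix(".nii.gz").removesuffix(".nii")

    def rd(suffix):
        return load_nifti_image(base.parent / f"{stem}_{suffix}.nii.gz")

    t2, spacing = rd("t2_ms")
    amp, _ = rd("amplitude")
    b1, _ = rd("b1")
    resid, _ = rd("residual")
    valid, _ = rd("valid")
    valid = valid > 0.5
    resid = resid.astype(float)
    resid[~valid] = np.nan
    b1 = b1.astype(float)
    b1[~valid] = np.nan
    return T2MapResult(
        t2_ms=t2.astype(float),
        amplitude=amp.astype(float),
        b1_scale=b1,
        residual=resid,
        valid=valid,
        pixel_spacing_mm=spacing,
    )


def save_roi_mask(path: str | Path, roi: RoiMask,
                  pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)) -> None:
    img = nib.Nifti1Image(
        roi.labels.astype(np.int16), _affine(pixel_spacing_mm)
    )
    img.header["descrip"] = ";".join(
        f"{k}:{v}" for k, v in sorted(roi.label_names.items())
    ).encode()[:80]
    nib.save(img, str(path))


def load_roi_mask(path: str | Path) -> RoiMask:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    desc = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="ignore")
    names = {}
    for chunk in desc.split(";"):
        if ":" in chunk:
            k, v = chunk.split(":", 1)
            try:
                names[int(k)] = v
            except ValueError:
                continue
    if not names:
        names = {int(v): str(v) for v in np.unique(labels) if v > 0}
    return RoiMask(labels=labels, label_names=names)


# -- CSV --------------------------------------------------------------------


def append_records_csv(path: str | Path, frame: pd.DataFrame) -> None:
    """Append lesion records; writes the fixed documented header when new."""
    path = Path(path)
    frame = frame[RECORD_COLUMNS]
    header = not path.exists()
    frame.to_csv(path, mode="a", header=header, index=False, encoding="utf-8")


def read_records_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    return df


# -- DICOM convenience export ----------------------------------------------


def export_dicom_secondary(path: str | Path, t2map: T2MapResult) -> None:
    """Write the T2 map as a DICOM secondary-capture image (uint16, ms×10)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import SecondaryCaptureImageStorage, generate_uid, ExplicitVRLittleEndian

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.SeriesDescription = "T2 map (0.1 ms units)"
    ds.Rows, ds.Columns = t2map.t2_ms.shape
    ds.PixelSpacing = [str(t2map.pixel_spacing_mm[0]), str(t2map.pixel_spacing_mm[1])]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = "0.1"
    ds.RescaleIntercept = "0"
    scaled = np.where(t2map.valid, t2map.t2_ms, 0.0) * 10.0
    ds.PixelData = np.clip(scaled, 0, 65535).astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)
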