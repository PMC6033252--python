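"""Read/write single-frame grayscale DICOM objects.

Only the uncompressed little-endian transfer syntaxes are supported: the
pipeline re-encodes pixel data itself, so transfer-syntax breadth is
plumbing, not method.  Metadata survival is governed by an explicit
whitelist (default: the five search-engine fields plus geometry), because
the downstream container format must bound its metadata section.

Field mapping to standard DICOM attributes:

====================  =============================================
whitelist key         DICOM attribute
====================  =============================================
PatientName           PatientName, given-name component
PatientSurname        PatientName, family-name component
CitizenshipID         PatientID
StudyDate             StudyDate
HIMSID                AccessionNumber (the HIS primary key)
====================  =============================================
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.errors import InvalidDicomError
from pydicom.uid import ExplicitVRLittleEndian, ImplicitVRLittleEndian

from .errors import DicomFormatError, PixelRangeError, UnsupportedSyntaxError

__all__ = ["ImageRecord", "read_dicom", "write_dicom", "METADATA_WHITELIST"]

METADATA_WHITELIST = (
    "HIMSID",
    "PatientName",
    "PatientSurname",
    "CitizenshipID",
    "StudyDate",
)

_MR_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.4"
_UID_ROOT = "2.25."


@dataclass
class ImageRecord:
    """A decoded grayscale image plane plus its DICOM-style metadata map."""

    pixels: np.ndarray
    bits_stored: int
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not (8 <= self.bits_stored <= 16):
            raise PixelRangeError(f"bits_stored {self.bits_stored} outside [8, 16]")
        if int(self.pixels.min()) < 0 or int(self.pixels.max()) >= 1 << self.bits_stored:
            raise PixelRangeError(
                f"pixel values exceed {self.bits_stored}-bit range"
            )
        if len(self.metadata) != len(set(self.metadata)):
            raise ValueError("duplicate metadata keys")

    @property
    def rows(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def cols(self) -> int:
        return int(self.pixels.shape[1])


def _content_uid(rec: ImageRecord) -> str:
    """Deterministic SOP instance UID derived from pixel + metadata content."""
    h = hashlib.md5()
    h.update(rec.pixels.astype("<u2").tobytes())
    for k in sorted(rec.metadata):
        h.update(k.encode())
        h.update(rec.metadata[k].encode())
    return _UID_ROOT + str(int.from_bytes(h.digest(), "big") % 10**36)


def write_dicom(rec: ImageRecord, whitelist: tuple[str, ...] = METADATA_WHITELIST) -> bytes:
    """Serialize to an explicit-VR little-endian Part-10 DICOM stream.

    Absent whitelist fields are simply omitted; ``read_dicom`` of the result
    reproduces the pixel matrix bit-exactly.
    """
    bytes_per_px = 2 if rec.bits_stored > 8 else 1
    ds = Dataset()
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _MR_IMAGE_STORAGE
    meta.MediaStorageSOPInstanceUID = _content_uid(rec)
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    ds.SOPClassUID = _MR_IMAGE_STORAGE
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"

    md = {k: v for k, v in rec.metadata.items() if k in whitelist}
    surname = md.get("PatientSurname", "")
    name = md.get("PatientName", "")
    if surname or name:
        ds.PatientName = f"{surname}^{name}"
    if "CitizenshipID" in md:
        ds.PatientID = md["CitizenshipID"]
    if "StudyDate" in md:
        ds.StudyDate = md["StudyDate"].replace("-", "")
    if "HIMSID" in md:
        ds.AccessionNumber = md["HIMSID"]

    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows = rec.rows
    ds.Columns = rec.cols
    ds.BitsAllocated = 8 * bytes_per_px
    ds.BitsStored = rec.bits_stored
    ds.HighBit = rec.bits_stored - 1
    ds.PixelRepresentation = 0
    dtype = "<u2" if bytes_per_px == 2 else "u1"
    ds.PixelData = rec.pixels.astype(dtype).tobytes()

    buf = io.BytesIO()
    pydicom.dcmwrite(buf, ds, enforce_file_format=True)
    return buf.getvalue()


def read_dicom(stream: bytes, whitelist: tuple[str, ...] = METADATA_WHITELIST) -> ImageRecord:
    """Parse a DICOM stream into an :class:`ImageRecord`.

    Raises :class:`DicomFormatError` on unparseable input and
    :class:`UnsupportedSyntaxError` for compressed transfer syntaxes.
    """
    if not stream:
        raise DicomFormatError("empty stream")
    try:
        ds = pydicom.dcmread(io.BytesIO(stream))
    except (InvalidDicomError, EOFError) as exc:
        raise DicomFormatError(f"not a parseable DICOM object: {exc}") from exc
    syntax = getattr(getattr(ds, "file_meta", None), "TransferSyntaxUID", None)
    if syntax is not None and syntax not in (ExplicitVRLittleEndian, ImplicitVRLittleEndian):
        raise UnsupportedSyntaxError(f"unsupported transfer syntax {syntax}")
    if "PixelData" not in ds:
        raise DicomFormatError("DICOM object has no pixel data")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise DicomFormatError("only single-sample grayscale images are supported")
    try:
        pixels = ds.pixel_array
    except Exception as exc:  # pydicom wraps handler errors loosely
        raise DicomFormatError(f"cannot decode pixel data: {exc}") from exc
    if pixels.ndim != 2:
        raise DicomFormatError("only single-frame images are supported")

    metadata: dict[str, str] = {}
    pn = getattr(ds, "PatientName", None)
    if pn is not None and str(pn):
        parts = str(pn).split("^")
        if parts[0] and "PatientSurname" in whitelist:
            metadata["PatientSurname"] = parts[0]
        if len(parts) > 1 and parts[1] and "PatientName" in whitelist:
            metadata["PatientName"] = parts[1]
    if getattr(ds, "PatientID", "") and "CitizenshipID" in whitelist:
        metadata["CitizenshipID"] = str(ds.PatientID)
    sd = str(getattr(ds, "StudyDate", ""))
    if sd and "StudyDate" in whitelist:
        if len(sd) == 8 and sd.isdigit():
            sd = f"{sd[:4]}-{sd[4:6]}-{sd[6:]}"
        metadata["StudyDate"] = sd
    if getattr(ds, "AccessionNumber", "") and "HIMSID" in whitelist:
        metadata["HIMSID"] = str(ds.AccessionNumber)

    return ImageRecord(
        pixels=pixels,
        bits_stored=int(getattr(ds, "BitsStored", 8 * pixels.dtype.itemsize)),
        metadata=metadata,
    )
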