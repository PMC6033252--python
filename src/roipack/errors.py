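"""Exception hierarchy shared by all roipack modules."""


class RoipackError(Exception):
    """Base class for all errors raised by roipack."""


class SizingError(RoipackError):
    """Requested phantom geometry cannot fit (ROI fraction vs text margins)."""


class UnsupportedCharacterError(RoipackError):
    """A character has no glyph in the font atlas."""


class DicomFormatError(RoipackError):
    """Stream is not a parseable DICOM object or violates the supported subset."""


class UnsupportedSyntaxError(DicomFormatError):
    """DICOM transfer syntax outside the uncompressed little-endian subset."""


class PixelRangeError(RoipackError):
    """Pixel values exceed the declared bit depth."""


class DegenerateImageError(RoipackError):
    """Image has no contrast to segment (constant intensity)."""


class DegenerateResultError(RoipackError):
    """Segmentation converged to an all-foreground/all-background mask or a tie."""


class EmptyMaskError(RoipackError):
    """Operation requires at least one foreground pixel."""


class EmptyPayloadError(RoipackError):
    """Huffman codebook construction needs a non-empty payload."""


class CoverageError(RoipackError):
    """Payload contains a symbol absent from the codebook."""


class StructureError(RoipackError):
    """Serialized codebook bytes do not follow the documented layout."""


class TruncationError(RoipackError):
    """Bitstream or container ended mid-record."""


class FormatError(RoipackError):
    """Bad magic / header in a roipack binary stream."""


class ConsistencyError(RoipackError):
    """Internally inconsistent container (counts or sizes disagree)."""


class CompletenessError(RoipackError):
    """A record to be written is missing a required field."""


class KeyConflictError(RoipackError):
    """Archive put() would overwrite an existing HIMS ID without permission."""


class NotFoundError(RoipackError):
    """No archive entry under the requested HIMS ID."""


class EmptyCriteriaError(RoipackError):
    """Criteria search invoked with no criteria (unbounded scan refused)."""
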