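"""Image and table I/O for the ultrasound IMF pipeline.

Reads 8-bit grayscale B-mode scans from uncompressed single-frame DICOM or
PNG, defines rectangular regions of interest (ROIs), and round-trips feature
tables as CSV.

Coordinate convention: 0-based, half-open, with ``y`` the row index
increasing downward and ``x`` the column index increasing rightward — i.e.
``pixels[y, x]``, matching how the image is displayed on screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid
from PIL import Image

__all__ = [
    "UltrasoundImage",
    "ROI",
    "ROIPatch",
    "MIN_ROI_SIDE",
    "read_image",
    "write_image",
    "extract_patch",
    "sample_roi",
    "write_feature_table",
    "read_feature_table",
]

#: Minimum ROI side length in pixels.  Offset-5 co-occurrence matrices and a
#: depth-2 Haar decomposition both need at least 16 pixels per side.
MIN_ROI_SIDE = 16


@dataclass
class UltrasoundImage:
    """A single-frame 8-bit grayscale ultrasound scan."""

    pixels: np.ndarray
    source_id: str = ""
    acquisition_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise ValueError("image must be at least 2x2 pixels")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ROI:
    """Rectangular region ``[x0, x0+width) x [y0, y0+height)``."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < MIN_ROI_SIDE or self.height < MIN_ROI_SIDE:
            raise ValueError(f"ROI sides must be >= {MIN_ROI_SIDE} pixels")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI origin must be non-negative")

    @property
    def area(self) -> int:
        return self.width * self.height


@dataclass
class ROIPatch:
    """Pixel grid cut from an image by an ROI, carrying its provenance."""

    pixels: np.ndarray
    source_id: str = ""
    roi: ROI | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("patch must be 2-D")
        if self.roi is not None and self.pixels.shape != (self.roi.height, self.roi.width):
            raise ValueError("patch dimensions must match the ROI")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def extract_patch(image: UltrasoundImage, roi: ROI) -> ROIPatch:
    """Cut the ROI out of the image (half-open bounds, bounds-checked)."""
    if roi.x0 + roi.width > image.width or roi.y0 + roi.height > image.height:
        raise ValueError(
            f"ROI {roi} does not fit inside a {image.height}x{image.width} image"
        )
    px = image.pixels[roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width].copy()
    return ROIPatch(pixels=px, source_id=image.source_id, roi=roi)


# ---------------------------------------------------------------------------
# image reading / writing
# ---------------------------------------------------------------------------

_DICOM_META_FIELDS = {
    "frequency": "TransducerFrequency",
    "depth": "DepthOfScanField",
    "gain": "OverallGain",
    "manufacturer": "Manufacturer",
    "modality": "Modality",
}


def read_image(path: str | Path) -> UltrasoundImage:
    """Read an 8-bit grayscale scan from DICOM or PNG.

    DICOM files must be single-frame, uncompressed and 8 bits allocated;
    MONOCHROME1 images (inverted display convention) are flipped so that
    higher values are brighter.  Anything else is rejected with an explicit
    message rather than silently converted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in (".dcm", ".dicom"):
        return _read_dicom(path)
    return _read_png(path)


def _read_dicom(path: Path) -> UltrasoundImage:
    ds = pydicom.dcmread(str(path))
    tsyntax = ds.file_meta.TransferSyntaxUID
    if tsyntax.is_compressed:
        raise ValueError(f"unsupported transfer syntax (compressed DICOM): {tsyntax}")
    nframes = int(getattr(ds, "NumberOfFrames", 1))
    if nframes != 1:
        raise ValueError(f"multi-frame DICOM not supported ({nframes} frames)")
    if int(ds.BitsAllocated) != 8:
        raise ValueError(f"only 8-bit images are supported (BitsAllocated={ds.BitsAllocated})")
    photo = str(ds.PhotometricInterpretation)
    if photo not in ("MONOCHROME1", "MONOCHROME2"):
        raise ValueError(f"color images are not supported ({photo})")
    px = ds.pixel_array.astype(np.uint8)
    if photo == "MONOCHROME1":  # inverted grayscale: flip to higher = brighter
        px = 255 - px
    meta = {}
    for key, tag in _DICOM_META_FIELDS.items():
        if hasattr(ds, tag):
            meta[key] = str(getattr(ds, tag))
    return UltrasoundImage(pixels=px, source_id=path.stem, acquisition_meta=meta)


def _read_png(path: Path) -> UltrasoundImage:
    img = Image.open(path)
    if img.mode == "I;16" or img.mode.startswith("I"):
        raise ValueError(f"only 8-bit images are supported (PNG mode {img.mode})")
    if img.mode != "L":
        raise ValueError(f"color images are not supported (PNG mode {img.mode})")
    return UltrasoundImage(pixels=np.asarray(img), source_id=path.stem)


def write_image(image: UltrasoundImage, path: str | Path) -> Path:
    """Write a scan as uncompressed 8-bit DICOM (``.dcm``) or PNG (``.png``)."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        _write_dicom(image, path)
    elif path.suffix.lower() == ".png":
        Image.fromarray(image.pixels, mode="L").save(path)
    else:
        raise ValueError(f"unsupported image extension: {path.suffix}")
    return path


def _write_dicom(image: UltrasoundImage, path: Path) -> None:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.PatientName = ""
    ds.PatientID = image.source_id or "SYNTH"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = image.pixels.shape
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = image.pixels.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# ROI sampling
# ---------------------------------------------------------------------------

def sample_roi(
    image: UltrasoundImage,
    area_mean: float = 33952.15,
    area_sd: float = 15146.17,
    aspect_range: tuple[float, float] = (0.5, 2.0),
    rng_seed: int | np.random.Generator = 0,
) -> ROI:
    """Randomly place a rectangular ROI mimicking manual selection.

    The target area is drawn from a normal distribution (defaults match the
    observed mean/SD of manually drawn ROIs, ~33,952 px ± 15,146 px) and
    clipped to what the image can hold; the aspect ratio (width/height) is
    uniform over ``aspect_range``; the position is uniform over all valid
    placements.  Deterministic for a fixed seed.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    if image.width < MIN_ROI_SIDE or image.height < MIN_ROI_SIDE:
        raise ValueError(
            f"image {image.height}x{image.width} cannot contain a "
            f"{MIN_ROI_SIDE}x{MIN_ROI_SIDE} ROI"
        )
    lo, hi = aspect_range
    if not (0 < lo <= hi):
        raise ValueError("aspect_range must be positive and ordered")
    aspect = rng.uniform(lo, hi)
    # both sides >= MIN_ROI_SIDE forces a minimum area for this aspect ratio
    min_area = MIN_ROI_SIDE**2 * max(aspect, 1.0 / aspect)
    max_area = image.width * image.height
    area = float(np.clip(rng.normal(area_mean, area_sd) if area_sd > 0 else area_mean,
                         min_area, max_area))
    width = int(round(math.sqrt(area * aspect)))
    height = int(round(math.sqrt(area / aspect)))
    width = int(np.clip(width, MIN_ROI_SIDE, image.width))
    height = int(np.clip(height, MIN_ROI_SIDE, image.height))
    x0 = int(rng.integers(0, image.width - width + 1))
    y0 = int(rng.integers(0, image.height - height + 1))
    return ROI(x0=x0, y0=y0, width=width, height=height)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

_ID_COL = "source_id"
_QA_COL = "IMFqa"


def write_feature_table(
    records: Sequence[tuple],
    path: str | Path,
) -> Path:
    """Write ``(source_id, FeatureVector, [IMFqa])`` records as CSV.

    One row per ROI, one column per descriptor using the canonical MaZda-style
    names.  Values survive a round-trip to at least 12 significant digits.
    All records must share the same descriptor set.
    """
    path = Path(path)
    rows = []
    names: list[str] | None = None
    has_qa = False
    for rec in records:
        if len(rec) == 3:
            source_id, fv, qa = rec
            has_qa = has_qa or qa is not None
        else:
            source_id, fv = rec
            qa = None
        rec_names = list(fv.values.keys())
        if names is None:
            names = rec_names
        elif rec_names != names:
            raise ValueError("inconsistent descriptor sets across records")
        row = {_ID_COL: source_id}
        if qa is not None:
            row[_QA_COL] = qa
        row.update(fv.values)
        rows.append(row)
    if names is None:
        names = []
    cols = [_ID_COL] + ([_QA_COL] if has_qa else []) + names
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path: str | Path):
    """Read a feature CSV back into ``(source_id, FeatureVector, IMFqa|None)``."""
    from .texture_features import FeatureVector

    df = pd.read_csv(path)
    if _ID_COL not in df.columns:
        raise ValueError(f"feature table is missing the '{_ID_COL}' column")
    feature_cols = [c for c in df.columns if c not in (_ID_COL, _QA_COL)]
    records = []
    for _, row in df.iterrows():
        fv = FeatureVector({c: float(row[c]) for c in feature_cols})
        qa = float(row[_QA_COL]) if _QA_COL in df.columns else None
        records.append((row[_ID_COL], fv, qa))
    return records


def feature_frame(records: Iterable[tuple]) -> pd.DataFrame:
    """Convenience: records -> DataFrame indexed by source_id."""
    rows = {}
    for rec in records:
        source_id, fv = rec[0], rec[1]
        rows[source_id] = fv.values
    return pd.DataFrame.from_dict(rows, orient="index")
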