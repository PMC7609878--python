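"""Read/write the standard formats: lambda stacks, plate CSVs, GP maps.

Lambda stacks are multi-page TIFFs (one page per emission channel) with
channel center wavelengths supplied by a JSON sidecar, embedded metadata
(OME-XML or a JSON image description written by this package), or an
explicit list. Plate-reader data is plain CSV with one row per
(well, flash, wavelength) sample.
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, InvalidParameterError, ValidationError
from .spectra import EmissionSpectrum

__all__ = [
    "SpectralImage",
    "PlateRecord",
    "channel_grid",
    "read_spectral_image",
    "write_spectral_image",
    "read_plate_csv",
    "write_plate_csv",
    "plate_records_to_frame",
    "write_gp_map",
    "read_gp_map",
    "write_label_map",
    "read_label_map",
]

PLATE_COLUMNS = ["well", "condition_mM", "flash", "wavelength_nm", "intensity"]


@dataclass
class SpectralImage:
    """A lambda stack: H x W pixels with a C-channel emission spectrum each.

    ``intensities`` has shape (H, W, C); ``channel_centers`` holds the C
    channel center wavelengths in nm, strictly increasing.
    """

    intensities: np.ndarray
    channel_centers: np.ndarray
    excitation_nm: float | None = None
    pixel_size_um: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        centers = np.asarray(self.channel_centers, dtype=float)
        if arr.ndim != 3:
            raise ValidationError(f"intensities must be H x W x C, got shape {arr.shape}")
        if centers.ndim != 1 or centers.size != arr.shape[2]:
            raise ValidationError(
                f"channel count mismatch: {arr.shape[2]} channels vs "
                f"{centers.size} wavelengths"
            )
        if not np.all(np.isfinite(centers)) or not np.all(np.diff(centers) > 0):
            raise ValidationError("channel_centers must be finite and strictly increasing")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("intensities must be finite")
        if np.any(arr < 0):
            raise ValidationError("intensities must be nonnegative")
        self.intensities = arr
        self.channel_centers = centers

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def n_channels(self) -> int:
        return int(self.channel_centers.size)

    def pixel_spectrum(self, row: int, col: int) -> EmissionSpectrum:
        """The emission spectrum of one pixel."""
        return EmissionSpectrum(
            self.channel_centers, self.intensities[row, col], self.excitation_nm
        )

    def summed_intensity(self) -> np.ndarray:
        """H x W map of per-pixel summed intensity over all channels."""
        return self.intensities.sum(axis=2)


@dataclass
class PlateRecord:
    """One plate-reader flash: a full emission spectrum for one well."""

    well: str
    condition: float  # calcium concentration, mM
    flash: int
    spectrum: EmissionSpectrum

    def __post_init__(self) -> None:
        if self.flash < 1:
            raise ValidationError(f"flash index must be >= 1, got {self.flash}")


def channel_grid(range_start: float, range_end: float, interval: float) -> np.ndarray:
    """Channel center wavelengths tiling ``[range_start, range_end]``.

    The channel count is the smallest ``n`` such that
    ``range_start + n * interval >= range_end``; centers are
    ``range_start + i * interval`` for ``i = 0 .. n-1``. With the 415-691 nm
    range at 8.9 nm intervals this yields 32 channels.
    """
    if interval <= 0:
        raise InvalidParameterError(f"interval must be positive, got {interval}")
    if range_end <= range_start:
        raise InvalidParameterError("range_end must exceed range_start")
    n = int(np.ceil((range_end - range_start) / interval - 1e-12))
    n = max(n, 1)
    return range_start + interval * np.arange(n, dtype=float)


# ---------------------------------------------------------------------------
# Lambda-stack TIFF I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def write_spectral_image(path: str | Path, image: SpectralImage) -> Path:
    """Write a lambda stack as a multi-page float32 TIFF plus JSON sidecar.

    Returns the sidecar path. The sidecar records the channel wavelengths,
    excitation wavelength and pixel size; the same metadata is embedded in
    the TIFF image description so the file is self-contained.
    """
    path = Path(path)
    meta = {
        "channel_centers_nm": [float(w) for w in image.channel_centers],
        "excitation_nm": image.excitation_nm,
        "pixel_size_um": image.pixel_size_um,
        "source_id": image.source_id,
    }
    pages = np.moveaxis(image.intensities.astype(np.float32), 2, 0)  # C,H,W
    tifffile.imwrite(path, pages, photometric="minisblack", description=json.dumps(meta))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def _wavelengths_from_ome(xml_text: str) -> list[float] | None:
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return None
    out: list[float] = []
    for ch in root.iter():
        if ch.tag.endswith("Channel") and "EmissionWavelength" in ch.attrib:
            out.append(float(ch.attrib["EmissionWavelength"]))
    return out or None


def read_spectral_image(
    path: str | Path,
    wavelength_source: str = "sidecar",
    wavelengths: list[float] | np.ndarray | None = None,
) -> SpectralImage:
    """Read a multi-page TIFF lambda stack with wavelength metadata.

    Parameters
    ----------
    wavelength_source : {'sidecar', 'embedded', 'explicit'}
        Where channel center wavelengths come from: a ``<file>.json``
        sidecar, metadata embedded in the TIFF (OME-XML
        ``EmissionWavelength`` attributes or this package's JSON image
        description), or the ``wavelengths`` argument.

    Pages are reordered so channels are ascending in wavelength regardless
    of page order on disk.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta: dict = {}
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        if pages.ndim == 2:
            pages = pages[None]
        if tif.ome_metadata and wavelength_source == "embedded":
            ome = _wavelengths_from_ome(tif.ome_metadata)
            if ome is not None:
                meta["channel_centers_nm"] = ome
        desc = tif.pages[0].description
    if wavelength_source == "explicit":
        if wavelengths is None:
            raise InvalidParameterError("wavelength_source='explicit' requires wavelengths")
        meta["channel_centers_nm"] = list(np.asarray(wavelengths, dtype=float))
    elif wavelength_source == "sidecar":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FormatError(f"wavelength sidecar not found: {sidecar}")
        meta = json.loads(sidecar.read_text())
    elif wavelength_source == "embedded":
        if "channel_centers_nm" not in meta:
            if not desc:
                raise FormatError(f"no embedded wavelength metadata in {path}")
            try:
                meta = json.loads(desc)
            except json.JSONDecodeError as exc:
                raise FormatError(
                    f"image description of {path} is neither OME-XML with "
                    f"emission wavelengths nor JSON metadata"
                ) from exc
    else:
        raise InvalidParameterError(
            f"unknown wavelength_source {wavelength_source!r}; "
            "expected 'sidecar', 'embedded' or 'explicit'"
        )
    if "channel_centers_nm" not in meta:
        raise FormatError(f"wavelength metadata for {path} lacks 'channel_centers_nm'")
    centers = np.asarray(meta["channel_centers_nm"], dtype=float)
    if centers.size != pages.shape[0]:
        raise FormatError(
            f"{path}: {pages.shape[0]} TIFF pages but {centers.size} wavelengths"
        )
    order = np.argsort(centers, kind="stable")
    centers = centers[order]
    if not np.all(np.diff(centers) > 0):
        raise FormatError(f"{path}: channel wavelengths are not distinct/monotone")
    stack = np.moveaxis(pages[order].astype(float), 0, 2)
    try:
        return SpectralImage(
            intensities=stack,
            channel_centers=centers,
            excitation_nm=meta.get("excitation_nm"),
            pixel_size_um=meta.get("pixel_size_um"),
            source_id=meta.get("source_id") or str(path),
        )
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Plate-reader CSV I/O


def plate_records_to_frame(records: list[PlateRecord]) -> pd.DataFrame:
    """Flatten records into the long-format plate table (one row per sample)."""
    frames = []
    for rec in records:
        frames.append(
            pd.DataFrame(
                {
                    "well": rec.well,
                    "condition_mM": rec.condition,
                    "flash": rec.flash,
                    "wavelength_nm": rec.spectrum.wavelengths,
                    "intensity": rec.spectrum.intensities,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_plate_csv(path: str | Path, records: list[PlateRecord]) -> None:
    """Write plate records as CSV with the standard five columns."""
    plate_records_to_frame(records).to_csv(path, index=False)


def read_plate_csv(path: str | Path, clamp_negative: bool = False) -> list[PlateRecord]:
    """Parse a plate CSV into per-(well, flash) records.

    Rows may appear in any order; spectra are assembled per (well, flash)
    group and sorted by wavelength. Negative intensities raise a
    :class:`ValidationError` unless ``clamp_negative`` is set, in which case
    they are clamped to zero with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise FormatError(f"{path}: plate file contains no records")
    neg = df["intensity"] < 0
    if neg.any():
        if clamp_negative:
            warnings.warn(
                f"{path}: clamped {int(neg.sum())} negative intensities to 0",
                stacklevel=2,
            )
            df.loc[neg, "intensity"] = 0.0
        else:
            raise ValidationError(f"{path}: {int(neg.sum())} negative intensities")
    records: list[PlateRecord] = []
    for (well, cond, flash), grp in df.groupby(["well", "condition_mM", "flash"], sort=True):
        grp = grp.sort_values("wavelength_nm")
        wl = grp["wavelength_nm"].to_numpy(dtype=float)
        if np.any(np.diff(wl) <= 0):
            raise FormatError(
                f"{path}: duplicate wavelengths for well {well!r} flash {flash}"
            )
        records.append(
            PlateRecord(
                well=str(well),
                condition=float(cond),
                flash=int(flash),
                spectrum=EmissionSpectrum(wl, grp["intensity"].to_numpy(dtype=float)),
            )
        )
    return records


# ---------------------------------------------------------------------------
# GP-map and label-map TIFF I/O


def write_gp_map(path: str | Path, gp: np.ndarray, valid_mask: np.ndarray) -> None:
    """Write a GP map as a 2-page float32 TIFF: page 0 GP (NaN where
    invalid), page 1 the validity mask as 0/1."""
    gp = np.asarray(gp, dtype=np.float32).copy()
    mask = np.asarray(valid_mask, dtype=bool)
    gp[~mask] = np.nan
    tifffile.imwrite(
        path, np.stack([gp, mask.astype(np.float32)]), photometric="minisblack"
    )


def read_gp_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a GP map written by :func:`write_gp_map`; returns (gp, mask)."""
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise FormatError(f"{path}: expected a 2-page GP/mask TIFF, got shape {arr.shape}")
    return arr[0].astype(float), arr[1].astype(bool)


def write_label_map(path: str | Path, labels: np.ndarray) -> None:
    """Write an integer label map (0 background, 1 interior, 2 membrane)."""
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint8), photometric="minisblack")


def read_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(int)
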