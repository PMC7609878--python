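"""Synthetic hyperspectral cells and plate-reader spectra with known
ground-truth membrane order.

The solvatochromic two-state picture is modeled with two unimodal basis
emission spectra — a blue-shifted "ordered" state peaking near 440 nm and a
red-shifted "disordered" (fluid) state peaking near 490 nm. A pixel or well
with ordered fraction ``phi`` emits the convex combination
``phi * ordered + (1 - phi) * disordered``; ground truth is parameterized as
``phi`` (not as a GP value) so recovered GP is a genuine pipeline output.

Cell phantoms are a disk with an ordered plasma-membrane ring and a more
fluid interior; plate wells pool a membrane and an interior population. A
logistic (Hill-type) map converts calcium concentration to membrane order,
with a collapse condition (brightness drop, mask fragmentation) at and above
a disruption threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError, InvalidParameterError
from .gp import gp_from_spectrum
from .spectra import EmissionSpectrum
from .spectral_io import PlateRecord, SpectralImage, channel_grid

__all__ = [
    "BasisSpectra",
    "CellPhantomConfig",
    "HillOrderMap",
    "CalciumSeriesConfig",
    "default_imaging_grid",
    "default_plate_grid",
    "make_basis_spectra",
    "mix_spectrum",
    "make_cell_image",
    "make_calcium_series",
    "LABEL_BACKGROUND",
    "LABEL_INTERIOR",
    "LABEL_MEMBRANE",
]

LABEL_BACKGROUND = 0
LABEL_INTERIOR = 1
LABEL_MEMBRANE = 2


def default_imaging_grid() -> np.ndarray:
    """32-channel confocal detection grid: 415-691 nm at 8.9 nm intervals."""
    return channel_grid(415.0, 691.0, 8.9)


def default_plate_grid(step: float = 5.0) -> np.ndarray:
    """Plate-reader emission grid covering 405-600 nm."""
    return channel_grid(405.0, 600.0 + step, step)


@dataclass(frozen=True)
class BasisSpectra:
    """The two solvatochromic emission states on a common wavelength grid.

    ``ordered_spectrum`` peaks near 440 nm (tightly packed lipids),
    ``disordered_spectrum`` near 490 nm (fluid membrane); both have unit
    peak amplitude.
    """

    ordered_spectrum: EmissionSpectrum
    disordered_spectrum: EmissionSpectrum

    def __post_init__(self) -> None:
        o, d = self.ordered_spectrum, self.disordered_spectrum
        if not np.array_equal(o.wavelengths, d.wavelengths):
            raise InvalidConfigError("basis spectra must share one wavelength grid")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.ordered_spectrum.wavelengths

    def analytic_gp(self, order: float) -> float:
        """GP of the noiseless mixture with ordered fraction ``order``."""
        return gp_from_spectrum(mix_spectrum(self, order, 1.0)).gp

    @property
    def gp_separation(self) -> float:
        """Analytic GP difference between the pure ordered and fluid states."""
        return self.analytic_gp(1.0) - self.analytic_gp(0.0)


def make_basis_spectra(
    grid: np.ndarray | None = None,
    ordered_peak: float = 440.0,
    disordered_peak: float = 490.0,
    width: float = 45.0,
) -> BasisSpectra:
    """Gaussian basis emission spectra for the two membrane states.

    ``width`` is the Gaussian standard deviation in nm. Both profiles are
    unimodal, nonnegative and unit peak amplitude on the grid; with the
    default 440/490 nm peaks the ordered basis has positive GP and the
    disordered basis negative GP.
    """
    if grid is None:
        grid = default_imaging_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise InvalidConfigError("grid must be a strictly increasing 1-D vector")
    if width <= 0:
        raise InvalidConfigError(f"width must be positive, got {width}")
    for name, peak in (("ordered_peak", ordered_peak), ("disordered_peak", disordered_peak)):
        if not (grid[0] <= peak <= grid[-1]):
            raise InvalidConfigError(
                f"{name}={peak} nm lies outside the grid range "
                f"[{grid[0]}, {grid[-1]}] nm"
            )

    def gaussian(peak: float) -> EmissionSpectrum:
        return EmissionSpectrum(grid, np.exp(-0.5 * ((grid - peak) / width) ** 2))

    return BasisSpectra(gaussian(ordered_peak), gaussian(disordered_peak))


def mix_spectrum(basis: BasisSpectra, order: float, brightness: float) -> EmissionSpectrum:
    """Noiseless two-state mixture ``brightness * (phi*ordered + (1-phi)*disordered)``."""
    if not (0.0 <= order <= 1.0):
        raise InvalidParameterError(f"ordered fraction must be in [0, 1], got {order}")
    if brightness < 0:
        raise InvalidParameterError(f"brightness must be nonnegative, got {brightness}")
    mixture = (
        order * basis.ordered_spectrum.intensities
        + (1.0 - order) * basis.disordered_spectrum.intensities
    )
    return EmissionSpectrum(basis.wavelengths, brightness * mixture)


# ---------------------------------------------------------------------------
# Cell phantom


@dataclass(frozen=True)
class CellPhantomConfig:
    """Geometry, photometry and noise settings for one synthetic cell.

    The phantom is a disk of ``outer_radius`` pixels whose outermost
    ``ring_thickness`` pixels form the plasma-membrane ring; the remainder is
    interior. ``brightness`` is the expected peak photon count per pixel.
    """

    image_size: tuple[int, int] = (64, 64)
    center: tuple[float, float] | None = None  # (row, col); default image center
    outer_radius: float = 24.0
    ring_thickness: float = 3.0
    interior_order: float = 0.3
    membrane_order: float = 0.8
    brightness: float = 500.0
    background_level: float = 0.0
    noise_model: str = "poisson"  # {"none", "poisson"}
    seed: int = 0

    def __post_init__(self) -> None:
        H, W = self.image_size
        if H < 4 or W < 4:
            raise InvalidConfigError(f"image_size too small: {self.image_size}")
        for name in ("interior_order", "membrane_order"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        if self.membrane_order < self.interior_order:
            raise InvalidConfigError(
                "membrane_order must be >= interior_order for a differentiating phantom"
            )
        if not (self.brightness > self.background_level >= 0):
            raise InvalidConfigError("need brightness > background_level >= 0")
        if self.ring_thickness <= 0 or self.ring_thickness > self.outer_radius:
            raise InvalidConfigError("need 0 < ring_thickness <= outer_radius")
        cy, cx = self.resolved_center
        if (
            cy - self.outer_radius < 0
            or cx - self.outer_radius < 0
            or cy + self.outer_radius > H - 1
            or cx + self.outer_radius > W - 1
        ):
            raise InvalidConfigError("ring geometry does not fit within image bounds")
        if self.noise_model not in ("none", "poisson"):
            raise InvalidConfigError(f"unknown noise_model {self.noise_model!r}")

    @property
    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        H, W = self.image_size
        return ((H - 1) / 2.0, (W - 1) / 2.0)


def _phantom_labels(config: CellPhantomConfig) -> np.ndarray:
    H, W = config.image_size
    cy, cx = config.resolved_center
    rr, cc = np.mgrid[0:H, 0:W]
    r = np.hypot(rr - cy, cc - cx)
    labels = np.full((H, W), LABEL_BACKGROUND, dtype=np.uint8)
    labels[r <= config.outer_radius] = LABEL_MEMBRANE
    labels[r <= config.outer_radius - config.ring_thickness] = LABEL_INTERIOR
    return labels


def make_cell_image(
    config: CellPhantomConfig, basis: BasisSpectra
) -> tuple[SpectralImage, np.ndarray]:
    """Render one synthetic cell as a lambda stack plus its label map.

    Ring pixels carry the membrane-order mixture spectrum, interior pixels
    the interior-order mixture, background pixels a flat
    ``background_level``. Poisson noise is applied channel-wise when
    requested; the same seed always reproduces the same image. The label map
    marks {0: background, 1: interior, 2: membrane}.
    """
    labels = _phantom_labels(config)
    C = basis.wavelengths.size
    expected = np.empty(config.image_size + (C,), dtype=float)
    expected[labels == LABEL_BACKGROUND] = config.background_level
    expected[labels == LABEL_INTERIOR] = mix_spectrum(
        basis, config.interior_order, config.brightness
    ).intensities
    expected[labels == LABEL_MEMBRANE] = mix_spectrum(
        basis, config.membrane_order, config.brightness
    ).intensities
    if config.noise_model == "poisson":
        rng = np.random.default_rng(config.seed)
        stack = rng.poisson(expected).astype(float)
    else:
        stack = expected
    image = SpectralImage(
        intensities=stack,
        channel_centers=basis.wavelengths,
        excitation_nm=405.0,
        source_id=f"phantom(seed={config.seed})",
    )
    return image, labels


# ---------------------------------------------------------------------------
# Calcium series


@dataclass(frozen=True)
class HillOrderMap:
    """Monotone saturating calcium -> membrane-order map.

    ``order(c) = floor + (ceiling - floor) * c^h / (c^h + half_max^h)``;
    non-decreasing in calcium for any positive half_max and steepness.
    """

    half_max_mM: float = 0.5
    steepness: float = 1.5
    floor: float = 0.25
    ceiling: float = 0.85

    def __post_init__(self) -> None:
        if self.half_max_mM <= 0 or self.steepness <= 0:
            raise InvalidConfigError("half_max_mM and steepness must be positive")
        if not (0.0 <= self.floor <= self.ceiling <= 1.0):
            raise InvalidConfigError("need 0 <= floor <= ceiling <= 1")

    def __call__(self, calcium_mM: float) -> float:
        c = float(calcium_mM)
        if c < 0:
            raise InvalidParameterError("calcium concentration must be nonnegative")
        ch = c**self.steepness
        return self.floor + (self.ceiling - self.floor) * ch / (
            ch + self.half_max_mM**self.steepness
        )


@dataclass(frozen=True)
class CalciumSeriesConfig:
    """A calcium-switch experiment: wells x flashes per calcium level.

    At levels at or above ``disruption_threshold_mM`` cell integrity
    collapses: brightness drops by ``disruption_brightness_factor`` and any
    generated images have a fragmented (randomly punched-out) cell mask.
    """

    calcium_levels: tuple[float, ...] = (0.06, 0.3, 0.6, 1.5, 5.0)
    order_map: HillOrderMap = field(default_factory=HillOrderMap)
    disruption_threshold_mM: float = 5.0
    disruption_brightness_factor: float = 0.2
    disruption_retain_fraction: float = 0.3
    wells_per_level: int = 3
    flashes_per_well: int = 25
    interior_order: float = 0.15
    membrane_fraction: float = 0.5
    brightness: float = 500.0
    noise_model: str = "poisson"
    images_per_level: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.calcium_levels) == 0:
            raise InvalidConfigError("calcium_levels must be non-empty")
        if any(c < 0 for c in self.calcium_levels):
            raise InvalidConfigError("calcium levels must be nonnegative")
        if self.wells_per_level < 1 or self.flashes_per_well < 1:
            raise InvalidConfigError("wells_per_level and flashes_per_well must be >= 1")
        if self.flashes_per_well < 25:
            import warnings

            warnings.warn(
                f"flashes_per_well={self.flashes_per_well} is below the "
                "recommended minimum of 25",
                stacklevel=3,
            )
        if not (0.0 <= self.membrane_fraction <= 1.0):
            raise InvalidConfigError("membrane_fraction must be in [0, 1]")
        if not (0.0 < self.disruption_brightness_factor <= 1.0):
            raise InvalidConfigError("disruption_brightness_factor must be in (0, 1]")
        if self.noise_model not in ("none", "poisson"):
            raise InvalidConfigError(f"unknown noise_model {self.noise_model!r}")


def _well_expected_spectrum(
    basis: BasisSpectra, config: CalciumSeriesConfig, membrane_order: float, brightness: float
) -> EmissionSpectrum:
    # Plate reader sees both populations pooled: membrane + interior.
    membrane = mix_spectrum(basis, membrane_order, brightness * config.membrane_fraction)
    interior = mix_spectrum(
        basis, config.interior_order, brightness * (1.0 - config.membrane_fraction)
    )
    return membrane + interior


def make_calcium_series(
    config: CalciumSeriesConfig,
    basis: BasisSpectra,
    plate_grid: np.ndarray | None = None,
) -> tuple[list[PlateRecord], list[dict], list[tuple[SpectralImage, np.ndarray]]]:
    """Generate the full calcium-switch dataset.

    Returns ``(records, ground_truth, images)``:

    * ``records`` — one :class:`PlateRecord` per (level, well, flash), flash
      spectra sampled on ``plate_grid`` (default 405-600 nm) with Poisson
      noise when configured;
    * ``ground_truth`` — one dict per level with the mapped membrane order,
      the analytic expected well GP, the brightness used and a
      ``disrupted`` flag;
    * ``images`` — ``images_per_level`` lambda stacks per level (empty list
      when 0); disrupted levels are dimmed and fragmented.
    """
    if plate_grid is None:
        plate_grid = default_plate_grid()
    plate_basis = _resample_basis(basis, np.asarray(plate_grid, dtype=float))
    rng = np.random.default_rng(config.seed)
    records: list[PlateRecord] = []
    ground_truth: list[dict] = []
    images: list[tuple[SpectralImage, np.ndarray]] = []

    for level_idx, calcium in enumerate(config.calcium_levels):
        order = config.order_map(calcium)
        disrupted = calcium >= config.disruption_threshold_mM
        brightness = config.brightness * (
            config.disruption_brightness_factor if disrupted else 1.0
        )
        expected = _well_expected_spectrum(plate_basis, config, order, brightness)
        ground_truth.append(
            {
                "calcium_mM": float(calcium),
                "membrane_order": float(order),
                "interior_order": float(config.interior_order),
                "expected_well_gp": gp_from_spectrum(expected).gp,
                "brightness": float(brightness),
                "disrupted": bool(disrupted),
            }
        )
        for well_idx in range(config.wells_per_level):
            well_id = f"L{level_idx}W{well_idx}"
            for flash in range(1, config.flashes_per_well + 1):
                if config.noise_model == "poisson":
                    intensities = rng.poisson(expected.intensities).astype(float)
                else:
                    intensities = expected.intensities.copy()
                records.append(
                    PlateRecord(
                        well=well_id,
                        condition=float(calcium),
                        flash=flash,
                        spectrum=EmissionSpectrum(plate_grid, intensities),
                    )
                )
        for img_idx in range(config.images_per_level):
            phantom = CellPhantomConfig(
                interior_order=min(config.interior_order, order),
                membrane_order=order,
                brightness=brightness,
                noise_model=config.noise_model,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            image, labels = make_cell_image(phantom, basis)
            if disrupted:
                image, labels = _fragment(image, labels, config.disruption_retain_fraction, rng)
            images.append((image, labels))
    return records, ground_truth, images


def _fragment(
    image: SpectralImage,
    labels: np.ndarray,
    retain_fraction: float,
    rng: np.random.Generator,
) -> tuple[SpectralImage, np.ndarray]:
    """Randomly punch out cell pixels to mimic membrane collapse."""
    cell = labels != LABEL_BACKGROUND
    keep = rng.random(labels.shape) < retain_fraction
    lost = cell & ~keep
    stack = image.intensities.copy()
    stack[lost] = 0.0
    new_labels = labels.copy()
    new_labels[lost] = LABEL_BACKGROUND
    return (
        SpectralImage(
            intensities=stack,
            channel_centers=image.channel_centers,
            excitation_nm=image.excitation_nm,
            source_id=image.source_id + "+fragmented",
        ),
        new_labels,
    )


def _resample_basis(basis: BasisSpectra, grid: np.ndarray) -> BasisSpectra:
    """Linearly interpolate both basis spectra onto a new wavelength grid.

    Outside the original grid the edge values are held (the tails are tiny
    for the default 440/490 nm Gaussians, and the GP bands are interior).
    """
    if np.array_equal(grid, basis.wavelengths):
        return basis

    def resample(spectrum: EmissionSpectrum) -> EmissionSpectrum:
        return EmissionSpectrum(
            grid, np.interp(grid, spectrum.wavelengths, spectrum.intensities)
        )

    return BasisSpectra(resample(basis.ordered_spectrum), resample(basis.disordered_spectrum))
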