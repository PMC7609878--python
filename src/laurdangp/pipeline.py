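"""End-to-end orchestration: imaging and plate pipelines, demo dataset.

Both pipelines are driven by a :class:`RunConfig` that round-trips through
YAML, and write provenance (settings, seeds, package version) next to their
outputs. Per-item failures never abort a batch: they are collected in the
run report and reflected in the exit status.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import EmptyDataError, InvalidConfigError, LaurdanGPError
from .gp import compute_gp_map, render_gp_map
from .populations import (
    ComparisonResult,
    compare_conditions,
    fit_gaussian_mixture,
    gp_histogram,
    mean_of_flash_gps,
    well_gp,
)
from .spectral_io import (
    read_plate_csv,
    read_spectral_image,
    write_gp_map,
    write_label_map,
    write_plate_csv,
    write_spectral_image,
)
from .synthetic import (
    CalciumSeriesConfig,
    CellPhantomConfig,
    HillOrderMap,
    make_basis_spectra,
    make_calcium_series,
    make_cell_image,
)

logger = logging.getLogger("laurdangp")

__all__ = [
    "RunConfig",
    "RunReport",
    "run_imaging_pipeline",
    "run_plate_pipeline",
    "make_demo_dataset",
]


@dataclass
class RunConfig:
    """Settings for one analysis run (imaging, plate, or both)."""

    mode: str = "both"  # {"imaging", "plate", "both"}
    image_paths: list[str] = field(default_factory=list)
    plate_path: str | None = None
    wavelength_source: str = "sidecar"
    gp_mode: str = "fit_eval"  # {"fit_eval", "nearest_channels", "band"}
    mask_policy: str = "quantile:0.05"
    band440: tuple[float, float] = (440.0, 10.0)
    band490: tuple[float, float] = (490.0, 10.0)
    mixture_k: int = 2
    mixture_method: str = "histogram_ls"
    histogram_bin_width: float = 0.02
    lut: str = "data_minmax"  # or "fixed:lo:hi"
    well_statistic: str = "gp_of_mean_spectrum"  # or "mean_of_flash_gps"
    seed: int = 0
    out_dir: str = "gp_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("imaging", "plate", "both"):
            raise InvalidConfigError(f"unknown mode {self.mode!r}")
        if self.gp_mode not in ("fit_eval", "nearest_channels", "band"):
            raise InvalidConfigError(f"unknown gp_mode {self.gp_mode!r}")
        if self.mixture_k not in (1, 2, 3):
            raise InvalidConfigError(f"mixture_k must be 1, 2 or 3, got {self.mixture_k}")
        if self.mixture_method not in ("histogram_ls", "em"):
            raise InvalidConfigError(f"unknown mixture_method {self.mixture_method!r}")
        if not (0 < self.histogram_bin_width <= 2):
            raise InvalidConfigError("histogram_bin_width must be in (0, 2]")
        if self.well_statistic not in ("gp_of_mean_spectrum", "mean_of_flash_gps"):
            raise InvalidConfigError(f"unknown well_statistic {self.well_statistic!r}")
        self.band440 = tuple(float(v) for v in self.band440)  # type: ignore[assignment]
        self.band490 = tuple(float(v) for v in self.band490)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band440"] = list(self.band440)
        d["band490"] = list(self.band490)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("band440", "band490"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunReport:
    """Outcome of one pipeline run: produced outputs and per-item failures."""

    outputs: dict[str, str] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    n_items: int = 0

    @property
    def exit_code(self) -> int:
        if self.n_items and len(self.failures) == self.n_items:
            return 1  # total failure
        return 2 if self.failures else 0


def _write_provenance(out_dir: Path, config: RunConfig, extra: dict | None = None) -> None:
    payload = {"package_version": __version__, "config": config.to_dict()}
    if extra:
        payload.update(extra)
    (out_dir / "provenance.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def _parse_lut(lut: str):
    if lut in ("data", "data_minmax"):
        return "data_minmax"
    if lut.startswith("fixed:"):
        _, lo, hi = lut.split(":")
        return (float(lo), float(hi))
    raise InvalidConfigError(f"unknown LUT spec {lut!r}")


def run_imaging_pipeline(config: RunConfig) -> RunReport:
    """Analyze each lambda stack: GP map, render, histogram, mixture fit.

    Writes per-image outputs plus one combined summary CSV; failures are
    recorded per image and the batch continues.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(n_items=len(config.image_paths))
    summary_rows = []
    for path in config.image_paths:
        stem = Path(path).stem
        try:
            image = read_spectral_image(path, wavelength_source=config.wavelength_source)
            gp_map = compute_gp_map(
                image,
                mask_policy=config.mask_policy,
                mode=config.gp_mode,
                band440=config.band440,
                band490=config.band490,
            )
            if gp_map.n_valid == 0:
                raise EmptyDataError("no valid pixels after masking")
            write_gp_map(out_dir / f"{stem}_gp.tif", gp_map.gp, gp_map.valid_mask)
            rgb, lut_range = render_gp_map(gp_map, lut_range=_parse_lut(config.lut))
            plt.imsave(out_dir / f"{stem}_gp.png", rgb)
            hist = gp_histogram(gp_map.valid_values, bin_width=config.histogram_bin_width)
            pd.DataFrame(
                {"bin_center": hist.bin_centers, "frequency": hist.frequencies}
            ).to_csv(out_dir / f"{stem}_histogram.csv", index=False)
            fit = fit_gaussian_mixture(
                gp_map.valid_values,
                k=config.mixture_k,
                method=config.mixture_method,
                seed=config.seed,
                bin_width=config.histogram_bin_width,
            )
            fit.to_frame().assign(image=stem, seed=config.seed).to_csv(
                out_dir / f"{stem}_mixture.csv", index=False
            )
            vals = gp_map.valid_values
            row = {
                "image": stem,
                "n_valid": gp_map.n_valid,
                "mean_gp": float(vals.mean()),
                "sd_gp": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "lut_low": lut_range[0],
                "lut_high": lut_range[1],
            }
            for i, comp in enumerate(fit.components):
                row[f"mix{i}_mean"] = comp.mean
                row[f"mix{i}_sd"] = comp.sd
                row[f"mix{i}_weight"] = comp.weight
            summary_rows.append(row)
            report.outputs[stem] = str(out_dir / f"{stem}_gp.tif")
        except Exception as exc:  # per-image isolation by design
            logger.warning("image %s failed: %s", path, exc)
            report.failures[str(path)] = f"{type(exc).__name__}: {exc}"
    if summary_rows:
        pd.DataFrame(summary_rows).to_csv(out_dir / "imaging_summary.csv", index=False)
        report.outputs["summary"] = str(out_dir / "imaging_summary.csv")
    _write_provenance(out_dir, config, {"failures": report.failures})
    return report


def run_plate_pipeline(config: RunConfig) -> RunReport:
    """Analyze a plate CSV: per-well GP, condition summaries, ANOVA/Tukey,
    box-plot figure."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.plate_path is None:
        raise InvalidConfigError("plate pipeline requires plate_path")
    records = read_plate_csv(config.plate_path)
    by_well: dict[str, list] = {}
    for rec in records:
        by_well.setdefault(rec.well, []).append(rec)
    report = RunReport(n_items=len(by_well))
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # <25-flash warnings already logged per run
        for well, recs in sorted(by_well.items()):
            try:
                if config.well_statistic == "gp_of_mean_spectrum":
                    gp = well_gp(recs, config.band440, config.band490).gp
                else:
                    gp = mean_of_flash_gps(recs, config.band440, config.band490)
                rows.append(
                    {
                        "well": well,
                        "condition_mM": recs[0].condition,
                        "n_flashes": len(recs),
                        "gp": gp,
                    }
                )
                report.outputs[well] = "ok"
            except Exception as exc:
                logger.warning("well %s failed: %s", well, exc)
                report.failures[well] = f"{type(exc).__name__}: {exc}"
    if not rows:
        _write_provenance(out_dir, config, {"failures": report.failures})
        return report
    well_table = pd.DataFrame(rows).sort_values(["condition_mM", "well"])
    well_table.to_csv(out_dir / "well_gp.csv", index=False)
    groups = {
        float(cond): grp["gp"].to_numpy()
        for cond, grp in well_table.groupby("condition_mM")
    }
    try:
        comparison = compare_conditions(groups)
        _write_comparison(out_dir, comparison)
    except EmptyDataError as exc:
        logger.warning("condition comparison skipped: %s", exc)
    report.outputs["well_table"] = str(out_dir / "well_gp.csv")
    _write_provenance(out_dir, config, {"failures": report.failures})
    return report


def _write_comparison(out_dir: Path, comparison: ComparisonResult) -> None:
    pd.DataFrame(
        [
            {
                "condition_mM": s.condition,
                "n": s.n,
                "mean_gp": s.mean,
                "sd_gp": s.sd,
                "q1": s.q1,
                "median": s.median,
                "q3": s.q3,
                "whisker_low": s.whisker_low,
                "whisker_high": s.whisker_high,
                "n_outliers": len(s.outliers),
            }
            for s in comparison.summaries
        ]
    ).to_csv(out_dir / "condition_summary.csv", index=False)
    anova = comparison.tukey.copy()
    anova.insert(0, "anova_F", comparison.f_statistic)
    anova.insert(1, "anova_p", comparison.p_value)
    anova.to_csv(out_dir / "anova_tukey.csv", index=False)

    fig, ax = plt.subplots(figsize=(6, 4))
    data = [[s.q1, s.median, s.q3] for s in comparison.summaries]
    ax.boxplot(
        [
            [s.whisker_low, s.q1, s.median, s.q3, s.whisker_high]
            for s in comparison.summaries
        ],
        tick_labels=[f"{s.condition:g}" for s in comparison.summaries],
    )
    for i, s in enumerate(comparison.summaries, start=1):
        if s.outliers:
            ax.plot([i] * len(s.outliers), s.outliers, "x", color="gray")
        ax.plot(i, s.mean, "k_", markersize=14)
    ax.set_xlabel("calcium (mM)")
    ax.set_ylabel("well GP")
    fig.tight_layout()
    fig.savefig(out_dir / "condition_boxplot.png", dpi=120)
    plt.close(fig)


def make_demo_dataset(out_dir: str | Path, seed: int = 0) -> dict:
    """Write a small, complete worked example under ``out_dir``.

    Contents: lambda stacks (TIFF + sidecar) and label maps for two calcium
    levels (0.06 and 1.5 mM), one plate CSV spanning five calcium levels,
    and a ground-truth JSON recording the ordered fractions used. Small
    enough to run both pipelines end-to-end in well under two minutes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    basis = make_basis_spectra()
    order_map = HillOrderMap()
    rng = np.random.default_rng(seed)
    imaging_levels = [0.06, 1.5]
    truth: dict = {"seed": seed, "images": {}, "plate": {}}
    image_paths = []
    for calcium in imaging_levels:
        order = order_map(calcium)
        phantom = CellPhantomConfig(
            image_size=(48, 48),
            outer_radius=18.0,
            ring_thickness=3.0,
            interior_order=0.15,
            membrane_order=order,
            brightness=400.0,
            noise_model="poisson",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, labels = make_cell_image(phantom, basis)
        stem = f"cell_ca{str(calcium).replace('.', 'p')}"
        write_spectral_image(out_dir / f"{stem}.tif", image)
        write_label_map(out_dir / f"{stem}_labels.tif", labels)
        truth["images"][stem] = {
            "calcium_mM": calcium,
            "membrane_order": order,
            "interior_order": phantom.interior_order,
            "phantom_seed": phantom.seed,
        }
        image_paths.append(str(out_dir / f"{stem}.tif"))
    series = CalciumSeriesConfig(
        calcium_levels=(0.06, 0.3, 0.6, 1.5, 2.5),
        order_map=order_map,
        wells_per_level=3,
        flashes_per_well=25,
        seed=seed,
    )
    records, gt, _ = make_calcium_series(series, basis)
    write_plate_csv(out_dir / "plate.csv", records)
    truth["plate"] = {"levels": gt}
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return {
        "image_paths": image_paths,
        "plate_path": str(out_dir / "plate.csv"),
        "ground_truth": str(out_dir / "ground_truth.json"),
    }
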