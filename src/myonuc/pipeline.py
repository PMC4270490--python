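"""End-to-end experiment orchestration.

A synthetic experiment mirrors the published cohort design: per genotype,
``muscles_per_hemisegment x hemisegments_per_embryo x embryos`` fibers are
generated for positioning metrics, and a (possibly smaller) profile cohort
is rendered to images for localization profiling.  All outputs are tidy CSV
plus a JSON manifest; given the same configuration and seed, every output
byte is reproducible (logs carry the only timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import positioning, profiles, stats, synthetic
from .io import write_image

__all__ = ["ExperimentConfig", "run_synthetic_experiment", "run_user_data"]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Everything that determines a run: genotypes, cohort design, parameters."""

    genotypes: list[str] = field(default_factory=lambda: ["control", "syd_like"])
    control: str = "control"
    # cohort design (embryonic profile assays use profile_muscles_per_hemisegment)
    muscles_per_hemisegment: int = 4
    hemisegments_per_embryo: int = 3
    embryos: int = 10
    profile_muscles_per_hemisegment: int = 2
    # fiber geometry; profile cohorts are rendered at high magnification
    fiber_length_um: float = 40.0
    fiber_width_um: float = 6.0
    um_per_pixel: float = 0.2
    profile_um_per_pixel: float = 0.05
    # analysis parameters
    box_width_um: float = 2.0
    distal_depth_um: float = 2.0
    alpha_levels: tuple[float, float] = (0.05, 0.01)
    # reproducibility
    seed: int = 0
    out_dir: str = "myonuc_run"
    preset_file: str | None = None
    write_images: bool = False
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed must be explicit (no silent clock seeding)")
        for fld in ("muscles_per_hemisegment", "hemisegments_per_embryo", "embryos"):
            if getattr(self, fld) < 1:
                raise ValueError(f"{fld} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "alpha_levels" in raw:
            raw["alpha_levels"] = tuple(raw["alpha_levels"])
        return cls(**raw)

    def parameter_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _fiber_seeds(config: ExperimentConfig, genotype_index: int, n: int) -> np.ndarray:
    """Deterministic per-fiber seeds derived from the experiment seed."""
    ss = np.random.SeedSequence([config.seed, genotype_index])
    return ss.generate_state(n) % (2**31 - 1)


def _position_fiber(preset, config, seed):
    """One whole-muscle fiber for positioning metrics (no rendering)."""
    fiber = synthetic.make_fiber(
        config.fiber_length_um,
        config.fiber_width_um,
        config.um_per_pixel,
        orientation_deg=0.0,
        seed=int(seed),
    )
    nuclei = synthetic.place_nuclei(fiber, preset, seed=int(seed))
    return positioning.position_report(fiber, nuclei)


def _profile_fiber(preset, config, seed):
    """One high-magnification fiber rendered to channels and profiled."""
    fiber = synthetic.make_fiber(
        config.fiber_length_um,
        config.fiber_width_um,
        config.profile_um_per_pixel,
        orientation_deg=0.0,
        seed=int(seed),
    )
    nuclei = synthetic.place_nuclei(fiber, preset, seed=int(seed))
    image, truth = synthetic.render_channels(fiber, nuclei, preset, seed=int(seed))
    roi = profiles.select_profile_roi(
        fiber, nuclei, "dorsal", width_um=config.box_width_um
    )
    prof = profiles.normalize_profile(profiles.compute_ratio_profile(image, roi))
    ref_prof = profiles.normalize_profile(
        profiles.compute_intensity_profile(image, roi, "reference")
    )
    distal = profiles.distal_region_ratio(
        image, fiber, depth_um=config.distal_depth_um, end_label="dorsal"
    )
    return {
        "profile": prof,
        "reference_profile": ref_prof,
        "distal_ratio": distal,
        "truth": truth,
        "image": image,
    }


def run_synthetic_experiment(config: ExperimentConfig) -> dict:
    """Generate cohorts per genotype, run all analyses, write the report bundle.

    Returns a dict with the tidy measurement frame, profile cohorts, the
    statistical report tables and the reference-control check; the same
    tables are written as CSV under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    presets = synthetic.load_presets(config.preset_file)
    missing = [g for g in config.genotypes if g not in presets]
    if missing:
        raise ValueError(f"presets not defined for genotypes: {missing}")

    n_position = (
        config.muscles_per_hemisegment * config.hemisegments_per_embryo * config.embryos
    )
    n_profile = (
        config.profile_muscles_per_hemisegment
        * config.hemisegments_per_embryo
        * config.embryos
    )

    meas_rows = []
    profile_rows = []
    cohort_profiles: dict[str, list] = {}
    ref_profiles: dict[str, list] = {}
    distal_rows = []
    errors = []
    for gi, genotype in enumerate(config.genotypes):
        preset = presets[genotype]
        pos_seeds = _fiber_seeds(config, gi, n_position)
        prof_seeds = _fiber_seeds(config, 1000 + gi, n_profile)
        cohort_profiles[genotype] = []
        ref_profiles[genotype] = []
        for fi, seed in enumerate(pos_seeds):
            try:
                report = _position_fiber(preset, config, seed)
            except (ValueError, RuntimeError) as exc:  # pragma: no cover - defensive
                errors.append({"genotype": genotype, "fiber": fi, "error": str(exc)})
                logger.error("fiber %s/%d failed: %s", genotype, fi, exc)
                continue
            fiber_id = f"{genotype}_{fi:03d}"
            tidy = report.to_frame(fiber_id)
            tidy.insert(0, "genotype", genotype)
            meas_rows.append(tidy)
        for fi, seed in enumerate(prof_seeds):
            fiber_id = f"{genotype}_hi_{fi:03d}"
            try:
                prof = _profile_fiber(preset, config, seed)
            except (ValueError, RuntimeError) as exc:  # pragma: no cover - defensive
                errors.append({"genotype": genotype, "fiber": fiber_id, "error": str(exc)})
                logger.error("profile fiber %s failed: %s", fiber_id, exc)
                continue
            p = prof["profile"]
            cohort_profiles[genotype].append(p)
            ref_profiles[genotype].append(prof["reference_profile"])
            distal_rows.append(
                {
                    "genotype": genotype,
                    "fiber_id": fiber_id,
                    "distal_ratio": prof["distal_ratio"],
                    "peak": p.peak,
                    "auc": p.auc,
                    "distal_mean_0_20": float(p.ratio[:21].mean()),
                }
            )
            for pos, val in zip(p.positions, p.ratio):
                profile_rows.append(
                    {
                        "profile_id": fiber_id,
                        "genotype": genotype,
                        "position_pct": float(pos),
                        "ratio": float(val),
                    }
                )
            if config.write_images:
                img_dir = out / "images"
                img_dir.mkdir(exist_ok=True)
                write_image(img_dir / f"{fiber_id}.tif", prof["image"])

    measurements = pd.concat(meas_rows, ignore_index=True)
    profile_table = pd.DataFrame(profile_rows)
    distal_table = pd.DataFrame(distal_rows)

    # stats input: one row per fiber per metric (positioning) + profile stats
    stat_frames = [
        measurements.rename(columns={"fiber_id": "unit_id"})[
            ["genotype", "unit_id", "metric", "value"]
        ]
    ]
    if len(distal_table):
        melted = distal_table.melt(
            id_vars=["genotype", "fiber_id"],
            value_vars=["distal_ratio", "peak", "auc", "distal_mean_0_20"],
            var_name="metric",
            value_name="value",
        ).rename(columns={"fiber_id": "unit_id"})
        stat_frames.append(melted)
    stats_input = pd.concat(stat_frames, ignore_index=True)
    report_tables = stats.build_report(stats_input, control_label=config.control)

    ref_check = None
    if all(len(v) >= 2 for v in ref_profiles.values()) and len(ref_profiles) >= 2:
        ref_check = profiles.reference_control_check(
            ref_profiles, control_label=config.control
        )

    cohorts = {
        g: profiles.average_profiles(v)
        for g, v in cohort_profiles.items()
        if len(v) >= 2
    }
    cohort_table = pd.DataFrame(
        [
            {
                "genotype": g,
                "peak_mean": c.peak_mean,
                "peak_sd": c.peak_sd,
                "auc_mean": c.auc_mean,
                "auc_sd": c.auc_sd,
                "n": c.n,
            }
            for g, c in cohorts.items()
        ]
    )

    # write bundle
    measurements.to_csv(out / "measurements.csv", index=False)
    profile_table.to_csv(out / "profiles.csv", index=False)
    distal_table.to_csv(out / "profile_stats.csv", index=False)
    cohort_table.to_csv(out / "cohorts.csv", index=False)
    report_tables["descriptives"].to_csv(out / "descriptives.csv", index=False)
    report_tables["comparisons"].to_csv(out / "comparisons.csv", index=False)
    if ref_check is not None:
        ref_check.to_csv(out / "reference_check.csv", index=False)
    manifest = {
        "package": "myonuc",
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "genotypes": config.genotypes,
        "n_position_fibers": n_position,
        "n_profile_fibers": n_profile,
        "n_errors": len(errors),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if errors:
        pd.DataFrame(errors).to_csv(out / "errors.csv", index=False)

    if config.make_plots and cohorts:
        _plot_bundle(out, cohorts, report_tables)

    return {
        "measurements": measurements,
        "profiles": profile_table,
        "profile_stats": distal_table,
        "cohorts": cohorts,
        "cohort_table": cohort_table,
        "report": report_tables,
        "reference_check": ref_check,
        "errors": errors,
        "out_dir": out,
    }


def _plot_bundle(out: Path, cohorts, report_tables) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    for g, c in cohorts.items():
        ax.plot(c.positions, c.mean, label=g)
        ax.fill_between(c.positions, c.mean - c.sd, c.mean + c.sd, alpha=0.2)
    ax.set_xlabel("normalized position (%)")
    ax.set_ylabel("target/reference x 100 (a.u.)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "profile_curves.png", dpi=150)
    plt.close(fig)

    desc = report_tables["descriptives"]
    for metric in ("end_distance_dorsal", "auc"):
        sub = desc[desc.metric == metric]
        if not len(sub):
            continue
        fig, ax = plt.subplots(figsize=(3.6, 3.2))
        ax.bar(sub.genotype, sub["mean"], yerr=sub.sd.fillna(0.0), capsize=3)
        ax.set_ylabel(metric)
        ax.tick_params(axis="x", rotation=30)
        fig.tight_layout()
        fig.savefig(out / f"bars_{metric}.png", dpi=150)
        plt.close(fig)


def run_user_data(config: ExperimentConfig, paths: dict) -> dict:
    """Run the same analyses on user images listed in ``paths``.

    ``paths`` maps genotype -> list of image files (multi-channel TIFF with
    reference/nuclei/target roles resolvable via ``channel_map``).  Images
    are segmented automatically (Otsu route); supply masks through
    ``io.load_segmentation(method="provided_masks")`` for the manual route.
    """
    from .io import load_segmentation, read_image, segmentation_to_geometry

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    channel_map = paths.get("channel_map")
    meas_rows = []
    calibrations = set()
    for genotype, files in paths.items():
        if genotype == "channel_map":
            continue
        for fpath in files:
            image = read_image(fpath, channel_map=channel_map)
            calibrations.add(image.um_per_pixel)
            seg = load_segmentation(image)
            fiber, nuclei = segmentation_to_geometry(seg, image.um_per_pixel)
            report = positioning.position_report(fiber, nuclei)
            tidy = report.to_frame(Path(fpath).stem)
            tidy.insert(0, "genotype", genotype)
            meas_rows.append(tidy)
    if len(calibrations) > 1:
        logger.warning(
            "mixed calibrations across files (%s); per-file µm/px used",
            sorted(calibrations),
        )
    measurements = pd.concat(meas_rows, ignore_index=True)
    measurements.to_csv(out / "measurements.csv", index=False)
    stats_input = measurements.rename(columns={"fiber_id": "unit_id"})[
        ["genotype", "unit_id", "metric", "value"]
    ]
    report_tables = stats.build_report(stats_input, control_label=config.control)
    report_tables["descriptives"].to_csv(out / "descriptives.csv", index=False)
    report_tables["comparisons"].to_csv(out / "comparisons.csv", index=False)
    return {"measurements": measurements, "report": report_tables, "out_dir": out}
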