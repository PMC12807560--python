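"""End-to-end orchestration: simulate -> detect -> fit -> aggregate -> stats.

A run is driven by a :class:`RunConfig` (YAML-serializable) whose defaults
are the acquisition and analysis constants of the slice protocol: 9 fps,
600 frames, stimulation at frame 200, 7 um ROI grid, k = 3 activity
threshold, 10 s tau_off exclusion.  All stage outputs land under the output
directory together with a config snapshot, and deterministic stages
reproduce bit-identical CSVs on rerun with the same config and inputs.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import kinetics as kin
from . import roi
from . import stack_io
from . import stats as gstats
from .synthetic import (
    AcquisitionProtocol,
    DesignSpec,
    GroundTruthManifest,
    NoiseModel,
    manifest_for_density,
    simulate_movie,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "sensitivity_sweep", "simulate_design_movies"]


@dataclass
class RunConfig:
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    tile_um: float = 7.0
    k_threshold: float = 3.0
    eps_abs: float = roi.DEFAULT_EPS_ABS
    tau_off_max_s: float = kin.TAU_OFF_MAX_S
    seed: int = 0
    manifest_csv: str | None = None
    output_dir: str = "nircat_run"

    def __post_init__(self) -> None:
        if self.tau_off_max_s <= 0:
            raise ValueError("tau_off_max_s must be positive")
        if self.tile_um <= 0 or self.k_threshold <= 0:
            raise ValueError("tile_um and k_threshold must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "protocol" in d and isinstance(d["protocol"], dict):
            d["protocol"] = AcquisitionProtocol(**d["protocol"])
        return cls(**d)


def simulate_design_movies(
    design: DesignSpec,
    out_dir: str | Path,
    protocol: AcquisitionProtocol | None = None,
    noise: NoiseModel | None = None,
    tile_um: float = 7.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> Path:
    """Write one TIFF stack per (slice, replicate) realizing a nested design.

    Per-slice true density, per-site amplitude, and decay constant are drawn
    from the design's group means with animal- and slice-level noise; every
    replicate of a slice shares the same planted truth but differs in camera
    noise.  Hotspots sit at tile centers of the ``tile_um`` grid so the
    planted density is exact.  Returns the path to the manifest CSV.
    """
    protocol = protocol or AcquisitionProtocol()
    noise = noise or NoiseModel()
    out_dir = Path(out_dir)
    (out_dir / "stacks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth = design.__class__(**{**dataclasses.asdict(design), "seed": seed})  # defensive copy
    rows = []
    truth_rows = []
    animal_counter = 0
    for group in truth.group_means:
        for _ in range(truth.n_animals_per_group):
            animal_counter += 1
            animal_id = f"m{animal_counter:02d}"
            animal_eff = {
                m: rng.normal(0.0, truth._sd(truth.animal_sd, m)) for m in truth.metrics()
            }
            for s in range(1, truth.slices_per_animal + 1):
                for region in truth.regions:
                    mu = truth.group_means[group][region]
                    dens = float(
                        np.clip(
                            mu["density_pct"]
                            + animal_eff["density_pct"]
                            + rng.normal(0.0, truth._sd(truth.slice_sd, "density_pct")),
                            0.0,
                            100.0,
                        )
                    )
                    amp = max(
                        mu["peak_dff_active"]
                        + animal_eff["peak_dff_active"]
                        + rng.normal(0.0, truth._sd(truth.slice_sd, "peak_dff_active")),
                        0.005,
                    )
                    tau = max(
                        mu["tau_off_s"]
                        + animal_eff["tau_off_s"]
                        + rng.normal(0.0, truth._sd(truth.slice_sd, "tau_off_s")),
                        0.5,
                    )
                    slice_id = f"{animal_id}_{region}_s{s}"
                    slice_seed = int(rng.integers(0, 2**31 - 1))
                    for rep in range(1, n_replicates + 1):
                        manifest = manifest_for_density(
                            dens,
                            seed=slice_seed + rep,
                            tile_um=tile_um,
                            protocol=protocol,
                            noise=noise,
                            amplitude=amp,
                            tau_off_s=tau,
                        )
                        stack = simulate_movie(manifest)
                        rel = f"stacks/{slice_id}_r{rep}.tif"
                        stack_io.write_stack(stack, out_dir / rel)
                        rows.append(
                            {
                                "animal_id": animal_id,
                                "treatment": group,
                                "region": region,
                                "slice_id": slice_id,
                                "replicate_index": rep,
                                "stack_path": rel,
                            }
                        )
                    truth_rows.append(
                        {
                            "animal_id": animal_id,
                            "treatment": group,
                            "region": region,
                            "slice_id": slice_id,
                            "true_density_pct": dens,
                            "true_amplitude": amp,
                            "true_tau_off_s": tau,
                        }
                    )
    manifest_path = out_dir / "manifest.csv"
    stack_io.write_table(pd.DataFrame(rows), manifest_path)
    stack_io.write_table(pd.DataFrame(truth_rows), out_dir / "ground_truth.csv")
    return manifest_path


def _analyze_replicate(
    record: stack_io.SampleRecord,
    stack: stack_io.FluorescenceStack,
    grid: roi.RoiGrid,
    config: RunConfig,
) -> tuple[agg.ReplicateMetrics, pd.DataFrame]:
    stim = stack.protocol.stim_frame
    traces = roi.extract_traces(stack, grid, stim)
    calls = roi.call_active(traces, stim, k=config.k_threshold, eps_abs=config.eps_abs)
    active_idx = {c.roi_index for c in calls if c.is_active}
    fits = {
        tr.roi_index: kin.fit_kinetics(
            tr.dff, stim, stack.protocol.frame_rate, config.tau_off_max_s
        )
        for tr in traces
        if tr.roi_index in active_idx
    }
    rep = agg.replicate_metrics(record, calls, fits, grid)
    frame = roi.calls_frame(traces, calls, grid)
    frame.insert(0, "replicate_index", record.replicate_index)
    frame.insert(0, "slice_id", record.slice_id)
    return rep, frame


def _stats_stage(table: pd.DataFrame, out_dir: Path) -> dict:
    """Treatment models per region x metric, region models per group x metric,
    and repeated-measures correlations per group x region x metric pair."""
    model_rows, contrast_rows, rmcorr_rows = [], [], []
    regions = [r for r in ("DMS", "DLS", "NAc") if r in set(table["region"])]
    groups = sorted(set(table["treatment"]))
    for region in regions:
        sub = table[table["region"] == region]
        for metric in agg.METRIC_COLUMNS:
            try:
                res, eff = gstats.lmm_treatment(sub, metric)
            except ValueError as exc:
                logger.warning("treatment model skipped (%s, %s): %s", region, metric, exc)
                continue
            model_rows.append(
                {
                    "comparison": "treatment",
                    "region": region,
                    "group": "",
                    "metric": metric,
                    "estimate": res.fixed_effect_estimate,
                    "se": res.standard_error,
                    "t": res.t_value,
                    "F": res.f_value,
                    "df1": res.numerator_df,
                    "df2": res.denominator_df,
                    "p": res.p_value,
                    "cohens_f2": eff.cohens_f2,
                    "eta2_partial": eff.eta2_partial,
                    "var_animal": res.variance_animal,
                    "var_residual": res.variance_residual,
                    "n_obs": res.n_obs,
                    "degenerate": res.degenerate,
                }
            )
    if len(regions) >= 2:
        for group in groups:
            for metric in agg.METRIC_COLUMNS:
                try:
                    res, contrasts, eff = gstats.lmm_region_tukey(table, metric, group)
                except (ValueError, np.linalg.LinAlgError) as exc:
                    logger.warning("region model skipped (%s, %s): %s", group, metric, exc)
                    continue
                model_rows.append(
                    {
                        "comparison": "region",
                        "region": "",
                        "group": group,
                        "metric": metric,
                        "estimate": math.nan,
                        "se": math.nan,
                        "t": math.nan,
                        "F": res.f_value,
                        "df1": res.numerator_df,
                        "df2": res.denominator_df,
                        "p": res.p_value,
                        "cohens_f2": eff.cohens_f2,
                        "eta2_partial": eff.eta2_partial,
                        "var_animal": res.variance_animal,
                        "var_residual": res.variance_residual,
                        "n_obs": res.n_obs,
                        "degenerate": res.degenerate,
                    }
                )
                for c in contrasts:
                    contrast_rows.append(
                        {
                            "group": group,
                            "metric": metric,
                            "pair": f"{c.pair[0]}-{c.pair[1]}",
                            "estimate": c.estimate,
                            "se": c.standard_error,
                            "z": c.z_value,
                            "p_raw": c.p_raw,
                            "adjusted_p": c.adjusted_p,
                            "hedges_g": eff.hedges_g.get(f"{c.pair[0]}-{c.pair[1]}", math.nan),
                        }
                    )
    for group in groups:
        for region in regions:
            sub = table[(table["treatment"] == group) & (table["region"] == region)]
            for mx, my in itertools.combinations(agg.METRIC_COLUMNS, 2):
                try:
                    rc = gstats.rmcorr(sub, mx, my)
                except ValueError as exc:
                    logger.info("rmcorr skipped (%s, %s, %s~%s): %s", group, region, mx, my, exc)
                    continue
                rmcorr_rows.append(
                    {
                        "group": group,
                        "region": region,
                        "pair": f"{mx}~{my}",
                        "r_m": rc.r_m,
                        "df": rc.df,
                        "p": rc.p_value,
                        "n_subjects": rc.n_subjects,
                        "n_obs": rc.n_obs,
                    }
                )
    models = pd.DataFrame(model_rows)
    contrasts = pd.DataFrame(contrast_rows)
    rmc = pd.DataFrame(rmcorr_rows)
    stack_io.write_table(models, out_dir / "stats_models.csv")
    stack_io.write_table(contrasts, out_dir / "stats_contrasts.csv")
    stack_io.write_table(rmc, out_dir / "stats_rmcorr.csv")
    _write_report(models, contrasts, rmc, out_dir / "stats_report.txt")
    return {"n_models": len(models), "n_contrasts": len(contrasts), "n_rmcorr": len(rmc)}


def _write_report(models: pd.DataFrame, contrasts: pd.DataFrame, rmc: pd.DataFrame, path: Path) -> None:
    lines = ["Release-metric statistics", "=" * 26, ""]
    for _, r in models.iterrows():
        if r["comparison"] == "treatment":
            lines.append(
                f"[{r['region']}] {r['metric']}: sham vs GDX estimate={r['estimate']:.4g}, "
                f"t({int(r['df2']) if not math.isnan(r['df2']) else '?'})="
                f"{r['t']:.3f}, p={r['p']:.4g}, f2={r['cohens_f2']:.3f}"
                if not r["degenerate"]
                else f"[{r['region']}] {r['metric']}: degenerate fit (no within-group variance)"
            )
        else:
            lines.append(
                f"[{r['group']}] {r['metric']} across regions: F({int(r['df1'])},{int(r['df2'])})="
                f"{r['F']:.3f}, p={r['p']:.4g}, eta2p={r['eta2_partial']:.3f}"
            )
    if len(contrasts):
        lines += ["", "Pairwise region contrasts (single-step adjusted):"]
        for _, c in contrasts.iterrows():
            lines.append(
                f"[{c['group']}] {c['metric']} {c['pair']}: z={c['z']:.3f}, "
                f"adj p={c['adjusted_p']:.4g}, g={c['hedges_g']:.3f}"
            )
    if len(rmc):
        lines += ["", "Repeated-measures correlations (uncorrected p):"]
        for _, c in rmc.iterrows():
            lines.append(
                f"[{c['group']}/{c['region']}] {c['pair']}: r_m={c['r_m']:.3f}, "
                f"df={int(c['df'])}, p={c['p']:.4g}"
            )
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run detect -> fit -> aggregate -> stats over a sample manifest.

    Stack paths in the manifest resolve relative to the manifest's directory.
    Returns a run summary (per-stage row counts); all outputs are written
    under ``config.output_dir`` with a config snapshot.
    """
    if config.manifest_csv is None:
        raise ValueError("config.manifest_csv is required (use simulate_design_movies first)")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config_snapshot.yaml")

    manifest_path = Path(config.manifest_csv)
    records = stack_io.read_manifest(manifest_path)
    grid = roi.build_grid(
        config.protocol.fov_width_um,
        config.protocol.fov_height_um,
        config.tile_um,
        config.protocol.um_per_pixel,
    )

    per_slice: dict[tuple, list[agg.ReplicateMetrics]] = {}
    roi_frames = []
    for record in records:
        stack_path = manifest_path.parent / record.stack_path
        try:
            stack = stack_io.read_stack(stack_path, config.protocol)
            rep, frame = _analyze_replicate(record, stack, grid, config)
        except (ValueError, FileNotFoundError) as exc:
            raise RuntimeError(
                f"stage 'detect/fit' failed for sample "
                f"{record.slice_id} replicate {record.replicate_index}: {exc}"
            ) from exc
        per_slice.setdefault(record.slice_key, []).append(rep)
        roi_frames.append(frame)
    stack_io.write_table(pd.concat(roi_frames, ignore_index=True), out_dir / "roi_calls.csv")

    slice_metrics = []
    skipped = []
    for key, reps in sorted(per_slice.items()):
        if len(reps) < 2:
            logger.warning("slice %s has %d replicate(s); below minimum, skipped", key, len(reps))
            skipped.append(key)
            continue
        slice_metrics.append(agg.aggregate_slice(reps))
    table = agg.build_metrics_table(records, slice_metrics)
    stack_io.write_table(table, out_dir / "slice_metrics.csv")

    stats_summary = _stats_stage(table, out_dir)

    counts = (
        table.groupby(["treatment", "region"]).size().rename("n_slices").reset_index()
    )
    summary = {
        "n_replicates_analyzed": len(records),
        "n_slices": len(table),
        "n_slices_skipped": len(skipped),
        "slice_counts": counts.to_dict(orient="records"),
        **stats_summary,
    }
    (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary


def sensitivity_sweep(config: RunConfig, tile_sizes=(4.0, 7.0, 10.0)) -> pd.DataFrame:
    """Re-analyze the same inputs at several ROI grid sizes.

    Emulates the grid-size control: per tile size, the three metrics and the
    treatment-model results are laid side by side.  Returns the combined
    comparison table (also written under the output directory).
    """
    frames = []
    for tile in tile_sizes:
        sub = dataclasses.replace(config, tile_um=float(tile), output_dir=str(Path(config.output_dir) / f"tile_{tile:g}um"))
        run_pipeline(sub)
        models = stack_io.read_table(Path(sub.output_dir) / "stats_models.csv")
        metrics = stack_io.read_table(Path(sub.output_dir) / "slice_metrics.csv")
        means = (
            metrics.groupby(["treatment", "region"])[list(agg.METRIC_COLUMNS)]
            .mean()
            .reset_index()
        )
        means.insert(0, "tile_um", tile)
        models.insert(0, "tile_um", tile)
        frames.append((means, models[models["comparison"] == "treatment"]))
    means_all = pd.concat([f[0] for f in frames], ignore_index=True)
    models_all = pd.concat([f[1] for f in frames], ignore_index=True)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack_io.write_table(means_all, out_dir / "sweep_metric_means.csv")
    stack_io.write_table(models_all, out_dir / "sweep_treatment_models.csv")
    return models_all
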