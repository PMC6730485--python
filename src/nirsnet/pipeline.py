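"""End-to-end orchestration: simulate (or load) -> preprocess -> activation
-> connectivity -> graph metrics -> group statistics, with every artifact
written under a run directory together with a machine-readable manifest.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .activation import block_average, build_dhrf, estimate_activation, t_map
from .connectivity import (
    ConnectivityMatrix,
    binarize_fixed,
    fc_matrix,
    fisher_z,
    group_average,
)
from .graph import sparsity_sweep
from .io import (
    Montage,
    PipelineConfig,
    RawRecording,
    default_montage,
    save_events,
    save_matrix,
    save_recording,
)
from .optics import HemoglobinSeries, filter_hemoglobin, mbll_convert, optical_density
from .stats import fc_compare, two_sample_t
from .synthetic import Cohort, default_profiles, make_default_schedule, simulate_cohort

log = logging.getLogger("nirsnet")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def preprocess_recording(
    rec: RawRecording, config: PipelineConfig | None = None
) -> HemoglobinSeries:
    """Raw intensities -> optical density -> MBLL -> band-pass filter.

    The optical-density baseline window is the resting-state segment when
    the recording declares one, otherwise the full series.
    """
    if config is None:
        config = PipelineConfig()
    baseline = None
    if "resting" in rec.segments:
        s = rec.segment_slice("resting")
        baseline = (s.start, s.stop)
    od = optical_density(rec.intensity, baseline=baseline, channels=rec.channels)
    hemo = mbll_convert(od, fs=rec.fs, channels=rec.channels)
    return filter_hemoglobin(
        hemo, low_cut=config.low_cut, high_cut=config.high_cut, order=config.filter_order
    )


def save_tmap_png(tm, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 3.2))
    im = ax.pcolormesh(tm.grid_x, tm.grid_y, tm.values, shading="auto", cmap="jet",
                       vmin=0.0, vmax=1.0)
    ax.scatter(tm.coords[:, 0], tm.coords[:, 1], c="k", s=12)
    for i, (x, y) in enumerate(tm.coords, start=1):
        ax.annotate(str(i), (x, y), fontsize=6, textcoords="offset points", xytext=(2, 2))
    fig.colorbar(im, ax=ax, label="normalized t")
    ax.set_title(title)
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_sweep_png(summaries: dict[str, pd.DataFrame], metric: str, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for label, df in summaries.items():
        ax.plot(df["sparsity"], df[metric], marker="o", ms=3, label=label)
    ax.set_xlabel("sparsity")
    ax.set_ylabel(metric.replace("_", " "))
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class RunReport:
    """Outcome of one pipeline run: key results plus artifact paths."""

    config: PipelineConfig
    outdir: Path
    group_mean_evoked: dict[str, float] = field(default_factory=dict)
    group_sweep_summary: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)
    stats_table: pd.DataFrame | None = None
    manifest_path: Path | None = None


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> RunReport:
    """Run every stage on a freshly simulated cohort and emit all artifacts."""
    config.validate()
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config, outdir=outdir)
    montage = default_montage()
    schedule = make_default_schedule()

    # --- simulate -----------------------------------------------------
    stage = "simulate"
    try:
        profiles = [p for p in default_profiles() if p.label in config.groups]
        missing = set(config.groups) - {p.label for p in profiles}
        if missing:
            raise ValueError(f"unknown group label(s): {sorted(missing)}")
        cohort = simulate_cohort(
            profiles, config.n_per_group, montage=montage, schedule=schedule,
            fs=config.fs, seed=config.seed, hrf_params=config.hrf_params(),
        )
        raw_dir = outdir / "raw"
        raw_dir.mkdir(exist_ok=True)
        save_events(schedule, raw_dir / "events.tsv")
        (outdir / "montage.json").write_text(montage.to_json())
        for label, subs in cohort.groups.items():
            for i, (rec, truth) in enumerate(subs):
                stem = f"{label}_sub{i:02d}"
                save_recording(rec, raw_dir / f"{stem}.tsv")
                (raw_dir / f"{stem}_truth.json").write_text(
                    json.dumps(
                        {
                            "amplitudes": truth.amplitudes.tolist(),
                            "seed": truth.seed,
                        },
                        indent=2,
                    )
                )
        (outdir / "cohort_manifest.json").write_text(
            json.dumps(cohort.manifest(), indent=2)
        )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- preprocess ---------------------------------------------------
    stage = "preprocess"
    try:
        hemo: dict[str, list[HemoglobinSeries]] = {}
        pre_dir = outdir / "preprocessed"
        pre_dir.mkdir(exist_ok=True)
        for label, subs in cohort.groups.items():
            hemo[label] = []
            for i, (rec, _) in enumerate(subs):
                h = preprocess_recording(rec, config)
                hemo[label].append(h)
                df = pd.DataFrame(h.hbo, columns=h.channels)
                df.insert(0, "time", h.time)
                df.to_csv(pre_dir / f"{label}_sub{i:02d}_hbo.tsv", sep="\t",
                          index=False, float_format="%.8g")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- activation ---------------------------------------------------
    stage = "activation"
    try:
        act_dir = outdir / "activation"
        act_dir.mkdir(exist_ok=True)
        regressor = build_dhrf(schedule, config.fs, config.hrf_params())
        coords = montage.coordinates()
        mean_evoked: dict[str, list[float]] = {}
        group_t: dict[str, np.ndarray] = {}
        for label, series_list in hemo.items():
            t_rows = []
            mean_evoked[label] = []
            for i, h in enumerate(series_list):
                act = estimate_activation(
                    h.select(config.chromophore), regressor, h.channels, config.alpha
                )
                act.table.to_csv(
                    act_dir / f"{label}_sub{i:02d}_activation.tsv", sep="\t", index=False
                )
                t_rows.append(act.t_values)
                ba = block_average(h.select(config.chromophore), schedule, config.fs)
                mean_evoked[label].append(float(ba.mean.mean()))
            group_t[label] = np.mean(t_rows, axis=0)
            tm = t_map(group_t[label], coords)
            pd.DataFrame(tm.values).to_csv(
                act_dir / f"{label}_tmap_grid.tsv", sep="\t", index=False, header=False
            )
            save_tmap_png(tm, act_dir / f"{label}_tmap.png", title=label)
        report.group_mean_evoked = {k: float(np.mean(v)) for k, v in mean_evoked.items()}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- connectivity -------------------------------------------------
    stage = "connectivity"
    try:
        fc_dir = outdir / "connectivity"
        fc_dir.mkdir(exist_ok=True)
        subject_fc: dict[str, dict[str, list[ConnectivityMatrix]]] = {}
        group_fc: dict[str, dict[str, ConnectivityMatrix]] = {}
        for label, series_list in hemo.items():
            subject_fc[label] = {"resting": [], "task": []}
            for h in series_list:
                for seg in ("resting", "task"):
                    m = fc_matrix(
                        h, segment=schedule.segments[seg],
                        chromophore=config.chromophore, segment_name=seg,
                    )
                    subject_fc[label][seg].append(m)
            group_fc[label] = {}
            for seg in ("resting", "task"):
                avg = group_average(subject_fc[label][seg])
                group_fc[label][seg] = avg
                save_matrix(avg.values, avg.labels, fc_dir / f"{label}_{seg}_r.tsv")
                save_matrix(
                    fisher_z(avg).values, avg.labels, fc_dir / f"{label}_{seg}_z.tsv"
                )
                binary = binarize_fixed(avg, config.fixed_threshold)
                save_matrix(
                    binary.values, binary.labels,
                    fc_dir / f"{label}_{seg}_binary.tsv",
                )
                sidecar = {
                    "kind": "binary", "threshold": config.fixed_threshold,
                    "segment": seg, "group": label,
                }
                (fc_dir / f"{label}_{seg}_binary.json").write_text(
                    json.dumps(sidecar, indent=2)
                )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- graph metrics ------------------------------------------------
    stage = "metrics"
    try:
        gm_dir = outdir / "graph_metrics"
        gm_dir.mkdir(exist_ok=True)
        sweep_summaries: dict[str, dict[str, pd.DataFrame]] = {}
        for label, segs in group_fc.items():
            sweep_summaries[label] = {}
            for seg, avg in segs.items():
                sweep = sparsity_sweep(
                    avg, grid=config.sparsity_grid(), n_nulls=config.n_nulls,
                    seed=config.seed,
                )
                summ = sweep.summary()
                sweep_summaries[label][seg] = summ
                summ.to_csv(gm_dir / f"{label}_{seg}_network.tsv", sep="\t", index=False)
                sweep.nodal_long().to_csv(
                    gm_dir / f"{label}_{seg}_nodal.tsv", sep="\t", index=False
                )
                sweep.mean_sd().to_csv(gm_dir / f"{label}_{seg}_mean_sd.tsv", sep="\t")
        for seg in ("resting", "task"):
            save_sweep_png(
                {lab: s[seg] for lab, s in sweep_summaries.items()},
                "global_efficiency",
                gm_dir / f"global_efficiency_{seg}.png",
            )
        report.group_sweep_summary = sweep_summaries
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- group statistics ----------------------------------------------
    stage = "stats"
    try:
        rows = []
        labels = list(hemo.keys())
        for ia in range(len(labels)):
            for ib in range(ia + 1, len(labels)):
                a, b = labels[ia], labels[ib]
                res = two_sample_t(
                    np.asarray(mean_evoked[a]), np.asarray(mean_evoked[b]),
                    alpha=config.alpha,
                )
                rows.append(
                    (f"mean_evoked {a} vs {b}", res.statistic, res.df, res.p,
                     res.significant)
                )
                for seg in ("resting", "task"):
                    res = fc_compare(
                        subject_fc[a][seg], subject_fc[b][seg], alpha=config.alpha
                    )
                    rows.append(
                        (f"fc_{seg} {a} vs {b}", res.statistic, res.df, res.p,
                         res.significant)
                    )
        stats_df = pd.DataFrame(
            rows, columns=["comparison", "statistic", "df", "p", "significant"]
        )
        stats_df.to_csv(outdir / "group_stats.tsv", sep="\t", index=False)
        report.stats_table = stats_df
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- manifest -------------------------------------------------------
    manifest = {
        "nirsnet_version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_subjects": cohort.n_subjects,
    }
    manifest_path = outdir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    report.manifest_path = manifest_path
    log.info("pipeline complete: %s", outdir)
    return report
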