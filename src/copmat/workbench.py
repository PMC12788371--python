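"""End-to-end experiment orchestration at desk scale.

One call simulates a cohort, renders and preprocesses every trial,
assembles synchronized records, trains the requested architectures
under both input conditions with leave-one-subject-out folds, and
emits result tables (overall and static/dynamic strata), ANOVA
summaries, stabilograms and a reproducibility manifest.

The desk-scale defaults (8 subjects, one repetition per protocol,
20 s analysis windows, slimmed encoder widths, short training) keep a
full run tractable on one CPU while preserving the experimental
design; ``paper_scale()`` restores the 23-subject, 8-trial, 80 s
protocol layout.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cop_models as cm
from . import evaluation as ev
from . import sensor_sim as sim
from . import sync_assemble as sa
from .tactile_pipeline import SensorGeometry


@dataclass
class ExperimentConfig:
    """Everything one experiment needs; the master seed drives all stages."""

    n_subjects: int = 8
    reps: int = 2
    trial_duration_s: float = 14.0
    analysis_window_s: float = 10.0
    protocols: tuple = sim.PROTOCOL_IDS
    conditions: tuple = ("WA", "OT")
    model_names: tuple = ("ResNet-Bi-LSTM", "CNN-Bi-LSTM", "CNN-LSTM", "Bi-LSTM")
    spec_overrides: dict = field(default_factory=lambda: dict(
        encoder_dim=32, encoder_channels=(4, 8, 16), blocks_per_stage=1,
        stem_stride=4, hidden_dim=32, head_dims=(32,),
    ))
    train: cm.TrainConfig = field(default_factory=lambda: cm.TrainConfig(
        lr=3e-3, step_size=4, gamma=0.5, epochs=8, batch_size=64,
        window_len=14, window_stride=14,
    ))
    ideal_sensor: bool = False
    master_seed: int = 0
    output_dir: str = "copmat_run"

    @classmethod
    def paper_scale(cls, **overrides) -> "ExperimentConfig":
        """The full-scale layout: 23 subjects, 4 protocols x 2 reps, 90 s."""
        base = dict(n_subjects=23, reps=2, trial_duration_s=90.0,
                    analysis_window_s=80.0,
                    spec_overrides={}, train=cm.TrainConfig())
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "train" in raw:
            raw["train"] = cm.TrainConfig(**raw["train"])
        for k in ("protocols", "conditions", "model_names"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as f:
            yaml.safe_dump(json.loads(json.dumps(d, default=list)), f)


@dataclass
class EvalReport:
    """Per-fold results plus the derived summary tables."""

    fold_results: list
    summary: pd.DataFrame
    gaps: pd.DataFrame
    anova: dict  # direction -> DataFrame (only when the design is complete)
    manifest: dict


def experiment_jobs(config: ExperimentConfig) -> list[tuple[str, str, str]]:
    """The (model, condition, held-out subject) training jobs of a run."""
    subjects = [f"S{i:03d}" for i in range(config.n_subjects)]
    return [
        (m, c, held)
        for m in config.model_names
        for c in config.conditions
        for held in subjects
    ]


def simulate_cohort_records(config: ExperimentConfig, geometry: SensorGeometry | None = None):
    """Simulate and assemble every trial of the cohort, deterministically."""
    geometry = geometry or SensorGeometry()
    root = np.random.default_rng(config.master_seed)
    cohort = sim.make_cohort(config.n_subjects, seed=int(root.integers(2**31)))
    noise_rng = np.random.default_rng(int(root.integers(2**31)))
    noise = (sim.NoiseModel.ideal() if config.ideal_sensor
             else sim.NoiseModel.default_nonlinear(noise_rng))
    protocols = sim.default_protocols(config.trial_duration_s, config.analysis_window_s)
    cam_a, cam_b = sim.default_camera_pair(geometry)
    records, trials = [], []
    for subject in cohort:
        for pid in config.protocols:
            for rep in range(config.reps):
                seed = int(root.integers(2**31))
                trial = sim.simulate_trial(subject, protocols[pid], noise,
                                           geometry, seed=seed,
                                           cam_a=cam_a, cam_b=cam_b)
                rec = sa.assemble_trial(trial, geometry, cam_a, cam_b, noise=noise)
                records.append(rec)
                trials.append(trial)
    return cohort, records, trials, noise


def _fold_result_for_model(model, records, held, name, condition, train_cfg):
    fr = ev.FoldResult(held_out_subject=held, model_name=name, condition=condition)
    for rec in records:
        if rec.subject_id != held:
            continue
        pred = cm.predict_record(model, rec, train_cfg)
        key = rec.protocol_name
        if key in fr.vectors:
            y, yh = fr.vectors[key]
            fr.vectors[key] = (np.vstack([y, rec.truth_cop]), np.vstack([yh, pred]))
        else:
            fr.vectors[key] = (rec.truth_cop.copy(), pred)
    return fr.compute()


def wma_baseline_folds(records) -> list[ev.FoldResult]:
    """The untrained weighted-mean CoP as a per-subject baseline."""
    out = []
    for held in sorted({r.subject_id for r in records}):
        fr = ev.FoldResult(held_out_subject=held, model_name="WMA", condition="OT")
        for rec in records:
            if rec.subject_id != held:
                continue
            key = rec.protocol_name
            pair = (rec.truth_cop.copy(), rec.tactile_wma_cop.copy())
            if key in fr.vectors:
                y, yh = fr.vectors[key]
                fr.vectors[key] = (np.vstack([y, pair[0]]), np.vstack([yh, pair[1]]))
            else:
                fr.vectors[key] = pair
        out.append(fr.compute())
    return out


def run_experiment(config: ExperimentConfig, write_outputs: bool = True) -> EvalReport:
    """Simulate -> preprocess -> assemble -> train -> evaluate, reproducibly."""
    outdir = Path(config.output_dir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    cohort, records, _, noise = simulate_cohort_records(config)
    subjects = sorted({r.subject_id for r in records})
    folds = ev.loocv_split(subjects)
    specs = cm.paper_model_specs(**config.spec_overrides)

    fold_results = list(wma_baseline_folds(records))
    for train_ids, (held,) in folds:
        train_recs = [r for r in records if r.subject_id != held]
        ds = cm.window_dataset(train_recs, config.train)
        for name in config.model_names:
            for condition in config.conditions:
                spec = replace(specs[name], use_angular=(condition == "WA"))
                try:
                    model = cm.build_model(spec, static_dim=ds.static.shape[1],
                                           seed=config.train.seed)
                    cm.train_model(model, ds, config.train)
                    fold_results.append(_fold_result_for_model(
                        model, records, held, name, condition, config.train))
                except Exception as e:  # halt with stage and trial id
                    raise RuntimeError(
                        f"stage=train model={name} condition={condition} "
                        f"fold={held}: {e}"
                    ) from e

    summary = ev.stratify_and_summarize(fold_results)
    gaps = ev.directional_gap(summary)
    anova = {}
    trained = [fr for fr in fold_results if fr.model_name != "WMA"]
    n_cells = len(config.model_names) * len(config.conditions)
    if len(config.model_names) >= 2 and len(config.conditions) == 2:
        for direction in ev.DIRECTIONS:
            table = ev.build_anova_table(trained, direction)
            if not table.empty and len(table) == n_cells * len(subjects):
                anova[direction] = ev.rm_anova_2way(table)

    manifest = dict(
        master_seed=config.master_seed,
        n_subjects=config.n_subjects,
        n_trials=len(records),
        jobs=len(experiment_jobs(config)),
        noise=dataclasses.asdict(noise),
        config=json.loads(json.dumps(dataclasses.asdict(config), default=list)),
    )
    report = EvalReport(fold_results=fold_results, summary=summary,
                        gaps=gaps, anova=anova, manifest=manifest)
    if write_outputs:
        summary.to_csv(outdir / "summary.csv", index=False)
        gaps.to_csv(outdir / "directional_gaps.csv", index=False)
        for direction, table in anova.items():
            table.to_csv(outdir / f"anova_{direction}.csv", index=False)
        with open(outdir / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, sort_keys=True)
        make_report(report, outdir)
    return report


def _combined_rmse(fr: ev.FoldResult) -> float:
    """One scalar per fold: RMS of the ML and AP overall RMSEs."""
    ml = fr.metrics[("overall", "ML")].rmse
    ap = fr.metrics[("overall", "AP")].rmse
    return float(np.sqrt((ml**2 + ap**2) / 2.0))


def model_ordering_experiment(
    master_seed: int = 1,
    train_seeds: tuple = (0, 1, 2),
    config: ExperimentConfig | None = None,
) -> dict:
    """The desk-scale model-comparison study on the default cohort.

    Simulates the default 8-subject cohort with the imperfect sensor
    (gamma 0.7, +/-20% module gains), then runs leave-one-subject-out
    folds: ResNet-Bi-LSTM (WA) and the no-encoder Bi-LSTM (WA) for each
    training seed, plus ResNet-Bi-LSTM (OT) for the first seed, against
    the untrained weighted-mean baseline.  Returns fold-mean RMSEs per
    seed and the derived orderings.
    """
    config = config or ExperimentConfig(master_seed=master_seed)
    config.master_seed = master_seed
    _, records, _, noise = simulate_cohort_records(config)
    subjects = sorted({r.subject_id for r in records})
    specs = cm.paper_model_specs(**config.spec_overrides)

    wma_folds = wma_baseline_folds(records)
    out = {
        "wma_rmse": float(np.mean([_combined_rmse(fr) for fr in wma_folds])),
        "wma_rmse_ml": float(np.mean(
            [fr.metrics[("overall", "ML")].rmse for fr in wma_folds])),
        "wma_rmse_ap": float(np.mean(
            [fr.metrics[("overall", "AP")].rmse for fr in wma_folds])),
        "seeds": {},
        "noise": dataclasses.asdict(noise),
    }

    fold_ds = {}
    for held in subjects:
        fold_ds[held] = cm.window_dataset(
            [r for r in records if r.subject_id != held], config.train)

    def run_arch(name: str, condition: str, seed: int):
        spec = replace(specs[name], use_angular=(condition == "WA"))
        folds = []
        for held in subjects:
            ds = fold_ds[held]
            cfg_s = replace(config.train, seed=seed)
            model = cm.build_model(spec, static_dim=ds.static.shape[1], seed=seed)
            cm.train_model(model, ds, cfg_s)
            folds.append(_fold_result_for_model(
                model, records, held, name, condition, cfg_s))
        return folds

    for seed in train_seeds:
        resnet = run_arch("ResNet-Bi-LSTM", "WA", seed)
        flat = run_arch("Bi-LSTM", "WA", seed)
        entry = {
            "resnet_wa_rmse": float(np.mean([_combined_rmse(f) for f in resnet])),
            "resnet_wa_rmse_ml": float(np.mean(
                [f.metrics[("overall", "ML")].rmse for f in resnet])),
            "flatten_wa_rmse": float(np.mean([_combined_rmse(f) for f in flat])),
        }
        if seed == train_seeds[0]:
            resnet_ot = run_arch("ResNet-Bi-LSTM", "OT", seed)
            entry["resnet_ot_rmse"] = float(np.mean(
                [_combined_rmse(f) for f in resnet_ot]))
            entry["resnet_ot_rmse_ml"] = float(np.mean(
                [f.metrics[("overall", "ML")].rmse for f in resnet_ot]))
        out["seeds"][seed] = entry

    wins_vs_wma = sum(
        e["resnet_wa_rmse"] < out["wma_rmse"] for e in out["seeds"].values())
    wins_vs_flat = sum(
        e["resnet_wa_rmse"] < e["flatten_wa_rmse"] for e in out["seeds"].values())
    first = out["seeds"][train_seeds[0]]
    out["ordering"] = {
        "n_seeds": len(train_seeds),
        "resnet_beats_wma_seeds": int(wins_vs_wma),
        "resnet_beats_flatten_seeds": int(wins_vs_flat),
        "wa_ml_rmse": first["resnet_wa_rmse_ml"],
        "ot_ml_rmse": first["resnet_ot_rmse_ml"],
        "wa_le_ot_ml": bool(
            first["resnet_wa_rmse_ml"] <= first["resnet_ot_rmse_ml"]),
    }
    return out


def report_checksum(report: EvalReport) -> str:
    """Stable digest of the numeric content of a report."""
    payload = report.summary.round(9).to_csv(index=False)
    for d in sorted(report.anova):
        payload += report.anova[d].round(9).to_csv(index=False)
    return hashlib.sha256(payload.encode()).hexdigest()


def make_report(report: EvalReport, outdir) -> list[Path]:
    """Figures: stabilogram overlays, RMSE boxplots, error-vs-position."""
    if not report.fold_results:
        raise ValueError("empty results")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    trained = [fr for fr in report.fold_results if fr.model_name != "WMA"]
    if trained:
        fr = trained[0]
        protos = list(fr.vectors)
        fig, axes = plt.subplots(1, len(protos), figsize=(4 * len(protos), 4),
                                 squeeze=False)
        for ax, p in zip(axes[0], protos):
            y, yh = fr.vectors[p]
            ax.plot(y[:, 0], y[:, 1], lw=0.8, label="ground truth")
            ax.plot(yh[:, 0], yh[:, 1], lw=0.8, label="estimate")
            ax.set_title(f"{p} ({fr.model_name}, {fr.condition})")
            ax.set_xlabel("CoP ML (mm)")
            ax.set_ylabel("CoP AP (mm)")
            ax.legend(fontsize=7)
        fig.tight_layout()
        path = outdir / "stabilograms.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

        # RMSE boxplots by model/condition, static vs dynamic separated
        rows = []
        for fr in report.fold_results:
            for stratum in ("static", "dynamic"):
                for d in ev.DIRECTIONS:
                    m = fr.metrics.get((stratum, d))
                    if m:
                        rows.append(dict(label=f"{fr.model_name}/{fr.condition}",
                                         stratum=stratum, direction=d, rmse=m.rmse))
        df = pd.DataFrame(rows)
        if not df.empty:
            fig, axes = plt.subplots(2, 2, figsize=(10, 7), squeeze=False)
            for i, stratum in enumerate(("static", "dynamic")):
                for j, d in enumerate(ev.DIRECTIONS):
                    sub = df[(df.stratum == stratum) & (df.direction == d)]
                    ax = axes[i][j]
                    if not sub.empty:
                        groups = [g["rmse"].values for _, g in sub.groupby("label")]
                        labels = [k for k, _ in sub.groupby("label")]
                        ax.boxplot(groups, tick_labels=labels)
                        ax.tick_params(axis="x", rotation=60, labelsize=6)
                    ax.set_title(f"{stratum} RMSE {d} (mm)")
            fig.tight_layout()
            path = outdir / "rmse_boxplots.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            written.append(path)

        # absolute error vs ground-truth position
        fr = trained[0]
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), squeeze=False)
        for j, d in enumerate(ev.DIRECTIONS):
            ax = axes[0][j]
            for p, (y, yh) in fr.vectors.items():
                ax.scatter(y[:, j], np.abs(yh[:, j] - y[:, j]), s=3, label=p)
            ax.set_xlabel(f"ground-truth CoP {d} (mm)")
            ax.set_ylabel("absolute error (mm)")
            ax.legend(fontsize=7)
        fig.tight_layout()
        path = outdir / "error_vs_position.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written
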