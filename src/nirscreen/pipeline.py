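"""End-to-end orchestration: simulate -> preprocess -> fc -> stats ->
classify -> report, with per-stage manifests and resumability.

Every stage writes its artifacts under the output directory plus a
manifest entry (config hash, seed, SHA-256 of each output). On ``--resume``
a stage is skipped when its manifest entry exists and all of its listed
outputs still hash to the recorded values; downstream stages are re-run.
A single seed governs all randomness.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .connectivity import average_rois, fc_matrix_set
from .groupstats import run_group_analysis
from .preprocess import preprocess_recording
from .reports import write_report
from .screening import ScreeningModel, build_feature_table
from .snirf import read_snirf, write_concentration, write_snirf
from .synth import CohortConfig, default_group_coupling, generate_cohort

__all__ = ["run_pipeline", "cohort_config_from_pipeline"]

STAGES = ("simulate", "preprocess", "fc", "stats", "classify")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config: PipelineConfig, seed: int) -> None:
        self.path = out_dir / "manifest.json"
        self.data: dict = {"config_hash": config.config_hash(), "seed": seed,
                           "version": config.version, "stages": {}}
        if self.path.exists():
            prev = json.loads(self.path.read_text())
            if (
                prev.get("config_hash") == self.data["config_hash"]
                and prev.get("seed") == seed
            ):
                self.data["stages"] = prev.get("stages", {})

    def stage_done(self, stage: str, out_dir: Path) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry:
            return False
        for rel, digest in entry["outputs"].items():
            p = out_dir / rel
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, stage: str, out_dir: Path, outputs: list[Path]) -> None:
        self.data["stages"][stage] = {
            "outputs": {
                str(p.relative_to(out_dir)): _sha256(p) for p in outputs
            }
        }
        self.path.write_text(json.dumps(self.data, indent=1))


def cohort_config_from_pipeline(config: PipelineConfig, seed: int) -> CohortConfig:
    s = config.synth
    return CohortConfig(
        group_sizes=dict(s.group_sizes),
        duration_s=s.duration_s,
        sampling_rate_hz=s.sampling_rate_hz,
        coupling=default_group_coupling(s.coupling_base, dict(s.coupling_deltas)),
        artifact_rate_per_min=s.artifact_rate_per_min,
        noise_sd=s.noise_sd,
        seed=seed,
    )


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    seed: int = 0,
    resume: bool = False,
    n_perm: int | None = None,
) -> Path:
    """Run the full pipeline into ``out_dir``; returns the report path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir, config, seed)

    # --- simulate -----------------------------------------------------
    rec_dir = out_dir / "recordings"
    cohort_csv = out_dir / "cohort.csv"
    truth_json = out_dir / "ground_truth.json"
    if not (resume and manifest.stage_done("simulate", out_dir)):
        rec_dir.mkdir(exist_ok=True)
        cohort = generate_cohort(cohort_config_from_pipeline(config, seed))
        outputs = []
        for rec in cohort.recordings:
            p = rec_dir / f"{rec.subject_id}.snirf"
            write_snirf(rec, p)
            outputs.append(p)
        cohort.scores.to_csv(cohort_csv, index=False)
        truth = {
            sid: {
                "group": t.group,
                "coupling": np.asarray(t.coupling).tolist(),
                "artifact_times_s": t.artifact_times_s,
            }
            for sid, t in cohort.ground_truth.items()
        }
        truth_json.write_text(json.dumps(truth))
        manifest.record("simulate", out_dir, outputs + [cohort_csv, truth_json])

    scores = pd.read_csv(cohort_csv)

    # --- preprocess ---------------------------------------------------
    conc_dir = out_dir / "concentrations"
    if not (resume and manifest.stage_done("preprocess", out_dir)):
        conc_dir.mkdir(exist_ok=True)
        outputs = []
        log_lines = []
        for sid in scores["subject_id"]:
            rec = read_snirf(rec_dir / f"{sid}.snirf")
            res = preprocess_recording(rec, config.preprocess)
            if res.excluded:
                log_lines.append(f"{sid}: excluded ({'; '.join(res.log)})")
                continue
            p = conc_dir / f"{sid}.h5"
            write_concentration(res.concentration, p)
            outputs.append(p)
            log_lines.append(f"{sid}: {'; '.join(res.log)}")
        log_path = out_dir / "preprocess.log"
        log_path.write_text("\n".join(log_lines) + "\n")
        manifest.record("preprocess", out_dir, outputs + [log_path])

    # --- fc -----------------------------------------------------------
    features_csv = out_dir / "features.csv"
    if not (resume and manifest.stage_done("fc", out_dir)):
        from .snirf import read_concentration

        band = (config.fc.band_low_hz, config.fc.band_high_hz)
        fc_by_subject = {}
        for p in sorted(conc_dir.glob("*.h5")):
            conc = read_concentration(p)
            roits = average_rois(conc)
            fc_by_subject[p.stem] = fc_matrix_set(
                roits, band=band, coh_seg_len_s=config.fc.coh_seg_len_s
            )
        features = build_feature_table(fc_by_subject, scores, include_scores=True)
        features.to_csv(features_csv, index=False)
        manifest.record("fc", out_dir, [features_csv])

    features = pd.read_csv(features_csv)

    # --- stats --------------------------------------------------------
    stats_csv = out_dir / "stats.csv"
    if not (resume and manifest.stage_done("stats", out_dir)):
        res = run_group_analysis(
            features,
            features["group"],
            alpha=config.stats.alpha,
            fdr_family=config.stats.fdr_family,
            normality_alpha=config.stats.normality_alpha,
        )
        res.to_csv(stats_csv)
        manifest.record("stats", out_dir, [stats_csv])

    # --- classify + report -------------------------------------------
    report_csv = out_dir / "report.csv"
    report_json = out_dir / "report.json"
    if not (resume and manifest.stage_done("classify", out_dir)):
        m = config.models
        model = ScreeningModel(
            features,
            models=tuple(m.models),
            fold_schemes=tuple(m.fold_schemes),
            feature_sets=tuple(m.feature_sets),
            reducer=m.reducer(),
        )
        results = model.fit(
            n_perm=n_perm if n_perm is not None else m.n_perm, seed=seed
        )
        write_report(results, report_csv, fmt="csv")
        write_report(results, report_json, fmt="json")
        manifest.record("classify", out_dir, [report_csv, report_json])

    return report_csv
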