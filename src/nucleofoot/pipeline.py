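"""End-to-end orchestration: simulate -> train -> score -> evaluate.

Every stage consumes and produces files recorded in a JSON manifest
(config hash, per-file SHA-256), and all randomness derives from one
global seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, synthetic
from .cna_zscore import build_reference_panel, correct_bins, score_sample_gwz
from .mixture_model import MixtureSettings, estimate_nucleosome_score, train_class_profiles

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative settings for a full simulated-cohort run."""

    out_dir: str = "nucleofoot_run"
    seed: int = 0
    n_per_group: int = 30
    n_train_per_class: int = 10
    cohort: synthetic.CohortSimSettings = field(
        default_factory=synthetic.CohortSimSettings
    )
    mixture: MixtureSettings = field(default_factory=MixtureSettings)
    bootstrap_iterations: int = 500

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = synthetic.CohortSimSettings(**raw.pop("cohort", {}))
        mixture = MixtureSettings(**raw.pop("mixture", {}))
        known = {"out_dir", "seed", "n_per_group", "n_train_per_class",
                 "bootstrap_iterations"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(cohort=cohort, mixture=mixture, **raw)

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        d = asdict(self)
        d.pop("out_dir")  # output location must not change the run identity
        blob = json.dumps(d, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a labeled cohort, train profiles, score, evaluate.

    Writes profiles, per-sample scores, the ground-truth sidecar, an
    evaluation report and the manifest into ``config.out_dir``; returns
    the manifest dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "stages": {},
        "complete": False,
    }
    manifest_path = out / "manifest.json"

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = {
            p.name: _sha256(p) for p in paths
        }
        manifest_path.write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )

    try:
        st = config.cohort
        rng = np.random.default_rng(config.seed)
        profiles_true = synthetic.make_m_profiles(st.profile_params)

        # --- stage: train -------------------------------------------------
        train_hists, train_labels = [], []
        for label, lam in (("healthy", 0.0), ("HGSOC", 1.0)):
            for i in range(config.n_train_per_class):
                train_hists.append(
                    synthetic.sample_distance_histogram(
                        profiles_true, lam, st.n_reads,
                        seed=int(rng.integers(2**31)),
                        sample_id=f"train_{label}_{i:03d}",
                    )
                )
                train_labels.append(label)
        profiles = train_class_profiles(train_hists, train_labels)
        profiles_path = out / "profiles.tsv"
        profiles.to_tsv(str(profiles_path))
        record("train", profiles_path)
        logger.info("stage train: %d histograms", len(train_hists))

        # --- stage: simulate + score -------------------------------------
        annotation = synthetic.make_bin_annotation(seed=st.annotation_seed)
        segments = synthetic.default_cna_segments(
            annotation.n_bins, st.gained_fraction, st.copy_number
        )
        panel_cov = [
            correct_bins(
                synthetic.simulate_binned_sample(
                    synthetic.CnaSimParams(
                        n_bins=annotation.n_bins, depth=st.depth,
                        seed=int(rng.integers(2**31)),
                    ),
                    annotation,
                ),
                annotation,
            )
            for _ in range(st.n_panel)
        ]
        panel = build_reference_panel(panel_cov, annotation)

        rows, truth = [], []
        for group in ("benign", "invasive"):
            for i in range(config.n_per_group):
                if group == "benign":
                    lam_true, tf = 0.0, 0.0
                else:
                    lam_true = float(rng.uniform(*st.lam_range))
                    tf = float(rng.uniform(*st.tf_range))
                sid = f"{group}_{i:03d}"
                hist = synthetic.sample_distance_histogram(
                    profiles_true, lam_true, st.n_reads,
                    seed=int(rng.integers(2**31)), sample_id=sid,
                )
                res = estimate_nucleosome_score(
                    hist, profiles, config.mixture
                )
                cov = correct_bins(
                    synthetic.simulate_binned_sample(
                        synthetic.CnaSimParams(
                            n_bins=annotation.n_bins,
                            segments=segments if tf > 0 else [],
                            tumor_fraction=tf,
                            depth=st.depth,
                            seed=int(rng.integers(2**31)),
                        ),
                        annotation,
                    ),
                    annotation,
                )
                gwz = score_sample_gwz(cov, panel, annotation)
                rows.append(
                    {
                        "sample_id": sid,
                        "nucleosome_score": round(res.score, 6),
                        "ci_low": round(res.ci_low, 6),
                        "ci_high": round(res.ci_high, 6),
                        "rhat": res.rhat,
                        "n_reads_used": res.n,
                        "genome_wide_z": round(gwz.zscore, 6),
                        "label": group,
                    }
                )
                truth.append((sid, lam_true, tf))
                logger.info("scored %s: nucl=%.3f gwz=%.2f",
                            sid, res.score, gwz.zscore)

        scores_df = pd.DataFrame(rows)
        scores_path = out / "cohort_scores.tsv"
        scores_df.to_csv(scores_path, sep="\t", index=False)
        truth_path = out / "ground_truth.tsv"
        pd.DataFrame(
            truth, columns=["sample_id", "lam_true", "tumor_fraction"]
        ).to_csv(truth_path, sep="\t", index=False)
        record("score", scores_path, truth_path)

        # --- stage: evaluate ---------------------------------------------
        cohort = evaluation.CohortTable(
            scores_df[
                ["sample_id", "nucleosome_score", "genome_wide_z", "label"]
            ]
        )
        y = cohort.table["label"].to_numpy()
        report = {}
        for col in ("nucleosome_score", "genome_wide_z"):
            r = evaluation.roc_auc(
                cohort.table[col].to_numpy(), y, positive="invasive"
            )
            report[col] = {
                "auc": r.auc, "ci_low": r.ci_low, "ci_high": r.ci_high,
            }
        combined = evaluation.combine_scores(
            cohort, positive="invasive",
            seed=config.seed + 1,
            n_bootstrap=config.bootstrap_iterations,
        )
        report["combined"] = {
            "apparent_auc": combined.apparent_auc,
            "optimism": combined.optimism,
            "corrected_auc": combined.corrected_auc,
        }
        inv = cohort.table["label"] == "invasive"
        _, p = evaluation.mann_whitney(
            cohort.table.loc[inv, "nucleosome_score"],
            cohort.table.loc[~inv, "nucleosome_score"],
        )
        report["mann_whitney_p_nucleosome"] = p
        report["spearman_rho_scores_invasive"] = evaluation.spearman_rho(
            cohort.table.loc[inv, "nucleosome_score"],
            cohort.table.loc[inv, "genome_wide_z"],
        )
        eval_path = out / "evaluation.json"
        eval_path.write_text(json.dumps(report, indent=1, sort_keys=True))
        record("evaluate", eval_path)

        manifest["complete"] = True
        manifest_path.write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest_path.write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
        raise
    return manifest
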