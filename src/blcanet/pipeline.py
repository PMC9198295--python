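"""End-to-end orchestration of the diagnostic workflow.

Stages, in order: ingest (real series-matrix files or the synthetic
generator) -> differential expression -> random-forest feature screening
-> median scoring -> neural-network training -> ROC evaluation on train
and test cohorts, plus optional over-representation analysis of the DEG
list and immune deconvolution.  The test cohort is scored with its own
medians (each cohort is binarized against itself) while the feature list
and the fitted network are frozen from training; a deployment mode that
freezes the training medians instead is available behind a flag.

Every stage writes its table under the output directory and contributes a
summary to the run manifest; stage seeds are derived from the global seed
by fixed offsets.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de, deconv, enrichment, features, geo, nn, roc, scoring, synthetic
from .cohort import CohortLabels, read_labels, write_labels

__all__ = ["PipelineConfig", "run_pipeline"]

# fixed per-stage seed offsets, added to the global seed
_SEED_OFFSETS = {
    "train_data": 101,
    "test_data": 211,
    "forest": 307,
    "nn": 401,
    "roc_train": 503,
    "roc_test": 601,
    "mixtures": 701,
    "deconv": 809,
    "gmt": 907,
}


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one input mode per cohort.

    Synthetic mode (``synthetic=True``) generates both cohorts, a planted
    gene-set collection for enrichment and signature/mixture pairs for
    deconvolution.  Real mode reads gene-level matrices and label TSVs
    from ``train_matrix``/``train_labels`` (and test counterparts) and
    runs enrichment/deconvolution only when ``gmt_path``/``signature_path``
    are supplied.
    """

    synthetic: bool = True
    train_spec: synthetic.SyntheticExpressionSpec | None = None
    test_spec: synthetic.SyntheticExpressionSpec | None = None
    train_matrix: str | None = None
    train_labels: str | None = None
    test_matrix: str | None = None
    test_labels: str | None = None
    gmt_path: str | None = None
    signature_path: str | None = None
    de_thresholds: de.DEThresholds = field(default_factory=de.DEThresholds)
    forest: features.ForestConfig = field(default_factory=features.ForestConfig)
    nn: nn.NNConfig = field(default_factory=nn.NNConfig)
    n_boot: int = 2000
    n_perm: int = 100
    deconv_p_threshold: float = 0.05
    freeze_train_medians: bool = False
    seed: int = 0
    out_dir: str = "blcanet_run"

    def __post_init__(self) -> None:
        if self.synthetic:
            if self.train_matrix or self.test_matrix:
                raise ValueError("synthetic mode excludes real input paths")
        else:
            for name in ("train_matrix", "train_labels", "test_matrix", "test_labels"):
                if getattr(self, name) is None:
                    raise ValueError(f"real-input mode requires {name}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (
            ("train_spec", synthetic.SyntheticExpressionSpec),
            ("test_spec", synthetic.SyntheticExpressionSpec),
            ("de_thresholds", de.DEThresholds),
            ("forest", features.ForestConfig),
            ("nn", nn.NNConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                if key in ("train_spec", "test_spec") and "gene_sd_range" in raw[key]:
                    raw[key]["gene_sd_range"] = tuple(raw[key]["gene_sd_range"])
                raw[key] = sub(**raw[key])
        return cls(**raw)


def _stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) + _SEED_OFFSETS[stage]) % (2**31)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_jsonable(v) for v in obj]
    return obj


def _load_cohort(cfg: PipelineConfig, which: str):
    if cfg.synthetic:
        spec = cfg.train_spec if which == "train" else cfg.test_spec
        if spec is None:
            base = synthetic.SyntheticExpressionSpec() if which == "train" else (
                synthetic.SyntheticExpressionSpec(n_control=3, n_treatment=3)
            )
            spec = base
        spec = dataclasses.replace(spec, seed=_stage_seed(cfg.seed, f"{which}_data"))
        matrix, labels, truth = synthetic.generate_expression(spec)
        labels.role = which
        return matrix, labels, truth, spec
    matrix = geo.read_matrix(getattr(cfg, f"{which}_matrix"))
    labels = read_labels(getattr(cfg, f"{which}_labels"), role=which)
    return matrix, labels, None, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow and return the run manifest.

    When no gene survives feature screening the pipeline stops before the
    network stage, records ``status: "aborted_no_features"`` in the
    manifest and keeps all partial outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _jsonable(cfg),
        "seed": cfg.seed,
        "stages": {},
        "status": "ok",
    }

    # ingest
    train_x, train_labels, train_truth, train_spec = _load_cohort(cfg, "train")
    test_x, test_labels, test_truth, _ = _load_cohort(cfg, "test")
    geo.write_matrix(train_x, out / "train_matrix.tsv")
    geo.write_matrix(test_x, out / "test_matrix.tsv")
    write_labels(train_labels, out / "train_labels.tsv")
    write_labels(test_labels, out / "test_labels.tsv")
    manifest["stages"]["ingest"] = {
        "n_genes": int(train_x.shape[0]),
        "train_samples": {
            "control": len(train_labels.control_samples),
            "treatment": len(train_labels.treatment_samples),
        },
        "test_samples": {
            "control": len(test_labels.control_samples),
            "treatment": len(test_labels.treatment_samples),
        },
        "synthetic": cfg.synthetic,
    }

    # differential expression
    det = de.moderated_t_table(train_x, train_labels, thresholds=cfg.de_thresholds)
    det.to_csv(out / "de_table.tsv", sep="\t", index_label="gene")
    degs = de.filter_degs(det, cfg.de_thresholds)
    pd.DataFrame(degs, columns=["gene", "direction"]).to_csv(
        out / "degs.tsv", sep="\t", index=False
    )
    manifest["stages"]["de"] = {
        "n_degs": len(degs),
        "n_up": sum(1 for _, d in degs if d == "up"),
        "n_down": sum(1 for _, d in degs if d == "down"),
    }

    # optional enrichment of the DEG list
    if cfg.synthetic or cfg.gmt_path:
        if cfg.synthetic:
            # planted set seeded from the ground-truth DE genes, universe =
            # all matrix genes
            planted = list(train_truth.index[train_truth != "none"]) or list(
                train_x.index[:20]
            )
            gmt = synthetic.generate_gmt(
                n_sets=50,
                universe_size=train_x.shape[0],
                planted_list=planted,
                planted_set_overlap=min(20, len(planted)),
                seed=_stage_seed(cfg.seed, "gmt"),
                universe=list(train_x.index),
            )
        else:
            gmt = enrichment.read_gmt(cfg.gmt_path)
        if degs:
            records = enrichment.ora_test([g for g, _ in degs], gmt)
            records.to_csv(out / "ora_table.tsv", sep="\t")
            kept = enrichment.apply_metascape_filters(records)
            manifest["stages"]["enrichment"] = {
                "n_sets_tested": int(len(records)),
                "n_sets_passing": int(len(kept)),
            }
        else:
            manifest["stages"]["enrichment"] = {"n_sets_tested": 0, "n_sets_passing": 0}

    if len(degs) < 2:
        manifest["status"] = "aborted_no_features"
        manifest["stages"]["features"] = {"n_features": 0, "n_candidates": len(degs)}
        _write_manifest(manifest, out)
        warnings.warn("fewer than 2 DEGs; stopping before feature screening")
        return manifest

    # random-forest feature screening
    forest_cfg = dataclasses.replace(cfg.forest, seed=_stage_seed(cfg.seed, "forest"))
    fgs = features.select_feature_genes(train_x, train_labels, degs, forest_cfg)
    pd.DataFrame(
        {"importance": fgs.importance, "direction": fgs.direction}
    ).to_csv(out / "feature_genes.tsv", sep="\t", index_label="gene")
    pd.DataFrame({"n_trees": np.arange(1, len(fgs.oob_curve) + 1), "oob_error": fgs.oob_curve}).to_csv(
        out / "oob_curve.tsv", sep="\t", index=False
    )
    manifest["stages"]["features"] = {
        "n_candidates": len(degs),
        "n_features": len(fgs.genes),
        "n_trees_selected": fgs.n_trees_selected,
        "oob_error_at_selection": float(fgs.oob_curve[fgs.n_trees_selected - 1]),
    }
    if not fgs.genes:
        manifest["status"] = "aborted_no_features"
        _write_manifest(manifest, out)
        warnings.warn("no gene passed the importance cutoff; stopping before the network")
        return manifest

    # scoring
    train_scores = scoring.score_samples(train_x, fgs, cohort="train")
    if cfg.freeze_train_medians:
        test_scores = scoring.score_samples(
            test_x, fgs, medians=train_scores.medians, cohort="test"
        )
    else:
        test_scores = scoring.score_samples(test_x, fgs, cohort="test")
    train_scores.scores.to_csv(out / "train_scores.tsv", sep="\t", index_label="sample")
    test_scores.scores.to_csv(out / "test_scores.tsv", sep="\t", index_label="sample")

    # neural network
    nn_cfg = dataclasses.replace(cfg.nn, seed=_stage_seed(cfg.seed, "nn"))
    model = nn.train_nn(train_scores, train_labels, nn_cfg)
    model.to_json(out / "nn_model.json")
    manifest["stages"]["nn"] = {
        "n_features": len(model.feature_schema),
        "final_loss": model.final_loss,
        "epochs_run": model.epochs_run,
    }

    # ROC on both cohorts
    summaries = {}
    for which, scores_m, labels in (
        ("train", train_scores, train_labels),
        ("test", test_scores, test_labels),
    ):
        preds = nn.predict_nn(model, scores_m)
        preds.to_csv(out / f"{which}_predictions.tsv", sep="\t", index_label="sample")
        y = labels.groups.reindex(preds.index).values
        result = roc.roc_analysis(
            preds["probability"].values, y, n_boot=cfg.n_boot,
            seed=_stage_seed(cfg.seed, f"roc_{which}"),
        )
        confusion = roc.confusion_at_threshold(preds["probability"].values, y)
        accuracy = (confusion["TP"] + confusion["TN"]) / len(preds)
        pd.DataFrame({"fpr": result.fpr, "tpr": result.tpr}).to_csv(
            out / f"{which}_roc_points.tsv", sep="\t", index=False
        )
        summaries[which] = {
            "auc": result.auc,
            "ci_low": result.ci_low,
            "ci_high": result.ci_high,
            "accuracy": accuracy,
            "confusion": confusion,
        }
    manifest["stages"]["roc"] = summaries

    # optional immune deconvolution on synthetic mixtures or a supplied signature
    if cfg.synthetic:
        mix_spec = synthetic.SyntheticMixtureSpec(seed=_stage_seed(cfg.seed, "mixtures"))
        sig, bulk, truth_fracs = synthetic.generate_mixtures(mix_spec)
        res = deconv.run_deconvolution(
            bulk, sig, n_perm=cfg.n_perm, seed=_stage_seed(cfg.seed, "deconv"),
            p_threshold=cfg.deconv_p_threshold,
        )
        res.fractions.to_csv(out / "deconv_fractions.tsv", sep="\t", index_label="sample")
        mae = float((res.fractions - truth_fracs).abs().values.mean())
        manifest["stages"]["deconv"] = {
            "n_samples": int(len(res.fractions)),
            "n_retained": int(res.retained.sum()),
            "mae_vs_truth": mae,
        }
    elif cfg.signature_path:
        sig = deconv.read_signature(cfg.signature_path)
        res = deconv.run_deconvolution(
            test_x, sig, n_perm=cfg.n_perm, seed=_stage_seed(cfg.seed, "deconv"),
            p_threshold=cfg.deconv_p_threshold, log2_scale=True,
        )
        res.fractions.to_csv(out / "deconv_fractions.tsv", sep="\t", index_label="sample")
        manifest["stages"]["deconv"] = {
            "n_samples": int(len(res.fractions)),
            "n_retained": int(res.retained.sum()),
        }

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=1, sort_keys=True)
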