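"""End-to-end workflows chaining downscaling, sampling, training,
prediction and evaluation.

Two modes mirror the two ways the trained translator is used:

* evaluation - per cross-validation fold, remove 10% of edges (N100 ->
  N90), remove a further 10% (N90 -> N81), train the translator on
  N81 -> N90 pairs, then feed it N90 subgraphs and score the ranked
  candidates against the fold's held-out edges.
* discovery - one holdout N100 -> N90, train N90 -> N100, then feed it
  N100 subgraphs to rank entirely unknown candidate links (~N110).

Every run derives all stage seeds from one master seed and can write a
JSON manifest sufficient to reproduce it exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .cgan import TrainingConfig, generate_batch, train
from .downscale import holdout_edge_split, kfold_edge_split
from .evaluate import MetricsReport, evaluate_fold, summarize
from .network_io import InteractionNetwork, PredictionRecord, write_predictions
from .predict import aggregate_predictions, coverage_stats
from .representation import build_pairs, subgraph_adjacency
from .sampling import SamplerConfig, enumerate_subgraphs

logger = logging.getLogger(__name__)

_STAGE_OFFSETS = {
    "kfold": 1,
    "holdout": 2,
    "sample_train": 3,
    "train": 4,
    "sample_predict": 5,
}


def derive_seed(master: int, stage: str, fold: int = 0) -> int:
    """Per-stage, per-fold seed by fixed offsets from the master seed."""
    return (master + 1_000_003 * (fold + 1) + 7919 * _STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class RunConfig:
    mode: str = "evaluation"
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    k_folds: int = 10
    keep_fraction: float = 0.9
    seed: int = 0
    strict_eval: bool = False
    max_folds: int | None = None  # run only the first n folds (scaled runs)
    out_dir: str | None = None

    def __post_init__(self):
        if self.mode not in ("evaluation", "discovery"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.keep_fraction < 1.0:
            raise ValueError("keep_fraction must be in (0, 1)")


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML (or JSON) mapping with optional
    ``sampler`` and ``training`` sub-mappings."""
    import yaml

    from .sampling import SamplerConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    sampler = SamplerConfig(**raw.pop("sampler", {}))
    training = TrainingConfig(**raw.pop("training", {}))
    return RunConfig(sampler=sampler, training=training, **raw)


def _predict_records(generator, network, specs, batch: int = 64):
    mats = np.stack([subgraph_adjacency(network, s).matrix for s in specs])
    outs = []
    for lo in range(0, len(specs), batch):
        outs.append(generate_batch(generator, mats[lo : lo + batch]))
    confidences = np.concatenate(outs) if outs else np.empty((0,))
    return aggregate_predictions(list(zip(specs, confidences)), network)


def _write_manifest(out_dir: Path, config: RunConfig, extra: dict) -> None:
    manifest = {"config": asdict(config), **extra}
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_evaluation(
    network: InteractionNetwork,
    config: RunConfig,
    generator_override=None,
) -> tuple[list[MetricsReport], dict]:
    """Cross-validated held-out-edge recovery.

    ``generator_override``, if given, replaces the trained model with a
    fixed map from condition stacks to confidence stacks (used for
    null-model controls such as a generator that echoes its input).
    Returns the per-fold reports and their mean summary.  A failing
    fold is logged and skipped; at least one fold must succeed.
    """
    master = config.seed
    folds = kfold_edge_split(network, k=config.k_folds, seed=derive_seed(master, "kfold"))
    if config.max_folds is not None:
        folds = folds[: config.max_folds]
    out_dir = Path(config.out_dir) if config.out_dir else None
    reports: list[MetricsReport] = []
    for fold in folds:
        try:
            n90 = fold.retained
            sub = holdout_edge_split(
                n90, config.keep_fraction, derive_seed(master, "holdout", fold.fold_index)
            )
            n81 = sub.retained

            if generator_override is None:
                specs81 = enumerate_subgraphs(
                    n81,
                    replace(config.sampler, seed=derive_seed(master, "sample_train", fold.fold_index)),
                )
                if not specs81:
                    raise RuntimeError("no eligible training subgraphs")
                pairs = build_pairs(n81, n90, specs81)
                gen = train(
                    pairs,
                    replace(config.training, seed=derive_seed(master, "train", fold.fold_index)),
                )
                predict_fn = None
            else:
                predict_fn = generator_override

            specs90 = enumerate_subgraphs(
                n90,
                replace(config.sampler, seed=derive_seed(master, "sample_predict", fold.fold_index)),
            )
            if not specs90:
                raise RuntimeError("no eligible prediction subgraphs")
            if predict_fn is None:
                records = _predict_records(gen, n90, specs90, config.training.batch_size)
            else:
                mats = np.stack([subgraph_adjacency(n90, s).matrix for s in specs90])
                records = aggregate_predictions(list(zip(specs90, predict_fn(mats))), n90)
            coverage = coverage_stats(specs90, n90, fold.removed_edges)
            report = evaluate_fold(
                records, fold.removed_edges, coverage, strict=config.strict_eval
            )
            reports.append(report)
            logger.info(
                "fold %d: auroc=%.3f auprc=%.3f ndcg=%.3f (%d candidates)",
                fold.fold_index, report.auroc, report.auprc, report.ndcg,
                report.n_candidates,
            )
            if out_dir is not None:
                fold_dir = out_dir / f"fold_{fold.fold_index}"
                fold_dir.mkdir(parents=True, exist_ok=True)
                write_predictions(records, fold_dir / "predictions.csv")
                (fold_dir / "metrics.csv").write_text(
                    "fold,auroc,auprc,ndcg,n_positives_scored,n_candidates\n"
                    f"{fold.fold_index},{report.auroc:.6f},{report.auprc:.6f},"
                    f"{report.ndcg:.6f},{report.n_positives_scored},"
                    f"{report.n_candidates}\n"
                )
                (fold_dir / "metrics.json").write_text(
                    json.dumps(
                        {
                            "auroc": report.auroc,
                            "auprc": report.auprc,
                            "ndcg": report.ndcg,
                            "n_positives_scored": report.n_positives_scored,
                            "n_candidates": report.n_candidates,
                            "coverage": asdict(coverage),
                        },
                        indent=2,
                    )
                )
        except Exception:
            logger.exception("fold %d failed; continuing", fold.fold_index)
    if not reports:
        raise RuntimeError("every cross-validation fold failed")
    summary = summarize(reports)
    if out_dir is not None:
        _write_manifest(out_dir, config, {"summary": summary})
    return reports, summary


def run_discovery(
    network: InteractionNetwork, config: RunConfig
) -> list[PredictionRecord]:
    """Train on a single holdout and rank candidate links of the full
    network that are not yet known edges."""
    master = config.seed
    split = holdout_edge_split(
        network, config.keep_fraction, derive_seed(master, "holdout")
    )
    n90 = split.retained
    specs90 = enumerate_subgraphs(
        n90, replace(config.sampler, seed=derive_seed(master, "sample_train"))
    )
    if not specs90:
        raise RuntimeError("no eligible training subgraphs")
    pairs = build_pairs(n90, network, specs90)
    gen = train(pairs, replace(config.training, seed=derive_seed(master, "train")))
    specs100 = enumerate_subgraphs(
        network, replace(config.sampler, seed=derive_seed(master, "sample_predict"))
    )
    records = _predict_records(gen, network, specs100, config.training.batch_size)
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_predictions(records, out_dir / "predictions.csv")
        _write_manifest(out_dir, config, {"n_records": len(records)})
    return records
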