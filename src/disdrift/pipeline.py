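"""End-to-end orchestration of the three analysis stages.

``run_pipeline`` executes detection -> initial characterization ->
semantic characterization on one cohort; the semantic stage only runs
when detection flagged at least one chunk (or ``force`` is set),
mirroring the gated monitoring loop.  Every stochastic component
receives the run seed, and the emitted JSON summary is byte-stable
under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from disdrift import characterization as ch
from disdrift import detection as det
from disdrift import semantic as sem
from disdrift.data_model import ChunkedDataset, Mode, validation_report

logger = logging.getLogger("disdrift")


@dataclasses.dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    input_path: str
    mode: str = "high_granularity"
    outcome_category: str = "deceased"
    reference_chunk: str | None = None
    steps: tuple[str, ...] = ("detect", "characterize", "semantic")
    metrics: tuple[str, ...] = ("jsd", "centroid", "pca", "classifier")
    k_sd: float = 2.0
    reference_window: int = 3
    n_bins: int = 5
    embedding_dim: int = 64
    embedding_window: int = 10
    embedding_epochs: int = 10
    top_k: int = 10
    seed: int = 0
    force_semantic: bool = False
    output_dir: str = "dis_output"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["steps"] = list(self.steps)
        d["metrics"] = list(self.metrics)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "steps" in raw:
            raw["steps"] = tuple(raw["steps"])
        if "metrics" in raw:
            raw["metrics"] = tuple(raw["metrics"])
        return cls(**raw)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _token_dataset(dataset: ChunkedDataset, config: RunConfig) -> ChunkedDataset:
    """Tokenized view used by JSD and the semantic stage."""
    if dataset.mode is Mode.HIGH:
        return dataset
    return sem.discretize_continuous(dataset, n_bins=config.n_bins)


def run_detection(dataset: ChunkedDataset, config: RunConfig) -> dict:
    token_view = _token_dataset(dataset, config)
    signals = {}
    for metric in config.metrics:
        kwargs: dict = {}
        source = token_view if metric == "jsd" else dataset
        if metric in ("autoencoder", "classifier"):
            kwargs["seed"] = config.seed
        signal = det.compute_signal(source, metric, **kwargs)
        window = min(config.reference_window, len(signal.raw_values) - 1)
        flagged = det.detect_drift(signal, k_sd=config.k_sd, reference_window=window)
        signals[metric] = {
            "chunks": list(signal.chunk_labels),
            "raw": [float(x) for x in signal.raw_values],
            "normalized": [float(x) for x in signal.normalized_values],
            "flagged_chunks": [signal.chunk_labels[i] for i in flagged],
            "threshold_policy": signal.threshold_policy,
        }
        logger.info("metric %s flagged %s", metric, signals[metric]["flagged_chunks"])
    return signals


def run_characterization(dataset: ChunkedDataset, config: RunConfig) -> dict:
    prevalence = ch.outcome_prevalence_over_time(dataset, config.outcome_category)
    corr = ch.correlation_over_time(dataset, outcome_category=config.outcome_category)
    imp = ch.feature_importance_over_time(
        dataset, outcome_category=config.outcome_category, seed=config.seed
    )
    cdrift = ch.class_centroid_drift(dataset)
    k = min(config.top_k, len(corr.entities))

    def _table(t: ch.TrajectoryTable) -> dict:
        return {
            "entities": list(t.entities),
            "chunks": list(t.chunk_labels),
            "values": [[None if np.isnan(v) else float(v) for v in row] for row in t.values],
        }

    return {
        "prevalence": _table(prevalence),
        "correlation": _table(corr),
        "importance": _table(imp),
        "class_centroid_drift": _table(cdrift),
        "top_correlated": ch.top_k_trajectories(corr, k),
        "top_important": ch.top_k_trajectories(imp, k),
    }


def run_semantic(dataset: ChunkedDataset, config: RunConfig) -> dict:
    first, last = dataset.chunks[0], dataset.chunks[-1]
    if dataset.mode is Mode.HIGH:
        corpus = sem.build_sequence_corpus(dataset)
        table = sem.train_sequence_embeddings(
            corpus,
            dimension=config.embedding_dim,
            window=config.embedding_window,
            epochs=config.embedding_epochs,
            seed=config.seed,
        )
    else:
        tokenized = sem.discretize_continuous(dataset, n_bins=config.n_bins)
        graph = sem.build_patient_graph(tokenized)
        table = sem.train_graph_embeddings(
            graph, dimension=config.embedding_dim, seed=config.seed
        )
    deltas = sem.similarity_change(
        table,
        config.outcome_category,
        first,
        last,
        chapter_map=dataset.chapter_map or None,
    )
    out = {
        "first_chunk": first,
        "last_chunk": last,
        "deltas": [
            {
                "token": d.token_id,
                "chapter": d.chapter,
                "sim_first": float(d.sim_first),
                "sim_last": float(d.sim_last),
                "delta": float(d.delta),
                "direction": d.direction,
            }
            for d in deltas
        ],
    }
    if dataset.chapter_map:
        agg = sem.aggregate_by_chapter(deltas)
        out["by_chapter"] = agg.to_dict(orient="records")
    return out, table


def run_pipeline(dataset: ChunkedDataset, config: RunConfig) -> dict:
    """Execute the configured stages in order and return the run report."""
    if config.reference_chunk is not None:
        dataset = dataset.with_reference(config.reference_chunk)
    report: dict = {
        "config": config.to_dict(),
        "dataset": validation_report(dataset),
    }
    any_flag = False
    if "detect" in config.steps:
        signals = run_detection(dataset, config)
        report["detection"] = signals
        any_flag = any(s["flagged_chunks"] for s in signals.values())
    if "characterize" in config.steps:
        report["initial_characterization"] = run_characterization(dataset, config)
    if "semantic" in config.steps:
        if "detect" in config.steps and not any_flag and not config.force_semantic:
            logger.info("no drift flagged; semantic step skipped (use force to override)")
            report["semantic"] = {"skipped": True, "reason": "no drift flagged"}
        else:
            semantic_report, table = run_semantic(dataset, config)
            report["semantic"] = semantic_report
            report["_embeddings"] = table  # stripped before JSON export
    return report


def write_report(report: dict, output_dir) -> Path:
    """Persist the JSON summary (and embeddings, if any) to disk.

    Floats are rounded to 10 digits and keys sorted so identical runs
    produce byte-identical files.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = report.pop("_embeddings", None)
    if table is not None:
        table.save_word2vec(out / "embeddings.w2v.txt")
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(_round_floats(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def render_report(report: dict, output_dir, plots: bool = True) -> Path:
    """Render a human-readable markdown summary plus one line plot of
    normalized signals per metric."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# Temporal drift run report", ""]
    ds = report.get("dataset", {})
    lines += [
        f"- patients: {ds.get('n_patients')}",
        f"- chunks: {', '.join(ds.get('chunks', []))}",
        f"- reference chunk: {ds.get('reference_chunk')}",
        "",
    ]
    detection = report.get("detection", {})
    if detection:
        lines.append("## Detection")
        lines.append("")
        lines.append("| metric | flagged chunks |")
        lines.append("|---|---|")
        for metric, s in detection.items():
            flagged = ", ".join(s["flagged_chunks"]) or "none"
            lines.append(f"| {metric} | {flagged} |")
        lines.append("")
        if plots:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            for metric, s in detection.items():
                fig, ax = plt.subplots(figsize=(5, 3))
                ax.plot(s["chunks"], s["normalized"], marker="o")
                ax.set_title(f"{metric}: normalized drift signal")
                ax.set_xlabel("chunk")
                ax.set_ylabel("normalized signal")
                fig.tight_layout()
                fig.savefig(out / f"signal_{metric}.png", dpi=100)
                plt.close(fig)
    semantic = report.get("semantic", {})
    lines.append("## Semantic characterization")
    lines.append("")
    if semantic.get("skipped"):
        lines.append("_skipped_ (no drift flagged)")
    elif semantic:
        lines.append("| token | delta | direction |")
        lines.append("|---|---|---|")
        for d in semantic.get("deltas", [])[:10]:
            lines.append(f"| {d['token']} | {d['delta']:+.4f} | {d['direction']} |")
    lines.append("")
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
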