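"""Initial characterization: global trajectories of what changed.

Per-chunk views of the outcome distribution P(y), feature-outcome
correlations and tree-ensemble importances (P(y|x)), and cosine drift
of each outcome class's centroid against the reference chunk.
"""

from __future__ import annotations

import enum
import warnings

import numpy as np
import pandas as pd
from dataclasses import dataclass
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from disdrift.data_model import ChunkedDataset, one_hot_matrix
from disdrift.detection import centroid, cosine_distance

OVERALL = "__overall__"


class Statistic(str, enum.Enum):
    PREVALENCE = "prevalence"
    PEARSON = "pearson"
    SPEARMAN = "spearman"
    IMPORTANCE = "importance"
    CENTROID = "centroid_cosine_distance"


@dataclass
class TrajectoryTable:
    """Per-entity series over ordered chunks for one statistic."""

    statistic: Statistic
    entities: tuple[str, ...]
    chunk_labels: tuple[str, ...]
    values: np.ndarray  # (n_entities, n_chunks), NaN = missing
    denominators: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.entities = tuple(self.entities)
        self.chunk_labels = tuple(self.chunk_labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entities), len(self.chunk_labels)):
            raise ValueError("values shape must be (entities, chunks)")

    def row(self, entity: str) -> np.ndarray:
        return self.values[self.entities.index(entity)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.entities), columns=list(self.chunk_labels))
        df.index.name = "entity"
        return df


def _feature_frame(dataset: ChunkedDataset) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Numeric feature matrix + outcome + chunk labels, both modes."""
    mat, cols, records = one_hot_matrix(dataset)
    X = pd.DataFrame(mat, columns=cols)
    y = pd.Series([r.outcome for r in records], name="outcome")
    chunks = pd.Series([r.chunk_label for r in records], name="chunk")
    return X, y, chunks


def outcome_prevalence_over_time(
    dataset: ChunkedDataset, outcome_category: str
) -> TrajectoryTable:
    """Fraction of patients with the outcome category, per chunk."""
    values = np.full((1, len(dataset.chunks)), np.nan)
    denoms = np.zeros((1, len(dataset.chunks)))
    for j, chunk in enumerate(dataset.chunks):
        recs = dataset.records_in(chunk)
        denoms[0, j] = len(recs)
        if recs:
            values[0, j] = sum(r.outcome == outcome_category for r in recs) / len(recs)
    return TrajectoryTable(
        Statistic.PREVALENCE, (outcome_category,), dataset.chunks, values, denoms
    )


def correlation_over_time(
    dataset: ChunkedDataset,
    features: list[str] | None = None,
    outcome_category: str = "deceased",
    method: str = "pearson",
) -> TrajectoryTable:
    """Per-chunk correlation of each feature with the binary outcome
    indicator (category of interest = 1).  A feature constant within a
    chunk yields a missing value, not zero."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    X, y, chunks = _feature_frame(dataset)
    if features is None:
        features = list(X.columns)
    unknown = [f for f in features if f not in X.columns]
    if unknown:
        raise ValueError(f"unknown feature(s): {unknown}")
    yy = (y == outcome_category).astype(float)

    values = np.full((len(features), len(dataset.chunks)), np.nan)
    for j, chunk in enumerate(dataset.chunks):
        mask = (chunks == chunk).to_numpy()
        yc = yy[mask].to_numpy()
        if yc.size < 3 or yc.std() == 0:
            continue
        for i, feat in enumerate(features):
            xc = X.loc[mask, feat].to_numpy()
            if xc.std() == 0:
                continue
            if method == "pearson":
                r = stats.pearsonr(xc, yc).statistic
            else:
                r = stats.spearmanr(xc, yc).statistic
            values[i, j] = r
    stat = Statistic.PEARSON if method == "pearson" else Statistic.SPEARMAN
    return TrajectoryTable(stat, tuple(features), dataset.chunks, values)


def feature_importance_over_time(
    dataset: ChunkedDataset,
    outcome_category: str = "deceased",
    seed: int = 0,
    n_estimators: int = 100,
    max_depth: int | None = None,
    permutation: bool = False,
) -> TrajectoryTable:
    """Per chunk, normalized importances of a seeded random forest fit
    on that chunk's features vs the binary outcome.  Impurity-based by
    default; ``permutation=True`` switches to permutation importance.
    Chunks with a single outcome class are skipped with a warning."""
    X, y, chunks = _feature_frame(dataset)
    features = list(X.columns)
    yy = (y == outcome_category).astype(int)

    values = np.full((len(features), len(dataset.chunks)), np.nan)
    for j, chunk in enumerate(dataset.chunks):
        mask = (chunks == chunk).to_numpy()
        Xc, yc = X[mask].to_numpy(), yy[mask].to_numpy()
        if len(np.unique(yc)) < 2:
            warnings.warn(f"chunk {chunk!r} has a single outcome class; skipped", stacklevel=2)
            continue
        forest = RandomForestClassifier(
            n_estimators=n_estimators, max_depth=max_depth, random_state=seed, n_jobs=1
        ).fit(Xc, yc)
        if permutation:
            from sklearn.inspection import permutation_importance

            imp = permutation_importance(
                forest, Xc, yc, n_repeats=5, random_state=seed, n_jobs=1
            ).importances_mean
            imp = np.clip(imp, 0, None)
        else:
            imp = forest.feature_importances_
        total = imp.sum()
        values[:, j] = imp / total if total > 0 else np.nan
    return TrajectoryTable(Statistic.IMPORTANCE, tuple(features), dataset.chunks, values)


def class_centroid_drift(
    dataset: ChunkedDataset, outcome_category: str | None = None
) -> TrajectoryTable:
    """Cosine drift of each outcome class's centroid (and the overall
    population's) from the same group's reference-chunk centroid, on the
    one-hot bag-of-events representation.  Reference values are 0; a
    group empty in a chunk yields a missing value."""
    mat, cols, records = one_hot_matrix(dataset)
    groups = list(dataset.outcome_categories)
    if outcome_category is not None and outcome_category not in groups:
        raise ValueError(f"unknown outcome category {outcome_category!r}")
    entities = groups + [OVERALL]

    chunk_of = np.array([r.chunk_label for r in records])
    outcome_of = np.array([r.outcome if r.outcome is not None else "" for r in records])

    ref = dataset.reference_chunk
    ref_centroids: dict[str, np.ndarray | None] = {}
    for ent in entities:
        mask = chunk_of == ref
        if ent != OVERALL:
            mask &= outcome_of == ent
        ref_centroids[ent] = centroid(mat[mask]) if mask.any() else None

    values = np.full((len(entities), len(dataset.chunks)), np.nan)
    for j, chunk in enumerate(dataset.chunks):
        for i, ent in enumerate(entities):
            mask = chunk_of == chunk
            if ent != OVERALL:
                mask &= outcome_of == ent
            rc = ref_centroids[ent]
            if rc is None or not mask.any():
                continue
            if chunk == ref:
                values[i, j] = 0.0
            else:
                values[i, j] = cosine_distance(rc, centroid(mat[mask]))
    return TrajectoryTable(Statistic.CENTROID, tuple(entities), dataset.chunks, values)


def top_k_trajectories(
    table: TrajectoryTable, k: int, ranking_chunk: str | None = None
) -> list[str]:
    """Entities ranked by absolute statistic in ``ranking_chunk`` (or by
    the pooled mean of absolute values when None); ties broken
    lexicographically by entity name.  Returns the top ``k``."""
    if k > len(table.entities):
        raise ValueError(f"k={k} exceeds {len(table.entities)} entities")
    if ranking_chunk is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            scores = np.nanmean(np.abs(table.values), axis=1)
    else:
        j = table.chunk_labels.index(ranking_chunk)
        scores = np.abs(table.values[:, j])
    scores = np.where(np.isnan(scores), -np.inf, scores)
    order = sorted(range(len(table.entities)), key=lambda i: (-scores[i], table.entities[i]))
    return [table.entities[i] for i in order[:k]]
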