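"""Core cohort data structures and ingestion.

A cohort is a collection of :class:`PatientRecord` objects partitioned
into ordered temporal chunks.  Two granularity modes are supported:

* ``high_granularity`` — one ordered event-token sequence per patient
  (e.g. diagnosis codes over a hospital stay);
* ``low_granularity`` — one attribute snapshot per patient (mixed
  continuous / categorical features plus an admission date).

The first chunk acts as the reference slice for every downstream drift
comparison unless overridden.
"""

from __future__ import annotations

import datetime as _dt
import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Reserved delimiter joining an outcome category with its chunk label,
#: e.g. ``death@2020``.  Must not appear in plain event tokens.
OUTCOME_DELIMITER = "@"


class Mode(str, enum.Enum):
    """Temporal granularity of a cohort."""

    HIGH = "high_granularity"
    LOW = "low_granularity"


class TokenKind(str, enum.Enum):
    EVENT = "event"
    ATTRIBUTE_BIN = "attribute_bin"
    OUTCOME = "outcome"


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class ValidationError(ValueError):
    """Input rows violate the declared schema contract."""


class DegenerateChunkError(ValueError):
    """A chunk contains no tokens and cannot yield a distribution."""


@dataclass(frozen=True)
class EventToken:
    """A discrete health care event, attribute bin or outcome marker."""

    token_id: str
    kind: TokenKind = TokenKind.EVENT
    chapter: str | None = None

    def __post_init__(self) -> None:
        if not self.token_id:
            raise ValueError("token_id must be nonempty")
        if self.kind is TokenKind.OUTCOME and OUTCOME_DELIMITER not in self.token_id:
            raise ValueError(
                f"outcome token {self.token_id!r} must carry a chunk suffix "
                f"separated by {OUTCOME_DELIMITER!r}"
            )


def outcome_token_id(category: str, chunk_label: str) -> str:
    """Build the chunk-tagged outcome token id, e.g. ``death@2020``."""
    return f"{category}{OUTCOME_DELIMITER}{chunk_label}"


@dataclass
class PatientRecord:
    """One patient: either an ordered event list or an attribute map."""

    patient_id: str
    chunk_label: str
    events: tuple[str, ...] | None = None
    attributes: dict[str, object] | None = None
    outcome: str | None = None
    admission_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if (self.events is None) == (self.attributes is None):
            raise ValueError(
                f"patient {self.patient_id!r}: exactly one of events/attributes "
                "must be populated"
            )
        if self.events is not None:
            self.events = tuple(self.events)


@dataclass
class ChunkedDataset:
    """A cohort partitioned into ordered temporal chunks."""

    mode: Mode
    chunks: tuple[str, ...]
    records: tuple[PatientRecord, ...]
    reference_chunk: str | None = None
    outcome_categories: tuple[str, ...] = ()
    chapter_map: dict[str, str] = field(default_factory=dict)
    rejected_rows: int = 0
    dropped_records: int = 0

    def __post_init__(self) -> None:
        self.chunks = tuple(self.chunks)
        self.records = tuple(self.records)
        if not self.chunks:
            raise ValueError("chunks must be nonempty")
        chunk_set = set(self.chunks)
        for rec in self.records:
            if rec.chunk_label not in chunk_set:
                raise ValueError(
                    f"record {rec.patient_id!r} has unknown chunk {rec.chunk_label!r}"
                )
        if self.reference_chunk is None:
            self.reference_chunk = self.chunks[0]
        elif self.reference_chunk not in chunk_set:
            raise ValueError(f"unknown reference chunk {self.reference_chunk!r}")
        if not self.outcome_categories:
            cats = sorted({r.outcome for r in self.records if r.outcome is not None})
            self.outcome_categories = tuple(cats)

    # -- convenience accessors -------------------------------------------------

    def records_in(self, chunk_label: str) -> list[PatientRecord]:
        return [r for r in self.records if r.chunk_label == chunk_label]

    def non_reference_chunks(self) -> list[str]:
        return [c for c in self.chunks if c != self.reference_chunk]

    @property
    def n_patients(self) -> int:
        return len(self.records)

    def vocabulary(self) -> list[str]:
        """Sorted union of event tokens over the whole cohort."""
        vocab: set[str] = set()
        for rec in self.records:
            if rec.events is not None:
                vocab.update(rec.events)
        return sorted(vocab)

    def with_reference(self, reference_chunk: str) -> "ChunkedDataset":
        return replace(self, reference_chunk=reference_chunk)

    # -- serialization ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular export (inverse of :func:`load_dataset`)."""
        rows = []
        if self.mode is Mode.HIGH:
            for rec in self.records:
                for order, ev in enumerate(rec.events or ()):
                    rows.append(
                        {
                            "patient_id": rec.patient_id,
                            "chunk": rec.chunk_label,
                            "order": order,
                            "event": ev,
                            "outcome": rec.outcome,
                        }
                    )
                if not rec.events:
                    rows.append(
                        {
                            "patient_id": rec.patient_id,
                            "chunk": rec.chunk_label,
                            "order": -1,
                            "event": "",
                            "outcome": rec.outcome,
                        }
                    )
            return pd.DataFrame(
                rows, columns=["patient_id", "chunk", "order", "event", "outcome"]
            )
        for rec in self.records:
            row = {"patient_id": rec.patient_id, "chunk": rec.chunk_label}
            if rec.admission_date is not None:
                row["admission_date"] = rec.admission_date.isoformat()
            row.update(rec.attributes or {})
            row["outcome"] = rec.outcome
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA = {
    "patient_id": "patient_id",
    "chunk": "chunk",
    "order": "order",
    "event": "event",
    "outcome": "outcome",
}


def load_dataset(
    path,
    schema: Mapping[str, str] | None = None,
    mode: Mode | str = Mode.HIGH,
    outcome_categories: Sequence[str] | None = None,
    feature_columns: Sequence[str] | None = None,
    reference_chunk: str | None = None,
) -> ChunkedDataset:
    """Load a delimited cohort file into a validated :class:`ChunkedDataset`.

    ``schema`` maps the roles ``patient_id``, ``chunk``, ``event``,
    ``order``, ``outcome`` (and ``admission_date`` in low-granularity
    mode) to column names.  Rows missing a patient id or chunk label are
    rejected and counted on ``rejected_rows``.  Event order is taken
    from the ordering column, ties broken by file order.
    """
    mode = Mode(mode)
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, dtype={schema["patient_id"]: str, schema["chunk"]: str})
    if df.empty:
        raise ValidationError(f"empty input file: {path}")

    required = [schema["patient_id"], schema["chunk"]]
    if mode is Mode.HIGH:
        required.append(schema["event"])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    pid_col, chunk_col = schema["patient_id"], schema["chunk"]
    bad = df[pid_col].isna() | (df[pid_col].astype(str).str.len() == 0)
    bad |= df[chunk_col].isna() | (df[chunk_col].astype(str).str.len() == 0)
    rejected = int(bad.sum())
    df = df[~bad]
    if df.empty:
        raise ValidationError("no valid rows after rejecting incomplete ones")

    outcome_col = schema.get("outcome")
    has_outcome = outcome_col in df.columns
    if has_outcome and outcome_categories is not None:
        observed = set(df[outcome_col].dropna().astype(str))
        unknown = sorted(observed - set(outcome_categories))
        if unknown:
            raise ValidationError(f"unknown outcome categories: {unknown}")

    records: list[PatientRecord] = []
    if mode is Mode.HIGH:
        order_col = schema.get("order")
        df = df.reset_index().rename(columns={"index": "__file_order__"})
        sort_cols = ["__file_order__"]
        if order_col in df.columns:
            sort_cols = [order_col, "__file_order__"]
        for pid, grp in df.groupby(pid_col, sort=True):
            grp = grp.sort_values(sort_cols, kind="stable")
            events = tuple(str(e) for e in grp[schema["event"]] if str(e) != "")
            chunk = str(grp[chunk_col].iloc[0])
            outcome = (
                str(grp[outcome_col].iloc[0])
                if has_outcome and pd.notna(grp[outcome_col].iloc[0])
                else None
            )
            records.append(
                PatientRecord(
                    patient_id=str(pid), chunk_label=chunk, events=events, outcome=outcome
                )
            )
    else:
        date_col = schema.get("admission_date", "admission_date")
        reserved = {pid_col, chunk_col, outcome_col, date_col}
        feats = (
            list(feature_columns)
            if feature_columns is not None
            else [c for c in df.columns if c not in reserved]
        )
        unknown_feats = [c for c in feats if c not in df.columns]
        if unknown_feats:
            raise SchemaError(f"unknown feature column(s): {unknown_feats}")
        for _, row in df.iterrows():
            date = None
            if date_col in df.columns and pd.notna(row[date_col]):
                date = _dt.date.fromisoformat(str(row[date_col]))
            outcome = (
                str(row[outcome_col])
                if has_outcome and pd.notna(row[outcome_col])
                else None
            )
            records.append(
                PatientRecord(
                    patient_id=str(row[pid_col]),
                    chunk_label=str(row[chunk_col]),
                    attributes={c: row[c] for c in feats},
                    outcome=outcome,
                    admission_date=date,
                )
            )

    chunks = tuple(sorted({r.chunk_label for r in records}))
    return ChunkedDataset(
        mode=mode,
        chunks=chunks,
        records=tuple(records),
        reference_chunk=reference_chunk,
        outcome_categories=tuple(outcome_categories or ()),
        rejected_rows=rejected,
    )


def assign_chunks(
    records: Iterable[PatientRecord],
    boundaries: Sequence[_dt.date],
    labels: Sequence[str] | None = None,
    mode: Mode | str = Mode.LOW,
) -> ChunkedDataset:
    """Bin records into chunks by admission date.

    ``boundaries`` are strictly increasing cutpoints; record with date
    ``d`` goes to chunk ``i`` where ``boundaries[i] <= d < boundaries[i+1]``
    (left-closed, right-open — a date exactly on a boundary belongs to
    the later chunk).  Records outside every interval are dropped and
    counted on ``dropped_records``.
    """
    boundaries = list(boundaries)
    if len(boundaries) < 2:
        raise ValueError("need at least two boundaries")
    if any(later <= earlier for earlier, later in zip(boundaries, boundaries[1:])):
        raise ValueError("boundaries must be strictly increasing")
    n_intervals = len(boundaries) - 1
    if labels is None:
        labels = [f"chunk{i}" for i in range(n_intervals)]
    if len(labels) != n_intervals:
        raise ValueError("need one label per interval")

    kept: list[PatientRecord] = []
    dropped = 0
    for rec in records:
        if rec.admission_date is None:
            raise ValueError(f"record {rec.patient_id!r} has no admission date")
        d = rec.admission_date
        idx = None
        for i in range(n_intervals):
            if boundaries[i] <= d < boundaries[i + 1]:
                idx = i
                break
        if idx is None:
            dropped += 1
            continue
        kept.append(replace(rec, chunk_label=labels[idx]))

    if not kept:
        raise ValidationError("no records fall inside the chunk boundaries")
    present = [lab for lab in labels if any(r.chunk_label == lab for r in kept)]
    return ChunkedDataset(
        mode=Mode(mode),
        chunks=tuple(present),
        records=tuple(kept),
        dropped_records=dropped,
    )


# ---------------------------------------------------------------------------
# frequency distributions
# ---------------------------------------------------------------------------


@dataclass
class FrequencyDistribution:
    """Smoothed probability vector over a fixed ordered vocabulary."""

    vocabulary: tuple[str, ...]
    probabilities: np.ndarray
    smoothing_epsilon: float = 0.0

    def __post_init__(self) -> None:
        self.vocabulary = tuple(self.vocabulary)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.vocabulary) != self.probabilities.shape[0]:
            raise ValueError("vocabulary and probabilities length mismatch")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be nonnegative")
        total = float(self.probabilities.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")

    @classmethod
    def from_counts(
        cls,
        vocabulary: Sequence[str],
        counts: Mapping[str, float] | np.ndarray,
        smoothing_epsilon: float = 0.0,
    ) -> "FrequencyDistribution":
        vocabulary = tuple(vocabulary)
        if isinstance(counts, Mapping):
            vec = np.array([float(counts.get(t, 0.0)) for t in vocabulary])
        else:
            vec = np.asarray(counts, dtype=float)
        vec = vec + smoothing_epsilon
        total = vec.sum()
        if total <= 0:
            raise DegenerateChunkError("no counts and no smoothing: empty distribution")
        return cls(vocabulary, vec / total, smoothing_epsilon)


def chunk_frequencies(
    dataset: ChunkedDataset,
    vocabulary_policy: str = "union",
    smoothing_epsilon: float = 0.5,
    per_patient: bool = False,
) -> dict[str, FrequencyDistribution]:
    """Per-chunk token frequency distributions over a common vocabulary.

    ``vocabulary_policy`` is ``"union"`` (all chunks) or
    ``"reference-only"``.  Counts are token occurrences unless
    ``per_patient`` is set, in which case each patient contributes at
    most one count per token.  Additive smoothing ``smoothing_epsilon``
    is applied per vocabulary cell before normalization so that
    divergences stay finite on disjoint supports.
    """
    if dataset.mode is not Mode.HIGH:
        raise ValueError(
            "chunk_frequencies requires event tokens; discretize low-granularity "
            "data first (semantic.discretize_continuous)"
        )
    if vocabulary_policy not in {"union", "reference-only"}:
        raise ValueError(f"unknown vocabulary policy {vocabulary_policy!r}")

    if vocabulary_policy == "union":
        vocab = dataset.vocabulary()
    else:
        vocab = sorted(
            {e for r in dataset.records_in(dataset.reference_chunk) for e in r.events}
        )
    if not vocab:
        raise DegenerateChunkError("empty vocabulary")
    index = {t: i for i, t in enumerate(vocab)}

    out: dict[str, FrequencyDistribution] = {}
    for chunk in dataset.chunks:
        counts = np.zeros(len(vocab))
        n_tokens = 0
        for rec in dataset.records_in(chunk):
            events = set(rec.events) if per_patient else rec.events
            for ev in events:
                n_tokens += 1
                i = index.get(ev)
                if i is not None:
                    counts[i] += 1
        if n_tokens == 0:
            raise DegenerateChunkError(f"chunk {chunk!r} contains zero tokens")
        if counts.sum() == 0 and smoothing_epsilon == 0:
            raise DegenerateChunkError(
                f"chunk {chunk!r} has no in-vocabulary tokens and no smoothing"
            )
        out[chunk] = FrequencyDistribution.from_counts(vocab, counts, smoothing_epsilon)
    return out


def one_hot_matrix(
    dataset: ChunkedDataset,
    chunk_label: str | None = None,
    vocabulary: Sequence[str] | None = None,
    binary: bool = True,
) -> tuple[np.ndarray, list[str], list[PatientRecord]]:
    """One-hot bag-of-events matrix (patients x vocabulary).

    For low-granularity cohorts, numeric attributes pass through as-is
    and categorical attributes are one-hot encoded; the "vocabulary"
    then lists the resulting column names.
    """
    records = (
        list(dataset.records) if chunk_label is None else dataset.records_in(chunk_label)
    )
    if dataset.mode is Mode.HIGH:
        vocab = list(vocabulary) if vocabulary is not None else dataset.vocabulary()
        index = {t: i for i, t in enumerate(vocab)}
        mat = np.zeros((len(records), len(vocab)))
        for row, rec in enumerate(records):
            for ev in rec.events or ():
                i = index.get(ev)
                if i is None:
                    continue
                if binary:
                    mat[row, i] = 1.0
                else:
                    mat[row, i] += 1.0
        return mat, vocab, records

    # low granularity: numeric passthrough + categorical one-hot
    frame = pd.DataFrame([r.attributes for r in records])
    numeric = frame.select_dtypes(include=[np.number])
    categorical = frame.drop(columns=numeric.columns)
    pieces = [numeric]
    if not categorical.empty:
        pieces.append(pd.get_dummies(categorical.astype(str), dtype=float))
    wide = pd.concat(pieces, axis=1)
    if vocabulary is not None:
        wide = wide.reindex(columns=list(vocabulary), fill_value=0.0)
    cols = list(wide.columns)
    return wide.to_numpy(dtype=float), cols, records


def validation_report(dataset: ChunkedDataset) -> dict:
    """JSON-serializable summary of an ingested cohort."""
    per_chunk = {c: len(dataset.records_in(c)) for c in dataset.chunks}
    return {
        "mode": dataset.mode.value,
        "n_patients": dataset.n_patients,
        "chunks": list(dataset.chunks),
        "reference_chunk": dataset.reference_chunk,
        "patients_per_chunk": per_chunk,
        "outcome_categories": list(dataset.outcome_categories),
        "rejected_rows": dataset.rejected_rows,
        "dropped_records": dataset.dropped_records,
    }
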