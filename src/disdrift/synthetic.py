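"""Seeded synthetic cohort generator with injectable temporal drifts.

Generates high-granularity (per-patient event sequences) and
low-granularity (per-patient attribute snapshot) cohorts whose chunk
schedules can be perturbed by four drift shapes — sudden, incremental,
gradual, reoccurring — acting on token frequencies, outcome prevalence,
token/feature-outcome associations or numeric outliers.

The generator is the ground-truth oracle for every recovery test in the
package: the injected schedule is known exactly, so detection and
characterization outputs can be checked against it.
"""

from __future__ import annotations

import datetime as _dt
import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from disdrift.data_model import ChunkedDataset, Mode, PatientRecord


class DriftType(str, enum.Enum):
    SUDDEN = "sudden"
    INCREMENTAL = "incremental"
    GRADUAL = "gradual"
    REOCCURRING = "reoccurring"


class DriftTarget(str, enum.Enum):
    TOKEN_FREQUENCY = "token_frequency"
    OUTCOME_PREVALENCE = "outcome_prevalence"
    TOKEN_OUTCOME_ASSOCIATION = "token_outcome_association"
    NUMERIC_OUTLIER = "numeric_outlier"


class ConfigError(ValueError):
    """The scenario/cohort configuration is internally inconsistent."""


@dataclass(frozen=True)
class DriftScenario:
    """One injectable drift.

    ``magnitude`` is the absolute effect size on the target's natural
    scale (frequency multiplier minus one, prevalence shift, log-odds
    shift, or outlier distance in feature SDs); ``direction`` signs it.
    ``targets`` names the affected token ids or feature names where that
    matters.  ``fraction`` is the share of rows receiving injected
    outliers (numeric_outlier only).
    """

    drift_type: DriftType
    target: DriftTarget
    onset_chunk: int
    magnitude: float
    targets: tuple[str, ...] = ()
    direction: int = 1
    period: int | None = None
    fraction: float = 0.01

    def __post_init__(self) -> None:
        object.__setattr__(self, "drift_type", DriftType(self.drift_type))
        object.__setattr__(self, "target", DriftTarget(self.target))
        object.__setattr__(self, "targets", tuple(self.targets))
        if self.magnitude < 0:
            raise ConfigError("magnitude must be >= 0")
        if self.direction not in (1, -1):
            raise ConfigError("direction must be +1 or -1")
        if self.drift_type is DriftType.REOCCURRING:
            if self.period is None or self.period < 2:
                raise ConfigError("reoccurring drift needs period >= 2")

    def schedule(self, chunk_index: int, n_chunks: int) -> float:
        """Activation weight in [0, 1] for the given chunk."""
        if self.onset_chunk >= n_chunks:
            raise ConfigError(
                f"onset_chunk {self.onset_chunk} beyond n_chunks {n_chunks}"
            )
        c, onset = chunk_index, self.onset_chunk
        if c < onset:
            return 0.0
        if self.drift_type is DriftType.SUDDEN:
            return 1.0
        if self.drift_type in (DriftType.INCREMENTAL, DriftType.GRADUAL):
            span = max(n_chunks - 1 - onset, 1)
            return min((c - onset + 1) / (span + 1), 1.0) if n_chunks - 1 > onset else 1.0
        # reoccurring: active during the first half of each period
        assert self.period is not None
        return 1.0 if (c - onset) % self.period < math.ceil(self.period / 2) else 0.0


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort."""

    n_patients_per_chunk: int = 200
    n_chunks: int = 4
    vocabulary_size: int = 50
    n_chapters: int = 5
    zipf_exponent: float = 1.1
    baseline_outcome_prevalence: float = 0.2
    events_per_patient_mean: float = 8.0
    scenarios: tuple[DriftScenario, ...] = ()
    seed: int = 0
    n_risk_tokens: int = 3
    risk_coefficient: float = 1.0
    outcome_categories: tuple[str, str] = ("deceased", "not_deceased")

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "scenarios",
            tuple(
                s if isinstance(s, DriftScenario) else DriftScenario(**s)
                for s in self.scenarios
            ),
        )
        if self.n_patients_per_chunk < 1 or self.n_chunks < 1:
            raise ConfigError("cohort dimensions must be positive")
        if not 0.0 <= self.baseline_outcome_prevalence <= 1.0:
            raise ConfigError("baseline_outcome_prevalence must be in [0, 1]")
        if self.vocabulary_size < self.n_chapters:
            raise ConfigError("vocabulary_size must be >= n_chapters")
        for s in self.scenarios:
            s.schedule(0, self.n_chunks)  # validates onset range

    @property
    def event_of_interest(self) -> str:
        return self.outcome_categories[0]

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["scenarios"] = tuple(
            DriftScenario(**s) for s in raw.get("scenarios", ())
        )
        if "outcome_categories" in raw:
            raw["outcome_categories"] = tuple(raw["outcome_categories"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {
            "n_patients_per_chunk": self.n_patients_per_chunk,
            "n_chunks": self.n_chunks,
            "vocabulary_size": self.vocabulary_size,
            "n_chapters": self.n_chapters,
            "zipf_exponent": self.zipf_exponent,
            "baseline_outcome_prevalence": self.baseline_outcome_prevalence,
            "events_per_patient_mean": self.events_per_patient_mean,
            "seed": self.seed,
            "n_risk_tokens": self.n_risk_tokens,
            "risk_coefficient": self.risk_coefficient,
            "outcome_categories": list(self.outcome_categories),
            "scenarios": [
                {
                    "drift_type": s.drift_type.value,
                    "target": s.target.value,
                    "onset_chunk": s.onset_chunk,
                    "magnitude": s.magnitude,
                    "targets": list(s.targets),
                    "direction": s.direction,
                    "period": s.period,
                    "fraction": s.fraction,
                }
                for s in self.scenarios
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def chunk_labels(config: CohortConfig) -> list[str]:
    return [f"C{i}" for i in range(config.n_chunks)]


def token_id(i: int) -> str:
    return f"t{i:03d}"


def chapter_map(config: CohortConfig) -> dict[str, str]:
    """Token -> chapter assignment in contiguous blocks."""
    return {
        token_id(i): f"ch{i * config.n_chapters // config.vocabulary_size:02d}"
        for i in range(config.vocabulary_size)
    }


def _zipf_probs(config: CohortConfig) -> np.ndarray:
    ranks = np.arange(1, config.vocabulary_size + 1, dtype=float)
    w = ranks ** (-config.zipf_exponent)
    return w / w.sum()


def _scenarios_for(config: CohortConfig, target: DriftTarget) -> list[DriftScenario]:
    return [s for s in config.scenarios if s.target is target]


def _token_distribution(
    config: CohortConfig, chunk_index: int, gradual_regime: bool | None = None
) -> np.ndarray:
    """Chunk-specific token distribution after frequency scenarios.

    ``gradual_regime`` selects the new/old regime for gradual drifts
    (None means 'apply deterministically with the schedule weight',
    used for expectation-level checks).
    """
    probs = _zipf_probs(config).copy()
    vocab = [token_id(i) for i in range(config.vocabulary_size)]
    index = {t: i for i, t in enumerate(vocab)}
    for scen in _scenarios_for(config, DriftTarget.TOKEN_FREQUENCY):
        s = scen.schedule(chunk_index, config.n_chunks)
        if scen.drift_type is DriftType.GRADUAL and gradual_regime is not None:
            s = 1.0 if gradual_regime else 0.0
        if s == 0.0:
            continue
        mult = (1.0 + scen.magnitude * s) ** scen.direction
        idx = [index[t] for t in scen.targets if t in index]
        if not idx:
            raise ConfigError(f"token_frequency scenario targets unknown tokens: {scen.targets}")
        probs[idx] *= mult
        probs = probs / probs.sum()
    return probs


def _target_prevalence(config: CohortConfig, chunk_index: int) -> float:
    p = config.baseline_outcome_prevalence
    for scen in _scenarios_for(config, DriftTarget.OUTCOME_PREVALENCE):
        p += scen.direction * scen.magnitude * scen.schedule(chunk_index, config.n_chunks)
    return float(np.clip(p, 0.01, 0.99))


def _calibrate_intercept(logits: np.ndarray, target: float) -> float:
    """Solve mean(sigmoid(logits + a)) == target by bisection."""
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if float(np.mean(1.0 / (1.0 + np.exp(-(logits + mid))))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _chunk_dates(chunk_index: int) -> tuple[_dt.date, _dt.date]:
    """Quarterly chunk intervals starting 2020-01-01."""
    start = _dt.date(2020 + chunk_index // 4, 1 + 3 * (chunk_index % 4), 1)
    nxt = chunk_index + 1
    end = _dt.date(2020 + nxt // 4, 1 + 3 * (nxt % 4), 1)
    return start, end


# ---------------------------------------------------------------------------
# high granularity
# ---------------------------------------------------------------------------


def generate_high_granularity(config: CohortConfig) -> ChunkedDataset:
    """Event-sequence cohort: per chunk, patients draw ordered tokens
    from the chunk's (possibly drifted) distribution and a logistic
    outcome on risk-token indicators; the intercept is calibrated per
    chunk so the expected prevalence follows the prevalence schedule.
    """
    rng = np.random.default_rng(config.seed)
    vocab = [token_id(i) for i in range(config.vocabulary_size)]
    index = {t: i for i, t in enumerate(vocab)}
    labels = chunk_labels(config)
    records: list[PatientRecord] = []

    # per-token outcome coefficients, per chunk
    assoc = _scenarios_for(config, DriftTarget.TOKEN_OUTCOME_ASSOCIATION)
    base_beta = np.zeros(config.vocabulary_size)
    base_beta[: config.n_risk_tokens] = config.risk_coefficient

    gradual_freq = [
        s
        for s in _scenarios_for(config, DriftTarget.TOKEN_FREQUENCY)
        if s.drift_type is DriftType.GRADUAL
    ]

    for ci, label in enumerate(labels):
        n = config.n_patients_per_chunk
        lengths = np.maximum(rng.poisson(config.events_per_patient_mean, size=n), 1)

        if gradual_freq:
            # regime-mixing: each patient samples wholly from old or new regime
            weight = max(s.schedule(ci, config.n_chunks) for s in gradual_freq)
            new_regime = rng.random(n) < weight
            p_old = _token_distribution(config, ci, gradual_regime=False)
            p_new = _token_distribution(config, ci, gradual_regime=True)
        else:
            new_regime = np.zeros(n, dtype=bool)
            p_old = p_new = _token_distribution(config, ci)

        beta = base_beta.copy()
        for scen in assoc:
            s = scen.schedule(ci, config.n_chunks)
            if s == 0.0:
                continue
            idx = [index[t] for t in scen.targets if t in index]
            if not idx:
                raise ConfigError(
                    f"association scenario targets unknown tokens: {scen.targets}"
                )
            beta[idx] += scen.direction * scen.magnitude * s

        event_lists = []
        logits = np.empty(n)
        for i in range(n):
            p = p_new if new_regime[i] else p_old
            ev_idx = rng.choice(config.vocabulary_size, size=lengths[i], p=p)
            event_lists.append([vocab[j] for j in ev_idx])
            present = np.zeros(config.vocabulary_size)
            present[np.unique(ev_idx)] = 1.0
            logits[i] = float(beta @ present)

        alpha = _calibrate_intercept(logits, _target_prevalence(config, ci))
        death = rng.random(n) < 1.0 / (1.0 + np.exp(-(logits + alpha)))
        dead_cat, alive_cat = config.outcome_categories

        for i in range(n):
            records.append(
                PatientRecord(
                    patient_id=f"{label}-p{i:05d}",
                    chunk_label=label,
                    events=tuple(event_lists[i]),
                    outcome=dead_cat if death[i] else alive_cat,
                )
            )

    return ChunkedDataset(
        mode=Mode.HIGH,
        chunks=tuple(labels),
        records=tuple(records),
        outcome_categories=config.outcome_categories,
        chapter_map=chapter_map(config),
    )


# ---------------------------------------------------------------------------
# low granularity
# ---------------------------------------------------------------------------

#: (mean, sd, family) per continuous feature; lognormal params on log scale.
CONTINUOUS_FEATURES: dict[str, tuple[float, float, str]] = {
    "age": (60.0, 15.0, "normal"),
    "heart_rate": (85.0, 12.0, "normal"),
    "respiratory_rate": (20.0, 4.0, "normal"),
    "sodium": (138.0, 4.0, "normal"),
    "fio2": (0.40, 0.12, "normal"),
    "crp": (3.0, 0.6, "lognormal"),
}

CATEGORICAL_FEATURES: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "sex": (("female", "male"), (0.5, 0.5)),
    "hypertension": (("no", "yes"), (0.7, 0.3)),
    "diabetes": (("no", "yes"), (0.8, 0.2)),
}

#: baseline log-odds coefficients on standardized continuous features
RISK_FEATURES: dict[str, float] = {"age": 1.0, "fio2": 0.6}


def feature_scale(name: str) -> float:
    mean, sd, family = CONTINUOUS_FEATURES[name]
    if family == "lognormal":
        return float(np.sqrt((np.exp(sd**2) - 1) * np.exp(2 * mean + sd**2)))
    return sd


def generate_low_granularity(config: CohortConfig) -> ChunkedDataset:
    """Snapshot cohort: one row per patient with continuous vitals,
    categorical comorbidities, a within-chunk admission date and a
    logistic binary outcome.  Association scenarios rescale feature
    coefficients (e.g. age–outcome decoupling); numeric_outlier
    scenarios overwrite a row fraction with values ``magnitude`` feature
    SDs above the mean.
    """
    rng = np.random.default_rng(config.seed)
    labels = chunk_labels(config)
    records: list[PatientRecord] = []
    assoc = _scenarios_for(config, DriftTarget.TOKEN_OUTCOME_ASSOCIATION)
    outliers = _scenarios_for(config, DriftTarget.NUMERIC_OUTLIER)

    for ci, label in enumerate(labels):
        n = config.n_patients_per_chunk
        cont: dict[str, np.ndarray] = {}
        for name, (mean, sd, family) in CONTINUOUS_FEATURES.items():
            if family == "lognormal":
                cont[name] = rng.lognormal(mean, sd, size=n)
            else:
                cont[name] = rng.normal(mean, sd, size=n)

        cat: dict[str, np.ndarray] = {}
        for name, (values, probs) in CATEGORICAL_FEATURES.items():
            cat[name] = rng.choice(values, size=n, p=probs)

        # outlier injection before outcome so reconstruction metrics see it
        for scen in outliers:
            s = scen.schedule(ci, config.n_chunks)
            if s == 0.0 or scen.magnitude == 0.0:
                continue
            targets = scen.targets or tuple(
                k for k, (_, _, fam) in CONTINUOUS_FEATURES.items() if fam == "normal"
            )
            n_out = int(round(scen.fraction * n))
            if n_out == 0:
                continue
            rows = rng.choice(n, size=n_out, replace=False)
            for name in targets:
                mean, sd, _ = CONTINUOUS_FEATURES[name]
                cont[name][rows] = mean + scen.direction * scen.magnitude * sd

        beta = dict(RISK_FEATURES)
        for scen in assoc:
            s = scen.schedule(ci, config.n_chunks)
            if s == 0.0:
                continue
            for name in scen.targets:
                if name not in CONTINUOUS_FEATURES:
                    raise ConfigError(f"association scenario targets unknown feature {name!r}")
                beta[name] = beta.get(name, 0.0) + scen.direction * scen.magnitude * s

        logits = np.zeros(n)
        for name, b in beta.items():
            mean, sd, family = CONTINUOUS_FEATURES[name]
            if family == "lognormal":
                z = (np.log(cont[name]) - mean) / sd
            else:
                z = (cont[name] - mean) / sd
            logits += b * z
        alpha = _calibrate_intercept(logits, _target_prevalence(config, ci))
        death = rng.random(n) < 1.0 / (1.0 + np.exp(-(logits + alpha)))
        dead_cat, alive_cat = config.outcome_categories

        start, end = _chunk_dates(ci)
        span = (end - start).days
        offsets = rng.integers(0, span, size=n)

        for i in range(n):
            attrs: dict[str, object] = {k: float(v[i]) for k, v in cont.items()}
            attrs.update({k: str(v[i]) for k, v in cat.items()})
            records.append(
                PatientRecord(
                    patient_id=f"{label}-p{i:05d}",
                    chunk_label=label,
                    attributes=attrs,
                    outcome=dead_cat if death[i] else alive_cat,
                    admission_date=start + _dt.timedelta(days=int(offsets[i])),
                )
            )

    return ChunkedDataset(
        mode=Mode.LOW,
        chunks=tuple(labels),
        records=tuple(records),
        outcome_categories=config.outcome_categories,
    )


def ground_truth(config: CohortConfig) -> dict:
    """JSON-serializable record of the injected drift schedule, for
    recovery tests and the run-report sidecar."""
    labels = chunk_labels(config)
    return {
        "chunks": labels,
        "seed": config.seed,
        "target_prevalence": [
            _target_prevalence(config, ci) for ci in range(config.n_chunks)
        ],
        "scenarios": [
            {
                "drift_type": s.drift_type.value,
                "target": s.target.value,
                "onset_chunk": s.onset_chunk,
                "magnitude": s.magnitude,
                "direction": s.direction,
                "targets": list(s.targets),
                "period": s.period,
                "fraction": s.fraction,
                "schedule": [s.schedule(ci, config.n_chunks) for ci in range(config.n_chunks)],
            }
            for s in config.scenarios
        ],
    }
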