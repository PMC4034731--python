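"""Genetic Function Approximation: descriptor-subset selection by a
genetic algorithm over least-squares linear models.

Each individual is a fixed-size descriptor subset; its linear model is fit
by ordinary least squares on the training split and scored by the Friedman
lack-of-fit statistic

    LOF = SSE / (n * (1 - (c + d*p) / n)**2)

with ``c = terms + 1`` (coefficients incl. intercept), smoothing ``d`` and
``p = terms``.  Fitness is ``-LOF`` (lower LOF is better); subsets whose
design matrix is rank-deficient receive fitness ``-inf``.  Evolution uses
tournament selection (k=2), one-point subset crossover with duplicate
repair, single-descriptor swap mutation, and elitism of one, and is
deterministic given the seed.

The module also ships a bundled linear scoring equation for FKBP52 pIC50
(intercept 14.911 over the ten canonical descriptors), loadable with
:func:`bundled_model` and usable without any training data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class UndefinedMetricError(ValueError):
    """Correlation is undefined (zero variance in the observations)."""


class MissingDescriptorError(KeyError):
    """A model term has no value in the supplied descriptor vector."""


@dataclass
class LinearModel:
    """Intercept plus named coefficients, in pIC50 units."""

    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)
    r_squared: Optional[float] = None

    @property
    def term_count(self) -> int:
        return len(self.coefficients)

    def to_json(self, path, metadata: Optional[dict] = None) -> None:
        payload = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "r_squared": self.r_squared,
        }
        if metadata:
            payload["metadata"] = metadata
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "LinearModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            intercept=payload["intercept"],
            coefficients=dict(payload["coefficients"]),
            r_squared=payload.get("r_squared"),
        )


@dataclass
class TrainingTable:
    """Descriptor/activity table with a train|test split label per row.

    ``data`` holds one row per molecule (unique id index), the descriptor
    columns, an observed-activity column and a split column.
    """

    data: pd.DataFrame
    descriptor_names: list[str]
    activity_col: str = "pIC50"
    split_col: str = "split"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate molecule ids in training table")
        if not np.isfinite(self.data[self.activity_col]).all():
            raise ValueError("non-finite activity values")
        bad = set(self.data[self.split_col]) - {"train", "test"}
        if bad:
            raise ValueError(f"unknown split labels: {sorted(bad)}")

    def split(self, which: str) -> pd.DataFrame:
        return self.data[self.data[self.split_col] == which]

    @classmethod
    def from_csv(cls, path, descriptor_names: Sequence[str],
                 activity_col: str = "pIC50", split_col: str = "split",
                 id_col: str = "name") -> "TrainingTable":
        df = pd.read_csv(path).set_index(id_col)
        return cls(df, list(descriptor_names), activity_col, split_col)


def bundled_model() -> LinearModel:
    """The packaged GFA linear scoring equation (no retraining needed)."""
    text = resources.files("fkbpscreen.data").joinpath("gfa_model.json").read_text()
    payload = json.loads(text)
    return LinearModel(
        intercept=payload["intercept"],
        coefficients=dict(payload["coefficients"]),
        r_squared=payload.get("r_squared"),
    )


def evaluate_linear(model: LinearModel, descriptors: dict) -> float:
    """``intercept + sum(coef * value)`` over the model's named terms."""
    total = model.intercept
    for name, coef in model.coefficients.items():
        if name not in descriptors or descriptors[name] is None:
            raise MissingDescriptorError(name)
        total += coef * descriptors[name]
    return float(total)


def r2(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Squared Pearson correlation between observation and prediction."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need two equal-length series of length >= 2")
    if np.ptp(obs) == 0:
        raise UndefinedMetricError("observed values have zero variance")
    if np.ptp(pred) == 0:
        raise UndefinedMetricError("predicted values have zero variance")
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r * r)


def _fit_subset(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """OLS fit; returns (coefs incl. intercept, SSE, R²). Raises
    LinAlgError-like ValueError on rank deficiency."""
    design = np.column_stack([np.ones(len(y)), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r_sq = 1.0 - sse / sst if sst > 0 else 0.0
    return beta, sse, r_sq


def friedman_lof(sse: float, n: int, terms: int, smoothing: float = 1.0) -> float:
    """Friedman lack-of-fit penalty; smaller is better."""
    c = terms + 1
    denom = 1.0 - (c + smoothing * terms) / n
    if denom <= 0:
        return np.inf
    return sse / (n * denom * denom)


def _model_from_subset(subset, names, beta, r_sq) -> LinearModel:
    coefs = {names[j]: float(beta[k + 1]) for k, j in enumerate(subset)}
    return LinearModel(intercept=float(beta[0]), coefficients=coefs, r_squared=r_sq)


def gfa_evolve(
    table: TrainingTable,
    n_terms: int,
    population: int = 100,
    generations: int = 50,
    seed: int = 0,
    mutation_rate: float = 0.1,
    lof_smoothing: float = 1.0,
) -> list[LinearModel]:
    """Evolve descriptor subsets of size ``n_terms``; returns all final
    individuals' models ranked by descending fitness (best first)."""
    if population < 2:
        raise ValueError("population must be >= 2")
    names = table.descriptor_names
    if n_terms > len(names):
        raise ValueError("n_terms exceeds available descriptors")
    train = table.split("train")
    x_full = train[names].to_numpy(dtype=float)
    y = train[table.activity_col].to_numpy(dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)

    cache: dict[tuple, tuple[float, LinearModel]] = {}

    def score(subset: tuple) -> tuple[float, LinearModel]:
        if subset not in cache:
            try:
                beta, sse, r_sq = _fit_subset(x_full[:, list(subset)], y)
                fitness = -friedman_lof(sse, n, len(subset), lof_smoothing)
                model = _model_from_subset(subset, names, beta, r_sq)
            except np.linalg.LinAlgError:
                fitness, model = -np.inf, LinearModel(0.0, {names[j]: 0.0 for j in subset})
            cache[subset] = (fitness, model)
        return cache[subset]

    def random_subset() -> tuple:
        return tuple(sorted(rng.choice(len(names), size=n_terms, replace=False)))

    pop = [random_subset() for _ in range(population)]

    def tournament() -> tuple:
        a, b = rng.integers(0, population, size=2)
        return pop[a] if score(pop[a])[0] >= score(pop[b])[0] else pop[b]

    def crossover(p1: tuple, p2: tuple) -> tuple:
        if n_terms == 1:
            child = list(p1)
        else:
            cut = int(rng.integers(1, n_terms))
            child = list(dict.fromkeys(p1[:cut] + p2[cut:]))
        pool = [j for j in range(len(names)) if j not in child]
        while len(child) < n_terms:
            pick = pool.pop(int(rng.integers(0, len(pool))))
            child.append(pick)
        return tuple(sorted(child))

    def mutate(subset: tuple) -> tuple:
        if rng.random() >= mutation_rate:
            return subset
        out = list(subset)
        pos = int(rng.integers(0, n_terms))
        pool = [j for j in range(len(names)) if j not in out]
        if pool:
            out[pos] = pool[int(rng.integers(0, len(pool)))]
        return tuple(sorted(out))

    for _ in range(generations):
        best = max(pop, key=lambda s: score(s)[0])
        nxt = [best]  # elitism of one
        while len(nxt) < population:
            nxt.append(mutate(crossover(tournament(), tournament())))
        pop = nxt

    ranked = sorted(pop, key=lambda s: score(s)[0], reverse=True)
    return [score(s)[1] for s in ranked]
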