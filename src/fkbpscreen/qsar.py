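"""The three pIC50 predictors: multiple linear regression, RBF support
vector regression, and a discretized Bayesian-network predictor.

The Bayesian-network route discretizes descriptors and pIC50 into at most
five equal-frequency categories, learns a DAG over the variables by BDeu
hill climbing with random restarts, fits one linear regression per pIC50
category, and predicts by (a) computing the exact posterior over pIC50
categories given the query's descriptor bins, (b) selecting the MAP
category (tie broken toward the lower category, or optionally a
posterior-weighted mean of the category regressions), and (c) returning
that category's regression evaluated at the query.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .gfa import LinearModel, TrainingTable, evaluate_linear

log = logging.getLogger(__name__)


class RankDeficiencyError(ValueError):
    """Design matrix is singular; names the offending columns."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"collinear design columns: {columns}")


class NotFittedError(RuntimeError):
    pass


# ---------------------------------------------------------------- MLR


def fit_mlr(table: TrainingTable,
            descriptor_names: Optional[Sequence[str]] = None) -> LinearModel:
    """Ordinary least squares on the training split; stores training R²."""
    names = list(table.descriptor_names if descriptor_names is None
                 else descriptor_names)
    train = table.split("train")
    if len(train) <= len(names) + 1:
        raise ValueError("need n_train > number of descriptors + 1")
    x = train[names].to_numpy(dtype=float)
    y = train[table.activity_col].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(y)), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # greedily identify which columns break independence
        kept = [0]
        bad = []
        for j in range(1, design.shape[1]):
            trial = design[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j - 1])
        raise RankDeficiencyError(bad)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    r_sq = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
    return LinearModel(
        intercept=float(beta[0]),
        coefficients={n: float(b) for n, b in zip(names, beta[1:])},
        r_squared=r_sq,
    )


# ---------------------------------------------------------------- SVR


@dataclass
class SvrSpec:
    """RBF ε-SVR hyperparameters plus (after fitting) the opaque state."""

    C: float = 10.0
    epsilon: float = 0.1
    gamma: Optional[float] = None  # default 1 / n_descriptors
    descriptor_names: list[str] = field(default_factory=list)
    _pipeline: Optional[Pipeline] = None
    _constant: Optional[float] = None

    def __post_init__(self) -> None:
        if self.C <= 0 or self.epsilon < 0:
            raise ValueError("require C > 0 and epsilon >= 0")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def fitted(self) -> bool:
        return self._pipeline is not None or self._constant is not None


def fit_svr(table: TrainingTable, spec: Optional[SvrSpec] = None) -> SvrSpec:
    """ε-insensitive RBF support-vector regression on z-scored descriptors.

    Constant descriptor columns are dropped with a warning; a single-row
    table degenerates to a constant predictor.
    """
    spec = spec or SvrSpec()
    names = list(table.descriptor_names)
    train = table.split("train")
    y = train[table.activity_col].to_numpy(dtype=float)
    if len(train) == 1:
        spec._constant = float(y[0])
        spec.descriptor_names = names
        return spec
    x = train[names].to_numpy(dtype=float)
    keep = [j for j in range(x.shape[1]) if np.ptp(x[:, j]) > 0]
    dropped = [names[j] for j in range(x.shape[1]) if j not in keep]
    if dropped:
        log.warning("dropping constant descriptor column(s): %s", dropped)
    names = [names[j] for j in keep]
    gamma = spec.gamma if spec.gamma is not None else 1.0 / max(len(names), 1)
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svr", SVR(kernel="rbf", C=spec.C, epsilon=spec.epsilon, gamma=gamma)),
    ])
    pipe.fit(x[:, keep], y)
    spec._pipeline = pipe
    spec.descriptor_names = names
    return spec


def _predict_svr(spec: SvrSpec, descriptors: dict) -> float:
    if not spec.fitted:
        raise NotFittedError("SVR model is not fitted")
    if spec._constant is not None:
        return spec._constant
    x = np.array([[descriptors[n] for n in spec.descriptor_names]], dtype=float)
    return float(spec._pipeline.predict(x)[0])


# ---------------------------------------------------------------- BN


def discretize(table: TrainingTable, max_bins: int = 5) -> dict[str, np.ndarray]:
    """Equal-frequency bin edges per variable (descriptors + activity).

    Edges are interior quantile cuts; duplicates are merged, so the
    realized bin count may be below ``max_bins``.  A constant column gets
    no edges (one bin).
    """
    if not 2 <= max_bins <= 5:
        raise ValueError("max_bins must be in 2..5")
    edges: dict[str, np.ndarray] = {}
    cols = table.descriptor_names + [table.activity_col]
    for col in cols:
        v = table.data[col].to_numpy(dtype=float)
        qs = np.quantile(v, np.linspace(0, 1, max_bins + 1)[1:-1])
        uniq = np.unique(qs)
        uniq = uniq[(uniq > v.min()) & (uniq < v.max())] if len(uniq) else uniq
        if len(uniq) + 1 < max_bins:
            log.info("%s: only %d bins realizable", col, len(uniq) + 1)
        edges[col] = uniq
    return edges


def assign_bins(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin index per value; outer bins are unbounded so out-of-range
    values clamp to the nearest bin."""
    return np.digitize(np.asarray(values, dtype=float), edges, right=True)


def _bdeu_local(data: np.ndarray, cards: np.ndarray, node: int,
                parents: tuple[int, ...], ess: float = 1.0) -> float:
    """BDeu local score of ``node`` given ``parents`` (log scale)."""
    r = cards[node]
    q = int(np.prod(cards[list(parents)])) if parents else 1
    a_j = ess / q
    a_jk = ess / (q * r)
    child = data[:, node]
    if parents:
        # flatten parent configurations into one index
        pidx = np.zeros(len(data), dtype=np.int64)
        for p in parents:
            pidx = pidx * cards[p] + data[:, p]
    else:
        pidx = np.zeros(len(data), dtype=np.int64)
    score = 0.0
    for j in np.unique(pidx):
        mask = pidx == j
        n_j = int(mask.sum())
        counts = np.bincount(child[mask], minlength=r)
        score += gammaln(a_j) - gammaln(a_j + n_j)
        score += float(np.sum(gammaln(a_jk + counts) - gammaln(a_jk)))
    return score


def learn_structure(
    binned: np.ndarray,
    cards: np.ndarray,
    seed: int = 0,
    max_parents: int = 3,
    n_restarts: int = 3,
) -> dict[int, tuple[int, ...]]:
    """Greedy hill climbing over DAGs maximizing the BDeu score
    (equivalent sample size 1); deterministic given ``seed``.

    ``binned`` is an (n_rows, n_vars) integer matrix; returns a parent map
    ``node -> tuple of parents``.
    """
    n_vars = binned.shape[1]
    if n_vars < 2:
        return {0: ()} if n_vars == 1 else {}
    rng = np.random.default_rng(seed)
    cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def local(node: int, parents: tuple[int, ...]) -> float:
        key = (node, parents)
        if key not in cache:
            cache[key] = _bdeu_local(binned, cards, node, parents)
        return cache[key]

    def creates_cycle(parents_map, child, new_parent) -> bool:
        # DFS from child along child->descendant edges
        stack, seen = [child], set()
        while stack:
            v = stack.pop()
            if v == new_parent:
                return True
            if v in seen:
                continue
            seen.add(v)
            stack.extend(u for u in range(n_vars) if v in parents_map[u])
        return False

    best_map, best_score = None, -np.inf
    for restart in range(n_restarts):
        parents = {v: () for v in range(n_vars)}
        if restart > 0:  # random starting DAG respecting a random order
            order = rng.permutation(n_vars)
            for pos, v in enumerate(order):
                prior = [int(u) for u in order[:pos] if rng.random() < 0.2]
                parents[int(v)] = tuple(sorted(prior[:max_parents]))
        total = sum(local(v, parents[v]) for v in range(n_vars))
        improved = True
        while improved:
            improved = False
            best_move, best_gain = None, 1e-10
            for child in range(n_vars):
                cur = parents[child]
                for other in range(n_vars):
                    if other == child:
                        continue
                    if other in cur:  # delete or reverse
                        without = tuple(p for p in cur if p != other)
                        gain = local(child, without) - local(child, cur)
                        if gain > best_gain:
                            best_move, best_gain = ("del", child, other), gain
                        if len(parents[other]) < max_parents and \
                                not creates_cycle({**parents, child: without},
                                                  other, child):
                            rev_p = tuple(sorted(parents[other] + (child,)))
                            gain = (local(child, without) - local(child, cur)
                                    + local(other, rev_p)
                                    - local(other, parents[other]))
                            if gain > best_gain:
                                best_move, best_gain = ("rev", child, other), gain
                    elif len(cur) < max_parents and \
                            not creates_cycle(parents, child, other):
                        with_p = tuple(sorted(cur + (other,)))
                        gain = local(child, with_p) - local(child, cur)
                        if gain > best_gain:
                            best_move, best_gain = ("add", child, other), gain
            if best_move is not None:
                op, child, other = best_move
                if op == "add":
                    parents[child] = tuple(sorted(parents[child] + (other,)))
                elif op == "del":
                    parents[child] = tuple(p for p in parents[child] if p != other)
                else:  # reverse
                    parents[child] = tuple(p for p in parents[child] if p != other)
                    parents[other] = tuple(sorted(parents[other] + (child,)))
                total += best_gain
                improved = True
        if total > best_score:
            best_map, best_score = dict(parents), total
    return best_map


@dataclass
class BayesNetModel:
    """Discretized Bayesian-network pIC50 predictor (fitted state)."""

    variables: list[str]                      # descriptors + activity (last)
    bin_edges: dict[str, np.ndarray]
    parents: dict[int, tuple[int, ...]]
    cpts: dict[int, dict[tuple, np.ndarray]]  # node -> parent-config -> probs
    cards: np.ndarray
    category_models: dict[int, LinearModel]
    category_prior: np.ndarray                # training frequencies
    combine: str = "map"                      # "map" | "posterior_mean"

    @property
    def activity_var(self) -> str:
        return self.variables[-1]


def _fit_category_models(table: TrainingTable, y_bins: np.ndarray,
                         n_cats: int) -> tuple[dict[int, LinearModel], np.ndarray]:
    names = table.descriptor_names
    train = table.split("train")
    x = train[names].to_numpy(dtype=float)
    y = train[table.activity_col].to_numpy(dtype=float)
    models: dict[int, LinearModel] = {}
    prior = np.zeros(n_cats)
    for k in range(n_cats):
        mask = y_bins == k
        prior[k] = mask.sum()
        if not mask.any():
            continue
        design = np.column_stack([np.ones(int(mask.sum())), x[mask]])
        # minimum-norm LS: categories can hold fewer rows than descriptors
        beta, *_ = np.linalg.lstsq(design, y[mask], rcond=None)
        models[k] = LinearModel(
            intercept=float(beta[0]),
            coefficients={n: float(b) for n, b in zip(names, beta[1:])},
        )
    return models, prior / max(prior.sum(), 1.0)


def fit_bn(table: TrainingTable, seed: int = 0, max_bins: int = 5,
           max_parents: int = 3, combine: str = "map") -> BayesNetModel:
    """Discretize, learn structure, estimate add-one-smoothed CPTs, and
    fit the per-category regressions."""
    edges = discretize(table, max_bins=max_bins)
    variables = table.descriptor_names + [table.activity_col]
    train = table.split("train")
    binned = np.column_stack([
        assign_bins(train[v].to_numpy(dtype=float), edges[v]) for v in variables
    ])
    cards = np.array([len(edges[v]) + 1 for v in variables])
    parents = learn_structure(binned, cards, seed=seed, max_parents=max_parents)
    cpts: dict[int, dict[tuple, np.ndarray]] = {}
    for node in range(len(variables)):
        r = cards[node]
        pset = parents[node]
        table_node: dict[tuple, np.ndarray] = {}
        for config in itertools.product(*[range(cards[p]) for p in pset]):
            mask = np.ones(len(binned), dtype=bool)
            for p, val in zip(pset, config):
                mask &= binned[:, p] == val
            counts = np.bincount(binned[mask, node], minlength=r).astype(float)
            counts += 1.0  # Dirichlet add-one smoothing
            table_node[config] = counts / counts.sum()
        cpts[node] = table_node
    y_bins = binned[:, -1]
    category_models, prior = _fit_category_models(table, y_bins, cards[-1])
    return BayesNetModel(variables, edges, parents, cpts, cards,
                         category_models, prior, combine=combine)


def bn_posterior(model: BayesNetModel, descriptors: dict) -> np.ndarray:
    """Exact posterior over pIC50 categories given observed descriptor
    bins (all non-activity nodes observed, so enumeration is over the
    activity node only)."""
    n_vars = len(model.variables)
    y_node = n_vars - 1
    obs = np.empty(n_vars, dtype=int)
    for i, v in enumerate(model.variables[:-1]):
        if v not in descriptors or descriptors[v] is None:
            raise KeyError(f"missing descriptor {v!r}")
        obs[i] = int(assign_bins(np.array([descriptors[v]]),
                                 model.bin_edges[v])[0])
    logpost = np.zeros(model.cards[y_node])
    for k in range(model.cards[y_node]):
        obs[y_node] = k
        lp = 0.0
        for node in range(n_vars):
            config = tuple(obs[p] for p in model.parents[node])
            lp += np.log(model.cpts[node][config][obs[node]])
        logpost[k] = lp
    logpost -= logpost.max()
    post = np.exp(logpost)
    return post / post.sum()


def predict_bn(model: BayesNetModel, descriptors: dict) -> float:
    """MAP-category regression output (default), or the posterior-weighted
    mean of category regressions when ``model.combine == 'posterior_mean'``."""
    post = bn_posterior(model, descriptors)
    if model.combine == "posterior_mean":
        total, weight = 0.0, 0.0
        for k, m in model.category_models.items():
            total += post[k] * evaluate_linear(m, descriptors)
            weight += post[k]
        return total / weight
    k_map = int(np.argmax(post))  # argmax ties break toward lower category
    if k_map not in model.category_models:
        k_map = min(model.category_models,
                    key=lambda k: (abs(k - k_map), k))
        log.warning("MAP category empty in training; falling back to %d", k_map)
    return evaluate_linear(model.category_models[k_map], descriptors)


# ---------------------------------------------------------------- dispatch


def predict(model, descriptors: dict) -> float:
    """Uniform prediction entry point for the three model kinds."""
    if isinstance(model, LinearModel):
        return evaluate_linear(model, descriptors)
    if isinstance(model, SvrSpec):
        return _predict_svr(model, descriptors)
    if isinstance(model, BayesNetModel):
        return predict_bn(model, descriptors)
    raise TypeError(f"unknown model type: {type(model).__name__}")
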