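"""Randomized-matrix null models and z-score machinery.

Two generators are provided:

* :func:`vaznull_sample` — the marginal-probability null of Vazquez et al.:
  keeps the observed dimensions, number of links L and total weight T fixed,
  requires every row and column to keep at least one link, and places both
  links and interaction events with probability proportional to the product
  of the observed marginal totals.  Marginal sums are thus conserved only
  probabilistically.

* :func:`restricted_null_sample` — the module-conserving extension: the
  matrix is cut into regions by module pair and the vaznull procedure is
  applied independently inside each region that holds observed links, so the
  planted modular skeleton (per-region fill and weight) survives
  randomization.

:func:`null_distribution` evaluates a metric over an ensemble of such
matrices and reports the z-score of the observed value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .metrics import (
    UNDEFINED,
    ModulePartition,
    barber_modularity,
    connectance,
    find_modules,
    wnodf,
    wnodf_sm,
)
from .netcore import (
    NetworkError,
    ValidationError,
    WeightedBipartiteNetwork,
    require_hygienic,
)

__all__ = [
    "NullEnsemble",
    "GenerationFailure",
    "vaznull_sample",
    "restricted_null_sample",
    "null_distribution",
    "z_score",
]


class GenerationFailure(NetworkError):
    """A null replicate could not be generated within the retry budget."""


def z_score(observed: float, null_values) -> float:
    """(observed - mean) / sd over the null ensemble, sample (n-1) sd.

    Returns the undefined marker (NaN) when the null spread is zero.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size < 2:
        raise ValidationError("z-score needs at least 2 null values")
    mean = null_values.mean()
    sd = null_values.std(ddof=1)
    # guard float residue when every null value is identical (conserved metric)
    if sd <= 1e-12 * max(1.0, abs(mean)):
        return UNDEFINED
    return float((observed - mean) / sd)


@dataclass
class NullEnsemble:
    """A metric's observed value against its null distribution."""

    metric: str
    observed: float
    null_values: np.ndarray
    n_failures: int = 0
    model: str = "vaznull"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)

    @property
    def z(self) -> float:
        return z_score(self.observed, self.null_values)

    @property
    def null_mean(self) -> float:
        return float(self.null_values.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null_values.std(ddof=1))

    def to_dict(self, include_values: bool = True) -> dict:
        z = self.z
        d = {
            "metric": self.metric,
            "model": self.model,
            "observed": self.observed,
            "n": int(self.null_values.size),
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": None if math.isnan(z) else z,
            "n_failures": self.n_failures,
            "seed": self.seed,
        }
        if include_values:
            d["null_values"] = [float(v) for v in self.null_values]
        return d


# ---------------------------------------------------------------------------
# vaznull core


def _fill_cells(
    p: np.ndarray,
    n_links: int,
    rng: np.random.Generator,
    need_row: np.ndarray,
    need_col: np.ndarray,
    max_attempts: int = 100_000,
) -> np.ndarray:
    """Stage 1: choose ``n_links`` distinct cells of the R x C grid.

    Cells are drawn one at a time with probability proportional to ``p``
    over still-empty cells.  A draw is rejected when accepting it would make
    full coverage impossible: after the fill, every still-uncovered required
    row and column must be reachable within the remaining cell budget.  One
    future cell can cover one uncovered row and one uncovered column at
    once, so the exact feasibility condition is
    ``remaining >= max(#uncovered required rows, #uncovered required cols)``.
    """
    R, C = p.shape
    filled = np.zeros((R, C), dtype=bool)
    row_uncov = need_row.copy()
    col_uncov = need_col.copy()
    weights = p.ravel().copy()
    attempts = 0
    placed = 0
    while placed < n_links:
        total = weights.sum()
        if total <= 0:
            raise GenerationFailure("no admissible cell left in stage 1")
        idx = rng.choice(R * C, p=weights / total)
        i, j = divmod(idx, C)
        remaining = n_links - placed - 1
        r_after = row_uncov.sum() - (1 if row_uncov[i] else 0)
        c_after = col_uncov.sum() - (1 if col_uncov[j] else 0)
        if remaining < max(r_after, c_after):
            attempts += 1
            if attempts > max_attempts:
                raise GenerationFailure("stage-1 retry budget exhausted")
            continue
        filled[i, j] = True
        weights[idx] = 0.0
        row_uncov[i] = False
        col_uncov[j] = False
        placed += 1
    return filled


def _distribute_weight(
    filled: np.ndarray, p: np.ndarray, extra: int, rng: np.random.Generator
) -> np.ndarray:
    """Stage 2: drop ``extra`` events on the filled cells, proportional to p."""
    out = filled.astype(np.int64)
    if extra == 0:
        return out
    ii, jj = np.nonzero(filled)
    pcell = p[ii, jj]
    pcell = pcell / pcell.sum()
    draws = rng.choice(ii.size, size=extra, p=pcell)
    np.add.at(out, (ii[draws], jj[draws]), 1)
    return out


def _vaznull_weights(
    weights: np.ndarray,
    rng: np.random.Generator,
    need_row: np.ndarray | None = None,
    need_col: np.ndarray | None = None,
) -> np.ndarray:
    """vaznull on a raw count matrix; coverage enforced for flagged rows/cols."""
    W = np.asarray(weights, dtype=np.int64)
    R, C = W.shape
    r = W.sum(axis=1).astype(float)
    c = W.sum(axis=0).astype(float)
    T = int(W.sum())
    L = int(np.count_nonzero(W))
    p = np.outer(r, c)
    p /= p.sum()
    if need_row is None:
        need_row = r > 0
    if need_col is None:
        need_col = c > 0
    filled = _fill_cells(p, L, rng, need_row.copy(), need_col.copy())
    return _distribute_weight(filled, p, T - L, rng)


def vaznull_sample(
    net: WeightedBipartiteNetwork, rng: int | np.random.Generator = 0
) -> np.ndarray:
    """One vaznull randomization of ``net``; returns the weight matrix.

    Hard constraints: same dimensions, same number of links L, same total
    weight T, every row and column covered by at least one link.
    """
    require_hygienic(net)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return _vaznull_weights(net.weights, rng)


def restricted_null_sample(
    net: WeightedBipartiteNetwork,
    partition: ModulePartition,
    rng: int | np.random.Generator = 0,
) -> np.ndarray:
    """Module-conserving vaznull: randomize each module-pair region separately.

    Regions with no observed link stay empty, so per-region fill and weight
    — and hence global L and T — are conserved exactly.  Within diagonal
    (same-module) regions every row/column that has an observed within-module
    link must keep at least one; between-module regions carry no coverage
    requirement (whole-matrix coverage is already guaranteed by the diagonal
    regions together with the preserved between-module fills).
    """
    require_hygienic(net)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    g, h = partition.row_assign, partition.col_assign
    if g.shape != (net.n_rows,) or h.shape != (net.n_cols,):
        raise ValidationError("partition does not index this network")
    out = np.zeros_like(net.weights)
    for gm in np.unique(g):
        rows = np.nonzero(g == gm)[0]
        for hm in np.unique(h):
            cols = np.nonzero(h == hm)[0]
            sub = net.weights[np.ix_(rows, cols)]
            if not sub.any():
                continue
            if gm == hm:
                need_r = sub.sum(axis=1) > 0
                need_c = sub.sum(axis=0) > 0
            else:
                need_r = np.zeros(len(rows), dtype=bool)
                need_c = np.zeros(len(cols), dtype=bool)
            out[np.ix_(rows, cols)] = _vaznull_weights(sub, rng, need_r, need_c)
    return out


# ---------------------------------------------------------------------------
# ensembles

#: metric name -> callable(net, context) used by null_distribution
def _metric_registry() -> dict[str, Callable]:
    return {
        "total_weight": lambda net, ctx: float(net.total_weight),
        "connectance": lambda net, ctx: connectance(net),
        "wnodf": lambda net, ctx: wnodf(net),
        "modularity": lambda net, ctx: find_modules(
            net, reps=ctx["reps"], seed=ctx["rng"]
        ).Q,
        "wnodf_sm": lambda net, ctx: wnodf_sm(net, ctx["partition"]),
    }


def null_distribution(
    net: WeightedBipartiteNetwork,
    metric: str,
    model: str = "vaznull",
    n: int = 1000,
    seed: int = 0,
    partition: ModulePartition | None = None,
    reps: int = 2,
    max_failure_frac: float = 0.10,
) -> NullEnsemble:
    """Evaluate ``metric`` over ``n`` null replicates and attach the z-score.

    ``model`` is ``"vaznull"`` or ``"restricted"`` (the latter needs the
    observed ``partition``, which is also held fixed when evaluating
    ``wnodf_sm`` on the replicates — the within-module null perturbs weights,
    not module membership).  For ``modularity`` each replicate is
    re-optimized with ``reps`` restarts.  Deterministic under ``seed``.
    Aborts when more than ``max_failure_frac`` of draws fail to generate.
    """
    require_hygienic(net)
    if n < 2:
        raise ValidationError("need n >= 2 null replicates")
    if model not in ("vaznull", "restricted"):
        raise ValidationError(f"unknown null model {model!r}")
    registry = _metric_registry()
    if metric not in registry:
        raise ValidationError(
            f"unknown metric {metric!r}; choose from {sorted(registry)}"
        )
    if metric == "wnodf_sm" and partition is None:
        raise ValidationError("wnodf_sm requires the observed partition")
    if model == "restricted" and partition is None:
        raise ValidationError("restricted null model requires the observed partition")
    rng = np.random.default_rng(seed)
    ctx = {"rng": rng, "reps": reps, "partition": partition}
    fn = registry[metric]
    if metric == "modularity" and partition is not None:
        observed = partition.Q  # the already-optimized observed partition
    else:
        observed = fn(net, ctx)
    values = np.empty(n)
    failures = 0
    max_failures = int(max_failure_frac * n) + 1
    i = 0
    while i < n:
        try:
            if model == "vaznull":
                w = _vaznull_weights(net.weights, rng)
            else:
                w = restricted_null_sample(net, partition, rng)
                # a species whose links are all between-module can, rarely,
                # lose every link; such a draw breaks coverage and is redrawn
                if (w.sum(axis=1) == 0).any() or (w.sum(axis=0) == 0).any():
                    raise GenerationFailure("restricted replicate lost coverage")
        except GenerationFailure:
            failures += 1
            if failures > max_failures:
                raise GenerationFailure(
                    f"{failures} generation failures out of {i + failures} draws "
                    f"(budget {max_failures}) for model {model}"
                )
            continue
        values[i] = fn(net.with_weights(w), ctx)
        i += 1
    return NullEnsemble(
        metric=metric,
        observed=float(observed),
        null_values=values,
        n_failures=failures,
        model=model,
        seed=seed,
    )
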