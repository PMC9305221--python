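"""Sampling-completeness estimation: Chao1 and individual-based rarefaction.

For network completeness the "individuals" are faecal detection events and
the classes are links: a link's abundance is its cell count, so singleton
links (seen in one bat) drive the Chao1 estimate of how many links remain
unobserved.  Per-bat diet accumulation treats plant taxa as classes and is
summarized by the exact hypergeometric rarefaction curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .netcore import ValidationError, WeightedBipartiteNetwork, require_hygienic

__all__ = [
    "Chao1Estimate",
    "RarefactionCurve",
    "chao1",
    "network_completeness",
    "rarefy_diet",
    "diet_rarefaction_table",
]


@dataclass
class Chao1Estimate:
    estimate: float
    s_obs: int
    f1: int
    f2: int
    variant: str
    fallback: bool = False  # classic requested but f2 = 0, bias-corrected used


def chao1(abundances: Iterable[int], variant: str = "classic") -> Chao1Estimate:
    """Chao1 richness estimate from class abundances.

    classic: S_obs + f1^2 / (2 f2); bias_corrected:
    S_obs + f1 (f1 - 1) / (2 (f2 + 1)), with f1/f2 the singleton/doubleton
    class counts.  Classic falls back to bias-corrected when f2 = 0 (flagged).
    """
    counts = np.asarray(list(abundances), dtype=np.int64)
    if counts.size == 0:
        raise ValidationError("need at least one class")
    if (counts <= 0).any():
        raise ValidationError("abundances must be positive integers")
    s_obs = int(counts.size)
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if variant not in ("classic", "bias_corrected"):
        raise ValidationError(f"unknown Chao1 variant {variant!r}")
    fallback = False
    if variant == "classic" and f2 == 0 and f1 > 0:
        variant_used, fallback = "bias_corrected", True
    elif variant == "classic" and f2 == 0:  # f1 = f2 = 0: estimate is S_obs
        variant_used = "bias_corrected"
    else:
        variant_used = variant
    if variant_used == "classic":
        estimate = s_obs + f1**2 / (2 * f2)
    else:
        estimate = s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    return Chao1Estimate(float(estimate), s_obs, f1, f2, variant_used, fallback)


def network_completeness(
    net: WeightedBipartiteNetwork, variant: str = "classic"
) -> float:
    """Percent sampling completeness: 100 * L / Chao1(link abundances).

    Classes are the realized links; a link's abundance is its cell count.
    """
    require_hygienic(net)
    counts = net.weights[net.weights > 0]
    est = chao1(counts, variant)
    return 100.0 * net.n_links / est.estimate


@dataclass
class RarefactionCurve:
    """Expected taxon richness at subsample sizes 1..N (exact hypergeometric)."""

    n: np.ndarray
    expected_richness: np.ndarray
    n_total: int
    s_obs: int

    def to_frame(self, label: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"n": self.n, "E_S": self.expected_richness})
        if label is not None:
            df.insert(0, "bat", label)
        return df


def rarefy_diet(
    counts: Sequence[int], grid: Sequence[int] | None = None
) -> RarefactionCurve:
    """Individual-based rarefaction of one bat's diet.

    ``counts`` holds the number of detection events per plant taxon; the
    expected richness in a random subsample of n events is
    E[S_n] = sum_k [1 - C(N - N_k, n) / C(N, n)], evaluated with exact
    integer binomials (C(a, b) = 0 when a < b).
    """
    counts = np.asarray(list(counts), dtype=np.int64)
    if counts.size == 0 or (counts <= 0).any():
        raise ValidationError("counts must be positive integers")
    N = int(counts.sum())
    if grid is None:
        grid = range(1, N + 1)
    grid = np.asarray(list(grid), dtype=np.int64)
    if (grid < 1).any() or (grid > N).any():
        raise ValidationError(f"subsample sizes must lie in 1..{N}")
    denom = [comb(N, int(n)) for n in grid]
    es = np.empty(len(grid))
    for gi, n in enumerate(grid):
        n = int(n)
        miss = sum(comb(N - int(Nk), n) for Nk in counts)
        es[gi] = counts.size - miss / denom[gi]
    return RarefactionCurve(grid, es, N, int(counts.size))


def diet_rarefaction_table(net: WeightedBipartiteNetwork) -> pd.DataFrame:
    """Long-format rarefaction curves, one per bat species in the network."""
    require_hygienic(net)
    frames = []
    for i, bat in enumerate(net.row_labels):
        counts = net.weights[i][net.weights[i] > 0]
        frames.append(rarefy_diet(counts).to_frame(bat))
    return pd.concat(frames, ignore_index=True)
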