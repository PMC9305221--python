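"""Synthetic bat-plant interaction matrices with planted structure.

The generator emulates the shape of molecular-diet interaction data: two
guilds, lognormal abundance skew producing supergeneralists, a block-modular
affinity structure, and integer counts arising from sampling individual
faecal detections from a categorical cell distribution.  Paired "seasonal"
networks add controlled species turnover (fraction tau of each guild
replaced) and link rewiring among shared species (fraction rho), so the
beta-diversity decomposition can be validated against planted drivers.

Defaults mirror the scale of the study system this pipeline targets:
roughly a dozen bat species, two dozen plant taxa, and on the order of a
hundred detection events per network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .netcore import (
    ValidationError,
    WeightedBipartiteNetwork,
    drop_empty,
)

__all__ = [
    "SyntheticTruth",
    "generate_network",
    "generate_perfect",
    "generate_season_pair",
]

# study-scale defaults: ~12 consumers, ~22 resources, ~130 detection events
DEFAULT_R = 12
DEFAULT_C = 22
DEFAULT_N_MODULES = 4
DEFAULT_AFFINITY_RATIO = 8.0
DEFAULT_ABUNDANCE_SD = 1.0
DEFAULT_T_EVENTS = 130


@dataclass
class SyntheticTruth:
    """Planted parameters of a generated network (or pair), for recovery tests."""

    row_modules: dict[str, int]
    col_modules: dict[str, int]
    row_abundance: dict[str, float]
    col_abundance: dict[str, float]
    affinity_ratio: float
    rho: float = 0.0  # rewired fraction of links among shared species
    tau: float = 0.0  # replaced fraction of species per guild
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def cell_probabilities(
        self, row_labels: list[str], col_labels: list[str]
    ) -> np.ndarray:
        """Exact expected cell probabilities for the given label ordering."""
        a = np.array([self.row_abundance[l] for l in row_labels])
        b = np.array([self.col_abundance[l] for l in col_labels])
        gm = np.array([self.row_modules[l] for l in row_labels])
        hm = np.array([self.col_modules[l] for l in col_labels])
        boost = np.where(gm[:, None] == hm[None, :], self.affinity_ratio, 1.0)
        p = np.outer(a, b) * boost
        return p / p.sum()

    def to_json(self) -> str:
        return json.dumps(
            {
                "row_modules": self.row_modules,
                "col_modules": self.col_modules,
                "row_abundance": self.row_abundance,
                "col_abundance": self.col_abundance,
                "affinity_ratio": self.affinity_ratio,
                "rho": self.rho,
                "tau": self.tau,
                "seed": self.seed,
                "params": self.params,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "SyntheticTruth":
        d = json.loads(s)
        d["row_modules"] = {k: int(v) for k, v in d["row_modules"].items()}
        d["col_modules"] = {k: int(v) for k, v in d["col_modules"].items()}
        return cls(**d)


def _labels(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:02d}" for i in range(n)]


def generate_network(
    R: int = DEFAULT_R,
    C: int = DEFAULT_C,
    n_modules: int = DEFAULT_N_MODULES,
    affinity_ratio: float = DEFAULT_AFFINITY_RATIO,
    abundance_sd: float = DEFAULT_ABUNDANCE_SD,
    T_events: int = DEFAULT_T_EVENTS,
    seed: int = 0,
    label_prefixes: tuple[str, str] = ("bat", "plant"),
) -> tuple[WeightedBipartiteNetwork, SyntheticTruth]:
    """Sample one interaction matrix from the planted affinity model.

    Species are assigned to ``n_modules`` modules round-robin; the
    probability of a detection event falling in cell (i, j) is proportional
    to a_i * b_j * affinity_ratio^[same module], with a, b lognormal(0,
    abundance_sd) abundance weights.  ``T_events`` events are drawn from
    that categorical distribution and the count matrix is passed through
    hygiene (species never detected are dropped).  Deterministic under
    ``seed``.
    """
    if not (R >= n_modules >= 1) or C < n_modules:
        raise ValidationError("need R, C >= n_modules >= 1")
    if T_events < max(R, C):
        raise ValidationError("T_events must be >= max(R, C)")
    if affinity_ratio <= 0 or abundance_sd < 0:
        raise ValidationError("affinity_ratio > 0 and abundance_sd >= 0 required")
    rng = np.random.default_rng(seed)
    row_labels = _labels(label_prefixes[0], R)
    col_labels = _labels(label_prefixes[1], C)
    truth = SyntheticTruth(
        row_modules={l: i % n_modules for i, l in enumerate(row_labels)},
        col_modules={l: j % n_modules for j, l in enumerate(col_labels)},
        row_abundance={
            l: float(v) for l, v in zip(row_labels, rng.lognormal(0, abundance_sd, R))
        },
        col_abundance={
            l: float(v) for l, v in zip(col_labels, rng.lognormal(0, abundance_sd, C))
        },
        affinity_ratio=float(affinity_ratio),
        seed=seed,
        params={
            "R": R,
            "C": C,
            "n_modules": n_modules,
            "abundance_sd": abundance_sd,
            "T_events": T_events,
        },
    )
    p = truth.cell_probabilities(row_labels, col_labels)
    events = rng.multinomial(T_events, p.ravel()).reshape(R, C)
    net = WeightedBipartiteNetwork(
        row_labels, col_labels, events, {"name": f"synthetic-seed{seed}", "seed": seed}
    )
    return drop_empty(net), truth


def generate_perfect(
    kind: str,
    R: int = 2,
    C: int = 2,
    k: int = 2,
    block_size: int = 2,
) -> WeightedBipartiteNetwork:
    """Deterministic fixtures with extremal structure.

    ``kind="nested"``: the packed triangular matrix w_ij = max(0, M - i - j)
    with M = max(R, C); marginal totals strictly decrease and every occupied
    cell of a poorer species is strictly below the richer one's, so
    WNODF = 1.  ``kind="block"``: k disjoint all-ones blocks, hence k
    compartments and (for equal blocks) Barber Q = 1 - 1/k under the planted
    partition.
    """
    if kind == "nested":
        if R < 1 or C < 1:
            raise ValidationError("need R, C >= 1")
        M = max(R, C)
        w = np.fromfunction(lambda i, j: np.maximum(0, M - i - j), (R, C), dtype=int)
        return WeightedBipartiteNetwork(
            _labels("bat", R), _labels("plant", C), w.astype(np.int64), {"name": "nested"}
        )
    if kind == "block":
        if k < 1 or block_size < 1:
            raise ValidationError("need k, block_size >= 1")
        n = k * block_size
        w = np.zeros((n, n), dtype=np.int64)
        for b in range(k):
            s = b * block_size
            w[s : s + block_size, s : s + block_size] = 1
        return WeightedBipartiteNetwork(
            _labels("bat", n), _labels("plant", n), w, {"name": f"block-{k}"}
        )
    raise ValidationError(f"unknown kind {kind!r}")


def planted_partition(
    net: WeightedBipartiteNetwork, truth: SyntheticTruth
) -> tuple[np.ndarray, np.ndarray]:
    """The planted module labels restricted to the species surviving hygiene."""
    g = np.array([truth.row_modules[l] for l in net.row_labels])
    h = np.array([truth.col_modules[l] for l in net.col_labels])
    return g, h


def generate_season_pair(
    rho: float,
    tau: float,
    seed: int = 0,
    **base_params,
) -> tuple[WeightedBipartiteNetwork, WeightedBipartiteNetwork, SyntheticTruth]:
    """A pair of networks differing by planted turnover and rewiring.

    Network A comes from :func:`generate_network`.  Network B keeps a
    fraction 1 - tau of each guild, replaces the rest with newly labeled
    species carrying fresh links, and rewires a fraction rho of the
    surviving links by moving their plant endpoint to a different shared
    plant (avoiding duplicate links).  Counts are resampled over B's link
    set proportional to the abundance model, every link keeping at least one
    event.
    """
    if not (0 <= rho <= 1 and 0 <= tau <= 1):
        raise ValidationError("rho and tau must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sub = int(rng.integers(0, 2**31 - 1))
    net_a, truth = generate_network(seed=sub, **base_params)
    truth.rho, truth.tau, truth.seed = float(rho), float(tau), seed

    bats = list(net_a.row_labels)
    plants = list(net_a.col_labels)
    n_drop_b = int(round(tau * len(bats)))
    n_drop_p = int(round(tau * len(plants)))
    if rho > 0 and len(plants) - n_drop_p < 2:
        raise ValidationError("rewiring needs at least two surviving plants")
    drop_b = set(rng.choice(bats, size=n_drop_b, replace=False)) if n_drop_b else set()
    drop_p = set(rng.choice(plants, size=n_drop_p, replace=False)) if n_drop_p else set()
    kept_b = [b for b in bats if b not in drop_b]
    kept_p = [p for p in plants if p not in drop_p]
    new_b = _labels("batB", n_drop_b)
    new_p = _labels("plantB", n_drop_p)

    n_mod = truth.params["n_modules"]
    sd = truth.params["abundance_sd"]
    for l in new_b:
        truth.row_modules[l] = int(rng.integers(0, n_mod))
        truth.row_abundance[l] = float(rng.lognormal(0, sd))
    for l in new_p:
        truth.col_modules[l] = int(rng.integers(0, n_mod))
        truth.col_abundance[l] = float(rng.lognormal(0, sd))

    # surviving links, then rewire a fraction rho of them
    links = sorted((b, p) for (b, p) in net_a.links() if b not in drop_b and p not in drop_p)
    link_set = set(links)
    n_rewire = int(round(rho * len(links)))
    if n_rewire:
        chosen = rng.choice(len(links), size=n_rewire, replace=False)
        for idx in chosen:
            b, p = links[idx]
            candidates = [q for q in kept_p if q != p and (b, q) not in link_set]
            if not candidates:
                continue
            q = candidates[int(rng.integers(0, len(candidates)))]
            link_set.discard((b, p))
            link_set.add((b, q))

    # fresh links for replacement species, degree matched to network A
    all_b = kept_b + new_b
    all_p = kept_p + new_p
    mean_deg_b = max(1, round(net_a.n_links / net_a.n_rows))
    mean_deg_p = max(1, round(net_a.n_links / net_a.n_cols))
    p_weights = np.array([truth.col_abundance[q] for q in all_p])
    b_weights = np.array([truth.row_abundance[b] for b in all_b])
    for b in new_b:
        deg = min(len(all_p), mean_deg_b)
        targets = rng.choice(all_p, size=deg, replace=False, p=p_weights / p_weights.sum())
        for q in targets:
            link_set.add((b, str(q)))
    for q in new_p:
        if not any(l[1] == q for l in link_set):
            deg = min(len(all_b), mean_deg_p)
            sources = rng.choice(
                all_b, size=deg, replace=False, p=b_weights / b_weights.sum()
            )
            for b in sources:
                link_set.add((str(b), q))

    # resample counts: one event per link, remainder proportional to abundance
    links_b = sorted(link_set)
    T = truth.params["T_events"]
    extra = max(0, T - len(links_b))
    w_link = np.array(
        [truth.row_abundance[b] * truth.col_abundance[q] for b, q in links_b]
    )
    counts = np.ones(len(links_b), dtype=np.int64)
    if extra:
        counts += rng.multinomial(extra, w_link / w_link.sum())

    bi = {b: i for i, b in enumerate(all_b)}
    pi = {q: j for j, q in enumerate(all_p)}
    W = np.zeros((len(all_b), len(all_p)), dtype=np.int64)
    for (b, q), c in zip(links_b, counts):
        W[bi[b], pi[q]] = c
    net_b = drop_empty(
        WeightedBipartiteNetwork(
            all_b, all_p, W, {"name": f"synthetic-pairB-seed{seed}", "seed": seed}
        )
    )
    return net_a, net_b, truth
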