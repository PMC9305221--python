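"""Pairwise network beta-diversity: species turnover vs interaction rewiring.

Following the betalink framework (Poisot et al.), a link is the identity
pair (bat label, plant label); weights are ignored.  For two networks:

* ``beta_S`` — Sorensen dissimilarity of the pooled species sets;
* ``beta_WN`` — Sorensen dissimilarity of the full link sets;
* ``beta_OS`` — Sorensen dissimilarity of the link sets of the subnetworks
  induced on species present in both networks (rewiring component);
* ``beta_ST`` — beta_WN - beta_OS, the part of interaction dissimilarity
  attributable to species turnover.

All use the Sorensen (2a) denominator by default; Jaccard is available
behind a flag for diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .metrics import UNDEFINED
from .netcore import ValidationError, WeightedBipartiteNetwork

__all__ = ["BetaReport", "species_beta", "interaction_beta", "beta_table"]


def _pair_dissimilarity(set1: set, set2: set, family: str = "sorensen") -> float:
    """(b + c) / (2a + b + c) for Sorensen; (b + c)/(a + b + c) for Jaccard."""
    a = len(set1 & set2)
    b = len(set1 - set2)
    c = len(set2 - set1)
    if a + b + c == 0:
        return UNDEFINED
    if family == "sorensen":
        return (b + c) / (2 * a + b + c)
    if family == "jaccard":
        return (b + c) / (a + b + c)
    raise ValidationError(f"unknown dissimilarity family {family!r}")


@dataclass
class BetaReport:
    """Beta-diversity decomposition for one ordered pair of networks.

    ``beta_st_flag`` is set when no link exists among shared species in
    either network: beta_OS is then undefined and beta_ST is reported equal
    to beta_WN.
    """

    beta_S: float
    beta_WN: float
    beta_OS: float
    beta_ST: float
    shared_species: set[str] = field(default_factory=set)
    shared_links: int = 0
    shared_bats: int = 0
    shared_plants: int = 0
    unique_bats: tuple[int, int] = (0, 0)
    unique_plants: tuple[int, int] = (0, 0)
    beta_S_bats: float = UNDEFINED
    beta_S_plants: float = UNDEFINED
    beta_st_flag: bool = False

    def to_dict(self) -> dict:
        def clean(x):
            return None if isinstance(x, float) and math.isnan(x) else x

        return {
            "beta_S": clean(self.beta_S),
            "beta_WN": clean(self.beta_WN),
            "beta_OS": clean(self.beta_OS),
            "beta_ST": clean(self.beta_ST),
            "shared_species": sorted(self.shared_species),
            "shared_links": self.shared_links,
            "shared_bats": self.shared_bats,
            "shared_plants": self.shared_plants,
            "unique_bats": list(self.unique_bats),
            "unique_plants": list(self.unique_plants),
            "beta_S_bats": clean(self.beta_S_bats),
            "beta_S_plants": clean(self.beta_S_plants),
            "beta_st_flag": self.beta_st_flag,
        }


def species_beta(
    net1: WeightedBipartiteNetwork,
    net2: WeightedBipartiteNetwork,
    family: str = "sorensen",
) -> float:
    """Dissimilarity of species composition, both guilds pooled.

    With a species in both networks and b, c unique to each:
    beta_S = (b + c) / (2a + b + c).
    """
    s1 = set(net1.row_labels) | set(net1.col_labels)
    s2 = set(net2.row_labels) | set(net2.col_labels)
    return _pair_dissimilarity(s1, s2, family)


def _induced_links(
    net: WeightedBipartiteNetwork, bats: set[str], plants: set[str]
) -> set[tuple[str, str]]:
    return {(b, p) for (b, p) in net.links() if b in bats and p in plants}


def interaction_beta(
    net1: WeightedBipartiteNetwork,
    net2: WeightedBipartiteNetwork,
    family: str = "sorensen",
) -> BetaReport:
    """Decompose whole-network link dissimilarity into rewiring and turnover.

    beta_WN is computed on the full link sets; beta_OS on the link sets of
    the subnetworks induced (guild-respecting) on species present in both
    networks; beta_ST = beta_WN - beta_OS.  When the shared-species
    subnetworks hold no links at all, beta_OS is the undefined marker and
    beta_ST falls back to beta_WN (flagged).
    """
    bats1, bats2 = set(net1.row_labels), set(net2.row_labels)
    plants1, plants2 = set(net1.col_labels), set(net2.col_labels)
    shared_bats = bats1 & bats2
    shared_plants = plants1 & plants2

    links1, links2 = net1.links(), net2.links()
    beta_wn = _pair_dissimilarity(links1, links2, family)

    sub1 = _induced_links(net1, shared_bats, shared_plants)
    sub2 = _induced_links(net2, shared_bats, shared_plants)
    flag = False
    if not sub1 and not sub2:
        beta_os = UNDEFINED
        beta_st = beta_wn
        flag = True
    else:
        beta_os = _pair_dissimilarity(sub1, sub2, family)
        beta_st = beta_wn - beta_os

    return BetaReport(
        beta_S=species_beta(net1, net2, family),
        beta_WN=beta_wn,
        beta_OS=beta_os,
        beta_ST=beta_st,
        shared_species=shared_bats | shared_plants,
        shared_links=len(links1 & links2),
        shared_bats=len(shared_bats),
        shared_plants=len(shared_plants),
        unique_bats=(len(bats1 - bats2), len(bats2 - bats1)),
        unique_plants=(len(plants1 - plants2), len(plants2 - plants1)),
        beta_S_bats=_pair_dissimilarity(bats1, bats2, family),
        beta_S_plants=_pair_dissimilarity(plants1, plants2, family),
        beta_st_flag=flag,
    )


def beta_table(
    networks: Mapping[str, WeightedBipartiteNetwork],
    pairs: Sequence[tuple[str, str]],
    family: str = "sorensen",
) -> pd.DataFrame:
    """One BetaReport row per requested pair of named networks."""
    if len(networks) < 2:
        raise ValidationError("need at least two networks")
    rows = []
    for name1, name2 in pairs:
        for n in (name1, name2):
            if n not in networks:
                raise ValidationError(f"unknown network label {n!r}")
        rep = interaction_beta(networks[name1], networks[name2], family)
        rows.append(
            {
                "pair": f"{name1} vs {name2}",
                "beta_S": rep.beta_S,
                "beta_WN": rep.beta_WN,
                "beta_OS": rep.beta_OS,
                "beta_ST": rep.beta_ST,
                "shared_species": len(rep.shared_species),
                "shared_links": rep.shared_links,
            }
        )
    return pd.DataFrame(rows)
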