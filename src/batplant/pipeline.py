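"""End-to-end per-network analysis and study-style table assembly.

Ties together the structure descriptors, null-model z-scores, beta-diversity
and completeness modules into the reports the analysis drivers and the CLI
write out.  One global seed expands into independent per-task seeds through
a counter-based scheme, so adding a network to a batch does not perturb the
results of the others.
"""

from __future__ import annotations

import hashlib
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .completeness import diet_rarefaction_table, network_completeness
from .dissimilarity import beta_table
from .metrics import ModulePartition, StructureReport, structure_report
from .netcore import WeightedBipartiteNetwork
from .nullmodels import null_distribution

__all__ = [
    "task_seed",
    "analyze_network",
    "reports_to_table",
    "completeness_table",
]


def task_seed(global_seed: int, *tags) -> int:
    """Derive a stable 31-bit sub-seed from a global seed and task tags."""
    h = hashlib.sha256(repr((int(global_seed),) + tuple(tags)).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31 - 1)


def analyze_network(
    net: WeightedBipartiteNetwork,
    name: str,
    n_nulls: int = 1000,
    reps: int = 10,
    seed: int = 0,
    null_reps: int = 2,
) -> tuple[StructureReport, ModulePartition]:
    """Descriptor panel plus null-model z-scores for one network.

    z-scores follow the study design: WNODF and modularity against the
    vaznull ensemble, WNODF_SM against the module-conserving ensemble (with
    the observed partition held fixed).  ``n_nulls=0`` skips them.
    """
    report, part = structure_report(
        net, reps=reps, seed=task_seed(seed, name, "modules"), name=name
    )
    if n_nulls:
        for metric, model in [
            ("wnodf", "vaznull"),
            ("modularity", "vaznull"),
            ("wnodf_sm", "restricted"),
        ]:
            ens = null_distribution(
                net,
                metric,
                model=model,
                n=n_nulls,
                seed=task_seed(seed, name, metric, model),
                partition=part,
                reps=null_reps,
            )
            report.z_scores[metric] = ens.z
    report.meta.update(n_nulls=n_nulls, version=__version__)
    return report, part


def _fmt(value: float, z: float | None, digits: int = 2) -> str:
    if isinstance(value, float) and math.isnan(value):
        return "NA"
    s = f"{value:.{digits}f}"
    if z is not None:
        s += " (NA)" if math.isnan(z) else f" ({z:.1f})"
    return s


def reports_to_table(reports: Sequence[StructureReport]) -> pd.DataFrame:
    """Study-style metrics table: one column per network, one row per metric."""
    cols = {}
    for r in reports:
        z = r.z_scores
        cols[r.name] = {
            "Plant richness": str(r.plant_richness),
            "Bat richness": str(r.bat_richness),
            "Number of compartments": str(r.n_compartments),
            "WNODF": _fmt(r.wnodf, z.get("wnodf")),
            "Modularity": _fmt(r.modularity, z.get("modularity")),
            "WNODF_SM": _fmt(r.wnodf_sm, z.get("wnodf_sm")),
            "Connectance": _fmt(r.connectance, None),
        }
    return pd.DataFrame(cols)


def completeness_table(
    networks: Mapping[str, WeightedBipartiteNetwork], variant: str = "classic"
) -> pd.DataFrame:
    """Per-network percent sampling completeness, both Chao1 variants."""
    rows = []
    for name, net in networks.items():
        rows.append(
            {
                "network": name,
                "links": net.n_links,
                "total_weight": net.total_weight,
                "completeness_classic": network_completeness(net, "classic"),
                "completeness_bc": network_completeness(net, "bias_corrected"),
            }
        )
    return pd.DataFrame(rows)
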