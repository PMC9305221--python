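"""Loading the deposited study matrices and the study's comparison design.

The field study behind this pipeline deposited seven weighted bat x plant
matrices (two forest sites x {whole-year, dry season, wet season} during an
extreme El Nino year, plus the dry-forest wet season of a non-El Nino
year).  This module maps a directory of such CSVs onto canonical network
names and lists the between-forest / between-season comparisons the
dissimilarity analysis runs on.

The deposit itself is not shipped here; point :func:`load_study_matrices`
at a local copy (CSV export, bats as rows).
"""

from __future__ import annotations

from pathlib import Path

from .netcore import WeightedBipartiteNetwork, drop_empty, read_matrix

__all__ = ["STUDY_NETWORKS", "STUDY_PAIRS", "load_study_matrices"]

#: canonical network names, in the study table's column order
STUDY_NETWORKS = [
    "dryforest_wholeyear",
    "dryforest_dry",
    "dryforest_wet",
    "dryforest_wet_2009",
    "rainforest_wholeyear",
    "rainforest_dry",
    "rainforest_wet",
]

#: the comparison design: across forests, across seasons within forest,
#: and the El Nino vs non-El Nino wet season in the dry forest
STUDY_PAIRS = [
    ("dryforest_wholeyear", "rainforest_wholeyear"),
    ("dryforest_dry", "dryforest_wet"),
    ("rainforest_dry", "rainforest_wet"),
    ("dryforest_wet", "dryforest_wet_2009"),
]


def load_study_matrices(
    directory: str | Path, transpose: bool = False
) -> dict[str, WeightedBipartiteNetwork]:
    """Load every ``<name>.csv`` under ``directory`` keyed by file stem.

    Files named after :data:`STUDY_NETWORKS` slot into the study design;
    other stems are carried along untouched.  Hygiene is applied.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(
            f"study matrix directory {directory} not found; place the deposited "
            "interaction CSVs (bats as rows, plants as columns) there"
        )
    nets = {}
    for path in sorted(directory.glob("*.csv")):
        nets[path.stem] = drop_empty(read_matrix(path, transpose=transpose))
    if not nets:
        raise FileNotFoundError(f"no CSV matrices found under {directory}")
    return nets
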