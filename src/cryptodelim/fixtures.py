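"""Packaged copies of the published summary tables of the motivating study.

The study's raw genotypes were never deposited, but its printed summary
tables are sufficient inputs for the concordance, marker-comparison,
Mantel, and divergence-dating stages.  Two tables ship with the package:

* the cross-tabulation of SNP-based vs SSR-based cluster assignments of
  435 individuals at q > 0.5, and
* the 15-pair matrix of genetic distances (theta, Nei's D_S, Goldstein's
  (delta mu)^2) and Schoener's niche overlap D between the six clusters.

Loaders return the package's own container types so every downstream
operation can run on them unchanged.
"""

from __future__ import annotations

import csv
from importlib import resources

import numpy as np

from .cluster_concord import ConfusionTable
from .geno_io import UNDEFINED, LabeledDistanceMatrix

__all__ = [
    "PUBLISHED_ALLELE_TOTALS",
    "load_crosstab_fixture",
    "load_distance_fixtures",
]

#: Published marker totals: marker type -> (n_loci, total alleles observed).
PUBLISHED_ALLELE_TOTALS = {"SSR": (7, 65), "SNP": (67, 134)}

_CLUSTERS = ["K1", "K2", "K3", "K4", "K5", "K6"]

_COLUMN_METRICS = {
    "dmu2_ssr": "DELTA_MU_SQ",
    "fst_ssr": "FST",
    "ds_ssr": "DS",
    "fst_snp": "FST",
    "ds_snp": "DS",
    "niche_d": "NICHE_D",
}


def _read_data_csv(name: str) -> list[list[str]]:
    text = (resources.files("cryptodelim") / "data" / name).read_text(encoding="utf-8")
    return [
        next(csv.reader([line]))
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def load_crosstab_fixture() -> ConfusionTable:
    """The published 435-individual SNP x SSR assignment cross-tabulation."""
    rows = _read_data_csv("table1_crosstab.csv")
    col_labels = rows[0][1:]
    row_labels = [r[0] for r in rows[1:]]
    counts = np.array([[int(x) for x in r[1:]] for r in rows[1:]], dtype=int)
    assert UNDEFINED in row_labels and UNDEFINED in col_labels
    return ConfusionTable(row_labels, col_labels, counts)


def load_distance_fixtures() -> dict[str, LabeledDistanceMatrix]:
    """The published pairwise distance/overlap matrices, one per column.

    Keys: ``dmu2_ssr, fst_ssr, ds_ssr, fst_snp, ds_snp, niche_d``.  The
    published multi-group ("global") estimates are attached as
    ``global_value`` where available.
    """
    rows = _read_data_csv("table3_distances.csv")
    header = rows[0]
    pair_rows = [r for r in rows[1:] if r[0] != "global"]
    global_row = next((r for r in rows[1:] if r[0] == "global"), None)
    out: dict[str, LabeledDistanceMatrix] = {}
    n = len(_CLUSTERS)
    for col, metric in _COLUMN_METRICS.items():
        j = header.index(col)
        values = np.eye(n) if metric == "NICHE_D" else np.zeros((n, n))
        for r in pair_rows:
            a, b = _CLUSTERS.index(r[0]), _CLUSTERS.index(r[1])
            values[a, b] = values[b, a] = float(r[j])
        global_value = None
        if global_row is not None and global_row[j].strip():
            global_value = float(global_row[j])
        out[col] = LabeledDistanceMatrix(list(_CLUSTERS), values, metric, global_value)
    return out
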