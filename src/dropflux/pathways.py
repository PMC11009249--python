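"""Pathway-activity aggregation over differential-expression tables.

Downstream of a single-cell differential-expression analysis, the activity
of a metabolic pathway (or cellular state such as apoptosis or oxidative
stress) in a cell category is summarised as the average log2 fold change of
the significant differentially expressed genes (DEGs, p < 0.05) that belong
to the pathway's gene set. Expresser subsets (e.g. IgG-low vs IgG-high) are
split at a log2 fold-change threshold of 1 (low: log2FC <= 1).

Gene sets ship as editable YAML/JSON configuration. The bundled placeholder
sets cover the canonical pathway memberships (glycolysis, lactate
metabolism, TCA cycle, PPP, OXPHOS, fatty-acid synthesis and oxidation,
glutaminolysis, apoptosis, oxidative stress) and are meant to be replaced
by the user's curated lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_GENE_SETS",
    "PathwayActivity",
    "load_gene_sets",
    "validate_deg_table",
    "filter_degs",
    "categorize_expressers",
    "pathway_activity",
    "log2fc_to_fold",
]

# Placeholder gene sets: canonical members of each pathway, to be replaced by
# curated lists when available. Symbols are uppercase-normalized.
DEFAULT_GENE_SETS: dict[str, frozenset[str]] = {
    "glycolysis": frozenset({"HK1", "HK2", "GPI1", "PFKL", "ALDOA", "GAPDH",
                             "PGK1", "PGAM1", "ENO1", "PKM"}),
    "lactate_metabolism": frozenset({"LDHA", "LDHB", "SLC16A1", "SLC16A3"}),
    "tca_cycle": frozenset({"CS", "ACO2", "IDH2", "IDH3A", "OGDH", "SUCLA2",
                            "SDHA", "FH1", "MDH2"}),
    "ppp": frozenset({"G6PDX", "PGLS", "PGD", "TKT", "TALDO1", "RPIA"}),
    "oxphos": frozenset({"NDUFA1", "NDUFB8", "SDHB", "UQCRC1", "COX4I1",
                         "COX5A", "ATP5A1", "ATP5B"}),
    "fa_synthesis": frozenset({"ACACA", "FASN", "SCD1", "ELOVL6", "ACLY"}),
    "fa_oxidation": frozenset({"CPT1A", "CPT2", "ACADM", "ACADL", "HADHA",
                               "ECHS1"}),
    "glutaminolysis": frozenset({"GLS", "GLS2", "GLUD1", "GOT1", "GOT2",
                                 "SLC1A5"}),
    "apoptosis": frozenset({"BAX", "BAK1", "CASP3", "CASP7", "CASP9", "APAF1",
                            "BCL2L11", "TP53"}),
    "oxidative_stress": frozenset({"SOD1", "SOD2", "CAT", "GPX1", "GPX4",
                                   "NFE2L2", "TXN1", "PRDX1"}),
}


@dataclass(frozen=True)
class PathwayActivity:
    """Average log2FC of a pathway's DEGs within one cell category."""

    pathway: str
    category: str
    mean_log2fc: Optional[float]
    n_degs_used: int

    def __post_init__(self) -> None:
        if self.mean_log2fc is not None and self.n_degs_used < 1:
            raise ValueError("a reported mean requires >= 1 DEG")


def load_gene_sets(path: Union[str, Path]) -> dict[str, frozenset[str]]:
    """Read pathway gene sets from a YAML or JSON mapping of name -> genes."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ValueError("gene-set file must map pathway names to gene lists")
    sets = {}
    for name, genes in raw.items():
        genes = [str(g).upper() for g in genes]
        if not genes:
            raise ValueError(f"pathway {name!r} has an empty gene set")
        sets[str(name)] = frozenset(genes)
    return sets


def validate_deg_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the DEG table schema: gene, cluster, log2fc, p_value."""
    missing = {"gene", "cluster", "log2fc", "p_value"} - set(table.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    p = table["p_value"]
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p_value outside [0, 1]")
    if table.duplicated(subset=["gene", "cluster"]).any():
        raise ValueError("duplicate (gene, cluster) rows")
    return table


def filter_degs(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Retain DEG rows with p_value strictly below alpha."""
    validate_deg_table(table)
    return table.loc[table["p_value"] < alpha].reset_index(drop=True)


def categorize_expressers(
    expression_log2fc: Sequence[float], threshold: float = 1.0
) -> np.ndarray:
    """Split expresser values into low (log2FC <= threshold) and high."""
    values = np.asarray(expression_log2fc, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression log2FC values must be finite")
    return np.where(values <= threshold, "low", "high")


def pathway_activity(
    degs: pd.DataFrame,
    sets: Mapping[str, frozenset[str]] = DEFAULT_GENE_SETS,
    category: str = "all",
) -> list[PathwayActivity]:
    """Mean log2FC of the DEGs in each pathway gene set.

    ``degs`` should already be significance-filtered. Pathways whose gene
    sets do not intersect the DEG table are reported with ``n_degs_used=0``
    and no mean rather than raised.
    """
    if not sets:
        raise ValueError("gene sets must be nonempty")
    genes_upper = degs["gene"].str.upper()
    out = []
    for pathway, members in sets.items():
        mask = genes_upper.isin(members)
        n = int(mask.sum())
        mean = float(degs.loc[mask, "log2fc"].mean()) if n else None
        out.append(
            PathwayActivity(
                pathway=pathway, category=category, mean_log2fc=mean, n_degs_used=n
            )
        )
    return out


def log2fc_to_fold(log2fc: float) -> float:
    """Multiplicative fold change for a log2 fold change (2 -> 4, -1 -> 0.5)."""
    value = float(log2fc)
    if not np.isfinite(value):
        raise ValueError("log2fc must be finite")
    return 2.0**value
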