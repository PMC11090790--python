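"""Integration of TF binding with differential expression.

A differential-expression (DE) table is a pandas DataFrame with columns
``gene_id``, ``lfc`` (log2 fold-change) and ``pvalue`` (optionally ``padj``).
Genes are called differentially expressed with *strict* inequalities
(p < p_max and |lfc| > lfc_min), so boundary rows are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from scipy.stats import hypergeom

from .errors import InvalidParameterError, ValidationError

__all__ = [
    "DEThresholds",
    "read_de_table",
    "validate_de_table",
    "select_de_genes",
    "bound_fraction_report",
    "classify_binding_dynamics",
]


@dataclass(frozen=True)
class DEThresholds:
    """Strict DE cutoffs: keep genes with p < p_max and |lfc| > lfc_min."""

    p_max: float = 0.001
    lfc_min: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.p_max < 1):
            raise InvalidParameterError("p_max must be in (0, 1)")
        if self.lfc_min < 0:
            raise InvalidParameterError("lfc_min must be >= 0")


def validate_de_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "lfc", "pvalue"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"DE table missing columns {sorted(missing)}")
    if table["gene_id"].duplicated().any():
        raise ValidationError("DE table: duplicate gene_id")
    bad = ~((table["pvalue"] > 0) & (table["pvalue"] <= 1))
    if bad.any():
        raise ValidationError("DE table: pvalue outside (0, 1]")
    return table


def read_de_table(path) -> pd.DataFrame:
    """Read a DE TSV with header (gene_id, lfc, pvalue[, padj])."""
    return validate_de_table(pd.read_csv(path, sep="\t", float_precision="round_trip"))


def select_de_genes(
    table: pd.DataFrame,
    thresholds: DEThresholds = DEThresholds(),
    use_padj: bool = False,
) -> tuple[set[str], set[str]]:
    """Return (up, down) gene sets under strict thresholds.

    up = {p < p_max and lfc > +lfc_min}; down = {p < p_max and lfc < -lfc_min}.
    """
    validate_de_table(table)
    pcol = "padj" if use_padj else "pvalue"
    if pcol not in table.columns:
        raise InvalidParameterError(f"DE table has no '{pcol}' column")
    sig = table[pcol] < thresholds.p_max
    up = set(table.loc[sig & (table["lfc"] > thresholds.lfc_min), "gene_id"])
    down = set(table.loc[sig & (table["lfc"] < -thresholds.lfc_min), "gene_id"])
    return up, down


def _enrichment_p(class_genes: set, bound: set, universe: set) -> float:
    """Hypergeometric upper tail: P(overlap >= observed) drawing |class| genes."""
    k = len(class_genes & bound)
    return float(hypergeom.sf(k - 1, len(universe), len(bound & universe), len(class_genes)))


def bound_fraction_report(
    up: set[str],
    down: set[str],
    bound: set[str],
    universe: set[str],
) -> pd.DataFrame:
    """Fractions of bound genes among DE classes, with enrichment p-values.

    Rows: ``all_de`` (up ∪ down), ``up``, ``down``, ``background`` (whole
    universe).  Fraction = |class ∩ bound| / |class|; the one-sided p is the
    hypergeometric upper tail for drawing |class| genes from the universe.
    """
    if not universe:
        raise InvalidParameterError("empty universe")
    if not (up <= universe and down <= universe and bound <= universe):
        raise InvalidParameterError("up, down and bound must be subsets of the universe")
    bound = bound & universe
    rows = {}
    classes = {"all_de": up | down, "up": up, "down": down, "background": universe}
    for name, genes in classes.items():
        n = len(genes)
        k = len(genes & bound)
        frac = k / n if n else float("nan")
        p = _enrichment_p(genes, bound, universe) if name != "background" else 1.0
        rows[name] = {"n": n, "n_bound": k, "fraction": frac, "pvalue": p}
    return pd.DataFrame.from_dict(rows, orient="index")


def classify_binding_dynamics(
    bound_basal: set[str],
    bound_induced: set[str],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Per-gene binding dynamics across a basal→induced contrast.

    conserved = bound in both conditions; de_novo = induced only;
    lost = basal only; unbound = neither.  The returned frame carries a
    ``status`` per universe gene; ``.attrs['induced_fractions']`` holds the
    conserved/de-novo split of the induced-bound set.
    """
    universe = set(universe)
    if not (bound_basal <= universe and bound_induced <= universe):
        raise InvalidParameterError("bound sets must be subsets of the universe")

    def status(g: str) -> str:
        b, i = g in bound_basal, g in bound_induced
        if b and i:
            return "conserved"
        if i:
            return "de_novo"
        if b:
            return "lost"
        return "unbound"

    df = pd.DataFrame(
        {"gene_id": sorted(universe)}
    )
    df["status"] = df["gene_id"].map(status)
    n_induced = len(bound_induced)
    counts = df["status"].value_counts()
    df.attrs["induced_fractions"] = {
        "conserved": counts.get("conserved", 0) / n_induced if n_induced else float("nan"),
        "de_novo": counts.get("de_novo", 0) / n_induced if n_induced else float("nan"),
    }
    return df
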