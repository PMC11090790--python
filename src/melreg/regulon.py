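"""Lineage-specific regulon construction and serialization.

A regulon is a transcription factor's signed, weighted target list.  The
melanoma-specific construction intersects the genes bound by the TF in at
least two cellular contexts with the strongly differentially expressed genes
of a contrast that raises TF activity; each surviving target's mode is the
sign of its fold-change times ``tf_direction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyRegulonError, InvalidParameterError, ValidationError
from .integration import DEThresholds, select_de_genes, validate_de_table
from .signatures import GeneSignature

__all__ = [
    "RegulonTarget",
    "Regulon",
    "build_lineage_regulon",
    "regulon_overlap",
    "read_regulon",
    "write_regulon",
    "import_regulon_table",
    "regulon_to_gmt",
]


@dataclass(frozen=True)
class RegulonTarget:
    gene_id: str
    mode: int  # +1 activated with TF activity, -1 repressed
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in (-1, 1):
            raise ValidationError(f"target {self.gene_id}: mode must be -1 or +1")
        if not (0 < self.weight <= 1):
            raise ValidationError(f"target {self.gene_id}: weight must be in (0, 1]")


@dataclass
class Regulon:
    tf_name: str
    targets: list[RegulonTarget] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.gene_id for t in self.targets]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"regulon {self.tf_name}: duplicate targets")

    def __len__(self) -> int:
        return len(self.targets)

    def target_ids(self) -> set[str]:
        return {t.gene_id for t in self.targets}

    def flipped(self) -> "Regulon":
        """Same regulon with every mode negated."""
        return Regulon(
            self.tf_name,
            [RegulonTarget(t.gene_id, -t.mode, t.weight) for t in self.targets],
        )


def build_lineage_regulon(
    bound_sets: Sequence[set[str]],
    de_table: pd.DataFrame,
    thresholds: DEThresholds = DEThresholds(),
    tf_direction: int = +1,
    tf_name: str = "TF",
    weight_mode: str = "uniform",  # or 'pvalue' -> weight = 1 - p
) -> Regulon:
    """Intersect >=2 bound-gene sets with strongly DE genes into a regulon.

    ``tf_direction=+1`` when the DE contrast raises TF activity (then an
    up-regulated bound gene is an activated target, mode +1).
    """
    if len(bound_sets) < 2:
        raise InvalidParameterError("need bound-gene sets from at least 2 contexts")
    if tf_direction not in (-1, 1):
        raise InvalidParameterError("tf_direction must be -1 or +1")
    if weight_mode not in ("uniform", "pvalue"):
        raise InvalidParameterError("weight_mode must be 'uniform' or 'pvalue'")
    validate_de_table(de_table)
    candidates = set.intersection(*map(set, bound_sets))
    up, down = select_de_genes(de_table, thresholds)
    rows = de_table.set_index("gene_id")
    targets: list[RegulonTarget] = []
    for gene in sorted(candidates & (up | down)):
        lfc = float(rows.at[gene, "lfc"])
        mode = int(np.sign(lfc)) * tf_direction
        weight = 1.0
        if weight_mode == "pvalue":
            weight = max(1.0 - float(rows.at[gene, "pvalue"]), np.finfo(float).tiny)
        targets.append(RegulonTarget(gene, mode, weight))
    if not targets:
        raise EmptyRegulonError(
            f"{tf_name}: no gene survives the intersection + DE filter"
        )
    return Regulon(tf_name, targets)


def regulon_overlap(a: Regulon, b: Regulon) -> dict:
    """Shared targets and Jaccard index of two regulons' target sets."""
    ta, tb = a.target_ids(), b.target_ids()
    union = ta | tb
    return {
        "shared": ta & tb,
        "jaccard": len(ta & tb) / len(union) if union else float("nan"),
    }


def write_regulon(regulon: Regulon, path) -> None:
    """TSV with header (tf, target, mode, weight), targets sorted by gene_id."""
    df = pd.DataFrame(
        {
            "tf": regulon.tf_name,
            "target": [t.gene_id for t in regulon.targets],
            "mode": [t.mode for t in regulon.targets],
            "weight": [t.weight for t in regulon.targets],
        }
    ).sort_values("target")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_regulon(path) -> Regulon:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"tf", "target", "mode", "weight"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    tfs = df["tf"].unique()
    if len(tfs) != 1:
        raise ValidationError(f"{path}: expected exactly one tf, found {len(tfs)}")
    targets = [
        RegulonTarget(str(r.target), int(r.mode), float(r.weight))
        for r in df.itertuples(index=False)
    ]
    return Regulon(str(tfs[0]), targets)


def import_regulon_table(
    path_or_df,
    tf: Optional[str] = None,
    columns: Optional[dict] = None,
) -> Regulon:
    """Import a DoRothEA-style regulon table via a column mapping.

    ``columns`` maps the roles {tf, target, mor} (optionally ``weight``) to
    column names; default is the DoRothEA layout (tf, confidence, target,
    mor).  The sign of ``mor`` becomes the mode; weight defaults to 1.
    ``tf`` selects one TF when the table holds several.
    """
    columns = {"tf": "tf", "target": "target", "mor": "mor", **(columns or {})}
    df = (
        path_or_df
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df, sep="\t")
    )
    for role in ("tf", "target", "mor"):
        if columns[role] not in df.columns:
            raise ValidationError(f"regulon table: no column '{columns[role]}' for {role}")
    if tf is not None:
        df = df[df[columns["tf"]] == tf]
        if df.empty:
            raise ValidationError(f"regulon table: no rows for tf '{tf}'")
    else:
        tfs = df[columns["tf"]].unique()
        if len(tfs) != 1:
            raise ValidationError("regulon table holds several TFs; pass tf=...")
        tf = str(tfs[0])
    targets = []
    for r in df.itertuples(index=False):
        mor = float(getattr(r, columns["mor"]))
        if mor == 0:
            raise ValidationError(f"target {getattr(r, columns['target'])}: mor is 0")
        weight = 1.0
        if "weight" in columns and columns["weight"] in df.columns:
            weight = float(getattr(r, columns["weight"]))
        targets.append(RegulonTarget(str(getattr(r, columns["target"])), int(np.sign(mor)), weight))
    return Regulon(tf, targets)


def regulon_to_gmt(regulon: Regulon) -> list[GeneSignature]:
    """Export as two directional signatures (<TF>_up, <TF>_down)."""
    out = []
    for mode, tag in ((+1, "up"), (-1, "down")):
        genes = tuple(sorted(t.gene_id for t in regulon.targets if t.mode == mode))
        if genes:
            out.append(
                GeneSignature(
                    f"{regulon.tf_name}_{tag}",
                    genes,
                    description=f"{regulon.tf_name} {tag}-regulated targets",
                    direction=tag,
                )
            )
    return out
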