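"""Gene signatures: GMT I/O, binding coverage, and single-sample ssGSEA.

The ssGSEA statistic follows the single-sample running-sum formulation:
genes are ranked by expression (descending); walking down the ranked list,
the score accumulates, at every position, the difference between the
weighted in-set empirical CDF (weights ``|rank|^alpha``, ranks on the 1..N
scale with midranks for ties) and the unweighted out-of-set CDF.  Being a
function of ranks only, the score is invariant under strictly increasing
transforms of the profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    DegenerateInputError,
    InvalidParameterError,
    NoOverlapError,
    ParseError,
)

__all__ = [
    "GeneSignature",
    "SsgseaParams",
    "read_gmt",
    "write_gmt",
    "signature_peak_coverage",
    "ssgsea_score",
    "ssgsea_matrix",
]


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set, optionally tagged with a direction."""

    name: str
    genes: tuple[str, ...]
    description: str = ""
    direction: str = "unsigned"  # {up, down, unsigned}

    def __post_init__(self) -> None:
        if not self.genes:
            raise InvalidParameterError(f"signature {self.name}: empty gene list")
        if len(set(self.genes)) != len(self.genes):
            raise InvalidParameterError(f"signature {self.name}: duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SsgseaParams:
    weight_exponent: float = 0.25
    tie_policy: str = "midrank"
    normalization: str = "none"  # {none, global_range}

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise InvalidParameterError("weight_exponent must be >= 0")
        if self.tie_policy != "midrank":
            raise InvalidParameterError("only midrank tie policy is supported")
        if self.normalization not in ("none", "global_range"):
            raise InvalidParameterError("normalization must be 'none' or 'global_range'")


def read_gmt(path) -> list[GeneSignature]:
    """Read GMT (name, description, genes...); duplicate genes collapsed."""
    sigs: list[GeneSignature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 fields")
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            sigs.append(GeneSignature(fields[0], genes, description=fields[1]))
    return sigs


def write_gmt(signatures: Iterable[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for s in signatures:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


def signature_peak_coverage(
    signature: GeneSignature, bound_by_condition: dict[str, set[str]]
) -> pd.Series:
    """Percent of signature genes carrying a peak, per condition."""
    if len(signature) == 0:
        raise InvalidParameterError("empty signature")
    sig = set(signature.genes)
    return pd.Series(
        {
            cond: 100.0 * len(sig & bound) / len(sig)
            for cond, bound in bound_by_condition.items()
        },
        name=signature.name,
    )


def _ranked_order(profile: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Descending order (ties by gene_id for determinism) and 1..N midranks
    aligned to that order (higher expression -> higher rank)."""
    genes = profile.index.to_numpy()
    values = profile.to_numpy(dtype=float)
    order = np.lexsort((genes, -values))  # descending value, then gene_id
    ranks = rankdata(values, method="average")  # ascending midranks
    return order, ranks[order]


def ssgsea_score(
    profile: pd.Series,
    signature: GeneSignature,
    params: SsgseaParams = SsgseaParams(),
) -> float:
    """Single-sample enrichment of ``signature`` in one expression profile.

    ``profile`` maps gene_id -> expression.  Signature genes absent from the
    profile are dropped (with a warning noting the count).
    """
    if profile.index.duplicated().any():
        raise InvalidParameterError("profile has duplicate gene ids")
    n = len(profile)
    if n < 2:
        raise InvalidParameterError("profile must cover at least 2 genes")
    in_set = set(signature.genes)
    present = in_set & set(profile.index)
    dropped = len(in_set) - len(present)
    if dropped:
        warnings.warn(
            f"signature {signature.name}: {dropped} gene(s) absent from profile"
        )
    if not present:
        raise NoOverlapError(f"signature {signature.name}: no overlap with profile")
    if len(present) == n:
        raise DegenerateInputError(
            f"signature {signature.name}: covers every profiled gene"
        )
    order, ranks = _ranked_order(profile)
    genes_sorted = profile.index.to_numpy()[order]
    member = np.isin(genes_sorted, list(present))
    weights = np.abs(ranks) ** params.weight_exponent
    w_in = np.where(member, weights, 0.0)
    cdf_in = np.cumsum(w_in) / w_in.sum()
    cdf_out = np.cumsum(~member) / (n - len(present))
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_matrix(
    expr: pd.DataFrame,
    signatures: Sequence[GeneSignature],
    params: SsgseaParams = SsgseaParams(),
    on_error: str = "raise",  # or 'warn' -> NaN entry
) -> pd.DataFrame:
    """Score every signature in every column of a genes × samples matrix."""
    if expr.isna().any().any():
        raise InvalidParameterError("expression matrix contains missing values")
    out = pd.DataFrame(
        index=[s.name for s in signatures], columns=expr.columns, dtype=float
    )
    for sig in signatures:
        for col in expr.columns:
            try:
                out.loc[sig.name, col] = ssgsea_score(expr[col], sig, params)
            except (NoOverlapError, DegenerateInputError):
                if on_error == "raise":
                    raise
                warnings.warn(f"signature {sig.name}, sample {col}: score undefined")
                out.loc[sig.name, col] = np.nan
    if params.normalization == "global_range":
        rng = out.max().max() - out.min().min()
        if rng > 0:
            out = out / rng
    return out
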