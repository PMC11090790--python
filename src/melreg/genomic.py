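"""Gene models, ChIP-seq peaks and peak-to-gene promoter assignment.

Coordinate conventions
----------------------
* BED files and all in-memory ``Peak`` intervals are **0-based half-open**.
* Gene tables (TSV) are declared **1-based inclusive** and converted on read,
  so in memory a gene body is also 0-based half-open ``[start, end)``.
* The transcription start site (TSS) is the first transcribed base:
  ``start`` on the + strand, ``end - 1`` on the − strand (0-based).
* Signed TSS distances are measured in the gene's transcriptional direction:
  negative = upstream of the TSS.

The promoter window is strand-oriented.  With ``upstream=1000, downstream=0``
a peak anchor is in the promoter iff its signed distance ``d`` satisfies
``-upstream < d <= downstream`` — the conventional (−1000, +0] window around
the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import (
    EmptyInputError,
    InvalidParameterError,
    ParseError,
    ValidationError,
)

__all__ = [
    "GeneModel",
    "Peak",
    "PeakSet",
    "PromoterWindow",
    "PeakGeneAssignment",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_gtf_genes",
    "assign_peaks_to_genes",
    "localization_summary",
    "tss_distance_profile",
    "merge_intervals",
    "peakset_overlap",
    "hypergeometric_overlap_test",
    "overlap_test_from_peaksets",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene with its TSS; coordinates 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if not self.start < self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def tss(self) -> int:
        """First transcribed base (0-based)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Peak:
    """A called ChIP-seq peak, 0-based half-open."""

    chrom: str
    start: int
    end: int
    peak_id: str = ""
    score: Optional[float] = None
    summit: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"peak {self.peak_id or '?'}: start ({self.start}) must be < end ({self.end})"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"peak {self.peak_id or '?'}: summit {self.summit} outside [{self.start}, {self.end})"
            )
        if self.score is not None and self.score < 0:
            raise ValidationError(f"peak {self.peak_id or '?'}: negative score")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def anchor(self, policy: str = "summit") -> int:
        """Anchor point for promoter membership: summit when present, else midpoint."""
        if policy == "summit" and self.summit is not None:
            return self.summit
        return self.midpoint


@dataclass
class PeakSet:
    """Peaks called under one condition (e.g. basal / induced)."""

    condition_label: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.peak_id for p in self.peaks if p.peak_id]
        if len(ids) != len(set(ids)):
            raise ValidationError(
                f"peak set '{self.condition_label}': peak_ids not unique"
            )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-oriented promoter window relative to the TSS (bp)."""

    upstream: int = 1000
    downstream: int = 0

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise InvalidParameterError("promoter window extents must be non-negative")
        if self.upstream + self.downstream == 0:
            raise InvalidParameterError("promoter window must have positive extent")


@dataclass(frozen=True)
class PeakGeneAssignment:
    peak_id: str
    gene_id: Optional[str]
    category: Literal["promoter", "gene_body", "intergenic"]
    signed_tss_distance: Optional[int]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path) -> PeakSet:
    """Read a 3–6 column BED file into a :class:`PeakSet`.

    Columns beyond the first three are interpreted as name, score, strand;
    strand is ignored for peaks.  Lines starting with ``#``, ``track`` or
    ``browser`` are skipped.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start >= end")
            peak_id = fields[3] if len(fields) > 3 and fields[3] != "." else f"peak_{lineno}"
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: bad score") from exc
            peaks.append(Peak(chrom, start, end, peak_id=peak_id, score=score))
    import os

    label = os.path.splitext(os.path.basename(str(path)))[0]
    return PeakSet(condition_label=label, peaks=peaks)


def write_bed(peakset: PeakSet, path) -> None:
    """Write peaks as BED; name/score columns emitted when present."""
    with open(path, "w") as fh:
        for p in peakset:
            cols = [p.chrom, str(p.start), str(p.end)]
            if p.peak_id or p.score is not None:
                cols.append(p.peak_id or ".")
            if p.score is not None:
                cols.append(f"{p.score:g}")
            fh.write("\t".join(cols) + "\n")


def read_gene_table(path) -> list[GeneModel]:
    """Read a gene-model TSV (gene_id, chrom, strand, start, end; 1-based inclusive).

    Converted to 0-based half-open on read.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene_id")
    genes = [
        GeneModel(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            strand=str(r.strand),
            start=int(r.start) - 1,
            end=int(r.end),
        )
        for r in df.itertuples(index=False)
    ]
    return genes


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    """Inverse of :func:`read_gene_table` (emits 1-based inclusive coordinates)."""
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start": [g.start + 1 for g in genes],
            "end": [g.end for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_gtf_genes(path) -> list[GeneModel]:
    """Minimal GTF reader: keeps ``gene`` features, gene_id from attributes."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: line {lineno}: fewer than 9 fields")
            if fields[2] != "gene":
                continue
            attrs = fields[8]
            gene_id = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gene_id = part.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise ParseError(f"{path}: line {lineno}: no gene_id attribute")
            if gene_id in seen:
                raise ValidationError(f"{path}: duplicate gene_id {gene_id}")
            seen.add(gene_id)
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=fields[0],
                    strand=fields[6],
                    start=int(fields[3]) - 1,  # GTF is 1-based inclusive
                    end=int(fields[4]),
                )
            )
    return genes


# ---------------------------------------------------------------------------
# Peak -> gene assignment
# ---------------------------------------------------------------------------

def signed_tss_distance(gene: GeneModel, position: int) -> int:
    """Distance of ``position`` from the TSS in the gene's orientation."""
    d = position - gene.tss
    return d if gene.strand == "+" else -d


def _promoter_interval(gene: GeneModel, window: PromoterWindow) -> tuple[int, int]:
    """Genomic half-open interval of anchor positions with -up < d <= +down."""
    if gene.strand == "+":
        # d = pos - tss in (-up, +down]  =>  pos in [tss-up+1, tss+down+1)
        return gene.tss - window.upstream + 1, gene.tss + window.downstream + 1
    # d = tss - pos in (-up, +down]  =>  pos in [tss-down, tss+up)
    return gene.tss - window.downstream, gene.tss + window.upstream


def assign_peaks_to_genes(
    peaks: PeakSet,
    genes: Iterable[GeneModel],
    window: PromoterWindow = PromoterWindow(),
    anchor: str = "summit",
) -> list[PeakGeneAssignment]:
    """Assign each peak to exactly one category (and at most one gene).

    Promoter beats gene body; among multiple eligible genes the one with
    the smallest ``|signed_tss_distance|`` wins, ties broken by lexicographic
    ``gene_id``.  Peaks on chromosomes absent from the annotation are
    intergenic.  Deterministic in the peak input order.
    """
    if anchor not in ("summit", "midpoint"):
        raise InvalidParameterError("anchor must be 'summit' or 'midpoint'")
    genes = list(genes)
    promoter_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    by_id = {g.gene_id: g for g in genes}
    if len(by_id) != len(genes):
        raise ValidationError("gene_id not unique within annotation")
    for g in genes:
        lo, hi = _promoter_interval(g, window)
        if lo < hi:
            promoter_trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.gene_id)
        body_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)

    def best(gene_ids: Iterable[str], pos: int) -> tuple[str, int]:
        # smallest |distance|, then lexicographic gene_id
        return min(
            ((gid, signed_tss_distance(by_id[gid], pos)) for gid in gene_ids),
            key=lambda t: (abs(t[1]), t[0]),
        )

    out: list[PeakGeneAssignment] = []
    for p in peaks:
        pos = p.anchor(anchor)
        hits = promoter_trees.get(p.chrom, IntervalTree())[pos]
        if hits:
            gid, d = best((h.data for h in hits), pos)
            out.append(PeakGeneAssignment(p.peak_id, gid, "promoter", d))
            continue
        hits = body_trees.get(p.chrom, IntervalTree())[pos]
        if hits:
            gid, d = best((h.data for h in hits), pos)
            out.append(PeakGeneAssignment(p.peak_id, gid, "gene_body", d))
            continue
        out.append(PeakGeneAssignment(p.peak_id, None, "intergenic", None))
    return out


def bound_genes(assignments: Iterable[PeakGeneAssignment],
                categories: tuple[str, ...] = ("promoter", "gene_body")) -> set[str]:
    """Genes with at least one peak assigned in the given categories."""
    return {a.gene_id for a in assignments if a.gene_id and a.category in categories}


def localization_summary(assignments: Sequence[PeakGeneAssignment]) -> pd.DataFrame:
    """Per-category peak counts and fractions (fractions sum to 1)."""
    if not assignments:
        raise EmptyInputError("no assignments")
    counts = pd.Series([a.category for a in assignments]).value_counts()
    df = pd.DataFrame({"count": counts})
    df["fraction"] = df["count"] / df["count"].sum()
    return df


def tss_distance_profile(
    assignments: Sequence[PeakGeneAssignment], bin_width: int = 500
) -> pd.Series:
    """Histogram of signed TSS distances for gene-assigned peaks.

    Returns counts indexed by the left edge of each ``bin_width``-wide bin
    (bin edges at integer multiples of ``bin_width``); total mass equals the
    number of assignments with a gene.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be positive")
    dists = np.array(
        [a.signed_tss_distance for a in assignments if a.gene_id is not None],
        dtype=int,
    )
    if dists.size == 0:
        return pd.Series(dtype=int)
    lefts = (np.floor_divide(dists, bin_width)) * bin_width
    return pd.Series(lefts).value_counts().sort_index()


# ---------------------------------------------------------------------------
# Peak-set comparison
# ---------------------------------------------------------------------------

def _overlap_bp(a: Peak, b: Peak) -> int:
    if a.chrom != b.chrom:
        return 0
    return min(a.end, b.end) - max(a.start, b.start)


def peakset_overlap(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1) -> dict:
    """Partition two peak sets into shared/unique peaks.

    A peak of ``a`` is *shared* iff it overlaps at least one peak of ``b``
    by >= ``min_overlap_bp`` bp (and symmetrically).  Returns the four peak
    lists plus ``conserved_fraction_a`` = |shared_a| / |a|.
    """
    if min_overlap_bp < 1:
        raise InvalidParameterError("min_overlap_bp must be >= 1")

    def shared_mask(xs: PeakSet, ys: PeakSet) -> list[bool]:
        trees: dict[str, IntervalTree] = {}
        for y in ys:
            trees.setdefault(y.chrom, IntervalTree()).addi(y.start, y.end)
        mask = []
        for x in xs:
            tree = trees.get(x.chrom)
            ok = False
            if tree is not None:
                for iv in tree[x.start:x.end]:
                    if min(x.end, iv.end) - max(x.start, iv.begin) >= min_overlap_bp:
                        ok = True
                        break
            mask.append(ok)
        return mask

    ma = shared_mask(a, b)
    mb = shared_mask(b, a)
    shared_a = [p for p, m in zip(a, ma) if m]
    return {
        "shared_a": shared_a,
        "unique_a": [p for p, m in zip(a, ma) if not m],
        "shared_b": [p for p, m in zip(b, mb) if m],
        "unique_b": [p for p, m in zip(b, mb) if not m],
        "conserved_fraction_a": len(shared_a) / len(a) if len(a) else float("nan"),
    }


def merge_intervals(peaks: Iterable[Peak]) -> list[Peak]:
    """Merge overlapping/abutting peaks into non-overlapping loci per chromosome."""
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    merged: list[Peak] = []
    for chrom in sorted(by_chrom):
        ivs = sorted((p.start, p.end) for p in by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(Peak(chrom, cur_s, cur_e, peak_id=f"{chrom}:{cur_s}-{cur_e}"))
                cur_s, cur_e = s, e
        merged.append(Peak(chrom, cur_s, cur_e, peak_id=f"{chrom}:{cur_s}-{cur_e}"))
    return merged


def hypergeometric_overlap_test(k: int, n_a: int, n_b: int, universe_n: int) -> float:
    """Upper-tail P(X >= k) that two sets of sizes n_a, n_b drawn from a
    universe of universe_n share at least k elements."""
    if not (0 <= k <= min(n_a, n_b) <= universe_n) or max(n_a, n_b) > universe_n:
        raise InvalidParameterError(
            f"inconsistent margins: k={k}, n_a={n_a}, n_b={n_b}, N={universe_n}"
        )
    from scipy.stats import hypergeom

    return float(hypergeom.sf(k - 1, universe_n, n_a, n_b))


def overlap_test_from_peaksets(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1) -> dict:
    """Venn-style significance of peak-set overlap.

    The universe is the union of both sets' peaks merged into non-overlapping
    loci; a locus counts for a set when a peak of that set overlaps it by
    >= ``min_overlap_bp``.  Returns counts and the hypergeometric upper-tail p.
    """
    loci = PeakSet("universe", merge_intervals(list(a) + list(b)))
    hit_a = peakset_overlap(loci, a, min_overlap_bp)
    hit_b = peakset_overlap(loci, b, min_overlap_bp)
    in_a = {p.peak_id for p in hit_a["shared_a"]}
    in_b = {p.peak_id for p in hit_b["shared_a"]}
    k = len(in_a & in_b)
    result = {
        "universe_n": len(loci),
        "n_a": len(in_a),
        "n_b": len(in_b),
        "k": k,
    }
    result["pvalue"] = hypergeometric_overlap_test(k, len(in_a), len(in_b), len(loci))
    return result
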