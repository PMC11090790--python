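"""Synthetic data with attached ground truth for every pipeline stage.

Every generator is a pure function of a :class:`SimulationConfig`: the single
top-level seed fans out to per-generator substreams by fixed offsets, so the
same config always yields the same files and adding a generator never
perturbs another's draws.

What the generators emulate
---------------------------
* ChIP-seq peaks concentrated in strand-oriented promoter windows (default
  62% of peaks), with a basal condition holding half as many peaks as the
  induced one and a planted conserved fraction (default 33% of induced peaks
  carried over from basal).
* DE tables in which bound genes are enriched among DE genes by a
  configurable odds multiplier, with planted DE calls exactly recoverable by
  the strict thresholds (p < p_max, |lfc| > lfc_min).
* Expression matrices with a planted per-cell regulon activity θ acting on
  signed targets: x_gj = baseline_g + mode_g · θ_j · effect + N(0, noise_sd).
* Spatial cell tables with clonal structure: Gaussian-blob clones whose
  marker levels encode the antagonism of a ZEB1-high clone (low
  MITF/SOX10/ZEB2, elevated NGFR/SOX9) plus a small triple-positive clone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.optimize import brentq

from .errors import InvalidParameterError
from .genomic import GeneModel, Peak, PeakSet, PromoterWindow
from .regulon import Regulon, RegulonTarget
from .spatial import DEFAULT_COMPARTMENTS, DEFAULT_LEVELS, MarkerLevelScheme

__all__ = [
    "SimulationConfig",
    "CloneSpec",
    "GroundTruth",
    "default_clone_layout",
    "simulate_annotation_and_peaks",
    "simulate_de_table",
    "simulate_regulon_inputs",
    "simulate_expression",
    "simulate_cell_table",
    "simulate_all",
]

# substream offsets: adding a generator must not perturb existing streams
_STREAM_PEAKS = 1
_STREAM_DE = 2
_STREAM_EXPR = 3
_STREAM_CELLS = 4
_STREAM_REGULON = 5


@dataclass(frozen=True)
class CloneSpec:
    """A spatial clone: Gaussian blob + planted marker levels."""

    name: str
    center: tuple[float, float]
    radius: float
    fraction: float
    levels: dict  # marker -> planted level name


def default_clone_layout() -> list[CloneSpec]:
    """Four tumor clones spanning the dedifferentiation axis.

    The ZEB1-high clones carry low MITF/SOX10/ZEB2 and elevated NGFR/SOX9;
    5% of tumor cells form a ZEB1/NGFR/SOX9 triple-positive clone.
    """
    return [
        CloneSpec(
            "differentiated", (300.0, 300.0), 120.0, 0.45,
            {"ZEB1": "not_expressed", "ZEB2": "high", "MITF": "high",
             "SOX10": "high", "SOX9": "not_expressed", "NGFR": "not_expressed"},
        ),
        CloneSpec(
            "early", (700.0, 350.0), 100.0, 0.15,
            {"ZEB1": "low", "ZEB2": "intermediate", "MITF": "intermediate",
             "SOX10": "high", "SOX9": "low", "NGFR": "not_expressed"},
        ),
        CloneSpec(
            "transitory", (350.0, 700.0), 100.0, 0.15,
            {"ZEB1": "intermediate", "ZEB2": "low", "MITF": "low",
             "SOX10": "low", "SOX9": "low", "NGFR": "not_expressed"},
        ),
        CloneSpec(
            "zeb1_high", (750.0, 750.0), 110.0, 0.20,
            {"ZEB1": "high", "ZEB2": "low", "MITF": "not_expressed",
             "SOX10": "low", "SOX9": "intermediate", "NGFR": "high"},
        ),
        CloneSpec(
            "triple_positive", (550.0, 550.0), 60.0, 0.05,
            {"ZEB1": "high", "ZEB2": "not_expressed", "MITF": "not_expressed",
             "SOX10": "not_expressed", "SOX9": "high", "NGFR": "high"},
        ),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for all generators; ``seed`` is mandatory."""

    seed: int
    # annotation / peaks
    n_genes: int = 2000
    n_peaks: int = 2000            # induced condition; basal holds basal_ratio as many
    basal_ratio: float = 0.5
    promoter_fraction: float = 0.62
    conserved_fraction: float = 0.33
    gene_spacing: int = 20_000
    peak_width: int = 300
    chrom_length: Optional[int] = None  # per chromosome; None -> sized to fit
    # differential expression
    de_fraction: float = 0.25
    bound_de_enrichment: float = 3.0
    p_max: float = 0.001
    lfc_min: float = 1.0
    # expression / activity
    n_true_targets: int = 25
    activity_levels: tuple[float, ...] = (0.0, 2.0)
    activity_effect: float = 1.0
    noise_sd: float = 1.0
    n_cells: int = 400
    # spatial cells
    n_cells_spatial: int = 1000
    intensity_sigma: float = 0.25   # log-scale sd of intensities
    clone_layout: Optional[tuple[CloneSpec, ...]] = None

    def __post_init__(self) -> None:
        for name in ("promoter_fraction", "conserved_fraction", "de_fraction",
                     "basal_ratio"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise InvalidParameterError(f"{name} must be in [0, 1]")
        if self.noise_sd <= 0 or self.intensity_sigma <= 0:
            raise InvalidParameterError("noise scales must be positive")
        if self.peak_width % 2:
            raise InvalidParameterError("peak_width must be even")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class GroundTruth:
    """Planted labels sufficient to evaluate every downstream stage."""

    peak_labels: dict = field(default_factory=dict)   # condition -> {peak_id: {category, gene_id, distance}}
    bound: dict = field(default_factory=dict)         # condition -> sorted gene list
    de_flags: dict = field(default_factory=dict)      # gene_id -> {de, lfc_sign}
    target_modes: dict = field(default_factory=dict)  # gene_id -> mode for true targets
    theta: dict = field(default_factory=dict)         # cell_id -> planted activity
    cell_groups: dict = field(default_factory=dict)   # cell_id -> group label
    clone_of_cell: dict = field(default_factory=dict)
    planted_levels: dict = field(default_factory=dict)  # cell_id -> {marker: level}
    scheme_cutoffs: dict = field(default_factory=dict)  # marker -> [cutoffs]

    def bound_sets(self) -> dict[str, set[str]]:
        return {cond: set(genes) for cond, genes in self.bound.items()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# annotation + peaks
# ---------------------------------------------------------------------------

def _place_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    n = config.n_genes
    per_chrom = (n + 1) // 2
    needed = per_chrom * config.gene_spacing + config.gene_spacing
    if config.chrom_length is not None and config.chrom_length < needed:
        raise InvalidParameterError(
            f"chrom_length {config.chrom_length} too small for "
            f"{per_chrom} genes at spacing {config.gene_spacing}"
        )
    genes = []
    width = len(str(n))
    for i in range(n):
        chrom = "chr1" if i < per_chrom else "chr2"
        slot = i if i < per_chrom else i - per_chrom
        base = slot * config.gene_spacing + 5000
        length = int(rng.integers(2000, 10001))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(f"g{str(i).zfill(width)}", chrom, strand, base, base + length)
        )
    return genes


def _peak_at(chrom: str, pos: int, width: int, peak_id: str) -> Peak:
    start = pos - width // 2
    return Peak(chrom, start, start + width, peak_id=peak_id, summit=pos)


def simulate_annotation_and_peaks(
    config: SimulationConfig,
) -> tuple[list[GeneModel], dict[str, PeakSet], GroundTruth]:
    """Synthetic gene annotation plus basal/induced peak sets.

    Peak categories are drawn per peak (promoter with probability
    ``promoter_fraction``, remainder split between gene body and intergenic);
    promoter anchors land inside the strand-oriented (−1000, +0] window.  The
    induced set carries ``conserved_fraction`` of its peaks over from basal
    (identical coordinates); de-novo induced peaks are rejection-sampled to
    avoid overlapping any basal peak.
    """
    rng = config.rng(_STREAM_PEAKS)
    genes = _place_genes(config, rng)
    window = PromoterWindow(1000, 0)
    truth = GroundTruth()

    basal_trees: dict[str, IntervalTree] = {}

    def draw_peak(idx: int, prefix: str, avoid: Optional[dict] = None):
        """One peak with its planted label; rejection sampling against `avoid`.

        The category is drawn once and only the placement is retried, so the
        planted category fractions are exact Bernoulli draws even when
        placements collide with existing peaks."""
        u = rng.random()
        if u < config.promoter_fraction:
            category = "promoter"
        elif u < config.promoter_fraction + (1 - config.promoter_fraction) / 2:
            category = "gene_body"
        else:
            category = "intergenic"
        for _ in range(100):
            if category == "intergenic":
                gi = int(rng.integers(len(genes)))
                g = genes[gi]
                slot_base = g.start - 5000
                pos = int(rng.integers(slot_base + 16100, slot_base + 19400))
                gene_id, dist = None, None
                chrom = g.chrom
            else:
                gi = int(rng.integers(len(genes)))
                g = genes[gi]
                chrom = g.chrom
                if category == "promoter":
                    d = -int(rng.integers(0, window.upstream))  # d in [-999, 0]
                    pos = g.tss + d if g.strand == "+" else g.tss - d
                    gene_id, dist = g.gene_id, d
                else:  # gene_body: anchor strictly downstream of the TSS base
                    if g.strand == "+":
                        pos = int(rng.integers(g.start + 1, g.end))
                    else:
                        pos = int(rng.integers(g.start, g.end - 1))
                    gene_id = g.gene_id
                    dist = pos - g.tss if g.strand == "+" else g.tss - pos
            peak = _peak_at(chrom, pos, config.peak_width, f"{prefix}_{idx}")
            if avoid is not None:
                tree = avoid.get(chrom)
                if tree is not None and tree[peak.start:peak.end]:
                    continue
            return peak, {"category": category, "gene_id": gene_id, "distance": dist}
        raise InvalidParameterError("could not place a non-overlapping peak")

    n_basal = int(round(config.n_peaks * config.basal_ratio))
    n_conserved = int(round(config.n_peaks * config.conserved_fraction))
    if n_conserved > n_basal:
        raise InvalidParameterError(
            "conserved_fraction * n_peaks exceeds the basal peak count"
        )

    basal_peaks, basal_labels = [], {}
    for i in range(n_basal):
        p, lab = draw_peak(i, "basal")
        basal_peaks.append(p)
        basal_labels[p.peak_id] = lab
        basal_trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)

    conserved_idx = rng.choice(n_basal, size=n_conserved, replace=False)
    induced_peaks, induced_labels = [], {}
    for j, bi in enumerate(sorted(int(i) for i in conserved_idx)):
        src = basal_peaks[bi]
        p = Peak(src.chrom, src.start, src.end, peak_id=f"induced_{j}", summit=src.summit)
        induced_peaks.append(p)
        induced_labels[p.peak_id] = dict(basal_labels[src.peak_id])
    for j in range(n_conserved, config.n_peaks):
        p, lab = draw_peak(j, "induced", avoid=basal_trees)
        induced_peaks.append(p)
        induced_labels[p.peak_id] = lab

    truth.peak_labels = {"basal": basal_labels, "induced": induced_labels}
    truth.bound = {
        cond: sorted(
            {lab["gene_id"] for lab in labels.values() if lab["gene_id"] is not None}
        )
        for cond, labels in truth.peak_labels.items()
    }
    peaksets = {
        "basal": PeakSet("basal", basal_peaks),
        "induced": PeakSet("induced", induced_peaks),
    }
    return genes, peaksets, truth


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _odds_prob(p0: float, mult: float) -> float:
    odds = mult * p0 / (1 - p0)
    return odds / (1 + odds)


def simulate_de_table(
    config: SimulationConfig,
    truth: GroundTruth,
    gene_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """DE table in which bound genes are DE-enriched by an odds multiplier.

    Planted DE genes draw p strictly below ``p_max`` and |lfc| strictly above
    ``lfc_min`` (construction guarantees recovery by the strict thresholds);
    non-DE genes draw p ~ U(0,1) and |lfc| < lfc_min.  DE flags and fold-
    change signs are recorded in ``truth.de_flags``.
    """
    rng = config.rng(_STREAM_DE)
    if gene_ids is None:
        width = len(str(config.n_genes))
        gene_ids = [f"g{str(i).zfill(width)}" for i in range(config.n_genes)]
    bound = set(truth.bound.get("induced", []))
    b = len(bound & set(gene_ids)) / len(gene_ids)
    mult = config.bound_de_enrichment
    target = config.de_fraction
    if b in (0.0, 1.0) or mult == 1.0:
        p_unbound = p_bound = target
    else:
        f = lambda p0: (1 - b) * p0 + b * _odds_prob(p0, mult) - target
        p_unbound = brentq(f, 1e-12, 1 - 1e-9)
        p_bound = _odds_prob(p_unbound, mult)

    rows = []
    for g in gene_ids:
        p_de = p_bound if g in bound else p_unbound
        is_de = rng.random() < p_de
        sign = 1 if rng.random() < 0.5 else -1
        if is_de:
            lfc = sign * (config.lfc_min + 1e-6 + rng.exponential(0.8))
            pval = 10.0 ** rng.uniform(-8.0, np.log10(config.p_max) - 0.05)
        else:
            lfc = sign * rng.uniform(0.0, config.lfc_min * 0.999)
            pval = rng.uniform(1e-9, 1.0)
        rows.append({"gene_id": g, "lfc": lfc, "pvalue": pval})
        truth.de_flags[g] = {"de": bool(is_de), "lfc_sign": int(sign)}
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regulon-recovery inputs
# ---------------------------------------------------------------------------

def simulate_regulon_inputs(
    config: SimulationConfig,
    n_genes: int = 500,
    n_decoys_bound_only: int = 50,
    n_decoys_de_only: int = 50,
    n_decoys_one_context: int = 50,
) -> tuple[list[set[str]], pd.DataFrame, Regulon]:
    """Inputs for ground-truth regulon recovery.

    Plants ``config.n_true_targets`` genes bound in *both* contexts and
    strongly DE, plus decoys that are bound-in-both but not DE, DE but
    unbound, or bound in only one context.  Returns (bound sets for the two
    contexts, DE table, the true regulon).
    """
    rng = config.rng(_STREAM_REGULON)
    n_true = config.n_true_targets
    if n_true + n_decoys_bound_only + n_decoys_de_only + n_decoys_one_context > n_genes:
        raise InvalidParameterError("too many planted genes for n_genes")
    width = len(str(n_genes))
    gene_ids = [f"g{str(i).zfill(width)}" for i in range(n_genes)]
    perm = list(rng.permutation(gene_ids))
    true = perm[:n_true]
    bound_only = perm[n_true:n_true + n_decoys_bound_only]
    de_only = perm[n_true + n_decoys_bound_only:
                   n_true + n_decoys_bound_only + n_decoys_de_only]
    one_ctx = perm[n_true + n_decoys_bound_only + n_decoys_de_only:
                   n_true + n_decoys_bound_only + n_decoys_de_only + n_decoys_one_context]

    ctx1 = set(true) | set(bound_only) | set(one_ctx)
    ctx2 = set(true) | set(bound_only)

    rows, targets = [], []
    de_genes = set(true) | set(de_only)
    for g in gene_ids:
        sign = 1 if rng.random() < 0.5 else -1
        if g in de_genes:
            lfc = sign * (config.lfc_min + 1e-6 + rng.exponential(0.8))
            pval = 10.0 ** rng.uniform(-8.0, np.log10(config.p_max) - 0.05)
        else:
            lfc = sign * rng.uniform(0.0, config.lfc_min * 0.999)
            pval = rng.uniform(1e-9, 1.0)
        rows.append({"gene_id": g, "lfc": lfc, "pvalue": pval})
        if g in true:
            targets.append(RegulonTarget(g, int(np.sign(lfc))))
    regulon = Regulon("TF_true", sorted(targets, key=lambda t: t.gene_id))
    return [ctx1, ctx2], pd.DataFrame(rows), regulon


# ---------------------------------------------------------------------------
# expression with planted activity
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
    regulon: Optional[Regulon] = None,
    theta: Optional[Sequence[float]] = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, Regulon, GroundTruth]:
    """Expression matrix (genes × cells) with planted per-cell activity θ.

    ``x_gj = baseline_g + mode_g · θ_j · effect + N(0, noise_sd)`` for target
    genes (mode 0 otherwise).  When ``theta`` is not given, cells split
    evenly over ``config.activity_levels`` as discrete groups.  Returns
    (expr, theta, groups, regulon, truth).
    """
    rng = config.rng(_STREAM_EXPR)
    width = len(str(config.n_genes))
    gene_ids = [f"g{str(i).zfill(width)}" for i in range(config.n_genes)]
    if regulon is None:
        if config.n_true_targets > config.n_genes:
            raise InvalidParameterError("n_true_targets exceeds n_genes")
        chosen = rng.choice(config.n_genes, size=config.n_true_targets, replace=False)
        regulon = Regulon(
            "TF_sim",
            [
                RegulonTarget(gene_ids[int(i)], 1 if rng.random() < 0.5 else -1)
                for i in sorted(chosen)
            ],
        )
    modes = pd.Series(0.0, index=gene_ids)
    for t in regulon.targets:
        modes[t.gene_id] = t.mode

    n_cells = config.n_cells
    cell_ids = [f"c{str(j).zfill(len(str(n_cells)))}" for j in range(n_cells)]
    if theta is None:
        levels = list(config.activity_levels)
        reps = int(np.ceil(n_cells / len(levels)))
        theta_arr = np.array((levels * reps)[:n_cells], dtype=float)
        group_lab = [f"theta={v:g}" for v in theta_arr]
    else:
        theta_arr = np.asarray(theta, dtype=float)
        if len(theta_arr) != n_cells:
            raise InvalidParameterError("theta length must equal n_cells")
        group_lab = ["all"] * n_cells
    theta_s = pd.Series(theta_arr, index=cell_ids, name="theta")
    groups = pd.Series(group_lab, index=cell_ids, name="group")

    baseline = rng.normal(5.0, 2.0, size=config.n_genes)
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_cells))
    x = baseline[:, None] + np.outer(modes.to_numpy(), theta_arr) * config.activity_effect + noise
    expr = pd.DataFrame(x, index=gene_ids, columns=cell_ids)

    truth = GroundTruth(
        target_modes={t.gene_id: t.mode for t in regulon.targets},
        theta={c: float(v) for c, v in theta_s.items()},
        cell_groups=dict(groups),
    )
    return expr, theta_s, groups, regulon, truth


# ---------------------------------------------------------------------------
# spatial cell tables
# ---------------------------------------------------------------------------

# geometric ladder of mean intensities per level; 5x spacing gives clean
# separation at intensity_sigma = 0.25 (log-scale)
_LEVEL_MEANS = {"not_expressed": 1.0, "low": 5.0, "intermediate": 25.0, "high": 125.0}


def _scheme_from_levels(marker: str, levels: tuple[str, ...]) -> MarkerLevelScheme:
    """Cutoffs at geometric midpoints between consecutive level means."""
    means = [_LEVEL_MEANS[lv] for lv in levels]
    cutoffs = tuple(float(np.sqrt(a * b)) for a, b in zip(means, means[1:]))
    return MarkerLevelScheme(marker, levels, cutoffs, DEFAULT_COMPARTMENTS[marker])


def truth_schemes() -> list[MarkerLevelScheme]:
    """Level schemes whose cutoffs separate the generator's level populations."""
    return [_scheme_from_levels(m, lv) for m, lv in DEFAULT_LEVELS.items()]


def simulate_cell_table(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Spatial per-cell table with clonal marker co-expression structure.

    Tumor cells are assigned to clones multinomially by clone fraction and
    placed as Gaussian blobs; each marker intensity is log-normal around the
    clone's planted level mean.  10% extra stroma and 5% epidermis cells are
    added with background (not-expressed) intensities.
    """
    rng = config.rng(_STREAM_CELLS)
    layout = list(config.clone_layout) if config.clone_layout else default_clone_layout()
    if not layout:
        raise InvalidParameterError("clone_layout must be non-empty")
    fr = np.array([c.fraction for c in layout], dtype=float)
    if not np.isclose(fr.sum(), 1.0):
        raise InvalidParameterError("clone fractions must sum to 1")
    n_tumor = config.n_cells_spatial
    assignment = rng.choice(len(layout), size=n_tumor, p=fr)
    counts = np.bincount(assignment, minlength=len(layout))
    import warnings as _warnings

    for clone, c in zip(layout, counts):
        if c == 0:
            _warnings.warn(f"clone '{clone.name}' received zero cells")

    markers = list(DEFAULT_LEVELS)
    rows = []
    truth = GroundTruth(scheme_cutoffs={s.marker: list(s.cutoffs) for s in truth_schemes()})
    n_total = n_tumor + int(0.10 * n_tumor) + int(0.05 * n_tumor)
    zw = len(str(n_total))
    cid = 0

    def intensity(level: str) -> float:
        return float(np.exp(rng.normal(np.log(_LEVEL_MEANS[level]), config.intensity_sigma)))

    for ci in assignment:
        clone = layout[ci]
        cell_id = f"cell{str(cid).zfill(zw)}"
        cid += 1
        x = float(rng.normal(clone.center[0], clone.radius / 2))
        y = float(rng.normal(clone.center[1], clone.radius / 2))
        row = {"cell_id": cell_id, "x": x, "y": y, "tissue_class": "tumor"}
        for m in markers:
            level = clone.levels.get(m, "not_expressed")
            row[f"{m}_{DEFAULT_COMPARTMENTS[m]}"] = intensity(level)
        rows.append(row)
        truth.clone_of_cell[cell_id] = clone.name
        truth.planted_levels[cell_id] = {m: clone.levels.get(m, "not_expressed") for m in markers}

    for tissue, n_extra in (("stroma", int(0.10 * n_tumor)), ("epidermis", int(0.05 * n_tumor))):
        for _ in range(n_extra):
            cell_id = f"cell{str(cid).zfill(zw)}"
            cid += 1
            row = {
                "cell_id": cell_id,
                "x": float(rng.uniform(0, 1100)),
                "y": float(rng.uniform(0, 1100)),
                "tissue_class": tissue,
            }
            for m in markers:
                row[f"{m}_{DEFAULT_COMPARTMENTS[m]}"] = intensity("not_expressed")
            rows.append(row)
            truth.clone_of_cell[cell_id] = tissue
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# one-call emission of every input file
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig, outdir) -> dict:
    """Emit genes.tsv, peaks_*.bed, de.tsv, sets.gmt, expr.tsv, cells.csv,
    truth.json under ``outdir``; returns the in-memory objects."""
    import os

    from .genomic import write_bed, write_gene_table
    from .signatures import GeneSignature, write_gmt

    os.makedirs(outdir, exist_ok=True)
    genes, peaksets, truth = simulate_annotation_and_peaks(config)
    write_gene_table(genes, os.path.join(outdir, "genes.tsv"))
    for cond, ps in peaksets.items():
        write_bed(ps, os.path.join(outdir, f"peaks_{cond}.bed"))

    de = simulate_de_table(config, truth, gene_ids=[g.gene_id for g in genes])
    de.to_csv(os.path.join(outdir, "de.tsv"), sep="\t", index=False)

    # signatures from planted structure: bound+down (proliferative-like)
    # and bound+up (invasive-like)
    bound = set(truth.bound["induced"])
    up = {g for g, f in truth.de_flags.items() if f["de"] and f["lfc_sign"] > 0}
    down = {g for g, f in truth.de_flags.items() if f["de"] and f["lfc_sign"] < 0}
    sigs = []
    for name, genes_set in (
        ("bound_down_like", bound & down),
        ("bound_up_like", bound & up),
    ):
        if genes_set:
            sigs.append(GeneSignature(name, tuple(sorted(genes_set))))
    if sigs:
        write_gmt(sigs, os.path.join(outdir, "sets.gmt"))

    expr, theta, groups, regulon, expr_truth = simulate_expression(config)
    expr.to_csv(os.path.join(outdir, "expr.tsv"), sep="\t")
    truth.target_modes = expr_truth.target_modes
    truth.theta = expr_truth.theta
    truth.cell_groups = expr_truth.cell_groups

    cells, cell_truth = simulate_cell_table(config)
    cells.to_csv(os.path.join(outdir, "cells.csv"), index=False)
    truth.clone_of_cell = cell_truth.clone_of_cell
    truth.planted_levels = cell_truth.planted_levels
    truth.scheme_cutoffs = cell_truth.scheme_cutoffs

    truth.to_json(os.path.join(outdir, "truth.json"))
    return {
        "genes": genes,
        "peaksets": peaksets,
        "de": de,
        "signatures": sigs,
        "expr": expr,
        "theta": theta,
        "groups": groups,
        "regulon": regulon,
        "cells": cells,
        "truth": truth,
    }
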