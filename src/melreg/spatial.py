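"""Cutoff-based single-cell phenotyping of multiplexed-immunofluorescence data.

Cell tables are pandas DataFrames with one row per segmented cell:
``cell_id, x, y, tissue_class`` plus one intensity column per
marker/compartment named ``<Marker>_<compartment>`` (e.g. ``ZEB1_nuclear``,
``NGFR_membrane``).  Level calls use lower-inclusive half-open bins: a cell
gets the highest level whose lower cutoff is <= its intensity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import InvalidParameterError, ValidationError

__all__ = [
    "MarkerLevelScheme",
    "DEFAULT_LEVELS",
    "DEFAULT_COMPARTMENTS",
    "LEVEL_COLORS",
    "read_cell_table",
    "write_cell_table",
    "classify_marker_levels",
    "quantile_schemes",
    "marker_by_group_comparison",
    "cooccurrence_summary",
    "reconstruction_export",
    "plot_reconstruction",
]

TISSUE_CLASSES = ("epidermis", "stroma", "tumor")

# Level vocabularies per marker: most markers carry four levels; SOX10 is
# scored on three and NGFR on two (positive/negative staining behaviour).
DEFAULT_LEVELS: dict[str, tuple[str, ...]] = {
    "ZEB1": ("not_expressed", "low", "intermediate", "high"),
    "ZEB2": ("not_expressed", "low", "intermediate", "high"),
    "MITF": ("not_expressed", "low", "intermediate", "high"),
    "SOX9": ("not_expressed", "low", "intermediate", "high"),
    "SOX10": ("not_expressed", "low", "high"),
    "NGFR": ("not_expressed", "high"),
}

# Antibody localization convention: nuclear TFs, membrane receptor NGFR.
DEFAULT_COMPARTMENTS: dict[str, str] = {
    "ZEB1": "nuclear",
    "ZEB2": "nuclear",
    "MITF": "nuclear",
    "SOX9": "nuclear",
    "SOX10": "nuclear",
    "NGFR": "membrane",
}

LEVEL_COLORS = {
    "high": "red",
    "intermediate": "yellow",
    "low": "blue",
    "not_expressed": "grey",
}


@dataclass(frozen=True)
class MarkerLevelScheme:
    """Ordered levels and ascending cutoffs for one marker/compartment."""

    marker: str
    levels: tuple[str, ...]
    cutoffs: tuple[float, ...]
    compartment: str = "nuclear"

    def __post_init__(self) -> None:
        if len(self.cutoffs) != len(self.levels) - 1:
            raise ValidationError(
                f"{self.marker}: need exactly {len(self.levels) - 1} cutoffs "
                f"for {len(self.levels)} levels"
            )
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValidationError(f"{self.marker}: cutoffs must be strictly ascending")
        if self.compartment not in ("nuclear", "cytoplasmic", "membrane"):
            raise ValidationError(f"{self.marker}: unknown compartment")

    @property
    def column(self) -> str:
        return f"{self.marker}_{self.compartment}"

    def call(self, intensity) -> np.ndarray:
        """Lower-inclusive binning: highest level whose lower cutoff <= x."""
        idx = np.searchsorted(np.asarray(self.cutoffs), np.asarray(intensity), side="right")
        return np.asarray(self.levels, dtype=object)[idx]


def read_cell_table(path, column_map: Optional[dict] = None) -> pd.DataFrame:
    """Read a per-cell CSV, renaming columns via ``column_map`` (file -> canonical).

    Canonical columns are ``cell_id, x, y, tissue_class`` and
    ``<Marker>_<compartment>`` intensities.  Validates coordinate finiteness
    and intensity non-negativity; non-tumor rows are retained.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    for col in ("cell_id", "x", "y", "tissue_class"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column '{col}'")
    if not np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all():
        raise ValidationError(f"{path}: non-finite coordinates")
    intensity_cols = [
        c for c in df.columns
        if c.endswith(("_nuclear", "_cytoplasmic", "_membrane"))
    ]
    for col in intensity_cols:
        if (df[col] < 0).any():
            raise ValidationError(f"{path}: negative intensity in '{col}'")
    unknown = set(df["tissue_class"]) - set(TISSUE_CLASSES)
    if unknown:
        raise ValidationError(f"{path}: unknown tissue_class values {sorted(unknown)}")
    return df


def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def classify_marker_levels(
    cells: pd.DataFrame,
    schemes: Sequence[MarkerLevelScheme],
    restrict_to: str = "tumor",
) -> pd.DataFrame:
    """Per-marker level calls for cells of ``restrict_to`` tissue class.

    Returns a DataFrame indexed by cell_id with one categorical column per
    marker.  Monotone in intensity and invariant to row order.
    """
    sub = cells[cells["tissue_class"] == restrict_to]
    calls = pd.DataFrame(index=pd.Index(sub["cell_id"], name="cell_id"))
    for scheme in schemes:
        if scheme.column not in cells.columns:
            raise ValidationError(f"no intensity column '{scheme.column}'")
        calls[scheme.marker] = pd.Categorical(
            scheme.call(sub[scheme.column].to_numpy(dtype=float)),
            categories=list(scheme.levels),
            ordered=True,
        )
    return calls


def quantile_schemes(
    cells: pd.DataFrame,
    markers: Iterable[str] = tuple(DEFAULT_LEVELS),
    restrict_to: str = "tumor",
) -> list[MarkerLevelScheme]:
    """Quantile-based cutoffs from the tumor-cell intensity distribution.

    For a k-level marker the cutoffs sit at the i/k quantiles (i = 1..k-1);
    for the four-level markers that is 0.25/0.5/0.75.  These are synthetic
    working defaults, not calibrated biological thresholds.
    """
    sub = cells[cells["tissue_class"] == restrict_to]
    schemes = []
    for marker in markers:
        levels = DEFAULT_LEVELS[marker]
        compartment = DEFAULT_COMPARTMENTS[marker]
        col = f"{marker}_{compartment}"
        if col not in cells.columns:
            raise ValidationError(f"no intensity column '{col}'")
        k = len(levels)
        qs = [i / k for i in range(1, k)]
        cutoffs = tuple(float(sub[col].quantile(q)) for q in qs)
        schemes.append(MarkerLevelScheme(marker, levels, cutoffs, compartment))
    return schemes


def marker_by_group_comparison(
    calls: pd.DataFrame,
    cells: pd.DataFrame,
    y_marker: str,
    group_marker: str,
    y_compartment: Optional[str] = None,
    group_levels: Optional[Sequence[str]] = None,
) -> dict:
    """Compare ``y_marker`` intensity across ``group_marker`` level groups.

    Cells are partitioned by their ``group_marker`` level call; ``y_marker``
    intensity is compared between every pair of groups with a two-sided
    Mann-Whitney rank-sum test, Bonferroni-corrected over the pairs actually
    tested.  Groups with fewer than 2 cells are excluded with a warning.
    Returns per-group n/median summaries and the pairwise test table.
    """
    if group_marker not in calls.columns:
        raise InvalidParameterError(f"no level calls for '{group_marker}'")
    y_compartment = y_compartment or DEFAULT_COMPARTMENTS.get(y_marker, "nuclear")
    ycol = f"{y_marker}_{y_compartment}"
    if ycol not in cells.columns:
        raise InvalidParameterError(f"no intensity column '{ycol}'")
    y = cells.set_index("cell_id").loc[calls.index, ycol]
    levels = list(group_levels) if group_levels else list(calls[group_marker].cat.categories)
    groups: dict[str, np.ndarray] = {}
    for level in levels:
        vals = y[(calls[group_marker] == level).to_numpy()].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(f"group '{level}': fewer than 2 cells, excluded")
            continue
        groups[level] = vals
    if len(groups) < 2:
        raise InvalidParameterError("need at least 2 non-empty groups")
    summary = pd.DataFrame(
        {
            "n": {g: len(v) for g, v in groups.items()},
            "median": {g: float(np.median(v)) for g, v in groups.items()},
        }
    )
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    rows = []
    for g1, g2 in pairs:
        a, b = groups[g1], groups[g2]
        # exact null distribution for small tie-free groups, normal
        # approximation otherwise
        tie_free = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        method = "exact" if (len(a) <= 8 and len(b) <= 8 and tie_free) else "asymptotic"
        stat, p = mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append(
            {
                "group_a": g1,
                "group_b": g2,
                "U": float(stat),
                "pvalue": float(p),
                "p_bonferroni": min(1.0, m * float(p)),
            }
        )
    return {"summary": summary, "tests": pd.DataFrame(rows), "n_tests": m}


def cooccurrence_summary(
    calls: pd.DataFrame, markers: Sequence[str]
) -> pd.Series:
    """Joint level counts over the Cartesian product of level vocabularies.

    Index: MultiIndex over marker levels (all combinations, zeros included);
    values: cell counts.  Marginal sums reproduce the per-marker compositions.
    """
    for m in markers:
        if m not in calls.columns:
            raise InvalidParameterError(f"no level calls for '{m}'")
    vocab = [list(calls[m].cat.categories) for m in markers]
    full = pd.MultiIndex.from_product(vocab, names=list(markers))
    counts = calls.groupby(list(markers), observed=False).size()
    return counts.reindex(full, fill_value=0)


def reconstruction_export(
    cells: pd.DataFrame, calls: pd.DataFrame, marker: str
) -> pd.DataFrame:
    """Whole-slide dot-map records for one marker: (cell_id, x, y, level, color).

    Colors follow the convention high→red, intermediate→yellow, low→blue,
    not expressed→grey.  Plain table consumable by any plotting layer.
    """
    if marker not in calls.columns:
        raise InvalidParameterError(f"no level calls for '{marker}'")
    pos = cells.set_index("cell_id").loc[calls.index, ["x", "y"]]
    out = pd.DataFrame(
        {
            "cell_id": calls.index,
            "x": pos["x"].to_numpy(),
            "y": pos["y"].to_numpy(),
            "level": calls[marker].astype(str).to_numpy(),
        }
    )
    out["color"] = out["level"].map(LEVEL_COLORS)
    return out


def plot_reconstruction(export: pd.DataFrame, ax=None, dot_size: float = 4.0):
    """Render a dot-map reconstruction (optional raster convenience)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for level, color in LEVEL_COLORS.items():
        sub = export[export["level"] == level]
        if len(sub):
            ax.scatter(sub["x"], sub["y"], s=dot_size, c=color, label=level, linewidths=0)
    ax.set_aspect("equal")
    ax.legend(markerscale=3, fontsize=8)
    return ax
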