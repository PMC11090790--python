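"""Independent brute-force / enumeration oracles used by the tests.

Everything here is deliberately naive (quadratic scans, exhaustive
enumeration, explicit loops) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


# --- peak -> gene assignment: all-pairs quadratic scan -----------------------

def brute_force_assign(peaks, genes, upstream, downstream, anchor="summit"):
    """List of (peak_id, gene_id, category, distance) by scanning every pair."""
    out = []
    for p in peaks:
        if anchor == "summit" and p.summit is not None:
            pos = p.summit
        else:
            pos = (p.start + p.end) // 2
        prom, body = [], []
        for g in genes:
            if g.chrom != p.chrom:
                continue
            d = pos - g.tss if g.strand == "+" else g.tss - pos
            if -upstream < d <= downstream:
                prom.append((abs(d), g.gene_id, d))
            elif g.start <= pos < g.end:
                body.append((abs(d), g.gene_id, d))
        if prom:
            _, gid, d = min(prom)
            out.append((p.peak_id, gid, "promoter", d))
        elif body:
            _, gid, d = min(body)
            out.append((p.peak_id, gid, "gene_body", d))
        else:
            out.append((p.peak_id, None, "intergenic", None))
    return out


# --- interval overlap: O(|a|*|b|) scan ---------------------------------------

def brute_force_shared(a_peaks, b_peaks, min_overlap_bp):
    """Boolean mask over a_peaks: overlaps any b peak by >= min_overlap_bp."""
    mask = []
    for x in a_peaks:
        ok = False
        for y in b_peaks:
            if x.chrom == y.chrom and min(x.end, y.end) - max(x.start, y.start) >= min_overlap_bp:
                ok = True
                break
        mask.append(ok)
    return mask


# --- hypergeometric upper tail by exhaustive enumeration ---------------------

def enumerate_overlap_tail(k, n_a, n_b, universe_n):
    """P(|A ∩ B| >= k) over all equally likely B of size n_b; A fixed."""
    a = set(range(n_a))
    hits = sum(
        1
        for b in itertools.combinations(range(universe_n), n_b)
        if len(a & set(b)) >= k
    )
    return hits / comb(universe_n, n_b)


# --- ssGSEA running sum: explicit loop re-implementation ---------------------

def naive_ssgsea(values: dict, in_set, alpha):
    """Barbie-style running sum computed with explicit loops.

    values: gene -> expression; in_set: genes in the signature (must overlap
    and not cover the namespace).  Midranks on the 1..N scale, descending
    walk with ties ordered by gene id.
    """
    genes = sorted(values, key=lambda g: (-values[g], g))
    n = len(genes)
    # midranks ascending in value
    by_val = sorted(values.items(), key=lambda kv: kv[1])
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j + 1 < n and by_val[j + 1][1] == by_val[i][1]:
            j += 1
        mid = (i + j) / 2 + 1  # average of 1-based positions
        for t in range(i, j + 1):
            ranks[by_val[t][0]] = mid
        i = j + 1
    members = set(in_set) & set(values)
    w_total = sum(abs(ranks[g]) ** alpha for g in genes if g in members)
    n_out = n - len(members)
    score, cum_in, cum_out = 0.0, 0.0, 0.0
    for g in genes:
        if g in members:
            cum_in += abs(ranks[g]) ** alpha / w_total
        else:
            cum_out += 1.0 / n_out
        score += cum_in - cum_out
    return score


# --- weighted two-tailed enrichment: direct evaluation -----------------------

def midrank_normal_scores(values, gene_ids):
    """Standard-normal quantiles of midranks (population-standardized),
    by explicit counting."""
    from scipy.stats import norm

    values = list(values)
    n = len(values)
    z = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        midrank = less + (equal + 1) / 2
        z.append(norm.ppf(midrank / (n + 1)))
    mean = sum(z) / n
    sd = (sum((zi - mean) ** 2 for zi in z) / n) ** 0.5
    z = [(zi - mean) / sd for zi in z]
    return dict(zip(gene_ids, z))


def exhaustive_label_permutation_null(z_values, modes, weights):
    """es over every permutation of gene labels; returns (mean, sd)."""
    k = len(modes)
    w_sum = sum(weights)
    draws = []
    for perm in itertools.permutations(z_values):
        es = sum(m * w * zz for m, w, zz in zip(modes, weights, perm[:k])) / w_sum
        draws.append(es)
    arr = np.array(draws)
    return float(arr.mean()), float(arr.std(ddof=0))


# --- Mann-Whitney two-sided p by exhaustive relabelling ----------------------

def exact_mannwhitney_two_sided(x, y):
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    combined = x + y
    mu = n1 * n2 / 2

    def u_stat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_stat(x, y)
    count = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        sel = set(idx)
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(n1 + n2) if i not in sel]
        if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


# --- binomial 99% acceptance band --------------------------------------------

def binomial_99_band(n, p):
    """(lo, hi) counts of the central 99% of Binomial(n, p)."""
    from scipy.stats import binom

    return int(binom.ppf(0.005, n, p)), int(binom.ppf(0.995, n, p))


# --- random genomic fixtures --------------------------------------------------

def random_genes(rng, n, chroms=("chr1", "chr2"), span=1_000_000):
    from melreg.genomic import GeneModel

    genes = []
    for i in range(n):
        start = int(rng.integers(0, span - 20_000))
        length = int(rng.integers(500, 15_000))
        genes.append(
            GeneModel(
                f"g{i:03d}",
                str(rng.choice(chroms)),
                "+" if rng.random() < 0.5 else "-",
                start,
                start + length,
            )
        )
    return genes


def random_peaks(rng, n, label, chroms=("chr1", "chr2"), span=1_000_000,
                 with_summit=True):
    from melreg.genomic import Peak, PeakSet

    peaks = []
    for i in range(n):
        start = int(rng.integers(0, span - 2000))
        width = int(rng.integers(50, 1500))
        summit = int(rng.integers(start, start + width)) if with_summit else None
        peaks.append(
            Peak(str(rng.choice(chroms)), start, start + width,
                 peak_id=f"{label}_{i}", summit=summit)
        )
    return PeakSet(label, peaks)
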