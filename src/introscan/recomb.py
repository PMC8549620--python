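"""Admixture-vs-recombination and cross-taxon correlation tests.

If recombination shaped local admixture levels (e.g. by breaking up
deleterious introgressed haplotypes faster in high-recombination regions),
local admixture proportions should correlate with recombination rate, and
the two admixed taxa should show correlated admixture landscapes.  Both
are tested with Pearson correlation / least-squares regression, genome-wide
and per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .types import RecombinationMap, warn


@dataclass
class CorrelationResult:
    r: float
    df: int  # n - 2
    p_two_sided: float
    slope: float
    intercept: float
    scope: str = "global"
    n: int = 0

    @property
    def significant(self) -> bool:
        return self.p_two_sided < 0.05


def interpolate_rate(rmap: RecombinationMap, chrom, positions):
    """Piecewise-constant rate of the enclosing map interval per position.

    Positions outside the map range take the nearest boundary interval's
    rate; the returned flag array marks them.
    """
    return rmap.rate_at(chrom, positions)


def correlate(x, y, scope: str = "global") -> CorrelationResult:
    """Pearson r with the t-transform p-value (df = n - 2) and the
    least-squares line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return CorrelationResult(
        r=float(r),
        df=n - 2,
        p_two_sided=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        scope=scope,
        n=n,
    )


def admixture_vs_recombination(
    profile,
    rmap: RecombinationMap,
    scope: str = "both",
    alpha: float = 0.05,
    bh_correct: bool = False,
):
    """Correlate per-SNP admixture proportion with local recombination rate.

    Returns ``(global_result, per_chromosome_dict)``; either element is
    None when excluded by ``scope`` ("global", "per_chromosome", "both").
    Chromosomes missing from the map, or with < 3 mapped SNPs, are skipped
    with a warning.  ``bh_correct`` applies Benjamini-Hochberg across the
    per-chromosome p-values (stored as ``p_adjusted`` attributes).
    """
    xs, ys = [], []
    per_chrom = {}
    for c in profile.chromosomes():
        sel = profile.chrom == c
        try:
            rate, _ = rmap.rate_at(c, profile.pos_bp[sel])
        except KeyError:
            warn(f"chromosome {c} absent from recombination map; SNPs dropped")
            continue
        y = profile.admix_prop[sel]
        xs.append(rate)
        ys.append(y)
        if scope in ("per_chromosome", "both"):
            if len(y) < 3 or rate.std() == 0 or y.std() == 0:
                warn(f"chromosome {c}: too few mapped SNPs or zero variance; skipped")
                continue
            per_chrom[c] = correlate(rate, y, scope=str(c))
    if bh_correct and per_chrom:
        order = sorted(per_chrom, key=lambda c: per_chrom[c].p_two_sided)
        m = len(order)
        adj_prev = 1.0
        for rank, c in reversed(list(enumerate(order, 1))):
            adj = min(per_chrom[c].p_two_sided * m / rank, adj_prev)
            per_chrom[c].p_adjusted = adj
            adj_prev = adj
    global_res = None
    if scope in ("global", "both") and xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if x.std() == 0 or y.std() == 0:
            warn("zero variance in rate or admixture; global correlation undefined")
        else:
            global_res = correlate(x, y, scope="global")
    return global_res, (per_chrom if scope in ("per_chromosome", "both") else None)


def cross_taxon_correlation(profile_a, profile_b, scope: str = "both"):
    """Correlate two taxa's admixture profiles over their shared SNP set.

    SNPs are matched on (chrom, pos); an empty intersection is an error.
    Returns ``(global_result, per_chromosome_dict)`` as above.
    """
    key_a = {(c, p): i for i, (c, p) in enumerate(zip(profile_a.chrom, profile_a.pos_bp))}
    idx_a, idx_b = [], []
    for i, (c, p) in enumerate(zip(profile_b.chrom, profile_b.pos_bp)):
        j = key_a.get((c, p))
        if j is not None:
            idx_a.append(j)
            idx_b.append(i)
    if not idx_a:
        raise ValueError("profiles share no SNPs")
    idx_a = np.array(idx_a)
    idx_b = np.array(idx_b)
    a = profile_a.admix_prop[idx_a]
    b = profile_b.admix_prop[idx_b]
    chroms = profile_a.chrom[idx_a]
    global_res = correlate(a, b, scope="global") if scope in ("global", "both") else None
    per_chrom = None
    if scope in ("per_chromosome", "both"):
        per_chrom = {}
        for c in sorted(set(chroms.tolist()), key=str):
            sel = chroms == c
            if sel.sum() < 3 or a[sel].std() == 0 or b[sel].std() == 0:
                continue
            per_chrom[c] = correlate(a[sel], b[sel], scope=str(c))
    return global_res, per_chrom
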