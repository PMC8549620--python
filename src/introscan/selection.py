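"""Extended haplotype homozygosity (EHH) and the standardized iHS statistic.

EHH at offset x from a core SNP is the probability that two randomly
chosen carrier haplotypes of a given core allele are identical at every
SNP from the core through x:

    EHH(x) = sum_i C(e_i, 2) / C(n, 2)

where n is the number of carrier haplotypes and e_i are the sizes of the
groups of carriers identical over the window.  iHH is the trapezoid
integral of the EHH decay away from the core, truncated (with linear
interpolation) where EHH first drops below 0.05.  The unstandardized
statistic ln(iHH_A / iHH_D) is standardized to zero mean / unit SD within
derived-allele-frequency bins, so that under neutrality iHS ~ N(0, 1) and
a two-sided normal p-value applies.  Positive selection on the derived
allele drives iHS strongly negative; |iHS| > 2 is the conventional signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .types import MISSING, HaplotypePanel


@dataclass
class EHHCurve:
    """EHH decay in one direction from a core SNP for one core allele."""

    core_index: int
    allele: str  # "ancestral" or "derived"
    direction: str  # "upstream" (decreasing position) or "downstream"
    distance_bp: np.ndarray  # offsets from the core, starting at 0
    ehh: np.ndarray  # starts at 1, non-increasing
    n_carriers: int
    valid: bool

    def reached(self, cutoff: float = 0.05) -> bool:
        return bool((self.ehh < cutoff).any())


@dataclass
class StandardizationBins:
    """Derived-frequency bins used to standardize ln(iHH_A/iHH_D)."""

    edges: np.ndarray
    group_of_bin: np.ndarray  # merged-group id per elementary bin
    mean: dict  # group id -> mean of uniHS
    sd: dict  # group id -> SD of uniHS
    count: dict  # group id -> n records


def _decay_groups(hap: np.ndarray, rows: np.ndarray, cols) -> list:
    """EHH values at each column of ``cols`` walking outward from the core.

    Carrier haplotypes hitting a missing allele are dropped from the group
    structure at that site but the denominator stays at the initial carrier
    count, keeping the curve non-increasing.
    """
    n0 = len(rows)
    denom = n0 * (n0 - 1) / 2.0
    labels = np.zeros(n0, dtype=np.int64)
    active = np.ones(n0, dtype=bool)
    values = []
    for j in cols:
        a = hap[rows, j]
        active &= a != MISSING
        key = labels * 2 + np.where(a == MISSING, 0, a)
        _, labels = np.unique(key, return_inverse=True)
        if active.any():
            _, counts = np.unique(labels[active], return_counts=True)
            val = float((counts * (counts - 1) / 2.0).sum() / denom)
        else:
            val = 0.0
        values.append(val)
    return values


def ehh(
    panel: HaplotypePanel,
    core_index: int,
    allele: str = "derived",
    direction: str = "downstream",
    ancestral: np.ndarray | None = None,
    stop_below: float | None = None,
) -> EHHCurve:
    """EHH decay curve for carriers of one core allele in one direction.

    ``ancestral`` gives the ancestral allele code (0/1) per SNP; by default
    the 0-coded (reference) allele is treated as ancestral.  ``stop_below``
    truncates the walk once EHH falls below the value (the curve keeps the
    first sub-threshold point so integration can interpolate the crossing).
    """
    anc = _ancestral_codes(panel, ancestral)
    code = anc[core_index] if allele == "ancestral" else 1 - anc[core_index]
    rows = np.flatnonzero(panel.hap_matrix[:, core_index] == code)
    chrom = panel.chrom[core_index]
    chrom_cols = np.flatnonzero(panel.chrom == chrom)
    if direction == "downstream":
        cols = chrom_cols[chrom_cols > core_index]
    elif direction == "upstream":
        cols = chrom_cols[chrom_cols < core_index][::-1]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if len(rows) < 2:
        return EHHCurve(core_index, allele, direction, np.array([0.0]), np.array([1.0]),
                        len(rows), valid=False)
    dist = [0.0]
    vals = [1.0]
    core_pos = panel.pos_bp[core_index]
    for j, v in zip(cols, _decay_groups(panel.hap_matrix, rows, cols)):
        dist.append(float(abs(panel.pos_bp[j] - core_pos)))
        vals.append(v)
        if stop_below is not None and v < stop_below:
            break
    return EHHCurve(
        core_index, allele, direction, np.array(dist), np.array(vals), len(rows), valid=True
    )


def _ancestral_codes(panel: HaplotypePanel, ancestral) -> np.ndarray:
    if ancestral is None:
        return np.zeros(panel.n_snps, dtype=np.int8)
    ancestral = np.asarray(ancestral, dtype=np.int8)
    if ancestral.shape != (panel.n_snps,):
        raise ValueError("ancestral must give one allele code per SNP")
    return ancestral


def ihh(curve: EHHCurve, cutoff: float = 0.05) -> tuple[float, bool]:
    """Trapezoid integral of an EHH curve over distance, truncated at the
    first crossing of ``cutoff`` (linear interpolation).

    Returns ``(area, reached)``; ``reached`` is False when the curve never
    falls below the cutoff (the integral to the last point is returned but
    the record should be flagged invalid by the caller).
    """
    d, e = curve.distance_bp, curve.ehh
    area = 0.0
    for k in range(1, len(d)):
        if e[k] < cutoff:
            # interpolate the crossing between k-1 and k
            frac = (e[k - 1] - cutoff) / (e[k - 1] - e[k])
            d_star = d[k - 1] + frac * (d[k] - d[k - 1])
            area += (e[k - 1] + cutoff) / 2.0 * (d_star - d[k - 1])
            return area, True
        area += (e[k - 1] + e[k]) / 2.0 * (d[k] - d[k - 1])
    return area, False


def _core_ihh(hap, rows, core_local, positions, cutoff, max_gap) -> tuple[float, bool]:
    """iHH for one carrier set: sum of upstream and downstream integrals."""
    if len(rows) < 2:
        return np.nan, False
    n = hap.shape[1]
    total = 0.0
    ok = True
    for step in (1, -1):
        if step == 1:
            cols = range(core_local + 1, n)
        else:
            cols = range(core_local - 1, -1, -1)
        cols = list(cols)
        dist = [abs(positions[j] - positions[core_local]) for j in cols]
        area, reached = _walk_ihh(hap, rows, cols, dist, cutoff, max_gap)
        total += area
        ok &= reached
    return total, ok


def _walk_ihh(hap, rows, cols, dist, cutoff, max_gap) -> tuple[float, bool]:
    """Incremental EHH walk with on-the-fly trapezoid integration."""
    n0 = len(rows)
    denom = n0 * (n0 - 1) / 2.0
    labels = np.zeros(n0, dtype=np.int64)
    active = np.ones(n0, dtype=bool)
    area, prev_e, prev_d = 0.0, 1.0, 0.0
    sub = hap[rows]
    for j, d in zip(cols, dist):
        if max_gap is not None and d - prev_d > max_gap:
            return area, False
        a = sub[:, j]
        active &= a != MISSING
        key = labels * 2 + np.where(a == MISSING, 0, a)
        _, labels = np.unique(key, return_inverse=True)
        if active.any():
            _, counts = np.unique(labels[active], return_counts=True)
            v = float((counts * (counts - 1) / 2.0).sum() / denom)
        else:
            v = 0.0
        if v < cutoff:
            frac = (prev_e - cutoff) / (prev_e - v)
            d_star = prev_d + frac * (d - prev_d)
            area += (prev_e + cutoff) / 2.0 * (d_star - prev_d)
            return area, True
        area += (prev_e + v) / 2.0 * (d - prev_d)
        prev_e, prev_d = v, d
    return area, False


def ihs_scan(
    panel: HaplotypePanel,
    ancestral: np.ndarray | None = None,
    maf_min: float = 0.05,
    bin_width: float = 0.025,
    cutoff: float = 0.05,
    min_bin_count: int = 10,
    max_gap: float | None = None,
    rmap=None,
    return_bins: bool = False,
):
    """Genome-wide iHS scan over all cores with derived frequency in
    [maf_min, 1 - maf_min].

    Integration is over physical distance (bp) by default; passing a
    :class:`~introscan.types.RecombinationMap` as ``rmap`` switches to
    genetic distance (cM).  Cores whose EHH does not reach ``cutoff``
    before the chromosome end (for either allele, either side) are flagged
    invalid and excluded from standardization.

    Returns a DataFrame with one row per tested core: chrom, pos, freq_der,
    ihh_a, ihh_d, unihs, ihs, p_value, valid.
    """
    anc = _ancestral_codes(panel, ancestral)
    records = []
    for c in panel.chromosomes():
        cols = np.flatnonzero(panel.chrom == c)
        hap = panel.hap_matrix[:, cols]
        if rmap is not None:
            positions = rmap.genetic_position(c, panel.pos_bp[cols])
        else:
            positions = panel.pos_bp[cols].astype(float)
        anc_c = anc[cols]
        der = np.where(anc_c == 0, 1, 0)
        obs = hap != MISSING
        n_obs = obs.sum(axis=0)
        freq_der = np.where(
            n_obs > 0, (hap == der[None, :]).sum(axis=0) / np.maximum(n_obs, 1), 0.0
        )
        for local in range(len(cols)):
            f = freq_der[local]
            if not (maf_min <= f <= 1 - maf_min):
                continue
            rows_a = np.flatnonzero(hap[:, local] == anc_c[local])
            rows_d = np.flatnonzero(hap[:, local] == der[local])
            ihh_a, ok_a = _core_ihh(hap, rows_a, local, positions, cutoff, max_gap)
            ihh_d, ok_d = _core_ihh(hap, rows_d, local, positions, cutoff, max_gap)
            valid = ok_a and ok_d and ihh_a > 0 and ihh_d > 0
            unihs = np.log(ihh_a / ihh_d) if valid else np.nan
            records.append(
                {
                    "chrom": c,
                    "pos": int(panel.pos_bp[cols[local]]),
                    "freq_der": float(f),
                    "ihh_a": ihh_a,
                    "ihh_d": ihh_d,
                    "unihs": unihs,
                    "valid": valid,
                }
            )
    df = pd.DataFrame(records)
    if len(df) == 0:
        df = pd.DataFrame(
            columns=["chrom", "pos", "freq_der", "ihh_a", "ihh_d", "unihs", "valid"]
        )
    df, bins = _standardize(df, bin_width, min_bin_count)
    return (df, bins) if return_bins else df


def _standardize(df: pd.DataFrame, bin_width: float, min_bin_count: int):
    """Bin-wise standardization of uniHS on derived frequency.

    Elementary bins of width ``bin_width`` partition (0, 1); bins with
    fewer than ``min_bin_count`` valid records are merged with the nearest
    (by bin centre) non-empty neighbour group until all groups qualify.
    """
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    df = df.copy()
    df["ihs"] = np.nan
    df["p_value"] = np.nan
    valid = df["valid"].to_numpy(dtype=bool) if len(df) else np.array([], dtype=bool)
    if valid.sum() == 0:
        bins = StandardizationBins(edges, np.arange(n_bins), {}, {}, {})
        return df, bins

    freq = df["freq_der"].to_numpy()
    bin_of = np.clip(np.floor(freq / bin_width).astype(int), 0, n_bins - 1)
    group_of_bin = np.arange(n_bins)

    def group_counts():
        g = group_of_bin[bin_of[valid]]
        return {gid: int(n) for gid, n in zip(*np.unique(g, return_counts=True))}

    counts = group_counts()
    # merge undersized groups with the nearest occupied neighbour
    while True:
        small = [g for g, n in counts.items() if n < min_bin_count]
        if not small or len(counts) == 1:
            break
        g = min(small, key=lambda gid: counts[gid])
        centres = {
            gid: np.mean([b for b in range(n_bins) if group_of_bin[b] == gid])
            for gid in counts
        }
        others = [gid for gid in counts if gid != g]
        nearest = min(others, key=lambda gid: abs(centres[gid] - centres[g]))
        group_of_bin[group_of_bin == g] = nearest
        counts = group_counts()

    group = group_of_bin[bin_of]
    means, sds = {}, {}
    for gid in counts:
        vals = df.loc[valid & (group == gid), "unihs"].to_numpy()
        means[gid] = float(vals.mean())
        sds[gid] = float(vals.std(ddof=0))
    sd_arr = np.array([sds.get(g, np.nan) for g in group])
    mean_arr = np.array([means.get(g, np.nan) for g in group])
    with np.errstate(invalid="ignore", divide="ignore"):
        ihs = (df["unihs"].to_numpy() - mean_arr) / sd_arr
    ihs[~valid] = np.nan
    df["ihs"] = ihs
    df["p_value"] = 2.0 * norm.sf(np.abs(ihs))
    bins = StandardizationBins(edges, group_of_bin, means, sds, counts)
    return df, bins


def significant_snps(records: pd.DataFrame, p_max: float = 0.05, ihs_min: float = 2.0):
    """Records with p < ``p_max`` AND |iHS| > ``ihs_min`` (strict)."""
    ok = (
        records["valid"]
        & (records["p_value"] < p_max)
        & (records["ihs"].abs() > ihs_min)
    )
    return records[ok.fillna(False)]


def bonferroni_significant(
    records: pd.DataFrame, alpha: float = 0.05, scope: str = "per_chromosome"
):
    """Records passing a Bonferroni threshold over the tested SNPs.

    ``per_chromosome`` divides alpha by the number of valid tested SNPs on
    the record's own chromosome; ``global`` by the genome-wide count.
    """
    valid = records["valid"].fillna(False)
    if scope == "per_chromosome":
        m = records.loc[valid].groupby("chrom")["pos"].transform("size")
        m = m.reindex(records.index)
        thr = alpha / m
    elif scope == "global":
        thr = alpha / valid.sum()
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return records[(valid & (records["p_value"] < thr)).fillna(False)]
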