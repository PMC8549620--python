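"""Detection of chromosomal blocks with outlying hybrid ancestry.

A per-SNP admixture profile (mean donor dosage / 2 across admixed
individuals) is scanned for maximal runs of consecutive SNPs whose
admixture proportion exceeds the mean by more than ``k_sd`` standard
deviations (over-represented hybrid ancestry, "OHA" blocks), or falls
below an absolute threshold (ancestry deserts).  Runs shorter than
``min_snps`` are discarded to control false positives.  The mean and SD
are taken either per chromosome (each chromosome is an independent
recombinational unit) or globally across all autosomal SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AncestryBlock, AncestryDosageMatrix, chrom_sort_key, warn


@dataclass
class SNPAdmixtureProfile:
    """Mean donor-ancestry proportion per SNP across admixed individuals."""

    chrom: np.ndarray
    pos_bp: np.ndarray
    admix_prop: np.ndarray
    n_individuals: int

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.admix_prop = np.asarray(self.admix_prop, dtype=float)
        if ((self.admix_prop < 0) | (self.admix_prop > 1)).any():
            raise ValueError("admix_prop must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return len(self.admix_prop)

    def chromosomes(self) -> list:
        return sorted(set(self.chrom.tolist()), key=chrom_sort_key)


@dataclass
class ChromStats:
    """Per-chromosome and global mean/SD of the admixture profile."""

    per_chrom: dict  # chrom -> (mean, sd, n_snps)
    global_mean: float
    global_sd: float
    n_snps: int
    ddof: int = 0
    excluded: list = field(default_factory=list)


def snp_admixture_profile(dosages: AncestryDosageMatrix, admixed_ids=None) -> SNPAdmixtureProfile:
    """Per-SNP mean donor proportion (dosage / 2) over the admixed individuals."""
    if admixed_ids is None:
        rows = np.arange(dosages.n_individuals)
    else:
        admixed_ids = list(admixed_ids)
        if not admixed_ids:
            raise ValueError("admixed_ids must be non-empty")
        index = {s: i for i, s in enumerate(dosages.individual_ids)}
        missing = [s for s in admixed_ids if s not in index]
        if missing:
            raise ValueError(f"unknown individual ids: {missing}")
        rows = np.array([index[s] for s in admixed_ids])
    prop = dosages.dosage[rows].mean(axis=0) / 2.0
    return SNPAdmixtureProfile(
        chrom=dosages.chrom, pos_bp=dosages.pos_bp, admix_prop=prop, n_individuals=len(rows)
    )


def chromosome_stats(profile: SNPAdmixtureProfile, ddof: int = 0) -> ChromStats:
    """Mean/SD of admix_prop per chromosome and globally.

    The default is the population SD (``ddof=0``); single-SNP chromosomes are
    excluded with a warning.
    """
    per = {}
    excluded = []
    for c in profile.chromosomes():
        v = profile.admix_prop[profile.chrom == c]
        if len(v) < 2:
            warn(f"chromosome {c} has a single SNP; excluded from stats")
            excluded.append(c)
            continue
        per[c] = (float(v.mean()), float(v.std(ddof=ddof)), len(v))
    keep = ~np.isin(profile.chrom.astype(str), [str(c) for c in excluded])
    v = profile.admix_prop[keep]
    return ChromStats(
        per_chrom=per,
        global_mean=float(v.mean()),
        global_sd=float(v.std(ddof=ddof)),
        n_snps=int(len(v)),
        ddof=ddof,
        excluded=excluded,
    )


def _runs(mask: np.ndarray):
    """Yield (start, end_inclusive) index pairs of maximal True runs."""
    if not mask.any():
        return
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    yield from zip(starts, ends)


def _blocks_from_mask(profile, mask, min_snps, block_type, scope) -> list[AncestryBlock]:
    blocks = []
    for c in profile.chromosomes():
        idx = np.flatnonzero(profile.chrom == c)
        for s, e in _runs(mask[idx]):
            n = e - s + 1
            if n < min_snps:
                continue
            gi, gj = idx[s], idx[e]
            blocks.append(
                AncestryBlock(
                    chrom=c,
                    start_bp=int(profile.pos_bp[gi]),
                    end_bp=int(profile.pos_bp[gj]),
                    n_snps=n,
                    mean_ancestry=float(profile.admix_prop[gi : gj + 1].mean()),
                    block_type=block_type,
                    scope=scope,
                    start_idx=int(gi),
                    end_idx=int(gj),
                )
            )
    return blocks


def detect_outlier_blocks(
    profile: SNPAdmixtureProfile,
    stats: ChromStats | None = None,
    k_sd: float = 3.0,
    min_snps: int = 10,
    scope: str = "per_chromosome",
) -> list[AncestryBlock]:
    """Maximal runs of >= ``min_snps`` consecutive SNPs with admixture
    strictly above mean + ``k_sd`` x SD.

    ``scope`` selects whether the mean/SD are the SNP's own chromosome's
    (default) or the global values across all SNPs.  Runs are never merged
    across a sub-threshold gap.
    """
    if stats is None:
        stats = chromosome_stats(profile)
    mask = np.zeros(profile.n_snps, dtype=bool)
    if scope == "per_chromosome":
        for c, (m, sd, _) in stats.per_chrom.items():
            sel = profile.chrom == c
            mask[sel] = profile.admix_prop[sel] > m + k_sd * sd
    elif scope == "global":
        mask = profile.admix_prop > stats.global_mean + k_sd * stats.global_sd
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return _blocks_from_mask(profile, mask, min_snps, "overrepresented", scope)


def detect_ancestry_deserts(
    profile: SNPAdmixtureProfile,
    threshold: float = 0.001,
    min_snps: int = 10,
    mode: str = "absolute",
    stats: ChromStats | None = None,
    k_sd: float = 3.0,
    scope: str = "per_chromosome",
) -> list[AncestryBlock]:
    """Runs of >= ``min_snps`` consecutive SNPs with depleted hybrid ancestry.

    The default mode flags admixture below an absolute ``threshold`` (0.1%);
    ``mode="sd_below"`` instead uses the symmetric outlier rule, admixture
    strictly below mean - ``k_sd`` x SD.
    """
    if mode == "absolute":
        mask = profile.admix_prop < threshold
        scope_label = "per_chromosome"
    elif mode == "sd_below":
        if stats is None:
            stats = chromosome_stats(profile)
        mask = np.zeros(profile.n_snps, dtype=bool)
        if scope == "per_chromosome":
            for c, (m, sd, _) in stats.per_chrom.items():
                sel = profile.chrom == c
                mask[sel] = profile.admix_prop[sel] < m - k_sd * sd
        else:
            mask = profile.admix_prop < stats.global_mean - k_sd * stats.global_sd
        scope_label = scope
    else:
        raise ValueError(f"unknown desert mode {mode!r}")
    return _blocks_from_mask(profile, mask, min_snps, "desert", scope_label)


def block_size(start_bp: int, end_bp: int) -> int:
    """Block size as the span between the first and last SNP positions."""
    if start_bp >= end_bp:
        raise ValueError("start_bp must be < end_bp")
    return end_bp - start_bp


def count_overlapping_genes(block: AncestryBlock, genes) -> int:
    """Genes counted with a >= 1 bp overlap rule (partial ORFs count)."""
    return sum(1 for g in genes if g.overlaps(block.chrom, block.start_bp, block.end_bp))


def summarize_blocks(blocks, profile=None, genes=None) -> pd.DataFrame:
    """Table of per-block summaries plus a Mean row.

    Columns: chrom, start_bp, end_bp, size_bp, mean_ancestry, n_snps and,
    when ``genes`` is given, n_genes (>= 1 bp overlap).  ``mean_ancestry``
    and ``n_snps`` are recomputed from ``profile`` when provided, otherwise
    taken from the block records.
    """
    rows = []
    for b in blocks:
        mean_anc, n_snps = b.mean_ancestry, b.n_snps
        if profile is not None:
            sel = (
                (profile.chrom == b.chrom)
                & (profile.pos_bp >= b.start_bp)
                & (profile.pos_bp <= b.end_bp)
            )
            vals = profile.admix_prop[sel]
            if len(vals):
                mean_anc, n_snps = float(vals.mean()), int(sel.sum())
        row = {
            "chrom": b.chrom,
            "start_bp": b.start_bp,
            "end_bp": b.end_bp,
            "size_bp": block_size(b.start_bp, b.end_bp),
            "mean_ancestry": mean_anc,
            "n_snps": n_snps,
        }
        if genes is not None:
            row["n_genes"] = count_overlapping_genes(b, genes)
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        mean_row = {"chrom": "Mean", "start_bp": pd.NA, "end_bp": pd.NA}
        for col in df.columns:
            if col in ("chrom", "start_bp", "end_bp"):
                continue
            mean_row[col] = df[col].mean()
        df = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    return df


def write_blocks_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
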