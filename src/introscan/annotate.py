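"""Gene-context classification of selection-significant SNPs.

SNPs flagged by the iHS scan inside over-represented-hybrid-ancestry (OHA)
blocks are classified against a gene annotation: inside a protein-coding
gene, inside a lncRNA, within 100 kb of either, or "far".  Because a
selective sweep can only be driven by a functional element, the far
fraction is an empirical false-discovery-rate estimate for the selection
scan.  Protein-coding genes in OHA blocks that contain at least one
significant SNP are called candidate-adaptive-introgression (CAI) genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

CATEGORIES = ("in_protein_coding", "in_lncRNA", "near_100kb", "far")


@dataclass(frozen=True)
class SNPContext:
    chrom: str
    pos: int
    category: str
    nearest_gene_id: str | None
    distance_bp: float


@dataclass(frozen=True)
class CAIGeneCall:
    gene_id: str
    block_id: int
    n_significant_snps: int
    proximal_flag: bool = False


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (23.15 -> 23, 5.56 -> 5.6)."""
    if x == 0:
        return 0.0
    digits = sig - 1 - math.floor(math.log10(abs(x)))
    return round(x, digits)


def classify_snp(chrom, pos, genes, window_bp: int = 100_000) -> SNPContext:
    """Classify one SNP with precedence in_protein_coding > in_lncRNA >
    near_100kb > far.

    Gene intervals are inclusive of both endpoints; "near" means a boundary
    distance <= ``window_bp`` (inclusive at exactly 100 kb) to the nearest
    protein-coding or lncRNA gene.  Genes of biotype "other" are ignored.
    """
    if not any(g.chrom == chrom for g in genes):
        raise KeyError(f"chromosome {chrom!r} absent from annotation")
    best_gene, best_dist = None, np.inf
    in_pc, in_lnc = None, None
    for g in genes:
        if g.biotype not in ("protein_coding", "lncRNA"):
            continue
        d = g.distance_to(chrom, pos)
        if d == 0:
            if g.biotype == "protein_coding" and in_pc is None:
                in_pc = g
            elif g.biotype == "lncRNA" and in_lnc is None:
                in_lnc = g
        if d < best_dist:
            best_gene, best_dist = g, d
    if in_pc is not None:
        return SNPContext(chrom, pos, "in_protein_coding", in_pc.gene_id, 0.0)
    if in_lnc is not None:
        return SNPContext(chrom, pos, "in_lncRNA", in_lnc.gene_id, 0.0)
    if best_gene is not None and best_dist <= window_bp:
        return SNPContext(chrom, pos, "near_100kb", best_gene.gene_id, float(best_dist))
    return SNPContext(
        chrom,
        pos,
        "far",
        None if best_gene is None else best_gene.gene_id,
        float(best_dist),
    )


def classify_snps(snps, genes, window_bp: int = 100_000) -> list[SNPContext]:
    """Classify an iterable of (chrom, pos) pairs."""
    return [classify_snp(c, p, genes, window_bp) for c, p in snps]


def category_counts(contexts) -> dict:
    counts = {c: 0 for c in CATEGORIES}
    for ctx in contexts:
        counts[ctx.category] += 1
    return counts


def category_percentages(contexts, ndigits: int = 1) -> dict:
    total = len(list(contexts)) if not isinstance(contexts, list) else len(contexts)
    counts = category_counts(contexts)
    return {c: round(100.0 * n / total, ndigits) for c, n in counts.items()}


def fdr_estimate(contexts) -> tuple[float, float]:
    """Empirical FDR of the selection scan: fraction of significant SNPs in
    the "far" category (no functional element within 100 kb).

    Returns ``(fraction, percent)`` with the percentage rounded to one
    decimal place.
    """
    contexts = list(contexts)
    if not contexts:
        raise ValueError("no SNP contexts supplied")
    n_far = sum(1 for c in contexts if c.category == "far")
    frac = n_far / len(contexts)
    return frac, round(100.0 * frac, 1)


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """Category percentage at the conventional one-decimal rounding."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def fdr_from_counts(n_total: int, n_far: int) -> tuple[float, float]:
    """FDR from pre-tabulated counts (same rounding as :func:`fdr_estimate`)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    frac = n_far / n_total
    return frac, round(100.0 * frac, 1)


def cai_genes(
    oha_blocks,
    significant_snps,
    genes,
    proximal_window: int = 10_000,
) -> list[CAIGeneCall]:
    """Candidate-adaptive-introgression gene calls.

    One call per protein-coding gene overlapping an OHA block that contains
    >= 1 significant SNP within its interval.  Significant SNPs in a block
    but outside every gene are reported against genes within
    ``proximal_window`` bp with ``proximal_flag=True`` (a sweep signal just
    outside the gene body).  ``significant_snps`` is an iterable of
    (chrom, pos) pairs, assumed restricted to OHA blocks.
    """
    calls = []
    seen = set()
    for block_id, b in enumerate(oha_blocks):
        block_genes = [
            g
            for g in genes
            if g.biotype == "protein_coding" and g.overlaps(b.chrom, b.start_bp, b.end_bp)
        ]
        snps_in_block = [
            (c, p)
            for c, p in significant_snps
            if c == b.chrom and b.start_bp <= p <= b.end_bp
        ]
        for g in block_genes:
            inside = sum(1 for c, p in snps_in_block if g.start_bp <= p <= g.end_bp)
            if inside >= 1:
                if (g.gene_id, False) not in seen:
                    calls.append(CAIGeneCall(g.gene_id, block_id, inside, False))
                    seen.add((g.gene_id, False))
                continue
            proximal = sum(
                1
                for c, p in snps_in_block
                if 0 < g.distance_to(c, p) <= proximal_window
            )
            if proximal >= 1 and (g.gene_id, True) not in seen:
                calls.append(CAIGeneCall(g.gene_id, block_id, proximal, True))
                seen.add((g.gene_id, True))
    return calls


def cai_proportion(cai_calls, oha_gene_count: int, ndigits: int | None = None) -> float:
    """Percentage of OHA genes called CAI (distinct genes; a gene spanning
    two blocks counts once).

    ``cai_calls`` may be a list of calls or an integer count of distinct CAI
    genes.  Default rounding is to two significant figures; pass ``ndigits``
    to round to a fixed number of decimals instead.
    """
    if oha_gene_count < 1:
        raise ValueError("oha_gene_count must be >= 1")
    if isinstance(cai_calls, (int, np.integer)):
        n = int(cai_calls)
    else:
        n = len({c.gene_id for c in cai_calls if not c.proximal_flag})
    pct = 100.0 * n / oha_gene_count
    if pct == 0:
        return 0.0
    return round(pct, ndigits) if ndigits is not None else round_sig(pct, 2)
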