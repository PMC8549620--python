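"""Readers/writers for external formats plus the standard SNP-chip filters.

Supported formats: VCF 4.x (phased GT), PLINK text .ped/.map, ELAI-style
dosage table with a mandatory SNP-info sidecar, recombination-map TSV,
BED4/BED6 and GFF3 gene annotations, and BED output for detected blocks.

Variant filters follow common SNP-chip practice: drop SNPs with minor-allele
frequency below 1% or more than 10% missing genotypes, and optionally prune
SNPs in strong LD (genotype r^2 > 0.1) with a greedy sliding window.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    AncestryDosageMatrix,
    GeneAnnotation,
    HaplotypePanel,
    RecombinationMap,
    chrom_sort_key,
    warn,
)


class ParseError(ValueError):
    pass


def _sort_panel(panel: HaplotypePanel) -> HaplotypePanel:
    order = sorted(
        range(panel.n_snps),
        key=lambda i: (chrom_sort_key(panel.chrom[i]), panel.pos_bp[i]),
    )
    if order != list(range(panel.n_snps)):
        warn("input positions not sorted; reordering by (chrom, pos)")
        panel = panel.take_snps(np.asarray(order))
    return panel


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def read_genotypes(path, format: str | None = None) -> HaplotypePanel:
    """Read phased/unphased genotypes from VCF or PLINK text .ped/.map.

    ``format`` is ``"vcf"`` or ``"plink_text"``; inferred from the file
    extension when omitted.  For PLINK text, ``path`` is the ``.ped`` file
    and the matching ``.map`` must sit alongside it.
    """
    path = str(path)
    if format is None:
        format = "plink_text" if path.endswith(".ped") else "vcf"
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_text":
        return _read_ped(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> HaplotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    chroms, pos, alleles, rows, ids = [], [], [], [], []
    all_phased = True
    for v in vcf:
        if len(v.ALT) != 1:
            raise ParseError(f"non-biallelic record at {v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        pos.append(v.POS)
        alleles.append((v.REF, v.ALT[0]))
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        row = np.empty(2 * len(sample_ids), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a, b, phased = g[0], g[1], g[-1]
            row[2 * i] = MISSING if a < 0 else a
            row[2 * i + 1] = MISSING if b < 0 else b
            if not phased and a >= 0 and b >= 0 and a != b:
                all_phased = False
        rows.append(row)
    if not rows:
        raise ParseError(f"no variant records in {path}")
    panel = HaplotypePanel(
        chrom=np.array(chroms, dtype=object),
        pos_bp=np.array(pos),
        alleles=np.array(alleles, dtype=object),
        hap_matrix=np.array(rows, dtype=np.int8).T,
        sample_ids=sample_ids,
        phased=all_phased,
        snp_ids=np.array(ids, dtype=object),
    )
    panel = _sort_panel(panel)
    panel.validate()
    return panel


def _read_ped(ped_path) -> HaplotypePanel:
    map_path = os.path.splitext(str(ped_path))[0] + ".map"
    if not os.path.exists(map_path):
        raise FileNotFoundError(f"missing .map companion for {ped_path}")
    mp = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str)
    if mp.shape[1] < 4:
        raise ParseError(f"{map_path}: expected 4 columns (chrom id cM pos)")
    chroms = mp[0].to_numpy(dtype=object)
    snp_ids = mp[1].to_numpy(dtype=object)
    pos = mp[3].astype(np.int64).to_numpy()
    n_snps = len(pos)

    sample_ids, geno_rows = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            geno_rows.append(fields[6:])
    if not geno_rows:
        raise ParseError(f"no individuals in {ped_path}")
    raw = np.array(geno_rows, dtype=object)  # (n_ind, 2*n_snps)

    hap = np.empty((2 * len(sample_ids), n_snps), dtype=np.int8)
    alleles = np.empty((n_snps, 2), dtype=object)
    any_het = False
    for j in range(n_snps):
        a1 = raw[:, 2 * j]
        a2 = raw[:, 2 * j + 1]
        seen = sorted({x for x in np.concatenate([a1, a2]) if x not in ("0", "-9")})
        if len(seen) > 2:
            raise ParseError(f"{ped_path}: SNP {snp_ids[j]} has >2 alleles: {seen}")
        while len(seen) < 2:
            seen.append("0")
        alleles[j] = seen
        code = {seen[0]: 0, seen[1]: 1, "0": MISSING, "-9": MISSING}
        col1 = np.array([code.get(x, MISSING) for x in a1], dtype=np.int8)
        col2 = np.array([code.get(x, MISSING) for x in a2], dtype=np.int8)
        het = (col1 != col2) & (col1 != MISSING) & (col2 != MISSING)
        if het.any():
            any_het = True
        hap[0::2, j] = col1
        hap[1::2, j] = col2
    # .ped carries no phase information: only a panel with no heterozygous
    # genotype is unambiguously phased
    panel = HaplotypePanel(
        chrom=chroms,
        pos_bp=pos,
        alleles=alleles,
        hap_matrix=hap,
        sample_ids=sample_ids,
        phased=not any_het,
        snp_ids=snp_ids,
    )
    panel = _sort_panel(panel)
    panel.validate()
    return panel


def write_vcf(panel: HaplotypePanel, path) -> None:
    """Write a panel as a minimal phased VCF 4.2 text file."""
    sep = "|" if panel.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in panel.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        ids = panel.snp_ids
        for j in range(panel.n_snps):
            ref, alt = panel.alleles[j]
            sid = ids[j] if ids is not None else f"{panel.chrom[j]}:{panel.pos_bp[j]}"
            gts = []
            for i in range(panel.n_individuals):
                a = panel.hap_matrix[2 * i, j]
                b = panel.hap_matrix[2 * i + 1, j]
                gts.append(
                    f"{'.' if a == MISSING else int(a)}{sep}{'.' if b == MISSING else int(b)}"
                )
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos_bp[j]}\t{sid}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# ancestry dosage
# ---------------------------------------------------------------------------


def read_ancestry_dosage(geno_path, snpinfo_path, donor_label="donor") -> AncestryDosageMatrix:
    """Read an ELAI-style dosage table.

    ``geno_path`` is a whitespace-delimited matrix, one row per individual,
    one column per SNP, dosages in [0, 2].  ``snpinfo_path`` is a TSV with
    columns chrom, pos, id (header optional) giving per-column SNP metadata.
    """
    info = pd.read_csv(snpinfo_path, sep=r"\s+", header=None, dtype=str, comment="#")
    if info.shape[1] < 2:
        raise ParseError(f"{snpinfo_path}: expected columns chrom, pos[, id]")
    if not info.iloc[0, 1].lstrip("+-").isdigit():  # header row
        info = info.iloc[1:].reset_index(drop=True)
    chroms = info[0].to_numpy(dtype=object)
    pos = info[1].astype(np.int64).to_numpy()
    snp_ids = info[2].to_numpy(dtype=object) if info.shape[1] > 2 else None

    dosage = np.loadtxt(geno_path, dtype=float, ndmin=2)
    if dosage.shape[1] != len(pos):
        raise ParseError(
            f"dosage has {dosage.shape[1]} columns but SNP info lists {len(pos)} SNPs"
        )
    mat = AncestryDosageMatrix(
        chrom=chroms,
        pos_bp=pos,
        dosage=dosage,
        individual_ids=[f"ind{i}" for i in range(dosage.shape[0])],
        donor_label=donor_label,
        snp_ids=snp_ids,
    )
    mat.validate()
    mat.dosage = np.clip(mat.dosage, 0.0, 2.0)
    return mat


def write_ancestry_dosage(mat: AncestryDosageMatrix, geno_path, snpinfo_path) -> None:
    np.savetxt(geno_path, mat.dosage, fmt="%.6g")
    ids = (
        mat.snp_ids
        if mat.snp_ids is not None
        else [f"snp{i}" for i in range(mat.n_snps)]
    )
    with open(snpinfo_path, "w") as fh:
        fh.write("chrom\tpos\tid\n")
        for c, p, s in zip(mat.chrom, mat.pos_bp, ids):
            fh.write(f"{c}\t{p}\t{s}\n")


# ---------------------------------------------------------------------------
# variant filters
# ---------------------------------------------------------------------------


def filter_variants(
    panel: HaplotypePanel, maf_min: float = 0.01, max_missing: float = 0.10
) -> HaplotypePanel:
    """Drop SNPs with MAF < ``maf_min`` or missing fraction > ``max_missing``.

    Missing calls are excluded from the MAF denominator.  Order preserved;
    idempotent.
    """
    if panel.n_snps == 0:
        raise ValueError("empty panel")
    obs = panel.hap_matrix != MISSING
    n_obs = obs.sum(axis=0)
    miss_frac = 1.0 - n_obs / panel.n_haplotypes
    with np.errstate(invalid="ignore"):
        freq = np.where(n_obs > 0, (panel.hap_matrix == 1).sum(axis=0) / np.maximum(n_obs, 1), 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = (maf >= maf_min) & (miss_frac <= max_missing)
    if not keep.any():
        warn("all SNPs removed by variant filters")
    return panel.take_snps(np.flatnonzero(keep))


def genotype_r2(panel: HaplotypePanel, i: int, j: int) -> float:
    """Squared Pearson correlation of individual genotype dosages at two SNPs.

    Individuals missing either genotype are excluded; monomorphic pairs
    return 0.
    """
    g = panel.genotype_dosage()
    x, y = g[:, i], g[:, j]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    panel: HaplotypePanel,
    r2_max: float = 0.1,
    window_snps: int = 50,
    step_snps: int = 5,
) -> HaplotypePanel:
    """Greedy left-to-right LD pruning within sliding windows, per chromosome.

    Within each window every kept pair must satisfy genotype r^2 <= ``r2_max``;
    when a pair exceeds it the later SNP is removed.
    """
    g = panel.genotype_dosage()
    keep = np.ones(panel.n_snps, dtype=bool)
    for c in panel.chromosomes():
        idx = np.flatnonzero(panel.chrom == c)
        start = 0
        while start < len(idx):
            window = idx[start : start + window_snps]
            for a_pos in range(len(window)):
                i = window[a_pos]
                if not keep[i]:
                    continue
                for b_pos in range(a_pos + 1, len(window)):
                    j = window[b_pos]
                    if not keep[j]:
                        continue
                    if _pair_r2(g, i, j) > r2_max:
                        keep[j] = False
            if start + window_snps >= len(idx):
                break
            start += step_snps
    return panel.take_snps(np.flatnonzero(keep))


def _pair_r2(g: np.ndarray, i: int, j: int) -> float:
    x, y = g[:, i], g[:, j]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# recombination map, annotations, BED
# ---------------------------------------------------------------------------


def read_recombination_map(path) -> RecombinationMap:
    """Read a TSV recombination map (chrom, pos_bp, rate_cM_per_Mb)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ParseError(f"{path}: expected columns chrom, pos_bp, rate_cM_per_Mb")
    if not df.iloc[0, 1].lstrip("+-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    rates = df[2].astype(float).to_numpy()
    if (rates < 0).any():
        raise ParseError(f"{path}: negative recombination rate")
    return RecombinationMap(
        chrom=df[0].to_numpy(dtype=object),
        pos_bp=df[1].astype(np.int64).to_numpy(),
        rate_cM_per_Mb=rates,
    )


_LNCRNA_ALIASES = {"lncrna", "lincrna", "long_noncoding_rna", "lnc_rna"}


def _normalise_biotype(raw: str | None) -> str:
    if raw is None:
        return "protein_coding"
    raw = raw.strip().lower()
    if raw == "protein_coding":
        return "protein_coding"
    if raw in _LNCRNA_ALIASES:
        return "lncRNA"
    return "other"


def read_gene_annotation(path, format: str | None = None) -> list[GeneAnnotation]:
    """Read gene annotations from BED (4+ columns) or GFF3.

    BED intervals (0-based half-open) are converted to the internal 1-based
    inclusive convention.  GFF3 biotypes are taken from the ``biotype`` (or
    ``gene_biotype``) attribute of ``gene`` features; BED files without a
    biotype column default every gene to protein_coding.
    """
    path = str(path)
    if format is None:
        format = "gff3" if path.endswith((".gff", ".gff3")) else "bed"
    if format == "bed":
        return _read_bed_genes(path)
    if format == "gff3":
        return _read_gff3_genes(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_bed_genes(path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            start0, end0 = int(f[1]), int(f[2])
            if start0 > end0:
                raise ParseError(f"{path}:{lineno}: start > end")
            name = f[3] if len(f) > 3 else f"gene{lineno}"
            biotype = _normalise_biotype(f[6]) if len(f) > 6 else "protein_coding"
            genes.append(
                GeneAnnotation(
                    gene_id=name, chrom=f[0], start_bp=start0 + 1, end_bp=end0, biotype=biotype
                )
            )
    return genes


def _read_gff3_genes(path) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = []
    for feat in db.features_of_type("gene"):
        raw = (feat.attributes.get("biotype") or feat.attributes.get("gene_biotype") or [None])[0]
        gid = (feat.attributes.get("ID") or feat.attributes.get("Name") or [feat.id])[0]
        genes.append(
            GeneAnnotation(
                gene_id=gid,
                chrom=feat.seqid,
                start_bp=feat.start,
                end_bp=feat.end,
                biotype=_normalise_biotype(raw),
            )
        )
    return genes


def write_blocks_bed(blocks, path) -> None:
    """Write blocks as BED4 (0-based half-open)."""
    with open(path, "w") as fh:
        for k, b in enumerate(blocks):
            fh.write(f"{b.chrom}\t{b.start_bp - 1}\t{b.end_bp}\tblock{k}_{b.block_type}\n")


def read_blocks_bed(path):
    """Re-read a block BED written by :func:`write_blocks_bed`."""
    from .types import AncestryBlock

    blocks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e, name = line.split("\t")[:4]
            btype = name.strip().split("_", 1)[1] if "_" in name else "overrepresented"
            blocks.append(
                AncestryBlock(
                    chrom=c,
                    start_bp=int(s) + 1,
                    end_bp=int(e),
                    n_snps=0,
                    mean_ancestry=float("nan"),
                    block_type=btype,
                )
            )
    return blocks
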