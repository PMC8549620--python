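"""Published worked-example inputs bundled with the package.

These are printed summary data from the reference wolf / free-ranging-dog
(FRD) admixture study this pipeline reimplements the analysis of: the
per-block coordinates and summaries of the over-represented-hybrid-ancestry
(OHA) blocks (CanFam3.1 SNP-chip coordinates), and the tabulated gene-context
counts of selection-significant SNPs.  They serve as small worked examples
for the block-summary and classification arithmetic; they are inputs, not
results computed here.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .types import AncestryBlock


def reference_blocks(population: str | None = None) -> pd.DataFrame:
    """Published OHA-block table (populations "wolf" and "frd")."""
    ref = importlib.resources.files("introscan").joinpath("data/reference_blocks.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if population is not None:
        df = df[df["population"] == population].reset_index(drop=True)
        if df.empty:
            raise KeyError(f"unknown population {population!r}")
    return df


def reference_blocks_as_records(population: str) -> list[AncestryBlock]:
    """The published blocks as AncestryBlock records (for summarize_blocks)."""
    df = reference_blocks(population)
    return [
        AncestryBlock(
            chrom=str(r.chrom),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            n_snps=int(r.n_snps),
            mean_ancestry=float(r.mean_ancestry),
        )
        for r in df.itertuples()
    ]


# Gene-context counts of selection-significant SNPs inside OHA blocks
# (per the reference study's CanFam3.1 classification).
SNP_CONTEXT_COUNTS = {
    "frd": {"total": 324, "in_protein_coding": 153, "in_lncRNA": 16, "near_100kb": 126, "far": 33},
    "wolf": {"total": 18, "in_protein_coding": 4, "in_lncRNA": 0, "near_100kb": 12, "far": 2},
}

# OHA gene counts (human-orthologue denominators) and distinct CAI gene counts.
OHA_GENE_COUNTS = {"frd": 311, "wolf": 72}
CAI_GENE_COUNTS = {"frd": 72, "wolf": 4}
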