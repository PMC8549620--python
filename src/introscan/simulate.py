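"""Synthetic admixed two-population panels with ground truth.

The generator emulates the statistical structure of an admixed canid
SNP-chip dataset: two source populations diverged to a target FST under
the Balding-Nichols model, admixed individuals whose ancestry switches
along the genome as a Poisson process (rate g per Morgan, g generations
since admixture, each tract donor-derived with probability m), planted
blocks of over-represented donor ancestry, and planted sweeps (a carrier
haplotype copied across a share of haplotypes to create extended
homozygosity).  Source-population sites are independent (no background
LD); haplotype structure is planted explicitly, which keeps every
downstream statistic analytically checkable.

Defaults mirror the study conditions the pipeline targets: FST 0.205,
m = 0.0274 (dog-into-wolf, "wolf-like") or 0.0075 (wolf-into-dog,
"FRD-like"), 10 generations since admixture, 88 admixed individuals,
5 chromosomes x 4,000 SNPs at 25-kb spacing under a uniform 1 cM/Mb map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .types import AncestryDosageMatrix, HaplotypePanel, RecombinationMap, warn

WOLF_LIKE_M = 0.0274  # dog ancestry in admixed West Eurasian wolves
FRD_LIKE_M = 0.0075  # wolf ancestry in admixed Eurasian free-ranging dogs
DEFAULT_FST = 0.205


@dataclass
class SimulationConfig:
    n_chromosomes: int = 5
    n_snps_per_chrom: int = 4000
    snp_spacing_bp: int = 25_000
    fst_target: float = DEFAULT_FST
    n_donor: int = 100
    n_recipient: int = 100
    n_admixed: int = 88
    admixture_proportion: float = WOLF_LIKE_M
    generations_since_admixture: float = 10.0
    rate_cM_per_Mb: float = 1.0
    seed: int | None = None
    # (chrom, start_bp, end_bp, donor_frequency)
    planted_blocks: list = field(default_factory=list)
    # (chrom, core_pos, carrier_fraction, tract_bp)
    planted_sweeps: list = field(default_factory=list)

    def __post_init__(self):
        if not 0 <= self.admixture_proportion < 1:
            raise ValueError("admixture_proportion must be in [0, 1)")
        if self.generations_since_admixture < 1:
            raise ValueError("generations_since_admixture must be >= 1")
        if not 0 <= self.fst_target < 1:
            raise ValueError("fst_target must be in [0, 1)")

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.n_snps_per_chrom


@dataclass
class SimulationTruth:
    """Ground truth aligned with the emitted panel."""

    chrom: np.ndarray
    pos_bp: np.ndarray
    freq_donor: np.ndarray
    freq_recipient: np.ndarray
    donor_indicator: np.ndarray  # (n_admixed_haplotypes, n_snps) int8
    tracts: list  # (hap_index, chrom, start_bp, end_bp, ancestry)
    planted_blocks: list = field(default_factory=list)
    planted_sweeps: list = field(default_factory=list)

    def dosage_matrix(self, donor_label: str = "donor") -> AncestryDosageMatrix:
        d = self.donor_indicator
        return AncestryDosageMatrix(
            chrom=self.chrom,
            pos_bp=self.pos_bp,
            dosage=(d[0::2] + d[1::2]).astype(float),
            individual_ids=[f"adm{i}" for i in range(d.shape[0] // 2)],
            donor_label=donor_label,
        )


# ---------------------------------------------------------------------------
# source populations
# ---------------------------------------------------------------------------


def simulate_source_frequencies(n_snps: int, fst: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Balding-Nichols allele frequencies for two populations.

    Ancestral frequency p ~ Uniform(0.05, 0.95); each population draws from
    Beta(p (1-F)/F, (1-p)(1-F)/F) with F = ``fst``; F = 0 degenerates to p.
    """
    if not 0 <= fst < 1:
        raise ValueError("fst must be in [0, 1)")
    p = rng.uniform(0.05, 0.95, size=n_snps)
    if fst == 0:
        return p.copy(), p.copy()
    scale = (1.0 - fst) / fst
    f1 = rng.beta(p * scale, (1.0 - p) * scale)
    f2 = rng.beta(p * scale, (1.0 - p) * scale)
    return f1, f2


def simulate_haplotypes(freqs: np.ndarray, n_hap: int, rng) -> np.ndarray:
    """Independent-site haplotypes: allele 1 at SNP j with probability
    ``freqs[j]``."""
    return (rng.random((n_hap, len(freqs))) < freqs[None, :]).astype(np.int8)


def hudson_fst(hap1: np.ndarray, hap2: np.ndarray) -> float:
    """Hudson FST estimator (ratio of averages) from two haplotype matrices."""
    n1, n2 = hap1.shape[0], hap2.shape[0]
    p1 = hap1.mean(axis=0)
    p2 = hap2.mean(axis=0)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    return float(num[ok].sum() / den[ok].sum())


# ---------------------------------------------------------------------------
# ancestry tracts
# ---------------------------------------------------------------------------


def sample_tract_ancestry(length_morgans: float, m: float, g: float, rng):
    """One haplotype's ancestry mosaic on a chromosome of given map length.

    Switch points form a Poisson process at rate ``g`` per Morgan; each
    tract is donor with probability ``m`` independently.  Returns
    ``(breakpoints_morgans, tract_ancestries)`` with len(ancestries) =
    len(breakpoints) + 1.
    """
    n_switch = rng.poisson(g * length_morgans)
    breaks = np.sort(rng.uniform(0.0, length_morgans, size=n_switch))
    anc = (rng.random(n_switch + 1) < m).astype(np.int8)
    return breaks, anc


def _chrom_layout(config: SimulationConfig):
    """Per-chromosome labels and positions."""
    chroms, pos = [], []
    for c in range(1, config.n_chromosomes + 1):
        label = f"chr{c}"
        p = np.arange(1, config.n_snps_per_chrom + 1, dtype=np.int64) * config.snp_spacing_bp
        chroms.append(np.full(config.n_snps_per_chrom, label, dtype=object))
        pos.append(p)
    return np.concatenate(chroms), np.concatenate(pos)


def simulate_ancestry_tracts(
    chrom: np.ndarray,
    pos_bp: np.ndarray,
    m: float,
    g: float,
    n_haplotypes: int,
    rng,
    rmap: RecombinationMap | None = None,
    rate_cM_per_Mb: float | None = None,
):
    """Donor-ancestry indicators for admixed haplotypes.

    Returns ``(donor_indicator, tracts)``; tracts are (hap, chrom,
    start_bp, end_bp, ancestry) records covering each chromosome.  With no
    map a uniform rate is assumed (1 cM/Mb unless ``rate_cM_per_Mb`` is
    given), with a warning when neither is supplied.
    """
    if rmap is None and rate_cM_per_Mb is None:
        warn("no recombination map supplied; assuming uniform 1 cM/Mb")
        rate_cM_per_Mb = 1.0
    chrom_labels = []
    seen = set()
    for c in chrom:
        if c not in seen:
            seen.add(c)
            chrom_labels.append(c)
    donor = np.zeros((n_haplotypes, len(pos_bp)), dtype=np.int8)
    tracts = []
    for c in chrom_labels:
        sel = np.flatnonzero(chrom == c)
        p = pos_bp[sel]
        if rmap is not None:
            gpos = rmap.genetic_position(c, p) / 100.0  # Morgans
        else:
            gpos = (p - p[0]) * rate_cM_per_Mb / 1e6 / 100.0
        length = float(gpos[-1]) if len(gpos) > 1 else 0.0
        for h in range(n_haplotypes):
            breaks, anc = sample_tract_ancestry(length, m, g, rng)
            seg = np.searchsorted(breaks, gpos, side="right")
            donor[h, sel] = anc[seg]
            bp_breaks = np.interp(breaks, gpos, p)
            bounds = np.concatenate([[p[0]], bp_breaks, [p[-1]]])
            for t in range(len(anc)):
                tracts.append((h, c, int(bounds[t]), int(bounds[t + 1]), int(anc[t])))
    return donor, tracts


def simulate_admixed(
    freq_donor: np.ndarray,
    freq_recipient: np.ndarray,
    m: float,
    g: float,
    chrom: np.ndarray,
    pos_bp: np.ndarray,
    n_admixed: int,
    rng,
    rmap: RecombinationMap | None = None,
    rate_cM_per_Mb: float | None = 1.0,
) -> tuple[HaplotypePanel, SimulationTruth]:
    """Admixed panel: alleles drawn from the tract-ancestry population."""
    n_hap = 2 * n_admixed
    donor, tracts = simulate_ancestry_tracts(
        chrom, pos_bp, m, g, n_hap, rng, rmap=rmap, rate_cM_per_Mb=rate_cM_per_Mb
    )
    probs = np.where(donor == 1, freq_donor[None, :], freq_recipient[None, :])
    hap = (rng.random(donor.shape) < probs).astype(np.int8)
    panel = HaplotypePanel(
        chrom=chrom,
        pos_bp=pos_bp,
        alleles=np.array([("A", "T")] * len(pos_bp), dtype=object),
        hap_matrix=hap,
        sample_ids=[f"adm{i}" for i in range(n_admixed)],
        phased=True,
    )
    truth = SimulationTruth(
        chrom=chrom,
        pos_bp=pos_bp,
        freq_donor=freq_donor,
        freq_recipient=freq_recipient,
        donor_indicator=donor,
        tracts=tracts,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# planted features
# ---------------------------------------------------------------------------


def plant_overrepresented_block(
    panel: HaplotypePanel,
    truth: SimulationTruth,
    chrom: str,
    start_bp: int,
    end_bp: int,
    target_donor_freq: float,
    rng,
) -> None:
    """Force donor ancestry onto ~``target_donor_freq`` of haplotypes over
    an interval, redrawing their alleles from the donor frequencies.

    No-op (with warning) when the target does not exceed the interval's
    background donor fraction, or the interval covers no SNPs.
    """
    cols = np.flatnonzero(
        (panel.chrom == chrom) & (panel.pos_bp >= start_bp) & (panel.pos_bp <= end_bp)
    )
    if len(cols) == 0:
        return
    background = truth.donor_indicator[:, cols].mean()
    if target_donor_freq <= background:
        warn("planted-block target below background admixture; no-op")
        return
    n_hap = panel.n_haplotypes
    k = int(round(target_donor_freq * n_hap))
    chosen = rng.choice(n_hap, size=k, replace=False)
    truth.donor_indicator[np.ix_(chosen, cols)] = 1
    draws = rng.random((k, len(cols))) < truth.freq_donor[cols][None, :]
    panel.hap_matrix[np.ix_(chosen, cols)] = draws.astype(np.int8)
    truth.planted_blocks.append(
        {
            "chrom": chrom,
            "start_bp": int(start_bp),
            "end_bp": int(end_bp),
            "target_donor_freq": float(target_donor_freq),
            "realized_donor_freq": float(truth.donor_indicator[:, cols].mean()),
            "n_snps": int(len(cols)),
        }
    )


def plant_sweep(
    panel: HaplotypePanel,
    chrom: str,
    core_pos: int,
    carrier_fraction: float,
    tract_bp: int,
    rng,
    truth: SimulationTruth | None = None,
) -> int:
    """Copy one derived-carrier haplotype's segment (``tract_bp`` centred on
    the core) onto a ``carrier_fraction`` share of haplotypes.

    Creates extended haplotype homozygosity among derived carriers, the
    footprint of a recent sweep.  Returns the core SNP's global index.
    """
    if not 0 < carrier_fraction <= 1:
        raise ValueError("carrier_fraction must be in (0, 1]")
    on_chrom = np.flatnonzero(panel.chrom == chrom)
    if len(on_chrom) == 0:
        raise ValueError(f"chromosome {chrom!r} not in panel")
    exact = on_chrom[panel.pos_bp[on_chrom] == core_pos]
    freqs = panel.allele_frequency()
    if len(exact) and 0 < freqs[exact[0]] < 1:
        core = int(exact[0])
    else:
        poly = on_chrom[(freqs[on_chrom] > 0) & (freqs[on_chrom] < 1)]
        if len(poly) == 0:
            raise ValueError(f"no polymorphic SNP on {chrom}")
        core = int(poly[np.argmin(np.abs(panel.pos_bp[poly] - core_pos))])
        warn(f"no polymorphic core at {chrom}:{core_pos}; using nearest at "
             f"{panel.pos_bp[core]}")
    cols = on_chrom[
        (panel.pos_bp[on_chrom] >= panel.pos_bp[core] - tract_bp // 2)
        & (panel.pos_bp[on_chrom] <= panel.pos_bp[core] + tract_bp // 2)
    ]
    derived_rows = np.flatnonzero(panel.hap_matrix[:, core] == 1)
    template = int(rng.choice(derived_rows))
    n_hap = panel.n_haplotypes
    k = int(round(carrier_fraction * n_hap))
    carriers = rng.choice(n_hap, size=k, replace=False)
    panel.hap_matrix[np.ix_(carriers, cols)] = panel.hap_matrix[template, cols][None, :]
    panel.hap_matrix[carriers, core] = 1
    if truth is not None:
        truth.planted_sweeps.append(
            {
                "chrom": chrom,
                "core_pos": int(panel.pos_bp[core]),
                "core_index": core,
                "carrier_fraction": float(carrier_fraction),
                "tract_bp": int(tract_bp),
            }
        )
    return core


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    config: SimulationConfig
    panel: HaplotypePanel  # admixed individuals
    donor_panel: HaplotypePanel
    recipient_panel: HaplotypePanel
    truth: SimulationTruth


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> SimulationResult:
    """Run the full generator: sources, admixed panel, planted features."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    chrom, pos = _chrom_layout(config)
    fa, fb = simulate_source_frequencies(config.n_snps, config.fst_target, rng)

    def _source(freqs, n_ind, prefix):
        return HaplotypePanel(
            chrom=chrom,
            pos_bp=pos,
            alleles=np.array([("A", "T")] * len(pos), dtype=object),
            hap_matrix=simulate_haplotypes(freqs, 2 * n_ind, rng),
            sample_ids=[f"{prefix}{i}" for i in range(n_ind)],
            phased=True,
        )

    donor_panel = _source(fa, config.n_donor, "don")
    recipient_panel = _source(fb, config.n_recipient, "rec")
    panel, truth = simulate_admixed(
        fa,
        fb,
        config.admixture_proportion,
        config.generations_since_admixture,
        chrom,
        pos,
        config.n_admixed,
        rng,
        rate_cM_per_Mb=config.rate_cM_per_Mb,
    )
    for c, s, e, f in config.planted_blocks:
        plant_overrepresented_block(panel, truth, c, s, e, f, rng)
    for c, p, f, t in config.planted_sweeps:
        plant_sweep(panel, c, p, f, t, rng, truth=truth)
    return SimulationResult(config, panel, donor_panel, recipient_panel, truth)


def write_truth(truth: SimulationTruth, prefix: str) -> dict:
    """Emit dosage table + SNP info, tract BED and planted-feature JSON.

    Returns the mapping of artefact names to paths.
    """
    from .io_formats import write_ancestry_dosage

    paths = {
        "dosage": f"{prefix}.dosage.txt",
        "snpinfo": f"{prefix}.snpinfo.tsv",
        "tracts": f"{prefix}.tracts.bed",
        "features": f"{prefix}.features.json",
    }
    write_ancestry_dosage(truth.dosage_matrix(), paths["dosage"], paths["snpinfo"])
    with open(paths["tracts"], "w") as fh:
        for h, c, s, e, a in truth.tracts:
            fh.write(f"{c}\t{max(s - 1, 0)}\t{e}\thap{h}_anc{a}\n")
    with open(paths["features"], "w") as fh:
        json.dump(
            {"planted_blocks": truth.planted_blocks, "planted_sweeps": truth.planted_sweeps},
            fh,
            indent=2,
        )
    return paths
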