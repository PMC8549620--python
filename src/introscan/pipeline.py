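"""End-to-end orchestration of the introgression-analysis stages.

A single YAML config drives: simulate -> profile -> scan -> validate ->
ihs -> annotate -> correlate -> report.  Outputs land in a run directory
with a manifest recording parameters, derived per-stage seeds and sha256
checksums of every artefact, so a re-run with the same master seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import cai_genes, category_counts, classify_snps, fdr_estimate
from .block_scan import (
    SNPAdmixtureProfile,
    chromosome_stats,
    detect_ancestry_deserts,
    detect_outlier_blocks,
    snp_admixture_profile,
    summarize_blocks,
    write_blocks_table,
)
from .io_formats import (
    read_ancestry_dosage,
    read_gene_annotation,
    read_genotypes,
    read_recombination_map,
    write_blocks_bed,
    write_vcf,
)
from .recomb import admixture_vs_recombination
from .resampling import validate_detection
from .selection import ihs_scan, significant_snps
from .simulate import SimulationConfig, simulate_dataset, write_truth
from .types import GeneAnnotation

log = logging.getLogger("introscan")

STAGES = ("simulate", "profile", "scan", "validate", "ihs", "annotate", "correlate", "report")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


_DEFAULTS = {
    "seed": 0,
    "log_level": "INFO",
    "simulate": {
        "enabled": True,
        "n_chromosomes": 5,
        "n_snps_per_chrom": 4000,
        "snp_spacing_bp": 25_000,
        "fst_target": 0.205,
        "n_donor": 100,
        "n_recipient": 100,
        "n_admixed": 88,
        "admixture_proportion": 0.0274,
        "generations_since_admixture": 10,
        "rate_cM_per_Mb": 1.0,
        "planted_blocks": [],
        "planted_sweeps": [],
    },
    "inputs": {
        "dosage": None,
        "snpinfo": None,
        "genotypes": None,
        "recomb_map": None,
        "genes": None,
    },
    "scan": {"k_sd": 3.0, "min_snps": 10, "scope": "per_chromosome", "desert_threshold": 0.001},
    "validate": {"n_blocks": 38, "min_len": 10, "max_len": 150},
    "ihs": {"maf_min": 0.05, "bin_width": 0.025, "cutoff": 0.05, "bonferroni": False},
    "annotate": {"window_bp": 100_000, "proximal_window": 10_000},
}

_DOMAINS = {
    ("scan", "k_sd"): lambda v: v > 0,
    ("scan", "min_snps"): lambda v: v >= 1,
    ("scan", "scope"): lambda v: v in ("per_chromosome", "global"),
    ("scan", "desert_threshold"): lambda v: 0 <= v <= 1,
    ("validate", "n_blocks"): lambda v: v >= 1,
    ("validate", "min_len"): lambda v: v >= 1,
    ("ihs", "maf_min"): lambda v: 0 <= v < 0.5,
    ("ihs", "bin_width"): lambda v: 0 < v <= 0.5,
    ("ihs", "cutoff"): lambda v: 0 < v < 1,
    ("annotate", "window_bp"): lambda v: v >= 0,
    ("annotate", "proximal_window"): lambda v: v >= 0,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=lambda: dict(_DEFAULTS["simulate"]))
    inputs: dict = field(default_factory=lambda: dict(_DEFAULTS["inputs"]))
    scan: dict = field(default_factory=lambda: dict(_DEFAULTS["scan"]))
    validate: dict = field(default_factory=lambda: dict(_DEFAULTS["validate"]))
    ihs: dict = field(default_factory=lambda: dict(_DEFAULTS["ihs"]))
    annotate: dict = field(default_factory=lambda: dict(_DEFAULTS["annotate"]))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - set(_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged = {}
        for key, default in _DEFAULTS.items():
            if isinstance(default, dict):
                sub = dict(default)
                extra = raw.get(key, {}) or {}
                bad = set(extra) - set(default)
                if bad:
                    raise ConfigError(f"unknown keys under {key!r}: {sorted(bad)}")
                sub.update(extra)
                merged[key] = sub
            else:
                merged[key] = raw.get(key, default)
        cfg = cls(**merged)
        for (section, key), check in _DOMAINS.items():
            val = getattr(cfg, section)[key]
            if not check(val):
                raise ConfigError(f"{section}.{key} = {val!r} outside its domain")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("pipeline config must be a YAML mapping")
        return cls.from_dict(raw)

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def synthetic_gene_grid(
    chrom_labels, chrom_span_bp, gene_every_bp=150_000, gene_len_bp=30_000, lncrna_every=7
) -> list[GeneAnnotation]:
    """Deterministic synthetic gene annotation tiled over simulated
    coordinates (every 7th gene is a lncRNA), so annotation stages run on
    fully synthetic datasets."""
    genes = []
    k = 0
    for c in chrom_labels:
        start = gene_every_bp // 2
        while start + gene_len_bp < chrom_span_bp:
            biotype = "lncRNA" if (k % lncrna_every) == lncrna_every - 1 else "protein_coding"
            genes.append(
                GeneAnnotation(
                    gene_id=f"SYNG{k:05d}",
                    chrom=c,
                    start_bp=start,
                    end_bp=start + gene_len_bp,
                    biotype=biotype,
                )
            )
            k += 1
            start += gene_every_bp
    return genes


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_genes_bed(genes, path):
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start_bp - 1}\t{g.end_bp}\t{g.gene_id}\t0\t+\t{g.biotype}\n")


def run_pipeline(config: PipelineConfig, run_dir) -> dict:
    """Execute all stages in dependency order; returns the manifest."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(run_dir / "run.log")
    log.addHandler(fh)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: getattr(config, k) for k in ("simulate", "scan", "validate", "ihs", "annotate")
        },
        "stages": [],
        "outputs": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                fn()
            except Exception as exc:  # noqa: BLE001
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(
                {"name": name, "seed": config.stage_seed(name), "seconds": time.time() - t0}
            )
            log.info("stage %s: done", name)

        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        if not config.simulate.get("enabled", True):
            _load_inputs(config, state)
            return
        sim_kwargs = {k: v for k, v in config.simulate.items() if k != "enabled"}
        sim_kwargs["planted_blocks"] = [tuple(b) for b in sim_kwargs.get("planted_blocks", [])]
        sim_kwargs["planted_sweeps"] = [tuple(s) for s in sim_kwargs.get("planted_sweeps", [])]
        sim = simulate_dataset(
            SimulationConfig(**sim_kwargs), seed=config.stage_seed("simulate")
        )
        state["panel"] = sim.panel
        state["dosages"] = sim.truth.dosage_matrix()
        state["truth"] = sim.truth
        span = config.simulate["n_snps_per_chrom"] * config.simulate["snp_spacing_bp"]
        state["genes"] = synthetic_gene_grid(sim.panel.chromosomes(), span)
        state["rmap"] = _uniform_map(
            sim.panel.chromosomes(), span, config.simulate["rate_cM_per_Mb"]
        )
        write_vcf(sim.panel, run_dir / "admixed.vcf")
        write_truth(sim.truth, str(run_dir / "truth"))
        _write_genes_bed(state["genes"], run_dir / "genes.bed")
        manifest["outputs"]["simulate"] = ["admixed.vcf", "truth.dosage.txt", "genes.bed"]

    @stage("profile")
    def _profile():
        state["profile"] = snp_admixture_profile(state["dosages"])
        df = pd.DataFrame(
            {
                "chrom": state["profile"].chrom,
                "pos": state["profile"].pos_bp,
                "admix_prop": state["profile"].admix_prop,
            }
        )
        df.to_csv(run_dir / "profile.tsv", sep="\t", index=False)
        manifest["outputs"]["profile"] = ["profile.tsv"]

    @stage("scan")
    def _scan():
        prof = state["profile"]
        stats = chromosome_stats(prof)
        blocks = detect_outlier_blocks(
            prof,
            stats,
            k_sd=config.scan["k_sd"],
            min_snps=config.scan["min_snps"],
            scope=config.scan["scope"],
        )
        deserts = detect_ancestry_deserts(
            prof, threshold=config.scan["desert_threshold"], min_snps=config.scan["min_snps"]
        )
        state["blocks"] = blocks
        state["deserts"] = deserts
        write_blocks_bed(blocks + deserts, run_dir / "blocks.bed")
        write_blocks_table(
            summarize_blocks(blocks, prof, state.get("genes")), run_dir / "blocks.tsv"
        )
        manifest["outputs"]["scan"] = ["blocks.bed", "blocks.tsv"]

    @stage("validate")
    def _validate():
        report = validate_detection(
            state["profile"],
            seed=config.stage_seed("validate"),
            n_blocks=config.validate["n_blocks"],
            min_len=config.validate["min_len"],
            max_len=config.validate["max_len"],
            k_sd=config.scan["k_sd"],
            min_snps=config.scan["min_snps"],
        )
        (run_dir / "error_rates.json").write_text(json.dumps(report.to_dict(), indent=2))
        state["error_rates"] = report
        manifest["outputs"]["validate"] = ["error_rates.json"]

    @stage("ihs")
    def _ihs():
        records = ihs_scan(
            state["panel"],
            maf_min=config.ihs["maf_min"],
            bin_width=config.ihs["bin_width"],
            cutoff=config.ihs["cutoff"],
        )
        records.to_csv(run_dir / "ihs.tsv", sep="\t", index=False)
        state["ihs"] = records
        state["significant"] = significant_snps(records)
        manifest["outputs"]["ihs"] = ["ihs.tsv"]

    @stage("annotate")
    def _annotate():
        genes = state.get("genes")
        if genes is None:
            raise StageError("no gene annotation available")
        sig = state["significant"]
        blocks = state["blocks"]
        in_blocks = []
        for _, row in sig.iterrows():
            for b in blocks:
                if row["chrom"] == b.chrom and b.start_bp <= row["pos"] <= b.end_bp:
                    in_blocks.append((row["chrom"], int(row["pos"])))
                    break
        contexts = classify_snps(in_blocks, genes, config.annotate["window_bp"]) if in_blocks else []
        calls = cai_genes(blocks, in_blocks, genes, config.annotate["proximal_window"])
        summary = {
            "n_significant_in_blocks": len(in_blocks),
            "category_counts": category_counts(contexts) if contexts else {},
            "fdr_percent": fdr_estimate(contexts)[1] if contexts else None,
            "cai_genes": [asdict(c) for c in calls],
        }
        (run_dir / "annotation.json").write_text(json.dumps(summary, indent=2))
        state["annotation"] = summary
        manifest["outputs"]["annotate"] = ["annotation.json"]

    @stage("correlate")
    def _correlate():
        global_res, per_chrom = admixture_vs_recombination(state["profile"], state["rmap"])
        rows = []
        if global_res is not None:
            rows.append({"scope": "global", **_corr_row(global_res)})
        for c, res in (per_chrom or {}).items():
            rows.append({"scope": str(c), **_corr_row(res)})
        pd.DataFrame(rows).to_csv(run_dir / "correlations.tsv", sep="\t", index=False)
        manifest["outputs"]["correlate"] = ["correlations.tsv"]

    @stage("report")
    def _report():
        paths = report(run_dir, state)
        manifest["outputs"]["report"] = [p.name for p in paths]

    checksums = {}
    for files in manifest["outputs"].values():
        for name in files:
            p = run_dir / name
            if p.exists():
                checksums[name] = _sha256(p)
    manifest["checksums"] = checksums
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.removeHandler(fh)
    fh.close()
    return manifest


def _corr_row(res):
    return {
        "r": res.r,
        "df": res.df,
        "p": res.p_two_sided,
        "slope": res.slope,
        "intercept": res.intercept,
        "significant": res.significant,
    }


def _uniform_map(chrom_labels, span_bp, rate):
    from .types import RecombinationMap

    chroms, pos, rates = [], [], []
    for c in chrom_labels:
        chroms += [c, c]
        pos += [1, span_bp]
        rates += [rate, rate]
    return RecombinationMap(
        chrom=np.array(chroms, dtype=object),
        pos_bp=np.array(pos),
        rate_cM_per_Mb=np.array(rates),
    )


def report(run_dir, state=None) -> list[Path]:
    """Emit the summary tables: a block table with a Mean row and a
    SNP-context summary."""
    run_dir = Path(run_dir)
    blocks_tsv = run_dir / "blocks.tsv"
    paths = []
    if blocks_tsv.exists():
        df = pd.read_csv(blocks_tsv, sep="\t")
        out = run_dir / "report_blocks.tsv"
        df.to_csv(out, sep="\t", index=False)
        paths.append(out)
    ann = run_dir / "annotation.json"
    if ann.exists():
        out = run_dir / "report_contexts.json"
        out.write_text(ann.read_text())
        paths.append(out)
    return paths


def _load_inputs(config: PipelineConfig, state: dict) -> None:
    inp = config.inputs
    if not (inp.get("dosage") and inp.get("snpinfo")):
        raise ConfigError("simulate disabled and no dosage inputs supplied")
    state["dosages"] = read_ancestry_dosage(inp["dosage"], inp["snpinfo"])
    if inp.get("genotypes"):
        state["panel"] = read_genotypes(inp["genotypes"])
    if inp.get("genes"):
        state["genes"] = read_gene_annotation(inp["genes"])
    if inp.get("recomb_map"):
        state["rmap"] = read_recombination_map(inp["recomb_map"])
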