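"""Randomised-chromosome resampling for block-detection error rates.

38 segments of 10-150 consecutive SNPs are drawn uniformly from the
autosomal admixture profile and concatenated into a "randomised
chromosome", which is then scanned with the same outlier rule as real
chromosomes (its own mean + k x SD threshold).  Comparing each segment's
significance status in the randomised context against the original
per-chromosome scan yields empirical false-positive and false-negative
rates for OHA-block detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .block_scan import SNPAdmixtureProfile, chromosome_stats, detect_outlier_blocks


@dataclass(frozen=True)
class Segment:
    """A sampled run of consecutive profile SNPs."""

    chrom: str
    start_idx: int  # index within the chromosome
    n_snps: int
    global_start: int  # index into the flat profile


@dataclass
class RandomisedChromosome:
    segments: list
    admix_prop: np.ndarray  # concatenation of the segments' profile values

    @property
    def n_snps(self) -> int:
        return len(self.admix_prop)


@dataclass
class ErrorRateReport:
    n_blocks: int
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def fp_rate(self) -> float:
        return self.fp / self.n_blocks

    @property
    def fn_rate(self) -> float:
        return self.fn / self.n_blocks

    @property
    def fp_percent(self) -> int:
        return round(100 * self.fp_rate)

    @property
    def fn_percent(self) -> int:
        return round(100 * self.fn_rate)

    def to_dict(self) -> dict:
        return {
            "n_blocks": self.n_blocks,
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "fp_rate": self.fp_rate,
            "fn_rate": self.fn_rate,
            "fp_percent": self.fp_percent,
            "fn_percent": self.fn_percent,
        }


def sample_random_block(
    profile: SNPAdmixtureProfile,
    rng: np.random.Generator,
    min_len: int = 10,
    max_len: int = 150,
) -> Segment:
    """Draw one segment: chromosome uniform, start uniform, length uniform
    in [min_len, max_len].

    A segment overrunning the chromosome end is truncated; if truncation
    takes it below ``min_len`` the draw is repeated.
    """
    chroms = profile.chromosomes()
    chrom_idx = {c: np.flatnonzero(profile.chrom == c) for c in chroms}
    while True:
        c = chroms[rng.integers(len(chroms))]
        idx = chrom_idx[c]
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(len(idx)))
        length = min(length, len(idx) - start)
        if length >= min_len:
            return Segment(
                chrom=c, start_idx=start, n_snps=length, global_start=int(idx[start])
            )


def build_randomised_chromosome(
    profile: SNPAdmixtureProfile,
    rng: np.random.Generator,
    n_blocks: int = 38,
    min_len: int = 10,
    max_len: int = 150,
) -> RandomisedChromosome:
    """Concatenate ``n_blocks`` independently sampled segments (with
    replacement) in draw order."""
    if profile.n_snps == 0:
        raise ValueError("empty profile")
    segments = [sample_random_block(profile, rng, min_len, max_len) for _ in range(n_blocks)]
    values = np.concatenate(
        [profile.admix_prop[s.global_start : s.global_start + s.n_snps] for s in segments]
    )
    return RandomisedChromosome(segments=segments, admix_prop=values)


def _segment_overlaps_blocks(seg_indices: np.ndarray, blocks) -> bool:
    """Majority-overlap rule: >50% of the segment's SNP indices fall
    inside some detected block (index ranges, inclusive)."""
    if not blocks:
        return False
    inside = np.zeros(len(seg_indices), dtype=bool)
    for b in blocks:
        inside |= (seg_indices >= b.start_idx) & (seg_indices <= b.end_idx)
    return inside.mean() > 0.5


def classify_error_rates(
    rand_chrom: RandomisedChromosome,
    original_blocks,
    k_sd: float = 3.0,
    min_snps: int = 10,
    ddof: int = 0,
) -> ErrorRateReport:
    """Re-run outlier detection on the randomised chromosome and compare
    segment status against the original scan.

    The randomised chromosome's own mean and SD set its threshold.  A
    segment is significant in either context when more than half its SNPs
    lie inside a detected block.  FP: significant in the randomised
    chromosome but not originally; FN: the reverse.
    """
    if original_blocks and any(b.start_idx is None for b in original_blocks):
        raise ValueError("original blocks must carry profile SNP indices")
    n = rand_chrom.n_snps
    pseudo = SNPAdmixtureProfile(
        chrom=np.array(["rand"] * n, dtype=object),
        pos_bp=np.arange(1, n + 1, dtype=np.int64),
        admix_prop=rand_chrom.admix_prop,
        n_individuals=0,
    )
    stats = chromosome_stats(pseudo, ddof=ddof)
    rand_blocks = detect_outlier_blocks(pseudo, stats, k_sd=k_sd, min_snps=min_snps)

    tp = tn = fp = fn = 0
    offset = 0
    for seg in rand_chrom.segments:
        rand_indices = np.arange(offset, offset + seg.n_snps)
        orig_indices = np.arange(seg.global_start, seg.global_start + seg.n_snps)
        offset += seg.n_snps
        sig_rand = _segment_overlaps_blocks(rand_indices, rand_blocks)
        sig_orig = _segment_overlaps_blocks(orig_indices, original_blocks)
        if sig_rand and sig_orig:
            tp += 1
        elif sig_rand and not sig_orig:
            fp += 1
        elif not sig_rand and sig_orig:
            fn += 1
        else:
            tn += 1
    return ErrorRateReport(n_blocks=len(rand_chrom.segments), tp=tp, tn=tn, fp=fp, fn=fn)


def validate_detection(
    profile: SNPAdmixtureProfile,
    seed: int,
    n_blocks: int = 38,
    min_len: int = 10,
    max_len: int = 150,
    k_sd: float = 3.0,
    min_snps: int = 10,
    ddof: int = 0,
) -> ErrorRateReport:
    """Convenience wrapper: original scan + one randomised-chromosome round."""
    rng = np.random.default_rng(seed)
    stats = chromosome_stats(profile, ddof=ddof)
    original = detect_outlier_blocks(profile, stats, k_sd=k_sd, min_snps=min_snps)
    rand = build_randomised_chromosome(profile, rng, n_blocks, min_len, max_len)
    return classify_error_rates(rand, original, k_sd=k_sd, min_snps=min_snps, ddof=ddof)
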