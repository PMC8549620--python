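"""EHH/iHS: oracle equivalence, integration arithmetic, standardization."""

import itertools
from math import comb

import numpy as np
import pytest

from introscan import (
    bonferroni_significant,
    ehh,
    ihh,
    ihs_scan,
    plant_sweep,
    significant_snps,
)
from introscan.selection import EHHCurve
from introscan.simulate import SimulationConfig, simulate_dataset, simulate_haplotypes

from conftest import make_panel


def ehh_oracle(hap, core, allele_code, direction):
    """Brute force: group carrier haplotypes by exact string identity over
    the window at every offset."""
    carriers = [i for i in range(hap.shape[0]) if hap[i, core] == allele_code]
    n = len(carriers)
    denom = comb(n, 2)
    if direction == "downstream":
        cols = list(range(core + 1, hap.shape[1]))
    else:
        cols = list(range(core - 1, -1, -1))
    values = [1.0]
    for stop in range(1, len(cols) + 1):
        window = cols[:stop]
        groups = {}
        for i in carriers:
            key = tuple(hap[i, j] for j in window)
            groups[key] = groups.get(key, 0) + 1
        values.append(sum(comb(c, 2) for c in groups.values()) / denom)
    return values


class TestEHH:
    def test_identical_carriers_stay_one(self):
        hap = np.tile(np.array([0, 1, 0, 1, 1], dtype=np.int8), (6, 1))
        panel = make_panel(hap)
        curve = ehh(panel, core_index=0, allele="ancestral", direction="downstream")
        np.testing.assert_allclose(curve.ehh, 1.0)

    def test_two_two_split_gives_third(self):
        # 4 carriers of allele 0 at the core split 2/2 at the next SNP
        hap = np.array(
            [[0, 0, 0], [0, 0, 0], [0, 1, 0], [0, 1, 0], [1, 0, 0], [1, 0, 0]],
            dtype=np.int8,
        )
        panel = make_panel(hap)
        curve = ehh(panel, 0, allele="ancestral", direction="downstream")
        assert curve.ehh[1] == pytest.approx((1 + 1) / 6)  # = 1/3

    def test_matches_brute_force_oracle(self, rng):
        """Exhaustive check against string-identity grouping on random small
        panels (<= 10 haplotypes x 12 SNPs)."""
        for _ in range(30):
            n_hap = int(rng.integers(2, 6)) * 2
            n_snp = int(rng.integers(3, 13))
            hap = (rng.random((n_hap, n_snp)) < rng.uniform(0.2, 0.8, n_snp)).astype(np.int8)
            panel = make_panel(hap)
            for core, direction in itertools.product(range(n_snp), ["downstream", "upstream"]):
                for allele, code in [("ancestral", 0), ("derived", 1)]:
                    n_car = int((hap[:, core] == code).sum())
                    curve = ehh(panel, core, allele=allele, direction=direction)
                    if n_car < 2:
                        assert not curve.valid
                        continue
                    np.testing.assert_allclose(
                        curve.ehh, ehh_oracle(hap, core, code, direction), atol=1e-12
                    )

    def test_non_increasing_on_random_panels(self, rng):
        for _ in range(200):
            hap = (rng.random((12, 10)) < 0.5).astype(np.int8)
            panel = make_panel(hap)
            core = int(rng.integers(10))
            curve = ehh(panel, core, allele="derived", direction="downstream")
            if curve.valid:
                assert (np.diff(curve.ehh) <= 1e-12).all()
                assert ((curve.ehh >= 0) & (curve.ehh <= 1)).all()

    def test_fewer_than_two_carriers_invalid(self):
        hap = np.zeros((4, 3), dtype=np.int8)
        hap[0, 0] = 1
        panel = make_panel(hap)
        assert not ehh(panel, 0, allele="derived").valid


class TestIHH:
    def test_rectangle(self):
        # EHH 1 over 1000 bp then an immediate drop below the cutoff
        curve = EHHCurve(0, "derived", "downstream",
                         np.array([0.0, 1000.0, 1025.0]), np.array([1.0, 1.0, 0.0]),
                         10, True)
        value, reached = ihh(curve, cutoff=0.05)
        assert reached
        assert value == pytest.approx(1000.0, rel=0.02)

    def test_linear_decay_closed_form(self):
        curve = EHHCurve(0, "derived", "downstream",
                         np.array([0.0, 1000.0]), np.array([1.0, 0.05 - 1e-12]), 10, True)
        value, reached = ihh(curve)
        assert reached
        assert value == pytest.approx((1 + 0.05) / 2 * 1000, rel=1e-6)

    def test_distance_doubling_doubles_ihh(self, rng):
        e = np.sort(rng.uniform(0, 1, 8))[::-1]
        e[0] = 1.0
        d = np.sort(rng.uniform(0, 5000, 8))
        d[0] = 0.0
        c1 = EHHCurve(0, "derived", "downstream", d, e, 10, True)
        c2 = EHHCurve(0, "derived", "downstream", 2 * d, e, 10, True)
        assert ihh(c2)[0] == pytest.approx(2 * ihh(c1)[0])

    def test_never_reaching_cutoff_flagged(self):
        curve = EHHCurve(0, "derived", "downstream",
                         np.array([0.0, 500.0]), np.array([1.0, 0.9]), 10, True)
        _, reached = ihh(curve)
        assert not reached


def neutral_panel(seed, n_snps=1200, n_hap=120, spacing=25_000):
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.05, 0.95, n_snps)
    hap = simulate_haplotypes(freqs, n_hap, rng)
    return make_panel(hap, positions=np.arange(1, n_snps + 1) * spacing)


class TestIHSScan:
    def test_allele_swap_negates_unihs(self):
        panel = neutral_panel(1, n_snps=120, n_hap=40)
        anc0 = np.zeros(panel.n_snps, dtype=np.int8)
        anc1 = np.ones(panel.n_snps, dtype=np.int8)
        a = ihs_scan(panel, ancestral=anc0)
        b = ihs_scan(panel, ancestral=anc1)
        both = (a["valid"] & b["valid"]).to_numpy()
        np.testing.assert_allclose(
            a.loc[both, "unihs"].to_numpy(), -b.loc[both, "unihs"].to_numpy(), atol=1e-10
        )

    def test_standardization_identity_neutral(self):
        """Per-bin mean ~0, SD ~1, and ~4.6% of |iHS| > 2 under neutrality."""
        panel = neutral_panel(2, n_snps=2500, n_hap=120)
        df, bins = ihs_scan(panel, return_bins=True, maf_min=0.05)
        v = df[df["valid"]]
        assert len(v) > 1500
        groups = bins.group_of_bin[
            np.clip((v["freq_der"] / 0.025).astype(int), 0, len(bins.group_of_bin) - 1)
        ]
        for gid in np.unique(groups):
            sub = v.loc[np.asarray(groups) == gid, "ihs"]
            assert abs(sub.mean()) < 0.05
            assert abs(sub.std(ddof=0) - 1) < 0.05
        frac = (v["ihs"].abs() > 2).mean()
        assert abs(frac - 0.046) < 0.02

    def test_small_bins_merged(self):
        panel = neutral_panel(3, n_snps=200, n_hap=30)
        df, bins = ihs_scan(panel, return_bins=True)
        for gid, n in bins.count.items():
            assert n >= 10 or len(bins.count) == 1

    def test_planted_sweep_detected(self):
        rng = np.random.default_rng(4)
        panel = neutral_panel(4, n_snps=1000, n_hap=120)
        # moderate baseline derived frequency so the swept core stays inside
        # the scan's frequency window
        panel.hap_matrix[:, 500] = (rng.random(120) < 0.2).astype(np.int8)
        core = plant_sweep(panel, "chr1", 501 * 25_000, 0.8, 500_000, rng)
        df = ihs_scan(panel)
        row = df[df["pos"] == panel.pos_bp[core]]
        assert row["valid"].iloc[0]
        assert abs(row["ihs"].iloc[0]) > 2


class TestThresholds:
    def make_records(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos": [1, 2, 3],
                "ihs": [2.5, 1.9, 2.0],
                "p_value": [0.012, 0.01, 0.01],
                "valid": [True, True, True],
            }
        )

    def test_joint_criterion(self):
        kept = significant_snps(self.make_records())
        assert list(kept["pos"]) == [1]  # 1.9 fails |iHS|; 2.0 exactly is excluded

    def test_bonferroni_threshold(self):
        import pandas as pd

        n = 1000
        rec = pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "pos": np.arange(n),
                "ihs": np.zeros(n),
                "p_value": np.full(n, 1.0),
                "valid": [True] * n,
            }
        )
        rec.loc[0, "p_value"] = 1e-6  # < 0.05/1000
        rec.loc[1, "p_value"] = 1e-4  # > 0.05/1000
        kept = bonferroni_significant(rec)
        assert list(kept["pos"]) == [0]

    def test_neutral_family_wise_control(self):
        hits = 0
        for seed in range(10):
            panel = neutral_panel(100 + seed, n_snps=400, n_hap=80)
            df = ihs_scan(panel)
            if len(bonferroni_significant(df)) > 0:
                hits += 1
        assert hits <= 1
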