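"""DMR and PMD segmentation behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from methmir.annotation import GeneModel
from methmir.segmentation import (assign_genes_to_regions, detect_dmrs,
                                  detect_pmds)


def make_calls(positions, fracs, coverage=20, chrom="chr1"):
    mc = np.round(np.asarray(fracs) * coverage).astype(int)
    return pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(positions, dtype=int),
        "strand": "+", "context": "CG", "mc_reads": mc,
        "total_reads": coverage})


class TestDmr:
    def test_identical_call_sets_yield_nothing(self, rng):
        pos = np.sort(rng.choice(50_000, size=400, replace=False))
        fr = rng.choice([0.0, 1.0], size=400)
        calls = make_calls(pos, fr)
        assert len(detect_dmrs(calls, calls.copy())) == 0

    def test_extreme_window_matches_hypergeometric_term(self):
        """A 0/10 vs B 10/10 methylated: one-sided p = 1 / C(20, 10)."""
        pos = np.arange(10) * 50
        a = make_calls(pos, np.zeros(10))
        b = make_calls(pos, np.ones(10))
        regions = detect_dmrs(a, b, window=1000, fdr=0.05)
        assert len(regions) == 1
        expected_p = 1.0 / comb(20, 10, exact=True)
        assert regions["min_q"].iloc[0] == pytest.approx(expected_p)

    def test_fdr_monotonicity(self, rng):
        pos = np.sort(rng.choice(200_000, size=2000, replace=False))
        fr_a = rng.choice([0.0, 1.0], size=2000, p=[0.6, 0.4])
        fr_b = rng.choice([0.0, 1.0], size=2000, p=[0.4, 0.6])
        a, b = make_calls(pos, fr_a), make_calls(pos, fr_b)
        loose = detect_dmrs(a, b, fdr=0.2)
        strict = detect_dmrs(a, b, fdr=0.01)
        loose_bases = sum(loose["end"] - loose["start"])
        strict_bases = sum(strict["end"] - strict["start"])
        assert strict_bases <= loose_bases

    def test_window_below_one_raises(self):
        calls = make_calls([1], [1.0])
        with pytest.raises(ValueError, match="window"):
            detect_dmrs(calls, calls, window=0)


class TestPmd:
    def test_fully_methylated_chromosome_has_none(self):
        pos = np.arange(0, 100_000, 100)
        calls = make_calls(pos, np.ones(pos.size))
        assert len(detect_pmds(calls)) == 0

    def test_boundary_mean_is_strictly_below(self):
        """A window at exactly the 70% threshold is not partially
        methylated; just below it is."""
        pos = np.arange(0, 10_000, 100)
        at_threshold = make_calls(pos, np.full(pos.size, 0.70), coverage=10)
        assert len(detect_pmds(at_threshold, threshold=0.70)) == 0
        below = make_calls(pos, np.full(pos.size, 0.69), coverage=100)
        assert len(detect_pmds(below, threshold=0.70)) == 1

    def test_threshold_monotonicity(self, rng):
        pos = np.arange(0, 300_000, 75)
        fr = rng.uniform(0.3, 1.0, size=pos.size)
        calls = make_calls(pos, fr)
        lo = detect_pmds(calls, threshold=0.5)
        hi = detect_pmds(calls, threshold=0.8)
        assert sum(lo["end"] - lo["start"]) <= sum(hi["end"] - hi["start"])

    def test_planted_domain_recovery(self, rng):
        """A 100-kb 0.4-methylation domain in a 0.9 background is found
        with both boundaries inside one window."""
        pos = np.arange(0, 500_000, 80)
        fr = np.full(pos.size, 0.9)
        inside = (pos >= 201_500) & (pos < 301_500)
        fr[inside] = 0.4
        calls = make_calls(pos, fr, coverage=12)
        regions = detect_pmds(calls)
        assert len(regions) == 1
        assert abs(regions["start"].iloc[0] - 201_500) <= 10_000
        assert abs(regions["end"].iloc[0] - 301_500) <= 10_000


class TestGeneAssignment:
    @staticmethod
    def gene(gid, chrom, lo, hi):
        return GeneModel(gid, chrom, "+", lo + 1000, (lo, hi),
                         (hi + 100, hi + 200))

    def regions(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df.attrs["kind"] = "DMR"
        return df

    def test_promoter_inside_region(self):
        genes = [self.gene("g1", "chr1", 5_000, 6_200)]
        flags = assign_genes_to_regions(genes,
                                        self.regions([("chr1", 4000, 8000)]))
        assert flags["g1"]

    def test_chromosome_without_regions(self):
        genes = [self.gene("g1", "chr9", 5_000, 6_200)]
        flags = assign_genes_to_regions(genes,
                                        self.regions([("chr1", 0, 10_000)]))
        assert not flags["g1"]

    def test_single_base_overlap_counts(self, rng):
        """Boundary enumeration against a naive interval-overlap oracle."""
        genes = [self.gene(f"g{i}", "chr1", s, s + 1200)
                 for i, s in enumerate(rng.integers(0, 50_000, size=300))]
        regs = [("chr1", int(s), int(s) + int(ln))
                for s, ln in zip(rng.integers(0, 50_000, size=40),
                                 rng.integers(1, 3000, size=40))]
        flags = assign_genes_to_regions(genes, self.regions(regs))
        for g in genes:
            s, e = g.promoter_interval
            naive = any(s < re_ and rs < e for _, rs, re_ in regs)
            assert flags[g.gene_id] == naive
        # the in/out split is an exhaustive partition
        assert flags.size == len(genes)

    def test_touching_edge_is_not_overlap(self):
        genes = [self.gene("g1", "chr1", 5_000, 6_200)]
        touching = self.regions([("chr1", 6_200, 7_000)])
        one_base = self.regions([("chr1", 6_199, 7_000)])
        assert not assign_genes_to_regions(genes, touching)["g1"]
        assert assign_genes_to_regions(genes, one_base)["g1"]
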