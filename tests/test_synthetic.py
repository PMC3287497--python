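"""The coupled synthetic-genome generator."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from methmir import methylome, mirna, evolution, expression
from methmir.synthetic import (SimulationConfig, draw_gene_features,
                               ground_truth_report, simulate)


def tree_digest(d, skip_suffixes=(".fai",)):
    h = hashlib.sha256()
    for p in sorted(Path(d).rglob("*")):
        if p.is_file() and p.suffix not in skip_suffixes:
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestLatentCouplings:
    def test_null_coupling_gives_zero_spearman(self):
        cfg = SimulationConfig(n_genes=5000, seed=5, rho_meth_targets=0.0)
        feats = draw_gene_features(cfg, np.random.default_rng(cfg.seed))
        rho, _ = spearmanr(feats["m_star"], feats["Nt_true"])
        assert rho == pytest.approx(0.0, abs=0.03)

    def test_configured_coupling_is_calibrated(self):
        """Monte-Carlo check of the copula calibration: the realized
        Spearman at n=5000 sits within +/-0.05 of the -0.29 target,
        averaged over independent seeds."""
        rhos = []
        for seed in range(8):
            cfg = SimulationConfig(n_genes=5000, seed=seed)
            feats = draw_gene_features(cfg, np.random.default_rng(seed))
            rhos.append(spearmanr(feats["m_star"], feats["Nt_true"])[0])
        assert np.mean(rhos) == pytest.approx(-0.29, abs=0.02)
        assert all(abs(r + 0.29) < 0.05 for r in rhos)

    def test_infeasible_coupling_raises_with_bound(self):
        # a severely discrete count marginal (mostly zeros) caps the
        # achievable Spearman well below the requested -0.9
        cfg = SimulationConfig(n_genes=100, rho_meth_targets=-0.9,
                               nb_mean=0.3, nb_size=0.2)
        with pytest.raises(ValueError, match="achievable bound"):
            draw_gene_features(cfg, np.random.default_rng(0))

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho_meth_targets"):
            SimulationConfig(rho_meth_targets=1.5).validate()


class TestDeterminism:
    def test_same_seed_is_byte_identical(self, small_config, tmp_path):
        cfg2 = SimulationConfig(**{**small_config.__dict__})
        a = simulate(small_config, tmp_path / "a")
        b = simulate(cfg2, tmp_path / "b")
        assert tree_digest(a.out_dir) == tree_digest(b.out_dir)


class TestRoundTrip:
    """Every emitted file parses with the package's own readers."""

    def test_calls_round_trip(self, small_bundle):
        for cell in ("H1", "IMR90"):
            calls = methylome.read_calls(small_bundle.paths[f"calls_{cell}"])
            assert (calls["mc_reads"] <= calls["total_reads"]).all()
            assert set(calls["context"]) <= {"CG", "CHH"}

    def test_targets_round_trip(self, small_bundle):
        t = mirna.read_target_table(small_bundle.paths["targets"])
        counts = mirna.count_target_sites(t, source="mirtarget2")
        truth = small_bundle.truth.set_index("gene_id")
        common = counts.index.intersection(truth.index)
        assert (counts.loc[common]
                == truth.loc[common, "Nt_true"]).all()

    def test_alignments_round_trip(self, small_bundle):
        pairs = evolution.read_pair_fasta(small_bundle.paths["utr3_pairs"])
        maf = evolution.read_maf_by_gene(small_bundle.paths["utr3_maf"])
        truth = small_bundle.truth
        assert len(pairs) == len(truth)
        assert len(maf) == len(truth)
        block = next(iter(maf.values()))
        assert set(block) == {"human", "chimp", "macaque"}

    def test_expression_round_trip(self, small_bundle):
        m = expression.read_matrix(small_bundle.paths["expression"])
        pm = pd.read_csv(small_bundle.paths["probe_map"], sep="\t",
                         index_col=0)["gene_id"]
        collapsed = expression.collapse_probes(m, pm)
        assert len(collapsed) == len(small_bundle.truth)


class TestGroundTruth:
    def test_every_gene_appears_exactly_once(self, small_bundle):
        report = ground_truth_report(small_bundle)
        assert report["gene_id"].is_unique
        assert len(report) == small_bundle.config.n_genes

    def test_planted_membership_flags(self, small_bundle):
        report = ground_truth_report(small_bundle).set_index("gene_id")
        assert report["in_dmr_true"].sum() == small_bundle.config.dmr_count
        assert report["in_pmd_true"].sum() > 0
        # planted-region genes come from the low-methylation stratum
        assert report.loc[report["in_dmr_true"], "m_star"].max() < 0.4

    def test_truth_joins_with_pipeline_output(self, small_bundle, small_run):
        feats = small_run["features"]
        report = ground_truth_report(small_bundle).set_index("gene_id")
        joined = feats.join(report, how="left", rsuffix="_truth")
        assert not joined["m_star"].isna().any()
        # measured promoter methylation tracks the true latent
        rho, _ = spearmanr(joined["mcg_cg_H1"], joined["m_star"])
        assert rho > 0.9
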