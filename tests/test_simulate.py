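"""Synthetic study generator: pedigree structure, Mendelian gene drop,
reduced-form trait covariance and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from pinesem import reference as ref
from pinesem.kinship import RelationshipMatrix, build_A
from pinesem.simulate import (
    SimulationConfig,
    SimulationError,
    lodgepole_scale_config,
    reference_network,
    simulate_genotypes,
    simulate_pedigree,
    simulate_traits,
)


def small_config(**kw):
    t = kw.pop("n_traits", 3)
    base = dict(
        n_founders=6, n_families=4, offspring_per_family=5, n_snps=50,
        n_genetic_groups=1,
        trait_names=tuple(f"y{i}" for i in range(t)),
        Sigma_a_true=0.4 * np.eye(t), R0_true=0.6 * np.eye(t),
        Lambda_true=np.zeros((t, t)),
        group_means=np.zeros((1, t)),
        design=(1, 1), rep_effect_sd=0.0, set_effect_sd=0.0,
        trait_missing_rates={}, seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestPedigree:
    def test_minimal_construction(self):
        cfg = small_config(n_founders=2, n_families=1, offspring_per_family=3)
        ped = simulate_pedigree(cfg)
        assert len(ped) == 5
        dams = ped.table.loc[ped.table["dam"] != "", "dam"]
        assert len(dams) == 3 and dams.nunique() == 1

    def test_reference_scale_counts(self):
        cfg = lodgepole_scale_config()
        ped = simulate_pedigree(cfg)
        founders = ped.founders()
        assert len(founders) == 52
        offspring = ped.table[ped.table["dam"] != ""]
        assert len(offspring) == 392
        assert offspring["dam"].nunique() == 47
        assert (offspring["sire"] == "").all()  # open pollination

    def test_same_seed_identical(self):
        a = simulate_pedigree(small_config(seed=7))
        b = simulate_pedigree(small_config(seed=7))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_invalid_counts_rejected(self):
        with pytest.raises(SimulationError):
            small_config(n_founders=0)
        with pytest.raises(SimulationError):
            small_config(n_founders=2, n_families=4)


class TestGeneDrop:
    def test_hardy_weinberg_mean(self):
        cfg = small_config(n_founders=2, n_families=1, offspring_per_family=1,
                           n_snps=4000, maf_range=(0.5, 0.5),
                           missing_genotype_rate=0.0)
        geno = simulate_genotypes(simulate_pedigree(cfg), cfg)
        founders = geno.dosages[:2]
        assert set(np.unique(founders)) <= {0.0, 1.0, 2.0}
        assert founders.mean() == pytest.approx(1.0, abs=0.05)

    def test_mendelian_zero_parents(self):
        cfg = small_config(n_founders=2, n_families=1, offspring_per_family=4,
                           n_snps=200, missing_genotype_rate=0.0)
        ped_rows = [
            {"id": "P1", "sire": "", "dam": "", "group": "1"},
            {"id": "P2", "sire": "", "dam": "", "group": "1"},
            {"id": "K1", "sire": "P1", "dam": "P2", "group": "1"},
        ]
        from pinesem.pedigree import Pedigree
        ped = Pedigree(pd.DataFrame(ped_rows))
        geno = simulate_genotypes(ped, cfg)
        zero_loci = (geno.dosages[0] == 0) & (geno.dosages[1] == 0)
        assert zero_loci.any()
        assert (geno.dosages[2, zero_loci] == 0).all()

    def test_founder_frequency_tracks_drawn_maf(self):
        # Monte-Carlo check: with 200 founders (400 alleles) the mean
        # absolute deviation of the empirical frequency stays within the
        # binomial-standard-error budget of 0.02
        cfg = small_config(n_founders=200, n_families=1,
                           offspring_per_family=1, n_snps=5000,
                           missing_genotype_rate=0.0, seed=5)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        p_drawn = np.random.default_rng(cfg.seed + 1).uniform(
            *cfg.maf_range, size=cfg.n_snps)
        founder_rows = [i for i, t in enumerate(geno.ids) if t.startswith("F")]
        p_hat = geno.dosages[founder_rows].mean(axis=0) / 2
        assert np.abs(p_hat - p_drawn).mean() < 0.02

    def test_half_sib_dosage_correlation(self):
        cfg = small_config(n_founders=10, n_families=10,
                           offspring_per_family=2, n_snps=4000,
                           maf_range=(0.3, 0.5), missing_genotype_rate=0.0,
                           seed=3)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        p = geno.allele_frequencies()
        W = geno.dosages - 2 * p
        ids = geno.ids
        corrs = []
        for fam in range(10):
            a = ids.index(f"T{2 * fam + 1:04d}")
            b = ids.index(f"T{2 * fam + 2:04d}")
            corrs.append(np.corrcoef(W[a], W[b])[0, 1])
        assert np.mean(corrs) == pytest.approx(0.25, abs=0.05)


class TestTraits:
    def test_degenerate_iid_standard_normal(self):
        t = 3
        cfg = small_config(
            n_traits=t, n_founders=40, n_families=40,
            offspring_per_family=25,
            Sigma_a_true=1e-8 * np.eye(t), R0_true=np.eye(t),
        )
        study = simulate_traits(simulate_pedigree(cfg), cfg)
        Y = study.traits.values()
        assert Y.shape == (1000, t)
        assert np.allclose(Y.mean(axis=0), 0.0, atol=0.12)
        assert np.allclose(Y.var(axis=0), 1.0, atol=0.15)

    def test_single_edge_variance_propagation(self):
        # y2 = 0.5 y1 + e2 => var(y2) = var2 + 0.25 var1
        lam = np.zeros((2, 2))
        lam[1, 0] = 0.5
        cfg = small_config(
            n_traits=2, n_founders=50, n_families=50, offspring_per_family=40,
            Sigma_a_true=1e-8 * np.eye(2), R0_true=np.diag([1.0, 0.5]),
            Lambda_true=lam, seed=9,
        )
        study = simulate_traits(simulate_pedigree(cfg), cfg)
        v2 = study.traits.values()[:, 1].var()
        assert v2 == pytest.approx(0.5 + 0.25 * 1.0, abs=0.06)

    def test_reduced_form_covariance(self):
        # empirical covariance ~ (I-L)^-1 (Sigma_a k_ii + R0) (I-L)^-T
        t = 3
        lam = np.zeros((t, t))
        lam[1, 0], lam[2, 1] = 0.6, -0.4
        Sa = np.array([[0.5, 0.1, 0.0], [0.1, 0.4, 0.1], [0.0, 0.1, 0.3]])
        R0 = np.diag([0.5, 0.6, 0.7])
        n = 4000
        ids = [f"t{i}" for i in range(n)]
        K = RelationshipMatrix(ids, np.eye(n), "A")
        cfg = small_config(n_traits=t, Sigma_a_true=Sa, R0_true=R0,
                           Lambda_true=lam, seed=2)
        study = simulate_traits(K, cfg)
        inv = np.linalg.inv(np.eye(t) - lam)
        expected = inv @ (Sa + R0) @ inv.T
        emp = np.cov(study.traits.values().T)
        # 3 Monte-Carlo SE per entry, SE ~ sqrt((v_ii v_jj + v_ij^2)/n)
        se = np.sqrt((np.outer(np.diag(expected), np.diag(expected))
                      + expected ** 2) / n)
        assert (np.abs(emp - expected) < 3.2 * se).all()

    def test_true_bvs_and_missingness_bookkeeping(self):
        cfg = small_config(trait_missing_rates={"y0": 0.3}, seed=4)
        study = simulate_traits(simulate_pedigree(cfg), cfg)
        assert len(study.true_bvs) == len(study.traits.ids)
        miss = np.isnan(study.traits.values()[:, 0]).mean()
        assert 0.05 < miss < 0.6
        assert not np.isnan(study.traits.values()[:, 1]).any()

    def test_seed_reproducibility(self):
        cfg = small_config(seed=11)
        a = simulate_traits(simulate_pedigree(cfg), cfg)
        b = simulate_traits(simulate_pedigree(cfg), cfg)
        pd.testing.assert_frame_equal(a.traits.data, b.traits.data)
        pd.testing.assert_frame_equal(a.true_bvs, b.true_bvs)


class TestReferenceNetwork:
    def test_edges_and_values(self):
        dag, lam = reference_network("GBLUP")
        assert dag.n_edges == 12
        idx = {n: i for i, n in enumerate(ref.TRAIT_ORDER)}
        assert lam.values[idx["DECL"], idx["RES"]] == pytest.approx(-0.509)
        assert lam.values[idx["WD"], idx["HT"]] == pytest.approx(0.413)
        assert dag.topological_order()  # acyclic by construction

    def test_truth_matrices_are_valid(self):
        Sa = ref.sigma_a_true()
        assert np.linalg.eigvalsh(Sa)[0] > 0
        assert np.allclose(Sa, Sa.T)
        lam = ref.lambda_true("ABLUP")
        assert np.triu(lam).sum() == 0 and (lam != 0).sum() == 12
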