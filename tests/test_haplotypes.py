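"""EM haplotype reconstruction, LD r², and haplotype-dosage GLM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import haplocc as h
from haplocc.association import fit_logistic
from haplocc.haplotypes import EmptyWindowError, PoolingError, em_haplotypes

from conftest import make_gm, make_subjects


def brute_force_two_snp_loglik(geno):
    """Independent oracle: maximize the HWE phase-mixture likelihood over
    the 4-haplotype frequency simplex by coarse grid + simplex polish."""
    def ll_of(f):
        tot = 0.0
        for g in geno:
            s = 0.0
            for a in itertools.product((0, 1), (0, 1)):
                for b in itertools.product((0, 1), (0, 1)):
                    if a[0] + b[0] == g[0] and a[1] + b[1] == g[1]:
                        s += f[a[0] * 2 + a[1]] * f[b[0] * 2 + b[1]]
            tot += np.log(max(s, 1e-300))
        return tot

    best, bp = -np.inf, None
    step = 0.05
    for i in np.arange(0, 1.0001, step):
        for j in np.arange(0, 1.0001 - i, step):
            for k in np.arange(0, 1.0001 - i - j, step):
                p0 = np.array([i, j, k, 1 - i - j - k])
                v = ll_of(np.clip(p0, 1e-9, None) / max(p0.sum(), 1e-9))
                if v > best:
                    best, bp = v, p0

    def neg(z):
        e = np.exp(z - z.max())
        return -ll_of(e / e.sum())

    res = minimize(neg, np.log(np.clip(bp, 1e-6, None)), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return -res.fun


class TestEm:
    def test_single_snp_equals_allele_frequencies(self):
        geno = np.array([0] * 5 + [1] * 6 + [2] * 4).reshape(-1, 1)
        gm = make_gm(geno, rsids=["s1"])
        t = em_haplotypes(gm, ["s1"])
        freqs = dict(zip(t.haplotypes, t.frequencies))
        n = 15
        assert freqs["A"] == pytest.approx((2 * 5 + 6) / (2 * n))
        assert freqs["G"] == pytest.approx((6 + 2 * 4) / (2 * n))

    def test_unambiguous_two_snp_equals_direct_counts(self):
        # no double heterozygotes: phase is observed
        geno = np.array([[0, 0], [0, 0], [1, 0], [2, 0], [0, 2], [2, 2]])
        gm = make_gm(geno, alleles=[("A", "G"), ("C", "T")])
        t = em_haplotypes(gm)
        freqs = dict(zip(t.haplotypes, t.frequencies))
        # direct haplotype counts over 2n=12: A-C x6, G-C x4? enumerate:
        # rows -> (AC,AC),(AC,AC),(AC,GC),(GC,GC),(AT,AT),(GT,GT)
        assert freqs["A-C"] == pytest.approx(5 / 12)
        assert freqs["G-C"] == pytest.approx(3 / 12)
        assert freqs["A-T"] == pytest.approx(2 / 12)
        assert freqs["G-T"] == pytest.approx(2 / 12)

    def test_matches_brute_force_likelihood(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = int(rng.integers(8, 30))
            geno = rng.integers(0, 3, size=(n, 2))
            gm = make_gm(geno.astype(np.int8))
            t = em_haplotypes(gm)
            assert t.loglik == pytest.approx(
                brute_force_two_snp_loglik(geno), abs=1e-6)

    def test_dosage_rows_sum_to_two(self, study_cohort):
        _, gm, _, _ = study_cohort
        t = em_haplotypes(gm, ["rs12483553", "rs2838950", "rs2838951",
                               "rs17004785"])
        np.testing.assert_allclose(t.dosage_matrix().sum(axis=1), 2.0,
                                   atol=1e-8)
        np.testing.assert_allclose(t.frequencies.sum(), 1.0, atol=1e-8)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(9)
        geno = rng.integers(0, 3, (60, 3)).astype(np.int8)
        gm = make_gm(geno)
        perm = rng.permutation(60)
        gm2 = gm.subset_subjects([gm.subject_ids[i] for i in perm])
        t1, t2 = em_haplotypes(gm), em_haplotypes(gm2)
        f1 = dict(zip(t1.haplotypes, t1.frequencies))
        f2 = dict(zip(t2.haplotypes, t2.frequencies))
        assert set(f1) == set(f2)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-9)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(10)
        geno = rng.integers(0, 3, (50, 2)).astype(np.int8)
        t1 = em_haplotypes(make_gm(geno))
        t2 = em_haplotypes(make_gm(2 - geno))      # consistent major/minor flip
        assert sorted(np.round(t1.frequencies, 9)) == \
            sorted(np.round(t2.frequencies, 9))
        assert t1.loglik == pytest.approx(t2.loglik, abs=1e-8)

    def test_missing_subjects_excluded_and_empty_window_errors(self):
        geno = np.array([[0, -1], [1, 1], [-1, 0]])
        gm = make_gm(geno)
        t = em_haplotypes(gm)
        assert t.subject_ids == ["I1"]
        all_missing = make_gm(np.full((3, 2), -1))
        with pytest.raises(EmptyWindowError):
            em_haplotypes(all_missing)

    def test_phase_posteriors_sum_to_one(self, study_cohort):
        _, gm, _, _ = study_cohort
        t = em_haplotypes(gm, ["rs12483553", "rs2838950"])
        for i in (0, 5, 10):
            phases = t.subject_phases(i)
            assert sum(p for _, p in phases) == pytest.approx(1.0, abs=1e-9)


class TestLd:
    def test_identical_columns_full_ld(self):
        rng = np.random.default_rng(11)
        g = rng.binomial(2, 0.4, 200)
        gm = make_gm(np.column_stack([g, g]), rsids=["a", "b"])
        subjects = make_subjects(np.zeros(200, int))
        assert h.ld_r2(gm, subjects, "a", "b").r2 == pytest.approx(1.0, abs=1e-6)

    def test_coupling_pool_r2_one_and_balanced_pool_r2_zero(self):
        # AB/ab only: genotypes perfectly coupled
        pool = h.HaplotypePool("G", [("AG", 0.5), ("CA", 0.5)])
        dip = h.sample_diplotypes(pool, 400, seed=3)
        minor = pool.minor_matrix()
        geno = minor[dip[:, 0]] + minor[dip[:, 1]]
        gm = make_gm(geno, alleles=[("A", "C"), ("G", "A")], rsids=["a", "b"])
        subjects = make_subjects(np.zeros(400, int))
        assert h.ld_r2(gm, subjects, "a", "b").r2 == pytest.approx(1.0, abs=1e-6)
        # all four haplotypes at 0.25: loci independent, D = 0.  Build an
        # exactly balanced sample from all 16 ordered pairs.
        haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        rows = [haps[i] + haps[j] for i in range(4) for j in range(4)]
        gm2 = make_gm(np.array(rows), rsids=["a", "b"])
        subjects2 = make_subjects(np.zeros(16, int))
        assert h.ld_r2(gm2, subjects2, "a", "b").r2 == pytest.approx(0.0, abs=1e-6)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(12)
        gm = make_gm(np.column_stack([rng.binomial(2, 0.3, 10_000),
                                      rng.binomial(2, 0.4, 10_000)]),
                     rsids=["a", "b"])
        subjects = make_subjects(np.zeros(10_000, int))
        assert h.ld_r2(gm, subjects, "a", "b").r2 < 0.01

    def test_symmetry(self, study_cohort):
        _, gm, subjects, _ = study_cohort
        ab = h.ld_r2(gm, subjects, "rs12483553", "rs17004785")
        ba = h.ld_r2(gm, subjects, "rs17004785", "rs12483553")
        assert ab.r2 == pytest.approx(ba.r2, abs=1e-9)

    def test_monomorphic_errors(self):
        gm = make_gm(np.column_stack([np.zeros(50, int),
                                      np.tile([0, 1], 25)]), rsids=["a", "b"])
        subjects = make_subjects(np.zeros(50, int))
        from haplocc.association import ModelError
        with pytest.raises(ModelError):
            h.ld_r2(gm, subjects, "a", "b")


class TestHaplotypeGlm:
    def _unambiguous_cohort(self, seed=0, n=400):
        """2-SNP genotypes with no double heterozygotes: phase is known."""
        rng = np.random.default_rng(seed)
        rows = np.array([[0, 0], [1, 0], [2, 0], [0, 1], [0, 2], [2, 1],
                         [1, 2], [2, 2]])
        geno = rows[rng.integers(0, len(rows), n)]
        # true haplotype dosages by unique decomposition
        hapset = [(0, 0), (1, 0), (0, 1), (1, 1)]
        dos = np.zeros((n, 4))
        for i, g in enumerate(geno):
            pairs = [(a, b) for a in hapset for b in hapset
                     if a[0] + b[0] == g[0] and a[1] + b[1] == g[1]]
            assert len({frozenset([p, q]) for p, q in pairs}) == 1
            a, b = pairs[0]
            dos[i, hapset.index(a)] += 1
            dos[i, hapset.index(b)] += 1
        beta = np.array([0.0, 0.4, -0.3, 0.6])
        eta = -0.3 + dos @ beta
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return make_gm(geno), make_subjects(y), dos, hapset

    def test_unambiguous_matches_true_count_regression(self):
        gm, subjects, dos, hapset = self._unambiguous_cohort(seed=4)
        res = h.haplotype_glm(gm, subjects, gm.rsids, covariates=(),
                              pool_threshold=0.01)
        # reference = most frequent; rebuild the oracle design accordingly
        ref = res.reference
        labels = ["-".join({0: "A", 1: "G"}[c] for c in hp) for hp in hapset]
        X = pd.DataFrame({"const": np.ones(len(subjects))})
        for lab, col in zip(labels, dos.T):
            if lab == ref or lab in res.pooled_rare:
                continue
            X[f"hap_{lab}"] = col
        if res.pooled_rare:
            X["hap_rare"] = dos[:, [labels.index(r)
                                    for r in res.pooled_rare]].sum(axis=1)
        oracle = fit_logistic(subjects["status"].to_numpy(float), X)
        for term in oracle.params.index:
            assert res.fit.params[term] == pytest.approx(
                oracle.params[term], abs=1e-8)

    def test_refinement_is_noop_when_unambiguous(self):
        gm, subjects, _, _ = self._unambiguous_cohort(seed=5)
        base = h.haplotype_glm(gm, subjects, gm.rsids, covariates=(),
                               pool_threshold=0.01)
        ref = h.haplotype_glm(gm, subjects, gm.rsids, covariates=(),
                              pool_threshold=0.01, refine=True)
        for term in base.fit.params.index:
            assert ref.fit.params[term] == pytest.approx(
                base.fit.params[term], abs=1e-6)

    def test_reference_is_most_frequent_and_rare_pooled(self, study_cohort):
        _, gm, subjects, _ = study_cohort
        res = h.haplotype_glm(gm, subjects,
                              ["rs12483553", "rs2838950", "rs2838951",
                               "rs17004785"])
        assert res.reference == "G-C-G-G"
        ref_rows = res.table[res.table["role"] == "reference"]
        assert len(ref_rows) == 1 and ref_rows["OR"].iloc[0] == 1.0
        rare = res.table[res.table["role"] == "rare"]
        assert len(rare) == 1 and rare["freq"].iloc[0] < 0.05 * 3
        assert all(f >= 0.05 for f in
                   res.table[res.table["role"] == "common"]["freq"])

    def test_pool_threshold_above_reference_errors(self, study_cohort):
        _, gm, subjects, _ = study_cohort
        with pytest.raises(PoolingError):
            h.haplotype_glm(gm, subjects, ["rs12483553", "rs2838950",
                                           "rs2838951", "rs17004785"],
                            pool_threshold=0.60)

    def test_case_control_split_consistent_with_overall(self, study_cohort):
        _, gm, subjects, _ = study_cohort
        res = h.haplotype_glm(gm, subjects,
                              ["rs12483553", "rs2838950", "rs2838951",
                               "rs17004785"])
        t = res.table
        n_case = (subjects.status == 1).sum()
        n_ctrl = (subjects.status == 0).sum()
        blend = (t["case_freq"] * n_case + t["control_freq"] * n_ctrl) \
            / (n_case + n_ctrl)
        np.testing.assert_allclose(blend, t["freq"], atol=0.02)
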