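"""F-statistics, LD and Mantel tests against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from snpqc import (
    DistanceMatrix,
    GenotypeError,
    SimConfig,
    asd_matrix,
    ld_r2,
    mantel,
    nei_fis,
    pairwise_theta,
    simulate_parents,
    wc_components,
    wc_fstats,
)

from conftest import make_gm, R, A, H, M


# ---------------------------------------------------------------------------
# brute-force Weir-Cockerham oracle: scalar transcription of the 1984
# variance-component formulas, one locus at a time
# ---------------------------------------------------------------------------


def wc_oracle_locus(pop_genotypes):
    """pop_genotypes: list (one per population) of genotype codes at one
    locus; returns (a, b, c)."""
    dos = {R: 0, H: 1, A: 2}
    ns, ps, hs = [], [], []
    for geno in pop_genotypes:
        called = [g for g in geno if g != M]
        if not called:
            continue
        n_i = len(called)
        p_i = sum(dos[g] for g in called) / (2 * n_i)
        h_i = sum(1 for g in called if g == H) / n_i
        ns.append(n_i)
        ps.append(p_i)
        hs.append(h_i)
    r = len(ns)
    if r < 2:
        return (np.nan,) * 3
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n**2 for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


WORKED_CALLS = [
    # 2 populations x 4 individuals x 2 loci
    [R, H, H, A, R, R, H, R],
    [H, H, A, A, R, H, R, M],
]
WORKED_POPS = {f"S{j + 1:03d}": ("X" if j < 4 else "Y") for j in range(8)}


class TestWeirCockerham:
    def test_worked_case_matches_brute_force(self):
        gm = make_gm(WORKED_CALLS)
        comp = wc_components(gm, WORKED_POPS)
        for locus_row, codes in zip(comp.itertuples(), WORKED_CALLS):
            a, b, c = wc_oracle_locus([codes[:4], codes[4:]])
            assert locus_row.a == pytest.approx(a, abs=1e-12)
            assert locus_row.b == pytest.approx(b, abs=1e-12)
            assert locus_row.c == pytest.approx(c, abs=1e-12)

    def test_identity_on_worked_case(self):
        st = wc_fstats(make_gm(WORKED_CALLS), WORKED_POPS)
        assert (1 - st.F) == pytest.approx((1 - st.theta) * (1 - st.f), abs=1e-9)

    def test_opposite_fixation_gives_theta_one(self):
        calls = [[R] * 4 + [A] * 4] * 5
        st = wc_fstats(make_gm(calls), WORKED_POPS)
        assert st.theta == pytest.approx(1.0)

    def test_duplicated_population_theta_near_zero(self, rng):
        cfg = SimConfig(populations=(("P", 50),), loci_per_chromosome=14,
                        target_fst=0.05, ploidy=2, missing_rate=0.0, seed=21)
        gm, _ = simulate_parents(cfg)  # 210 loci, HWE-shaped genotypes
        calls = np.hstack([gm.calls, gm.calls[:, rng.permutation(gm.n_samples)]])
        pops = {f"S{j + 1:03d}": ("X" if j < 50 else "Y") for j in range(100)}
        st = wc_fstats(make_gm(calls), pops)
        assert st.theta <= 0 and abs(st.theta) < 0.02

    def test_components_match_oracle_on_simulated_data(self):
        cfg = SimConfig(
            populations=(("P1", 12), ("P2", 9), ("P3", 15)),
            loci_per_chromosome=2,
            target_fst=0.15,
            ploidy=6,
            missing_rate=0.1,
            seed=77,
        )
        gm, truth = simulate_parents(cfg)
        comp = wc_components(gm)
        pops = truth.populations
        cols = {p: [j for j, s in enumerate(gm.samples) if pops[s.sample_id] == p]
                for p in ("P1", "P2", "P3")}
        for i, row in enumerate(comp.itertuples()):
            geno = [list(gm.calls[i, cols[p]]) for p in ("P1", "P2", "P3")]
            a, b, c = wc_oracle_locus(geno)
            assert row.a == pytest.approx(a, abs=1e-10)
            assert row.b == pytest.approx(b, abs=1e-10)
            assert row.c == pytest.approx(c, abs=1e-10)

    def test_single_sample_population_excluded_with_warning(self):
        calls = [[R, A, H, R, A], [H, H, R, A, R]]
        pops = {"S001": "X", "S002": "X", "S003": "X", "S004": "Y", "S005": "Z"}
        # Y and Z have 1 sample each -> excluded; only X remains -> no theta
        with pytest.warns(UserWarning, match="fewer than 2"):
            with pytest.raises(GenotypeError):
                wc_fstats(make_gm(calls), pops)

    def test_order_invariance(self, structured_parents):
        gm, truth, _ = structured_parents
        st1 = wc_fstats(gm)
        perm = np.random.default_rng(0).permutation(gm.n_samples)
        gm2 = gm.subset(sample_ids=[gm.sample_ids[j] for j in perm])
        st2 = wc_fstats(gm2)
        assert st1.theta == pytest.approx(st2.theta, abs=1e-12)
        assert st1.F == pytest.approx(st2.F, abs=1e-12)


class TestPairwiseTheta:
    def test_symmetric_zero_diagonal(self, structured_parents):
        gm, _, _ = structured_parents
        mat = pairwise_theta(gm)
        np.testing.assert_allclose(mat.values, mat.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat.values), 0.0)
        assert (mat.values[~np.eye(4, dtype=bool)] > 0).all()


class TestNeiFis:
    def test_forced_extremes(self):
        # two homozygote classes, no hets: H_obs 0 -> F_IS = 1
        gm = make_gm([[R, A]], populations=["X", "X"])
        assert nei_fis(gm).per_population["X"] == pytest.approx(1.0)
        # all heterozygous: H_obs 1, H_exp 0.5 -> F_IS = -1
        gm2 = make_gm([[H, H, H]], populations=["X"] * 3)
        assert nei_fis(gm2).per_population["X"] == pytest.approx(-1.0)

    def test_monomorphic_population_flagged(self):
        gm = make_gm([[R, R], [R, R]], populations=["X", "X"])
        res = nei_fis(gm)
        assert np.isnan(res.per_population["X"])

    def test_near_zero_without_inbreeding(self):
        cfg = SimConfig(populations=(("P", 200),), loci_per_chromosome=14,
                        target_fst=0.05, ploidy=2, missing_rate=0.0, seed=3)
        gm, _ = simulate_parents(cfg)
        res = nei_fis(gm)
        assert abs(res.per_population["P"]) < 0.05

    def test_positive_under_inbreeding(self):
        cfg = SimConfig(populations=(("P", 200),), loci_per_chromosome=14,
                        target_fst=0.05, ploidy=2, inbreeding_f=0.3,
                        missing_rate=0.0, seed=4)
        gm, _ = simulate_parents(cfg)
        assert nei_fis(gm).per_population["P"] > 0.15


class TestLD:
    def test_identical_locus_pair_r2_one(self):
        gm = make_gm([[R, H, A, R], [R, H, A, R]], chroms=["Chr01"] * 2,
                     positions=[1, 2])
        res = ld_r2(gm)[0]
        assert res.pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        gm = make_gm([[R, H, A, R], [A, H, R, A]], chroms=["Chr01"] * 2,
                     positions=[1, 2])
        res = ld_r2(gm)[0]
        assert res.pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_loci_mean_r2_near_one_over_n(self):
        n = 500
        rng = np.random.default_rng(9)
        calls = rng.choice([R, H, A], size=(40, n), p=[0.25, 0.5, 0.25])
        gm = make_gm(calls.astype(np.int8), chroms=["Chr01"] * 40,
                     positions=list(range(1, 41)))
        res = ld_r2(gm)[0]
        assert res.mean_r2 < 0.01

    def test_monomorphic_pairs_excluded_and_counted(self):
        gm = make_gm([[R, R, R, R], [R, H, A, R], [H, R, A, A]],
                     chroms=["Chr01"] * 3, positions=[1, 2, 3])
        res = ld_r2(gm)[0]
        assert res.n_excluded == 2  # both pairs involving the monomorphic locus
        assert len(res.pairs) == 1

    def test_single_locus_chromosome_empty(self):
        gm = make_gm([[R, H, A]], chroms=["Chr07"], positions=[5])
        res = ld_r2(gm)
        assert len(res[0].pairs) == 0

    def test_genome_wide_mode(self):
        gm = make_gm([[R, H, A, R], [A, H, R, A], [R, R, A, H]],
                     chroms=["Chr01", "Chr02", "Chr03"], positions=[1, 1, 1])
        res = ld_r2(gm, by_chromosome=False)
        assert len(res) == 1 and len(res[0].pairs) == 3


class TestMantel:
    @staticmethod
    def _random_dm(rng, n, labels=None):
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        return DistanceMatrix(labels=labels or [f"s{i}" for i in range(n)], values=v)

    def test_self_comparison(self):
        d = self._random_dm(np.random.default_rng(1), 12)
        res = mantel(d, d, n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_affine_transform_r_one(self):
        d1 = self._random_dm(np.random.default_rng(2), 10)
        d2 = DistanceMatrix(labels=list(d1.labels), values=2.5 * d1.values)
        assert mantel(d1, d2, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_label_alignment_not_order(self):
        rng = np.random.default_rng(3)
        d1 = self._random_dm(rng, 8)
        perm = rng.permutation(8)
        d2 = DistanceMatrix(labels=[d1.labels[i] for i in perm],
                            values=d1.values[np.ix_(perm, perm)])
        assert mantel(d1, d2, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_label_mismatch_raises(self):
        d1 = self._random_dm(np.random.default_rng(4), 5)
        d2 = self._random_dm(np.random.default_rng(5), 5,
                             labels=[f"t{i}" for i in range(5)])
        with pytest.raises(GenotypeError, match="different labels"):
            mantel(d1, d2, n_perm=99)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(6)
        d1 = self._random_dm(rng, 15)
        d2 = self._random_dm(rng, 15)
        r1 = mantel(d1, d2, n_perm=199, seed=42)
        r2 = mantel(d1, d2, n_perm=199, seed=42)
        assert r1 == r2

    def test_agrees_with_skbio(self):
        """Cross-check r and p against scikit-bio's implementation."""
        from skbio.stats.distance import DistanceMatrix as SkbioDM, mantel as sk_mantel

        rng = np.random.default_rng(8)
        base = self._random_dm(rng, 20)
        noise = self._random_dm(rng, 20)
        d2 = DistanceMatrix(labels=list(base.labels),
                            values=0.7 * base.values + 0.3 * noise.values)
        mine = mantel(base, d2, n_perm=999, seed=1)
        corr, pval, _ = sk_mantel(
            SkbioDM(base.values, ids=base.labels),
            SkbioDM(d2.values, ids=d2.labels),
            method="pearson", permutations=999, alternative="greater",
        )
        assert mine.r == pytest.approx(float(corr), abs=1e-12)
        assert mine.p_value == pytest.approx(float(pval), abs=0.02)
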