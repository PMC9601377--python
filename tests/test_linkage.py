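"""EM haplotype-frequency estimation and likelihood-ratio LD testing."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from indelpop.linkage import (
    TwoLocusData,
    all_pairs_ld,
    bonferroni_adjust,
    em_haplotype_frequencies,
    ld_permutation_test,
    lr_statistic,
    null_loglik,
)
from indelpop.simulate import simulate_hwe_genotypes, simulate_multiallelic_locus
from indelpop.types import Locus, ValidationError


def biallelic_profile_oracle(data: TwoLocusData) -> float:
    """Independent maximum of the two-locus likelihood for biallelic pairs.

    The allele frequencies are fixed at their observed values (the marginal
    counts are observed regardless of phase), leaving a single free
    parameter, the gametic disequilibrium D; the profile log-likelihood is
    maximized by a grid scan refined with bounded scalar optimization.
    """
    pa, pb = data.allele_frequencies()

    def loglik_at(dval: float) -> float:
        h = np.array(
            [
                [pa[0] * pb[0] + dval, pa[0] * pb[1] - dval],
                [pa[1] * pb[0] - dval, pa[1] * pb[1] + dval],
            ]
        )
        if np.any(h < -1e-12):
            return -np.inf
        h = np.clip(h, 0.0, None)
        logl = 0.0
        for ia, (a1, a2) in enumerate(data.genotypes_a):
            for ib, (b1, b2) in enumerate(data.genotypes_b):
                c = data.counts[ia, ib]
                if c == 0:
                    continue
                if a1 != a2 and b1 != b2:
                    p = 2 * h[a1, b1] * h[a2, b2] + 2 * h[a1, b2] * h[a2, b1]
                elif a1 != a2 or b1 != b2:
                    p = 2 * h[a1, b1] * h[a2, b2]
                else:
                    p = h[a1, b1] * h[a2, b2]
                logl += c * np.log(max(p, 1e-300))
        return logl

    lo = -min(pa[0] * pb[0], pa[1] * pb[1])
    hi = min(pa[0] * pb[1], pa[1] * pb[0])
    if hi - lo < 1e-12:
        return loglik_at(0.0)
    grid = np.linspace(lo, hi, 2001)
    vals = [loglik_at(d) for d in grid]
    best = int(np.argmax(vals))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(lambda d: -loglik_at(d), bounds=(a, b), method="bounded",
                          options={"xatol": 1e-12})
    return max(vals[best], -res.fun)


def test_complete_association_closed_form():
    col = np.array([[0, 0]] * 50 + [[1, 1]] * 50)
    data = TwoLocusData.from_columns(col, col, 2, 2)
    h, logl = em_haplotype_frequencies(data)
    np.testing.assert_allclose(h, [[0.5, 0.0], [0.0, 0.5]], atol=1e-9)
    assert logl == pytest.approx(100 * np.log(0.25), abs=1e-6)


def test_monomorphic_second_locus_forces_product_structure():
    rng = np.random.default_rng(5)
    col_a = np.sort(rng.integers(0, 2, size=(40, 2)), axis=1)
    col_b = np.zeros((40, 2), dtype=int)
    data = TwoLocusData.from_columns(col_a, col_b, 2, 2)
    h, _ = em_haplotype_frequencies(data)
    pa, _ = data.allele_frequencies()
    np.testing.assert_allclose(h[:, 0], pa, atol=1e-9)
    np.testing.assert_allclose(h[:, 1], [0.0, 0.0], atol=1e-9)
    lr, *_ = lr_statistic(data)
    assert lr == pytest.approx(0.0, abs=1e-9)


def test_em_dominates_null_likelihood():
    rng = np.random.default_rng(11)
    for _ in range(5):
        col_a = np.sort(rng.integers(0, 2, size=(60, 2)), axis=1)
        col_b = np.sort(rng.integers(0, 2, size=(60, 2)), axis=1)
        data = TwoLocusData.from_columns(col_a, col_b, 2, 2)
        _, logl = em_haplotype_frequencies(data)
        assert logl >= null_loglik(data) - 1e-9


@pytest.mark.parametrize("seed", range(8))
def test_em_matches_profile_likelihood_oracle(seed):
    """EM reaches the global biallelic maximum found by an independent 1-D
    profile-likelihood maximization, on small (n <= 30) datasets."""
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(8, 31))
    col_a = np.sort(rng.integers(0, 2, size=(n, 2)), axis=1)
    col_b = np.sort(rng.integers(0, 2, size=(n, 2)), axis=1)
    data = TwoLocusData.from_columns(col_a, col_b, 2, 2)
    _, logl_em = em_haplotype_frequencies(data)
    logl_oracle = biallelic_profile_oracle(data)
    assert abs(logl_em - logl_oracle) <= 1e-6


def test_permutation_test_monomorphic_locus():
    col_a = np.array([[0, 1]] * 30)
    col_b = np.array([[1, 1]] * 30)
    data = TwoLocusData.from_columns(col_a, col_b, 2, 2)
    res = ld_permutation_test(data, n_perm=100, seed=0)
    assert res.lr_stat == 0.0
    assert res.p_perm == 1.0


def test_permutation_test_detects_complete_association():
    col = np.array([[0, 0]] * 50 + [[1, 1]] * 50)
    data = TwoLocusData.from_columns(col, col, 2, 2)
    res = ld_permutation_test(data, n_perm=1000, seed=4)
    assert res.lr_stat > 0
    assert res.p_perm <= 0.01


def test_permutation_test_deterministic():
    rng = np.random.default_rng(21)
    col_a = np.sort(rng.integers(0, 2, size=(80, 2)), axis=1)
    col_b = np.sort(rng.integers(0, 2, size=(80, 2)), axis=1)
    data = TwoLocusData.from_columns(col_a, col_b, 2, 2)
    a = ld_permutation_test(data, n_perm=200, seed=9)
    b = ld_permutation_test(data, n_perm=200, seed=9)
    assert a.p_perm == b.p_perm and a.lr_stat == b.lr_stat


def test_biallelic_by_multiallelic_pair():
    """Mixed DIP x STR-like pair: EM converges, LR is non-negative, and the
    permutation test runs on the larger genotype-class space."""
    n = 200
    col_a = simulate_multiallelic_locus(np.full(6, 1 / 6), n, seed=31)
    col_b = np.sort(np.random.default_rng(32).integers(0, 2, size=(n, 2)), axis=1)
    data = TwoLocusData.from_columns(col_a, col_b, 6, 2)
    h, logl = em_haplotype_frequencies(data, seed=1)
    assert h.shape == (6, 2)
    assert abs(h.sum() - 1.0) < 1e-9
    res = ld_permutation_test(data, n_perm=50, seed=2)
    assert res.lr_stat >= 0.0
    assert 0.0 < res.p_perm <= 1.0


def test_bonferroni_adjust():
    assert bonferroni_adjust(0.05, 30) == pytest.approx(0.0016667, abs=5e-8)
    assert bonferroni_adjust(0.05, 435) == pytest.approx(0.000115, abs=5e-7)
    assert bonferroni_adjust(0.05, 1) == 0.05
    with pytest.raises(ValidationError):
        bonferroni_adjust(0.05, 0)


def test_all_pairs_counts_and_determinism():
    freqs = [np.array([0.5, 0.5])] * 4
    table = simulate_hwe_genotypes(freqs, 60, seed=77)
    results = all_pairs_ld(table, n_perm=50, seed=3)
    assert len(results) == 6  # C(4, 2)
    again = all_pairs_ld(table, n_perm=50, seed=3)
    assert [r.p_perm for r in results] == [r.p_perm for r in again]
    assert [r.pair for r in results] == [r.pair for r in again]

    two = simulate_hwe_genotypes(freqs[:2], 40, seed=78)
    assert len(all_pairs_ld(two, n_perm=20, seed=1)) == 1

    with pytest.raises(ValidationError):
        all_pairs_ld(simulate_hwe_genotypes(freqs[:1], 40, seed=79), n_perm=10, seed=0)
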