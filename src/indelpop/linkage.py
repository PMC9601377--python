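"""Pairwise linkage-disequilibrium testing on unphased genotypes.

Haplotype frequencies for a pair of loci are estimated by EM over the
gametic-phase ambiguity of double heterozygotes (Excoffier–Slatkin).  The
likelihood-ratio statistic compares the EM maximum against the null of
gametic equilibrium (haplotype frequencies equal to the product of the
single-locus allele frequencies, evaluated under the same genotype
likelihood), and significance comes from permuting one locus' genotype
column across individuals — which preserves both single-locus genotype
distributions while destroying between-locus association.  Supports
biallelic x biallelic and biallelic x multiallelic (e.g. STR) pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeTable, ValidationError

_LOG_FLOOR = 1e-300


def _genotype_codes(k: int) -> list[tuple[int, int]]:
    """Unordered genotype classes (i <= j) for a k-allele locus."""
    return [(i, j) for i in range(k) for j in range(i, k)]


@dataclass
class TwoLocusData:
    """Joint genotype-class counts for a pair of loci.

    ``counts[ga, gb]`` is the number of individuals with genotype class
    ``ga`` at locus A and ``gb`` at locus B, where classes enumerate
    unordered allele pairs ``(i, j), i <= j``.
    """

    k_a: int
    k_b: int
    counts: np.ndarray
    pair: tuple[str, str] = ("A", "B")
    genotypes_a: list[tuple[int, int]] = field(init=False)
    genotypes_b: list[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.genotypes_a = _genotype_codes(self.k_a)
        self.genotypes_b = _genotype_codes(self.k_b)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.genotypes_a), len(self.genotypes_b)):
            raise ValidationError("joint count matrix shape mismatch")
        if np.any(self.counts < 0):
            raise ValidationError("negative genotype counts")
        if self.n < 1:
            raise ValidationError("empty two-locus data")

    @property
    def n(self) -> int:
        return int(round(self.counts.sum()))

    @classmethod
    def from_columns(
        cls,
        col_a: np.ndarray,
        col_b: np.ndarray,
        k_a: int | None = None,
        k_b: int | None = None,
        pair: tuple[str, str] = ("A", "B"),
    ) -> "TwoLocusData":
        """Build joint counts from two (n, 2) call columns; rows with a
        missing call at either locus are dropped."""
        col_a = np.asarray(col_a)
        col_b = np.asarray(col_b)
        keep = (col_a[:, 0] != MISSING) & (col_b[:, 0] != MISSING)
        col_a, col_b = col_a[keep], col_b[keep]
        if k_a is None:
            k_a = int(col_a.max()) + 1
        if k_b is None:
            k_b = int(col_b.max()) + 1
        ga = _class_index(col_a, k_a)
        gb = _class_index(col_b, k_b)
        counts = np.zeros((k_a * (k_a + 1) // 2, k_b * (k_b + 1) // 2))
        np.add.at(counts, (ga, gb), 1.0)
        return cls(k_a=k_a, k_b=k_b, counts=counts, pair=pair)

    def allele_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """Single-locus allele frequencies from the genotype marginals."""
        pa = np.zeros(self.k_a)
        pb = np.zeros(self.k_b)
        marg_a = self.counts.sum(axis=1)
        marg_b = self.counts.sum(axis=0)
        for idx, (i, j) in enumerate(self.genotypes_a):
            pa[i] += marg_a[idx]
            pa[j] += marg_a[idx]
        for idx, (i, j) in enumerate(self.genotypes_b):
            pb[i] += marg_b[idx]
            pb[j] += marg_b[idx]
        return pa / (2 * self.n), pb / (2 * self.n)


def _class_index(col: np.ndarray, k: int) -> np.ndarray:
    """Map sorted allele pairs to the genotype-class enumeration index."""
    i = np.minimum(col[:, 0], col[:, 1]).astype(np.int64)
    j = np.maximum(col[:, 0], col[:, 1]).astype(np.int64)
    # index of (i, j), i<=j, in row-major upper-triangular order
    return (i * (2 * k - i - 1)) // 2 + j


@dataclass(frozen=True)
class LdResult:
    pair: tuple[str, str]
    haplotype_freqs: np.ndarray
    logl_full: float
    logl_null: float
    lr_stat: float
    p_perm: float
    n_perm: int
    seed: int


@lru_cache(maxsize=None)
def _phase_configs(k_a: int, k_b: int) -> list[tuple[int, int, list[tuple[int, int, int, int, float]]]]:
    """Per joint genotype class, the compatible haplotype-pair resolutions.

    Each entry is (class_a, class_b, configs) with configs a list of
    (h1_row, h1_col, h2_row, h2_col, multiplicity); the genotype probability
    is sum over configs of mult * h[h1] * h[h2].
    """
    out = []
    for ia, (a1, a2) in enumerate(_genotype_codes(k_a)):
        for ib, (b1, b2) in enumerate(_genotype_codes(k_b)):
            het_a, het_b = a1 != a2, b1 != b2
            if het_a and het_b:
                configs = [
                    (a1, b1, a2, b2, 2.0),
                    (a1, b2, a2, b1, 2.0),
                ]
            elif het_a or het_b:
                configs = [(a1, b1, a2, b2, 2.0)]
            else:
                configs = [(a1, b1, a2, b2, 1.0)]
            out.append((ia, ib, configs))
    return out


def _loglik_and_expected(
    data: TwoLocusData, h: np.ndarray, accumulate: bool
) -> tuple[float, np.ndarray | None]:
    """Log-likelihood of the joint counts under haplotype frequencies ``h``;
    optionally also the E-step expected haplotype counts."""
    logl = 0.0
    expected = np.zeros_like(h) if accumulate else None
    for ia, ib, configs in _phase_configs(data.k_a, data.k_b):
        c = data.counts[ia, ib]
        if c == 0:
            continue
        probs = [mult * h[r1, c1] * h[r2, c2] for r1, c1, r2, c2, mult in configs]
        total = sum(probs)
        logl += c * np.log(max(total, _LOG_FLOOR))
        if accumulate and total > 0:
            for (r1, c1, r2, c2, _), pr in zip(configs, probs):
                w = c * pr / total
                expected[r1, c1] += w
                expected[r2, c2] += w
    return logl, expected


def em_haplotype_frequencies(
    data: TwoLocusData,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Maximum-likelihood haplotype frequencies by EM.

    The product of single-locus allele frequencies is always one starting
    point (so the returned log-likelihood dominates the gametic-equilibrium
    null); additional seeded Dirichlet restarts guard against local optima
    in multiallelic pairs.  The log-likelihood is non-decreasing across
    iterations by construction and is asserted to be.
    """
    pa, pb = data.allele_frequencies()
    inits = [np.outer(pa, pb)]
    if n_restarts > 1:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts - 1):
            draw = rng.dirichlet(np.ones(data.k_a * data.k_b))
            inits.append(draw.reshape(data.k_a, data.k_b))

    best_h, best_logl = None, -np.inf
    for h in inits:
        h = np.clip(h, 1e-12, None)
        h = h / h.sum()
        logl, expected = _loglik_and_expected(data, h, accumulate=True)
        for _ in range(max_iter):
            total = expected.sum()
            if total == 0:
                break
            h_new = expected / total
            logl_new, expected = _loglik_and_expected(data, h_new, accumulate=True)
            if logl_new < logl - 1e-7:
                raise AssertionError("EM log-likelihood decreased")
            h = h_new
            if logl_new - logl < tol:
                logl = logl_new
                break
            logl = logl_new
        if logl > best_logl:
            best_h, best_logl = h, logl
    return best_h, float(best_logl)


def null_loglik(data: TwoLocusData) -> float:
    """Log-likelihood at gametic equilibrium (product haplotype frequencies)."""
    pa, pb = data.allele_frequencies()
    logl, _ = _loglik_and_expected(data, np.outer(pa, pb), accumulate=False)
    return float(logl)


def lr_statistic(data: TwoLocusData, **em_kwargs) -> tuple[float, np.ndarray, float, float]:
    """(-2·(logL_null − logL_full), haplotype freqs, logL_full, logL_null)."""
    h, logl_full = em_haplotype_frequencies(data, **em_kwargs)
    logl_null = null_loglik(data)
    lr = -2.0 * (logl_null - logl_full)
    if lr < -1e-9:
        raise AssertionError("negative likelihood-ratio statistic")
    return max(lr, 0.0), h, logl_full, logl_null


def ld_permutation_test(
    data: TwoLocusData,
    n_perm: int = 1000,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LdResult:
    """Likelihood-ratio LD test with permutation significance.

    The null distribution is generated by randomly permuting the locus-B
    genotype assignment across individuals (both single-locus genotype
    distributions are preserved); p = (1 + #{LR_perm >= LR_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    em_kwargs = dict(tol=tol, max_iter=max_iter, n_restarts=1)
    lr_obs, h, logl_full, logl_null = lr_statistic(data, **em_kwargs)

    # expand the joint classes back to per-individual class labels
    ga_idx, gb_idx = np.nonzero(data.counts)
    reps = data.counts[ga_idx, gb_idx].astype(int)
    a_arr = np.repeat(ga_idx, reps)
    b_arr = np.repeat(gb_idx, reps)

    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_perm):
        b_perm = rng.permutation(b_arr)
        counts = np.zeros_like(data.counts)
        np.add.at(counts, (a_arr, b_perm), 1.0)
        perm = TwoLocusData(k_a=data.k_a, k_b=data.k_b, counts=counts, pair=data.pair)
        lr_p, _, _, _ = lr_statistic(perm, **em_kwargs)
        if lr_p >= lr_obs - 1e-9:
            k += 1
    p = (1 + k) / (n_perm + 1)
    return LdResult(
        pair=data.pair,
        haplotype_freqs=h,
        logl_full=logl_full,
        logl_null=logl_null,
        lr_stat=lr_obs,
        p_perm=p,
        n_perm=n_perm,
        seed=seed,
    )


def bonferroni_adjust(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test threshold alpha / m."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    return alpha / m


def all_pairs_ld(
    table: GenotypeTable,
    n_perm: int = 1000,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> list[LdResult]:
    """LD test for every unordered locus pair (30 loci -> 435 pairs).

    Per-pair permutation streams are derived from the master seed so the
    result list is reproducible and independent of evaluation order.
    """
    if table.n_loci < 2:
        raise ValidationError("need at least two loci")
    pairs = list(itertools.combinations(range(table.n_loci), 2))
    streams = np.random.SeedSequence(seed).spawn(len(pairs))
    results = []
    for (i, j), ss in zip(pairs, streams):
        data = TwoLocusData.from_columns(
            table.calls[:, i, :],
            table.calls[:, j, :],
            k_a=table.loci[i].n_alleles,
            k_b=table.loci[j].n_alleles,
            pair=(table.loci[i].id, table.loci[j].id),
        )
        pair_seed = int(ss.generate_state(1)[0] % (2**31))
        results.append(
            ld_permutation_test(data, n_perm=n_perm, seed=pair_seed, tol=tol, max_iter=max_iter)
        )
    return results


def ld_results_frame(results: list[LdResult], alpha: float = 0.05) -> pd.DataFrame:
    """Long-format report with the Bonferroni-gated significance flag."""
    threshold = bonferroni_adjust(alpha, len(results))
    return pd.DataFrame(
        {
            "locus_a": [r.pair[0] for r in results],
            "locus_b": [r.pair[1] for r in results],
            "lr_stat": [r.lr_stat for r in results],
            "p_perm": [r.p_perm for r in results],
            "significant_bonferroni": [r.p_perm < threshold for r in results],
        }
    )
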