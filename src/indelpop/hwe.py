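"""Hardy–Weinberg equilibrium testing for biallelic loci.

Conditional on the observed allele counts, the heterozygote count under HWE
follows the Levene/Haldane distribution

    P(n_DI | n_D, n_I, n) = n! / (n_DD! n_DI! n_II!) · 2^{n_DI} · n_D! n_I! / (2n)!

over the heterozygote counts of the same parity as the minor allele count.
The exact test sums the probabilities of all outcomes no more likely than the
observed one (probability-mass ordering, two-sided).  The Monte-Carlo test
re-pairs the pooled 2n allele copies uniformly at random and applies the same
ordering, with the add-one estimator p = (1 + k) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .types import LocusCounts, ValidationError


@dataclass(frozen=True)
class HweResult:
    locus_id: str
    p_exact: float | None
    p_mc: float
    n_perm: int
    seed: int


def _levene_support_and_logpmf(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Admissible heterozygote counts and their log conditional probabilities.

    ``n_minor`` is the smaller allele copy number; admissible heterozygote
    counts share its parity and run from 0 or 1 up to ``n_minor``.
    """
    support = np.arange(n_minor % 2, n_minor + 1, 2)
    n_major = 2 * n - n_minor
    n_aa = (n_minor - support) // 2  # minor-allele homozygotes
    n_bb = n - support - n_aa
    logpmf = (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(support + 1)
        - gammaln(n_bb + 1)
        + support * np.log(2)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    return support, logpmf


def hwe_exact_p(counts: LocusCounts) -> float:
    """Two-sided exact HWE p-value by probability-mass ordering.

    Monomorphic loci return 1.0 (a single admissible outcome).
    """
    n = counts.n
    c_del, c_ins = counts.allele_counts
    n_minor = min(c_del, c_ins)
    if n_minor == 0:
        return 1.0
    support, logpmf = _levene_support_and_logpmf(n, n_minor)
    obs_idx = np.searchsorted(support, counts.n_di)
    if obs_idx >= len(support) or support[obs_idx] != counts.n_di:
        raise ValidationError(
            f"{counts.locus.id}: heterozygote count {counts.n_di} inconsistent "
            f"with allele counts"
        )
    # relative tolerance guards against log-space rounding at ties
    obs = logpmf[obs_idx]
    p = np.exp(logpmf[logpmf <= obs + 1e-9]).sum()
    return float(min(p, 1.0))


def hwe_permutation_p(
    counts: LocusCounts, n_perm: int = 10_000, seed: int = 0
) -> HweResult:
    """Monte-Carlo HWE test by random re-pairing of the pooled allele copies.

    p = (1 + #{permutations whose heterozygote-count probability <= the
    observed one}) / (n_perm + 1); deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    n = counts.n
    c_del, c_ins = counts.allele_counts
    n_minor = min(c_del, c_ins)
    p_exact = hwe_exact_p(counts)
    if n_minor == 0:
        return HweResult(counts.locus.id, p_exact, 1.0, n_perm, seed)

    support, logpmf = _levene_support_and_logpmf(n, n_minor)
    obs_logp = logpmf[np.searchsorted(support, counts.n_di)]

    rng = np.random.default_rng(seed)
    pool = np.zeros(2 * n, dtype=np.int8)
    pool[:n_minor] = 1
    tiled = np.tile(pool, (n_perm, 1))
    tiled = rng.permuted(tiled, axis=1)
    # pair consecutive copies: heterozygote where the two alleles differ
    pairs = tiled.reshape(n_perm, n, 2)
    het = (pairs[:, :, 0] != pairs[:, :, 1]).sum(axis=1)
    perm_logp = logpmf[np.searchsorted(support, het)]
    k = int(np.sum(perm_logp <= obs_logp + 1e-9))
    p_mc = (1 + k) / (n_perm + 1)
    return HweResult(counts.locus.id, p_exact, p_mc, n_perm, seed)
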