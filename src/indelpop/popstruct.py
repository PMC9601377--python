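"""Between-population differentiation: bias-corrected FST and AMOVA.

FST estimation follows Nei & Chesser's sample-bias-corrected gene-diversity
estimators computed from allele frequencies and sample sizes alone (random
mating within populations assumed).  With s populations of harmonic-mean
size ñ and per-population frequency vectors x_k:

    Hs~ = 2ñ/(2ñ-1) · (1 - mean_k Σ_i x_ki²)            within-population
    Ht~ = 1 - Σ_i x̄_i² + Hs~/(2ñs)                      total (sampled pops)
    Dst' = s/(s-1) · (Ht~ - Hs~)                         corrected for the
    Ht' = Hs~ + Dst'                                     finite number of
    fst  = Dst' / Ht'                                    sampled populations

The s/(s-1) correction makes the estimator recover the Balding–Nichols
differentiation parameter without the downward bias that raw Gst incurs when
only a few populations are sampled.  The multilocus value is the ratio of
summed Dst' over summed Ht' (ratio of averages).  AMOVA partitions allelic
variance among/within populations on the allele identity distance, with
permutation significance obtained by reassigning whole individuals to
groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    DistanceMatrix,
    GenotypeTable,
    PopulationFrequencyTable,
    ValidationError,
)


@dataclass(frozen=True)
class FstResult:
    """Per-locus and multilocus bias-corrected FST over a set of populations."""

    populations: tuple[str, ...]
    locus_ids: tuple[str, ...]
    hs: np.ndarray
    ht_corrected: np.ndarray
    fst_locus: np.ndarray  # NaN where the locus is monomorphic across pops
    fst: float


@dataclass(frozen=True)
class AmovaResult:
    locus_id: str
    ss_among: float
    ss_within: float
    var_among: float
    var_within: float
    phi_st: float
    p_perm: float
    n_perm: int
    seed: int


def _fst_components(
    freqs: list[np.ndarray], sizes: np.ndarray
) -> tuple[float, float]:
    """(Hs~, Dst') for one locus over s populations."""
    s = len(freqs)
    n_harm = s / np.sum(1.0 / sizes)
    x = np.vstack(freqs)
    hs = (2 * n_harm / (2 * n_harm - 1)) * (1.0 - float(np.mean(np.sum(x**2, axis=1))))
    xbar = x.mean(axis=0)
    ht = 1.0 - float(np.sum(xbar**2)) + hs / (2 * n_harm * s)
    dst_corr = (s / (s - 1)) * (ht - hs)
    return hs, dst_corr


def _fst_over_pops(table: PopulationFrequencyTable) -> FstResult:
    s = len(table.populations)
    if s < 2:
        raise ValidationError("need at least two populations")
    hs_arr, htp_arr, fst_arr = [], [], []
    for j in range(len(table.loci)):
        freqs = [table.freqs[i][j] for i in range(s)]
        sizes = table.sizes[:, j].astype(float)
        hs, dst = _fst_components(freqs, sizes)
        ht_prime = hs + dst
        hs_arr.append(hs)
        htp_arr.append(ht_prime)
        fst_arr.append(dst / ht_prime if ht_prime > 0 else np.nan)
    hs_arr = np.array(hs_arr)
    htp_arr = np.array(htp_arr)
    # monomorphic loci contribute zero to both sums, so the ratio of sums
    # implicitly excludes them
    denom = htp_arr.sum()
    fst_multi = float(1.0 - hs_arr.sum() / denom) if denom > 0 else 0.0
    return FstResult(
        populations=tuple(table.populations),
        locus_ids=tuple(loc.id for loc in table.loci),
        hs=hs_arr,
        ht_corrected=htp_arr,
        fst_locus=np.array(fst_arr),
        fst=fst_multi,
    )


def pairwise_fst(
    freq_table: PopulationFrequencyTable, pop_a: str, pop_b: str
) -> FstResult:
    """Bias-corrected FST between two populations (per locus and multilocus)."""
    if pop_a == pop_b:
        raise ValidationError("populations must differ; fst(A, A) is 0 by definition")
    return _fst_over_pops(freq_table.subset_populations([pop_a, pop_b]))


def fst_matrix(freq_table: PopulationFrequencyTable) -> DistanceMatrix:
    """Symmetric matrix of pairwise multilocus FST.

    Small negative estimates (possible under the bias correction when
    populations are effectively identical) are clamped to 0 so the result is
    a valid distance matrix; raw values are available via
    :func:`pairwise_fst`.
    """
    pops = freq_table.populations
    k = len(pops)
    if k < 2:
        raise ValidationError("need at least two populations")
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            fst = pairwise_fst(freq_table, pops[i], pops[j]).fst
            d[i, j] = d[j, i] = max(fst, 0.0)
    return DistanceMatrix(labels=list(pops), d=d)


def locus_specific_fst(freq_table: PopulationFrequencyTable) -> pd.DataFrame:
    """Per-locus multi-population FST, rank-ordered for AIM screening.

    Loci with high locus-specific FST are candidates for ancestry-informative
    markers; the returned frame is sorted by descending FST with a rank
    column.
    """
    res = _fst_over_pops(freq_table)
    df = pd.DataFrame({"locus": res.locus_ids, "fst": res.fst_locus})
    df = df.sort_values("fst", ascending=False, na_position="last").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def _amova_phi(
    group_allele_counts: np.ndarray, group_sizes: np.ndarray
) -> tuple[float, float, float, float, float]:
    """AMOVA components for one locus from per-group allele-copy counts.

    ``group_allele_counts[g, a]`` counts copies of allele ``a`` in group
    ``g``; ``group_sizes[g]`` is the number of copies (2 x individuals).
    Returns (ss_among, ss_within, var_among, var_within, phi_st).
    """
    s = group_allele_counts.shape[0]
    n_copies = group_sizes.astype(float)
    total_copies = n_copies.sum()
    totals = group_allele_counts.sum(axis=0)

    # pairwise allele-identity distance: SS = (unequal pairs) / group size
    ss_within = 0.0
    for g in range(s):
        unequal = (n_copies[g] ** 2 - np.sum(group_allele_counts[g] ** 2.0)) / 2.0
        ss_within += unequal / n_copies[g]
    ss_total = (total_copies**2 - np.sum(totals**2.0)) / 2.0 / total_copies
    ss_among = ss_total - ss_within

    df_among = s - 1
    df_within = total_copies - s
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n_prime = (total_copies - np.sum(n_copies**2) / total_copies) / df_among
    var_among = (ms_among - ms_within) / n_prime
    var_within = ms_within
    denom = var_among + var_within
    phi = var_among / denom if denom > 0 else 0.0
    return ss_among, ss_within, var_among, var_within, phi


def amova_locus(
    table: GenotypeTable, n_perm: int = 1000, seed: int = 0
) -> list[AmovaResult]:
    """One-level locus-by-locus AMOVA across the table's population labels.

    Uses the allele identity/non-identity distance over the 2n allele copies;
    Phi_ST = among-population variance / total.  The permutation null
    reassigns whole individuals (keeping their two copies together) across
    groups; p = (1 + #{phi_perm >= phi_obs}) / (n_perm + 1).
    """
    if table.populations is None:
        raise ValidationError("table carries no population labels")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    labels = list(dict.fromkeys(table.populations))
    if len(labels) < 2:
        raise ValidationError("need at least two groups")
    group_of = np.array([labels.index(p) for p in table.populations])
    counts_per_group = np.bincount(group_of, minlength=len(labels))
    if np.any(counts_per_group < 2):
        raise ValidationError("every group needs at least two individuals")

    streams = np.random.SeedSequence(seed).spawn(table.n_loci)
    results = []
    for j in range(table.n_loci):
        loc = table.loci[j]
        col = table.calls[:, j, :]
        present = col[:, 0] != -1
        alleles = col[present]
        groups = group_of[present]
        k = loc.n_alleles
        s = len(labels)

        def tabulate(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            gc = np.zeros((s, k))
            np.add.at(gc, (g, alleles[:, 0]), 1.0)
            np.add.at(gc, (g, alleles[:, 1]), 1.0)
            return gc, gc.sum(axis=1)

        gc, sizes = tabulate(groups)
        ss_a, ss_w, var_a, var_w, phi_obs = _amova_phi(gc, sizes)

        rng = np.random.default_rng(streams[j])
        hits = 0
        for _ in range(n_perm):
            g_perm = rng.permutation(groups)
            _, _, _, _, phi_p = _amova_phi(*tabulate(g_perm))
            if phi_p >= phi_obs - 1e-12:
                hits += 1
        p = (1 + hits) / (n_perm + 1)
        results.append(
            AmovaResult(
                locus_id=loc.id,
                ss_among=ss_a,
                ss_within=ss_w,
                var_among=var_a,
                var_within=var_w,
                phi_st=phi_obs,
                p_perm=p,
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results


def amova_frame(results: list[AmovaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus": [r.locus_id for r in results],
            "var_among": [r.var_among for r in results],
            "var_within": [r.var_within for r in results],
            "phi_st": [r.phi_st for r in results],
            "p_perm": [r.p_perm for r in results],
        }
    )
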