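"""Per-locus genetic diversity and forensic efficiency parameters, plus
panel-level combined identification indexes.

For a biallelic locus with allele frequencies p, q and observed heterozygote
proportion h (H = 1 - h):

* unbiased expected heterozygosity  He = 2n/(2n-1) · (1 - p² - q²)   (Nei)
* polymorphism information content  PIC = 1 - Σp_i² - Σ_{i<j} 2 p_i² p_j²   (Botstein)
* match probability                 PM = Σ (observed genotype frequency)²
* power of discrimination           PD = 1 - PM
* power of exclusion                PE = h² (1 - 2 h H²)   (Brenner/Fisher)
* typical paternity index           TPI = 1 / (2H)

PM deliberately uses observed genotype proportions rather than HWE-expected
ones.  Panel-level indexes combine multiplicatively across loci:
cPM = Π PM_l, cPD = 1 - cPM, cPE = 1 - Π (1 - PE_l).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hwe import hwe_exact_p, hwe_permutation_p
from .types import GenotypeTable, Locus, LocusCounts, ValidationError


def allele_frequencies(counts: LocusCounts) -> np.ndarray:
    """(deletion, insertion) allele frequencies; each allele count over 2n."""
    n = counts.n
    c_del, c_ins = counts.allele_counts
    return np.array([c_del, c_ins]) / (2 * n)


def observed_heterozygosity(counts: LocusCounts) -> float:
    """Heterozygote proportion n_DI / n."""
    return counts.n_di / counts.n


def unbiased_expected_heterozygosity(freqs: np.ndarray, n: int) -> float:
    """Nei's unbiased gene diversity, 2n/(2n-1) · (1 - Σ p²)."""
    freqs = np.asarray(freqs, dtype=float)
    if 2 * n < 2:
        raise ValidationError("need at least one diploid individual")
    return (2 * n / (2 * n - 1)) * (1 - float(np.sum(freqs**2)))


def pic(freqs: np.ndarray) -> float:
    """Botstein's polymorphism information content."""
    p = np.asarray(freqs, dtype=float)
    sq = p**2
    cross = np.outer(sq, sq)
    upper = np.triu(cross, k=1).sum()
    return 1.0 - float(sq.sum()) - 2.0 * float(upper)


def match_probability(counts: LocusCounts) -> float:
    """Sum of squared observed genotype proportions."""
    g = np.array(counts.genotype_counts) / counts.n
    return float(np.sum(g**2))


def power_of_discrimination(counts: LocusCounts) -> float:
    return 1.0 - match_probability(counts)


def power_of_exclusion(het_obs: float) -> float:
    """PE = h² (1 - 2 h H²) with h the heterozygote proportion, H = 1 - h."""
    if not 0.0 <= het_obs <= 1.0:
        raise ValidationError("het_obs out of [0, 1]")
    h = het_obs
    H = 1.0 - h
    return h * h * (1.0 - 2.0 * h * H * H)


def typical_paternity_index(het_obs: float) -> float:
    """TPI = 1 / (2H); undefined (infinite) when every individual is heterozygous."""
    if het_obs >= 1.0:
        raise ValidationError("TPI is infinite at het_obs = 1")
    return 1.0 / (2.0 * (1.0 - het_obs))


@dataclass(frozen=True)
class LocusSummary:
    """One report row: frequencies, diversity and forensic parameters."""

    locus: Locus
    n: int
    p_del: float
    p_ins: float
    het_obs: float
    het_exp_unbiased: float
    pic: float
    pm: float
    pd: float
    pe: float
    tpi: float
    p_hwe: float


@dataclass(frozen=True)
class PanelSummary:
    """Per-locus summaries plus the combined identification indexes."""

    summaries: list[LocusSummary]
    cpm: float
    cpd: float
    cpe: float


def summarize_counts(
    counts: LocusCounts,
    hwe_method: str = "exact",
    n_perm: int = 10_000,
    seed: int = 0,
) -> LocusSummary:
    """All per-locus parameters from genotype counts."""
    freqs = allele_frequencies(counts)
    h = observed_heterozygosity(counts)
    pm = match_probability(counts)
    if hwe_method == "exact":
        p_hwe = hwe_exact_p(counts)
    elif hwe_method == "permutation":
        p_hwe = hwe_permutation_p(counts, n_perm=n_perm, seed=seed).p_mc
    else:
        raise ValueError(f"unknown HWE method {hwe_method!r}")
    return LocusSummary(
        locus=counts.locus,
        n=counts.n,
        p_del=float(freqs[0]),
        p_ins=float(freqs[1]),
        het_obs=h,
        het_exp_unbiased=unbiased_expected_heterozygosity(freqs, counts.n),
        pic=pic(freqs),
        pm=pm,
        pd=1.0 - pm,
        pe=power_of_exclusion(h),
        tpi=typical_paternity_index(h) if h < 1.0 else math.inf,
        p_hwe=p_hwe,
    )


def combined_indexes(summaries: list[LocusSummary]) -> PanelSummary:
    """cPM = Π PM, cPD = 1 - cPM, cPE = 1 - Π (1 - PE)."""
    if not summaries:
        raise ValidationError("need at least one locus")
    cpm = 1.0
    non_excl = 1.0
    for s in summaries:
        cpm *= s.pm
        non_excl *= 1.0 - s.pe
    return PanelSummary(summaries=summaries, cpm=cpm, cpd=1.0 - cpm, cpe=1.0 - non_excl)


def summarize_panel(
    table: GenotypeTable,
    hwe_method: str = "permutation",
    n_perm: int = 10_000,
    seed: int = 0,
) -> PanelSummary:
    """Full panel report from an individual-level genotype table.

    Missing calls are excluded per locus (complete-case n per locus); HWE
    permutation streams are derived per locus from the master seed.
    """
    streams = np.random.SeedSequence(seed).spawn(table.n_loci)
    summaries = []
    for j in range(table.n_loci):
        counts = table.locus_counts(j)
        locus_seed = int(streams[j].generate_state(1)[0] % (2**31))
        summaries.append(
            summarize_counts(counts, hwe_method=hwe_method, n_perm=n_perm, seed=locus_seed)
        )
    return combined_indexes(summaries)


def panel_frame(panel: PanelSummary, decimals: int | None = None) -> pd.DataFrame:
    """Panel report as a DataFrame in the conventional column order.

    With ``decimals`` set, numeric columns are rounded for display (published
    reports use 4 decimals); values are stored at full precision otherwise.
    """
    records = []
    for s in panel.summaries:
        records.append(
            {
                "locus": s.locus.id,
                "location": s.locus.location,
                "rs_id": s.locus.rs_id,
                "p_del": s.p_del,
                "p_ins": s.p_ins,
                "het_exp": s.het_exp_unbiased,
                "het_obs": s.het_obs,
                "p_hwe": s.p_hwe,
                "pic": s.pic,
                "pd": s.pd,
                "pe": s.pe,
                "tpi": s.tpi,
            }
        )
    df = pd.DataFrame(records)
    if decimals is not None:
        num = df.select_dtypes(include="number").columns
        df[num] = df[num].round(decimals)
    return df


def write_panel_report(panel: PanelSummary, path, decimals: int = 4) -> None:
    df = panel_frame(panel, decimals=decimals)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    with open(path, "w") as fh:
        df.to_csv(fh, sep=sep, index=False)
        fh.write(f"# cPM={panel.cpm:.6e} cPD={panel.cpd:.10f} cPE={panel.cpe:.4f}\n")
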