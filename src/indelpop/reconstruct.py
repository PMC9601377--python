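"""Rebuild integer genotype counts from published per-locus summaries.

A published summary row for a biallelic locus — allele frequencies rounded
to four decimals, observed heterozygosity, sample size n — determines the
integer genotype counts (n_DD, n_DI, n_II) essentially uniquely: the
heterozygote count is n·Ho rounded to the nearest integer, the insertion
allele copy number is 2n·p rounded to the nearest integer, and the
homozygote counts follow by subtraction.  Reconstructing the counts recreates
the dataset at sufficient-statistic level for every single-locus quantity;
the multi-locus phase of the original individuals is not recoverable and
:func:`counts_to_genotype_table` re-pairs loci arbitrarily (valid for all
single-locus statistics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .published import PANEL_N, polish_panel_frame, polish_panel_loci
from .types import GenotypeTable, Locus, LocusCounts, ValidationError

#: Consistency tolerance: half of one unit in the fourth printed decimal.
ROUNDING_TOL = 5e-5


class ReconstructionError(ValueError):
    """No integer genotype counts reproduce the published row within tolerance."""


@dataclass(frozen=True)
class SummaryRow:
    """One published per-locus summary: allele frequencies, observed
    heterozygosity and sample size."""

    locus: Locus
    p_del: float
    p_ins: float
    het_obs: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.p_del + self.p_ins - 1.0) > ROUNDING_TOL:
            raise ValidationError(
                f"{self.locus.id}: allele frequencies sum to {self.p_del + self.p_ins}"
            )
        if not 0.0 <= self.het_obs <= 1.0:
            raise ValidationError(f"{self.locus.id}: het_obs out of [0, 1]")
        if self.n < 1:
            raise ValidationError(f"{self.locus.id}: n must be >= 1")


def reconstruct_locus_counts(row: SummaryRow) -> LocusCounts:
    """Integer genotype counts (n_DD, n_DI, n_II) reproducing a summary row.

    Uses nearest-integer rounding of ``het_obs * n`` (heterozygotes) and
    ``p_ins * 2n`` (insertion copies); raises :class:`ReconstructionError`
    with the best exhaustive-search candidate when no consistent integer
    solution exists within the printed-rounding tolerance.
    """
    n = row.n
    n_di = round(row.het_obs * n)
    ins_copies = round(row.p_ins * 2 * n)
    candidate = None
    if (ins_copies - n_di) % 2 == 0:
        n_ii = (ins_copies - n_di) // 2
        n_dd = n - n_di - n_ii
        if min(n_dd, n_di, n_ii) >= 0:
            candidate = (n_dd, n_di, n_ii)

    if candidate is not None:
        counts = LocusCounts(row.locus, *candidate)
        resid = _max_residual(counts, row)
        if resid <= ROUNDING_TOL:
            return counts

    best, best_resid = _best_candidate(row)
    raise ReconstructionError(
        f"{row.locus.id}: no integer genotype counts match the published row "
        f"within {ROUNDING_TOL}; best candidate (n_DD, n_DI, n_II) = {best} "
        f"with max residual {best_resid:.2e}"
    )


def _max_residual(counts: LocusCounts, row: SummaryRow) -> float:
    n = counts.n
    p_ins = counts.allele_counts[1] / (2 * n)
    het = counts.n_di / n
    return max(abs(p_ins - row.p_ins), abs(het - row.het_obs))


def _best_candidate(row: SummaryRow) -> tuple[tuple[int, int, int], float]:
    """Exhaustive search near the rounded solution, minimizing the max residual."""
    n = row.n
    center = round(row.het_obs * n)
    best, best_resid = None, np.inf
    for n_di in range(max(0, center - 3), min(n, center + 3) + 1):
        remaining = n - n_di
        for n_ii in range(remaining + 1):
            counts = LocusCounts(row.locus, remaining - n_ii, n_di, n_ii)
            resid = _max_residual(counts, row)
            if resid < best_resid:
                best, best_resid = counts.genotype_counts, resid
    return best, best_resid


def summary_rows_from_frame(df: pd.DataFrame, n: int | None = None) -> list[SummaryRow]:
    """Build summary rows from a frame with columns locus, p_del, p_ins,
    het_obs and (per-row or global) n."""
    rows = []
    for _, rec in df.iterrows():
        locus = rec["locus"]
        if not isinstance(locus, Locus):
            locus = Locus(
                id=str(locus),
                rs_id=str(rec.get("rs_id", "")),
                location=str(rec.get("location", "")),
            )
        rows.append(
            SummaryRow(
                locus=locus,
                p_del=float(rec["p_del"]),
                p_ins=float(rec["p_ins"]),
                het_obs=float(rec["het_obs"]),
                n=int(rec["n"]) if n is None else n,
            )
        )
    return rows


def polish_panel_counts() -> list[LocusCounts]:
    """Reconstructed genotype counts for all 30 published loci (n = 631)."""
    df = polish_panel_frame()
    loci = polish_panel_loci()
    counts = []
    for locus, (_, rec) in zip(loci, df.iterrows()):
        row = SummaryRow(
            locus=locus,
            p_del=float(rec["p_del"]),
            p_ins=float(rec["p_ins"]),
            het_obs=float(rec["het_obs"]),
            n=PANEL_N,
        )
        counts.append(reconstruct_locus_counts(row))
    return counts


def counts_to_genotype_table(
    counts: list[LocusCounts],
    seed: int,
    populations: list[str] | None = None,
) -> GenotypeTable:
    """Individual-level table whose per-locus genotype counts equal ``counts``.

    Each locus' genotypes are assigned to samples by an independent seeded
    random permutation, so per-locus counts are exact while the multi-locus
    pairing is arbitrary — valid for all single-locus statistics, not a
    preserved haplotype phase.
    """
    if not counts:
        raise ValidationError("need at least one locus")
    n = counts[0].n
    if any(c.n != n for c in counts):
        raise ValidationError("all loci must share the same sample size")
    if populations is not None and len(populations) != n:
        raise ValidationError("population labels length mismatch")

    streams = np.random.SeedSequence(seed).spawn(len(counts))
    calls = np.empty((n, len(counts), 2), dtype=np.int16)
    genotypes = np.array([(0, 0), (0, 1), (1, 1)], dtype=np.int16)
    for j, (c, ss) in enumerate(zip(counts, streams)):
        rng = np.random.default_rng(ss)
        column = np.repeat(genotypes, (c.n_dd, c.n_di, c.n_ii), axis=0)
        calls[:, j, :] = column[rng.permutation(n)]
    samples = [f"S{i + 1:04d}" for i in range(n)]
    return GenotypeTable(
        loci=[c.locus for c in counts],
        samples=samples,
        calls=calls,
        populations=populations,
    )
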