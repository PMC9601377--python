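"""Seeded genotype simulators with the statistical structure the analysis
assumes.

Three generative models cover the pipeline's needs: random-mating (HWE)
genotypes for null calibration, inbreeding (FIS > 0) genotypes as the
alternative for HWE power, and the Balding–Nichols beta/Dirichlet model for
population differentiation with a known FST.  The default panel configuration
mirrors the study design this package re-analyses: 30 biallelic DIP loci at
the published Polish allele frequencies, 631 individuals, three regional
subpopulations.

All generators derive independent per-locus / per-population random streams
from a single master seed via ``numpy``'s ``SeedSequence.spawn``, so output
is bit-reproducible and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .published import PANEL_N, polish_panel_frame, polish_panel_loci
from .types import GenotypeTable, Locus, PopulationFrequencyTable, ValidationError


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation settings.

    ``fis`` is the within-population inbreeding coefficient; ``fst_target``
    the Balding–Nichols differentiation parameter used when
    ``n_populations > 1``.
    """

    loci: list[Locus]
    freqs: list[np.ndarray]
    n_individuals: int
    n_populations: int = 1
    fis: float = 0.0
    fst_target: float | None = None
    seed: int = 0
    population_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.freqs):
            raise ValidationError("loci and frequency vectors length mismatch")
        if not 0.0 <= self.fis < 1.0:
            raise ValidationError("fis must be in [0, 1)")
        if self.fst_target is not None and not 0.0 < self.fst_target < 1.0:
            raise ValidationError("fst_target must be in (0, 1)")
        for loc, f in zip(self.loci, self.freqs):
            f = np.asarray(f, dtype=float)
            if f.shape != (loc.n_alleles,) or np.any(f < 0) or abs(f.sum() - 1) > 1e-9:
                raise ValidationError(f"invalid frequency vector for {loc.id}")


def study_panel_config(seed: int = 0) -> SimulationConfig:
    """The default rehearsal of the study design: 30 DIP loci at the
    published Polish frequencies, n = 631, three regional labels."""
    df = polish_panel_frame()
    loci = polish_panel_loci()
    freqs = [np.array([r.p_del, r.p_ins]) for r in df.itertuples()]
    return SimulationConfig(
        loci=loci,
        freqs=freqs,
        n_individuals=PANEL_N,
        n_populations=3,
        seed=seed,
        population_names=["Poznan", "Warsaw", "Bialystok"],
    )


def _draw_locus(
    rng: np.random.Generator, freqs: np.ndarray, n: int, fis: float
) -> np.ndarray:
    """(n, 2) sorted allele pairs under HWE (fis = 0) or inbreeding.

    With inbreeding, the second allele copies the first with probability
    ``fis``, giving genotype probabilities p_i² + fis·p_i(1-p_i) for
    homozygotes and (1-fis)·2·p_i·p_j for heterozygotes.
    """
    freqs = np.asarray(freqs, dtype=float)
    k = len(freqs)
    first = rng.choice(k, size=n, p=freqs)
    if fis > 0:
        second = rng.choice(k, size=n, p=freqs)
        ibd = rng.random(n) < fis
        second = np.where(ibd, first, second)
    else:
        second = rng.choice(k, size=n, p=freqs)
    pair = np.stack([first, second], axis=1).astype(np.int16)
    return np.sort(pair, axis=1)


def simulate_hwe_genotypes(
    freqs: list[np.ndarray],
    n: int,
    seed: int,
    loci: list[Locus] | None = None,
    populations: list[str] | None = None,
) -> GenotypeTable:
    """Independent loci under Hardy–Weinberg proportions."""
    return simulate_with_fis(freqs, n, fis=0.0, seed=seed, loci=loci, populations=populations)


def simulate_with_fis(
    freqs: list[np.ndarray],
    n: int,
    fis: float,
    seed: int,
    loci: list[Locus] | None = None,
    populations: list[str] | None = None,
) -> GenotypeTable:
    """Independent loci with within-population inbreeding coefficient ``fis``."""
    if not 0.0 <= fis < 1.0:
        raise ValidationError("fis must be in [0, 1)")
    if loci is None:
        loci = [
            Locus(id=f"L{j + 1:03d}") if len(f) == 2
            else Locus(id=f"L{j + 1:03d}", alleles=tuple(f"A{a}" for a in range(len(f))))
            for j, f in enumerate(freqs)
        ]
    streams = np.random.SeedSequence(seed).spawn(len(loci))
    calls = np.empty((n, len(loci), 2), dtype=np.int16)
    for j, (f, ss) in enumerate(zip(freqs, streams)):
        calls[:, j, :] = _draw_locus(np.random.default_rng(ss), np.asarray(f), n, fis)
    samples = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeTable(loci=loci, samples=samples, calls=calls, populations=populations)


def simulate_multiallelic_locus(freqs: np.ndarray, n: int, seed: int) -> np.ndarray:
    """One HWE genotype column over k >= 2 alleles, shape (n, 2), sorted pairs."""
    freqs = np.asarray(freqs, dtype=float)
    if len(freqs) < 2:
        raise ValidationError("need at least two alleles")
    return _draw_locus(np.random.default_rng(seed), freqs, n, fis=0.0)


def simulate_balding_nichols(
    ancestral_freqs: list[np.ndarray],
    fst_target: float,
    sizes: list[int],
    seed: int,
    loci: list[Locus] | None = None,
    population_names: list[str] | None = None,
) -> tuple[PopulationFrequencyTable, GenotypeTable]:
    """Differentiated populations under the Balding–Nichols model.

    Each population's frequency vector at each locus is drawn from a
    Dirichlet with parameters ``p_i (1 - F) / F`` (the beta model for
    biallelic loci), then genotypes are drawn under HWE within the
    population.  Returns the sample allele-frequency table (estimated from
    the simulated genotypes, with sample sizes) and the pooled genotype
    table with population labels.
    """
    if not 0.0 < fst_target < 1.0:
        raise ValidationError("fst_target must be in (0, 1)")
    n_pops = len(sizes)
    if population_names is None:
        population_names = [f"P{k + 1}" for k in range(n_pops)]
    if loci is None:
        loci = [Locus(id=f"L{j + 1:03d}") for j in range(len(ancestral_freqs))]

    scale = (1.0 - fst_target) / fst_target
    master = np.random.SeedSequence(seed)
    pop_streams = master.spawn(n_pops)

    tables = []
    for k, (size, ss) in enumerate(zip(sizes, pop_streams)):
        freq_stream, geno_stream = ss.spawn(2)
        rng = np.random.default_rng(freq_stream)
        pop_freqs = [rng.dirichlet(np.asarray(f) * scale) for f in ancestral_freqs]
        tables.append(
            simulate_hwe_genotypes(
                pop_freqs,
                size,
                seed=int(geno_stream.generate_state(1)[0] % (2**31)),
                loci=loci,
                populations=[population_names[k]] * size,
            )
        )

    merged = _concat_tables(tables)
    freq_table = frequency_table_from_genotypes(merged)
    return freq_table, merged


def _concat_tables(tables: list[GenotypeTable]) -> GenotypeTable:
    loci = tables[0].loci
    samples, populations, calls = [], [], []
    for idx, t in enumerate(tables):
        if t.loci != loci:
            raise ValidationError("tables disagree on loci")
        samples.extend(f"{t.populations[i]}_{s}" for i, s in enumerate(t.samples))
        populations.extend(t.populations)
        calls.append(t.calls)
    return GenotypeTable(
        loci=loci,
        samples=samples,
        calls=np.concatenate(calls, axis=0),
        populations=populations,
    )


def frequency_table_from_genotypes(table: GenotypeTable) -> PopulationFrequencyTable:
    """Per-population sample allele frequencies and sizes from a labelled
    genotype table (missing calls excluded per locus)."""
    if table.populations is None:
        raise ValidationError("table carries no population labels")
    pops = list(dict.fromkeys(table.populations))
    pop_arr = np.asarray(table.populations)
    freqs: list[list[np.ndarray]] = []
    sizes = np.zeros((len(pops), table.n_loci), dtype=np.int64)
    for i, pop in enumerate(pops):
        sub = table.subset(pop_arr == pop)
        row = []
        for j, loc in enumerate(sub.loci):
            col = sub.allele_column(j)
            if col.shape[0] == 0:
                raise ValidationError(f"{pop}/{loc.id}: all calls missing")
            counts = np.bincount(col.ravel(), minlength=loc.n_alleles).astype(float)
            row.append(counts / counts.sum())
            sizes[i, j] = col.shape[0]
        freqs.append(row)
    return PopulationFrequencyTable(populations=pops, loci=table.loci, freqs=freqs, sizes=sizes)


def simulate_study_panel(seed: int = 0, fis: float = 0.0) -> GenotypeTable:
    """A full synthetic rehearsal of the study sample: 631 individuals at the
    30 published loci, split over three regional labels, under HWE (or with
    inbreeding ``fis``)."""
    cfg = study_panel_config(seed=seed)
    n = cfg.n_individuals
    base, extra = divmod(n, cfg.n_populations)
    labels: list[str] = []
    for k, name in enumerate(cfg.population_names):
        labels.extend([name] * (base + (1 if k < extra else 0)))
    return simulate_with_fis(
        cfg.freqs, n, fis=fis, seed=cfg.seed if seed is None else seed,
        loci=cfg.loci, populations=labels,
    )
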