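"""Core domain containers for biallelic insertion/deletion (DIP) panel analysis.

The pipeline's raw input is an individual-level diploid genotype table
(samples x loci, unordered allele pairs, optional population label).  All
single-locus statistics factor through per-locus genotype counts
(``LocusCounts``); multi-population comparisons factor through per-population
allele-frequency tables (``PopulationFrequencyTable``).  Distance matrices and
unrooted trees carry the between-population results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel allele index for a missing call.
MISSING = -1


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


class ParseError(ValueError):
    """A file could not be parsed into a valid object."""


@dataclass(frozen=True)
class Locus:
    """A single marker.

    For DIP loci the allele labels are ``("D", "I")`` — deletion first,
    insertion second.  Generic (e.g. STR) loci may carry any >=2 distinct
    labels.
    """

    id: str
    rs_id: str = ""
    location: str = ""
    alleles: tuple[str, ...] = ("D", "I")

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("locus id must be non-empty")
        if len(self.alleles) < 2:
            raise ValidationError(f"locus {self.id}: need >=2 allele labels")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValidationError(f"locus {self.id}: allele labels not distinct")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def allele_index(self, label: str) -> int:
        try:
            return self.alleles.index(label)
        except ValueError:
            raise ValidationError(
                f"locus {self.id}: unknown allele label {label!r}"
            ) from None


@dataclass(frozen=True)
class LocusCounts:
    """Per-locus genotype counts for a biallelic marker.

    ``n_dd``, ``n_di``, ``n_ii`` count the deletion homozygotes,
    heterozygotes and insertion homozygotes among ``n = n_dd + n_di + n_ii``
    individuals.  This is the sufficient statistic for every single-locus
    quantity computed downstream.
    """

    locus: Locus
    n_dd: int
    n_di: int
    n_ii: int

    def __post_init__(self) -> None:
        for name in ("n_dd", "n_di", "n_ii"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{self.locus.id}: {name}={v} not a non-negative integer")
        if self.n < 1:
            raise ValidationError(f"{self.locus.id}: empty genotype counts")

    @property
    def n(self) -> int:
        return self.n_dd + self.n_di + self.n_ii

    @property
    def allele_counts(self) -> tuple[int, int]:
        """(deletion copies, insertion copies); sums to 2n."""
        return (2 * self.n_dd + self.n_di, self.n_di + 2 * self.n_ii)

    @property
    def genotype_counts(self) -> tuple[int, int, int]:
        return (self.n_dd, self.n_di, self.n_ii)


@dataclass
class GenotypeTable:
    """Individual-level diploid calls at multiple loci.

    ``calls`` has shape ``(n_samples, n_loci, 2)`` holding allele indices
    into each locus' label list, sorted within the pair (calls are unordered);
    a missing call is ``(-1, -1)``.
    """

    loci: list[Locus]
    samples: list[str]
    calls: np.ndarray
    populations: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        self.validate()

    def validate(self) -> None:
        n, m = len(self.samples), len(self.loci)
        if self.calls.shape != (n, m, 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} != ({n}, {m}, 2)"
            )
        if len(set(self.samples)) != n:
            raise ValidationError("duplicate sample identifiers")
        if len({loc.id for loc in self.loci}) != m:
            raise ValidationError("duplicate locus ids")
        if self.populations is not None and len(self.populations) != n:
            raise ValidationError("population labels length mismatch")
        # normalize unordered pairs and range-check indices
        self.calls = np.sort(self.calls, axis=2)
        for j, loc in enumerate(self.loci):
            col = self.calls[:, j, :]
            missing = col[:, 0] == MISSING
            if np.any(col[missing, 1] != MISSING):
                raise ValidationError(f"locus {loc.id}: half-missing call")
            ok = col[~missing]
            if ok.size and (ok.min() < 0 or ok.max() >= loc.n_alleles):
                raise ValidationError(f"locus {loc.id}: allele index out of range")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus_id: str) -> int:
        for j, loc in enumerate(self.loci):
            if loc.id == locus_id:
                return j
        raise KeyError(locus_id)

    def allele_column(self, j: int) -> np.ndarray:
        """Calls at locus ``j`` for the samples with a non-missing call, shape (k, 2)."""
        col = self.calls[:, j, :]
        return col[col[:, 0] != MISSING]

    def locus_counts(self, j: int) -> LocusCounts:
        """Biallelic genotype counts at locus ``j`` (missing calls dropped)."""
        loc = self.loci[j]
        if loc.n_alleles != 2:
            raise ValidationError(f"locus {loc.id} is not biallelic")
        col = self.allele_column(j)
        if col.shape[0] == 0:
            raise ValidationError(f"locus {loc.id}: all calls missing")
        s = col.sum(axis=1)
        return LocusCounts(
            loc,
            n_dd=int(np.sum(s == 0)),
            n_di=int(np.sum(s == 1)),
            n_ii=int(np.sum(s == 2)),
        )

    def subset(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeTable(
            loci=self.loci,
            samples=[s for s, m in zip(self.samples, mask) if m],
            calls=self.calls[mask],
            populations=None
            if self.populations is None
            else [p for p, m in zip(self.populations, mask) if m],
        )

    def by_population(self) -> dict[str, "GenotypeTable"]:
        if self.populations is None:
            raise ValidationError("table carries no population labels")
        out = {}
        pops = np.asarray(self.populations)
        for label in dict.fromkeys(self.populations):  # preserve order
            out[label] = self.subset(pops == label)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.samples == other.samples
            and self.populations == other.populations
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PopulationFrequencyTable:
    """Per-population, per-locus allele frequencies with sample sizes.

    ``freqs[i][j]`` is the frequency vector of population ``i`` at locus
    ``j`` (aligned with ``loci[j].alleles``); ``sizes[i, j]`` is the number
    of individuals typed.
    """

    populations: list[str]
    loci: list[Locus]
    freqs: list[list[np.ndarray]]
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        npop, nloc = len(self.populations), len(self.loci)
        if len(set(self.populations)) != npop:
            raise ValidationError("duplicate population labels")
        if len(self.freqs) != npop or any(len(row) != nloc for row in self.freqs):
            raise ValidationError("frequency table dimensions mismatch")
        if self.sizes.shape != (npop, nloc):
            raise ValidationError("sizes shape mismatch")
        if np.any(self.sizes < 1):
            raise ValidationError("sample sizes must be >= 1")
        for i in range(npop):
            for j, loc in enumerate(self.loci):
                f = np.asarray(self.freqs[i][j], dtype=float)
                self.freqs[i][j] = f
                if f.shape != (loc.n_alleles,):
                    raise ValidationError(
                        f"{self.populations[i]}/{loc.id}: frequency vector length mismatch"
                    )
                if np.any(f < 0):
                    raise ValidationError(
                        f"{self.populations[i]}/{loc.id}: negative frequency"
                    )
                if abs(f.sum() - 1.0) > 1e-9:
                    raise ValidationError(
                        f"{self.populations[i]}/{loc.id}: frequencies sum to {f.sum():.10f}"
                    )

    def population_index(self, label: str) -> int:
        try:
            return self.populations.index(label)
        except ValueError:
            raise KeyError(label) from None

    def subset_populations(self, labels: list[str]) -> "PopulationFrequencyTable":
        idx = [self.population_index(p) for p in labels]
        return PopulationFrequencyTable(
            populations=list(labels),
            loci=self.loci,
            freqs=[[self.freqs[i][j].copy() for j in range(len(self.loci))] for i in idx],
            sizes=self.sizes[idx],
        )


@dataclass
class DistanceMatrix:
    """A labelled symmetric matrix of non-negative distances with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.validate()

    def validate(self) -> None:
        k = len(self.labels)
        if len(set(self.labels)) != k:
            raise ValidationError("duplicate labels")
        if self.d.shape != (k, k):
            raise ValidationError(f"matrix shape {self.d.shape} != ({k}, {k})")
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("non-finite distances")
        if np.any(np.abs(self.d - self.d.T) > 1e-12):
            raise ValidationError("matrix not symmetric within 1e-12")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("diagonal not zero")
        if np.any(self.d < 0):
            raise ValidationError("negative distances")

    @property
    def size(self) -> int:
        return len(self.labels)


class Tree:
    """An unrooted tree with branch lengths over named leaves.

    Internal structure is a node adjacency map; leaves carry labels.  Trees
    produced by neighbor-joining are binary unrooted: every internal node has
    degree 3.
    """

    def __init__(self) -> None:
        self._adj: dict[int, dict[int, float]] = {}
        self.leaf_name: dict[int, str] = {}
        self._next = 0

    def add_node(self, name: str | None = None) -> int:
        node = self._next
        self._next += 1
        self._adj[node] = {}
        if name is not None:
            self.leaf_name[node] = name
        return node

    def add_edge(self, u: int, v: int, length: float) -> None:
        if length < 0:
            raise ValidationError(f"negative branch length {length}")
        self._adj[u][v] = float(length)
        self._adj[v][u] = float(length)

    def neighbors(self, u: int) -> dict[int, float]:
        return self._adj[u]

    def degree(self, u: int) -> int:
        return len(self._adj[u])

    @property
    def nodes(self) -> list[int]:
        return list(self._adj)

    @property
    def leaves(self) -> dict[str, int]:
        return {name: node for node, name in self.leaf_name.items()}

    def validate(self, labels: list[str] | None = None) -> None:
        names = list(self.leaf_name.values())
        if len(set(names)) != len(names):
            raise ValidationError("duplicate leaf labels")
        if labels is not None and sorted(names) != sorted(labels):
            raise ValidationError("leaf labels do not match expected label set")
        for node in self._adj:
            deg = self.degree(node)
            if node in self.leaf_name:
                if deg != 1:
                    raise ValidationError(f"leaf {self.leaf_name[node]} has degree {deg}")
            elif deg != 3:
                raise ValidationError(f"internal node {node} has degree {deg} != 3")

    def path_length(self, name_a: str, name_b: str) -> float:
        """Sum of branch lengths on the unique path between two leaves."""
        start, goal = self.leaves[name_a], self.leaves[name_b]
        stack = [(start, -1, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node == goal:
                return dist
            for nbr, ln in self._adj[node].items():
                if nbr != parent:
                    stack.append((nbr, node, dist + ln))
        raise ValidationError("leaves not connected")
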