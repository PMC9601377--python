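"""Readers and writers for the delimited-text formats used by the pipeline.

Genotype tables and frequency tables travel as CSV/TSV (delimiter picked by
file extension); distance matrices as PHYLIP square matrices; trees as Newick
(see :mod:`indelpop.treemds`).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    DistanceMatrix,
    GenotypeTable,
    Locus,
    ParseError,
    PopulationFrequencyTable,
    ValidationError,
)

#: Default cell for a missing genotype call.
MISSING_TOKEN = "./."

_RESERVED_COLUMNS = ("sample", "population")


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_genotype_table(
    path: str | Path,
    loci: list[Locus] | None = None,
    genotype_delimiter: str = "/",
    missing_token: str = MISSING_TOKEN,
) -> GenotypeTable:
    """Read a genotype table from delimited text.

    The file has one row per sample with a ``sample`` column, an optional
    ``population`` column, and one column per locus whose cells are
    ``"A1/A2"`` (unordered) or the missing token.  If ``loci`` is omitted,
    loci default to biallelic DIP markers with alleles ``("D", "I")`` when
    the observed labels are a subset of ``{D, I}``, otherwise to the sorted
    set of observed labels.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if "sample" not in df.columns:
        raise ParseError(f"{path}: missing 'sample' column")
    locus_cols = [c for c in df.columns if c not in _RESERVED_COLUMNS]
    if loci is None:
        loci = []
        for col in locus_cols:
            labels: set[str] = set()
            for cell in df[col]:
                if cell != missing_token:
                    labels.update(cell.split(genotype_delimiter))
            if labels <= {"D", "I"}:
                loci.append(Locus(id=col))
            else:
                loci.append(Locus(id=col, alleles=tuple(sorted(labels))))
    else:
        if [loc.id for loc in loci] != locus_cols:
            raise ParseError(f"{path}: locus columns do not match supplied loci")

    samples = df["sample"].tolist()
    if len(set(samples)) != len(samples):
        raise ValidationError(f"{path}: duplicate sample id")
    populations = df["population"].tolist() if "population" in df.columns else None

    calls = np.full((len(samples), len(loci), 2), MISSING, dtype=np.int16)
    for j, loc in enumerate(loci):
        for i, cell in enumerate(df[loc.id]):
            if cell == missing_token:
                continue
            parts = cell.split(genotype_delimiter)
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: malformed cell {cell!r} at row {i + 1}, column {loc.id}"
                )
            calls[i, j, 0] = loc.allele_index(parts[0])
            calls[i, j, 1] = loc.allele_index(parts[1])
    return GenotypeTable(loci=loci, samples=samples, calls=calls, populations=populations)


def write_genotype_table(
    table: GenotypeTable,
    path: str | Path,
    genotype_delimiter: str = "/",
    missing_token: str = MISSING_TOKEN,
) -> None:
    """Write a genotype table as delimited text re-readable by :func:`read_genotype_table`."""
    path = Path(path)
    data: dict[str, list[str]] = {"sample": list(table.samples)}
    if table.populations is not None:
        data["population"] = list(table.populations)
    for j, loc in enumerate(table.loci):
        col = []
        for i in range(table.n):
            a, b = table.calls[i, j]
            if a == MISSING:
                col.append(missing_token)
            else:
                col.append(loc.alleles[a] + genotype_delimiter + loc.alleles[b])
        data[loc.id] = col
    pd.DataFrame(data).to_csv(path, sep=_sep_for(path), index=False)


def read_population_frequency_table(path: str | Path) -> PopulationFrequencyTable:
    """Read a long-format frequency table.

    Expected columns: ``population, locus, allele, frequency, n`` — one row
    per (population, locus, allele).  Frequencies at each (population, locus)
    must sum to 1 within 1e-6 (renormalized if closer than that, rejected
    otherwise).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"population": str, "locus": str, "allele": str})
    required = {"population", "locus", "allele", "frequency", "n"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")

    populations = list(dict.fromkeys(df["population"]))
    locus_ids = list(dict.fromkeys(df["locus"]))
    loci = []
    for lid in locus_ids:
        alleles = tuple(dict.fromkeys(df.loc[df["locus"] == lid, "allele"]))
        if set(alleles) == {"D", "I"}:
            loci.append(Locus(id=lid, alleles=("D", "I")))
        else:
            loci.append(Locus(id=lid, alleles=alleles))

    freqs: list[list[np.ndarray]] = []
    sizes = np.zeros((len(populations), len(loci)), dtype=np.int64)
    grouped = df.set_index(["population", "locus"]).sort_index()
    for i, pop in enumerate(populations):
        row = []
        for j, loc in enumerate(loci):
            try:
                block = grouped.loc[(pop, loc.id)]
            except KeyError:
                raise ParseError(f"{path}: missing block for ({pop}, {loc.id})") from None
            f = np.zeros(loc.n_alleles)
            for _, rec in block.iterrows():
                f[loc.allele_index(rec["allele"])] = float(rec["frequency"])
            if np.any(f < 0):
                raise ValidationError(f"{pop}/{loc.id}: negative frequency")
            total = f.sum()
            if abs(total - 1.0) > 1e-6:
                raise ValidationError(
                    f"{pop}/{loc.id}: frequencies sum to {total:.8f}, off by more than 1e-6"
                )
            row.append(f / total)
            sizes[i, j] = int(block["n"].iloc[0])
        freqs.append(row)
    return PopulationFrequencyTable(populations=populations, loci=loci, freqs=freqs, sizes=sizes)


def write_population_frequency_table(
    table: PopulationFrequencyTable, path: str | Path
) -> None:
    path = Path(path)
    records = []
    for i, pop in enumerate(table.populations):
        for j, loc in enumerate(table.loci):
            for a, label in enumerate(loc.alleles):
                records.append(
                    {
                        "population": pop,
                        "locus": loc.id,
                        "allele": label,
                        "frequency": repr(float(table.freqs[i][j][a])),
                        "n": int(table.sizes[i, j]),
                    }
                )
    pd.DataFrame(records).to_csv(path, sep=_sep_for(path), index=False)


def write_distance_matrix(m: DistanceMatrix, path: str | Path) -> None:
    """Write a PHYLIP square distance matrix.

    Labels up to 10 characters are padded to the strict 10-column PHYLIP
    field; longer labels are written in relaxed PHYLIP (full label followed
    by whitespace).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{m.size}\n")
        for i, label in enumerate(m.labels):
            name = label.ljust(10) if len(label) <= 10 else label + " "
            row = " ".join(f"{v:.17g}" for v in m.d[i])
            fh.write(f"{name} {row}\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a (relaxed) PHYLIP square distance matrix."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    try:
        k = int(lines[0].strip())
    except (IndexError, ValueError):
        raise ParseError(f"{path}: first line must be the taxon count") from None
    if len(lines) != k + 1:
        raise ParseError(f"{path}: expected {k} matrix rows, found {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != k + 1:
            raise ParseError(f"{path}: row {ln!r} has wrong field count")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    d = np.array(rows)
    d = (d + d.T) / 2  # printed precision can break exact symmetry
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, d=d)


def distance_matrix_to_string(m: DistanceMatrix) -> str:
    buf = _io.StringIO()
    buf.write(f"{m.size}\n")
    for i, label in enumerate(m.labels):
        name = label.ljust(10) if len(label) <= 10 else label + " "
        buf.write(name + " " + " ".join(f"{v:.17g}" for v in m.d[i]) + "\n")
    return buf.getvalue()
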