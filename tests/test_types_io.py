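"""Container validation and delimited-text round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indelpop.io import (
    read_distance_matrix,
    read_genotype_table,
    read_population_frequency_table,
    write_distance_matrix,
    write_genotype_table,
    write_population_frequency_table,
)
from indelpop.types import (
    MISSING,
    DistanceMatrix,
    GenotypeTable,
    Locus,
    ParseError,
    PopulationFrequencyTable,
    ValidationError,
)


def test_locus_rejects_degenerate_allele_sets():
    with pytest.raises(ValidationError):
        Locus(id="X", alleles=("D",))
    with pytest.raises(ValidationError):
        Locus(id="X", alleles=("D", "D"))
    with pytest.raises(ValidationError):
        Locus(id="")


def test_genotype_table_normalizes_unordered_calls(tmp_path):
    path = tmp_path / "g.csv"
    path.write_text("sample,L1,L2\ns1,D/I,I/I\ns2,I/D,D/D\n")
    table = read_genotype_table(path)
    # "I/D" and "D/I" are the same unordered genotype
    assert np.array_equal(table.calls[0, 0], table.calls[1, 0])
    assert table.n == 2
    assert [loc.id for loc in table.loci] == ["L1", "L2"]


def test_genotype_table_parse_errors(tmp_path):
    bad_cell = tmp_path / "bad.csv"
    bad_cell.write_text("sample,L1\ns1,D/I/I\n")
    with pytest.raises(ParseError, match="L1"):
        read_genotype_table(bad_cell)

    bad_allele = tmp_path / "allele.csv"
    bad_allele.write_text("sample,L1\ns1,D/Z\n")
    with pytest.raises(ValidationError, match="Z"):
        read_genotype_table(bad_allele, loci=[Locus("L1")])

    dup = tmp_path / "dup.csv"
    dup.write_text("sample,L1\ns1,D/I\ns1,D/D\n")
    with pytest.raises(ValidationError, match="duplicate"):
        read_genotype_table(dup)


def test_genotype_table_roundtrip_with_missing_and_populations(tmp_path):
    loci = [Locus("L1"), Locus("L2", alleles=("8", "9", "10"))]
    calls = np.array(
        [
            [[0, 1], [0, 2]],
            [[MISSING, MISSING], [1, 1]],
            [[1, 1], [MISSING, MISSING]],
        ],
        dtype=np.int16,
    )
    table = GenotypeTable(
        loci=loci, samples=["a", "b", "c"], calls=calls, populations=["x", "x", "y"]
    )
    path = tmp_path / "t.tsv"
    write_genotype_table(table, path)
    assert read_genotype_table(path, loci=loci) == table


def test_empty_genotype_table_roundtrip(tmp_path):
    loci = [Locus("L1")]
    table = GenotypeTable(
        loci=loci, samples=[], calls=np.empty((0, 1, 2), dtype=np.int16)
    )
    path = tmp_path / "empty.csv"
    write_genotype_table(table, path)
    assert path.read_text().splitlines() == ["sample,L1"]
    assert read_genotype_table(path, loci=loci) == table


@settings(max_examples=25, deadline=None)
@given(st.data())
def test_random_genotype_table_roundtrip(tmp_path_factory, data):
    """write . read is the identity on arbitrary valid tables."""
    n = data.draw(st.integers(1, 8))
    m = data.draw(st.integers(1, 4))
    loci = [Locus(f"L{j}") for j in range(m)]
    cells = data.draw(
        st.lists(
            st.lists(
                st.sampled_from([(0, 0), (0, 1), (1, 1), (MISSING, MISSING)]),
                min_size=m,
                max_size=m,
            ),
            min_size=n,
            max_size=n,
        )
    )
    calls = np.array(cells, dtype=np.int16)
    table = GenotypeTable(loci=loci, samples=[f"s{i}" for i in range(n)], calls=calls)
    path = tmp_path_factory.mktemp("rt") / "t.csv"
    write_genotype_table(table, path)
    assert read_genotype_table(path, loci=loci) == table


def test_frequency_table_roundtrip_and_published_row(tmp_path):
    path = tmp_path / "f.csv"
    path.write_text(
        "population,locus,allele,frequency,n\n"
        "Poland,HLD77,D,0.4422,631\n"
        "Poland,HLD77,I,0.5578,631\n"
    )
    table = read_population_frequency_table(path)
    assert table.populations == ["Poland"]
    assert table.sizes[0, 0] == 631
    np.testing.assert_allclose(table.freqs[0][0], [0.4422, 0.5578])

    out = tmp_path / "f2.csv"
    write_population_frequency_table(table, out)
    again = read_population_frequency_table(out)
    np.testing.assert_allclose(again.freqs[0][0], table.freqs[0][0], atol=1e-12)


def test_frequency_table_tolerance_rule(tmp_path):
    near = tmp_path / "near.csv"
    near.write_text(
        "population,locus,allele,frequency,n\n"
        "P,L,D,0.5,10\nP,L,I,0.5000000001,10\n"
    )
    table = read_population_frequency_table(near)
    assert abs(table.freqs[0][0].sum() - 1.0) < 1e-12

    off = tmp_path / "off.csv"
    off.write_text("population,locus,allele,frequency,n\nP,L,D,0.6,10\nP,L,I,0.6,10\n")
    with pytest.raises(ValidationError, match="sum"):
        read_population_frequency_table(off)

    neg = tmp_path / "neg.csv"
    neg.write_text("population,locus,allele,frequency,n\nP,L,D,-0.1,10\nP,L,I,1.1,10\n")
    with pytest.raises(ValidationError, match="negative"):
        read_population_frequency_table(neg)


def test_distance_matrix_phylip_roundtrip(tmp_path):
    m = DistanceMatrix(labels=["POL", "ESP"], d=np.array([[0.0, 0.037], [0.037, 0.0]]))
    path = tmp_path / "d.phy"
    write_distance_matrix(m, path)
    lines = path.read_text().splitlines()
    assert len(lines) == 3 and lines[0] == "2"
    again = read_distance_matrix(path)
    assert again.labels == m.labels
    np.testing.assert_allclose(again.d, m.d, atol=1e-12)


def test_distance_matrix_single_taxon(tmp_path):
    m = DistanceMatrix(labels=["POL"], d=np.zeros((1, 1)))
    path = tmp_path / "one.phy"
    write_distance_matrix(m, path)
    again = read_distance_matrix(path)
    assert again.labels == ["POL"] and again.d[0, 0] == 0.0


def test_distance_matrix_validation():
    with pytest.raises(ValidationError, match="symmetric"):
        DistanceMatrix(labels=["a", "b"], d=np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValidationError, match="diagonal"):
        DistanceMatrix(labels=["a", "b"], d=np.array([[1.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(ValidationError, match="negative"):
        DistanceMatrix(labels=["a", "b"], d=np.array([[0.0, -1.0], [-1.0, 0.0]]))


def test_population_frequency_table_invariants():
    loci = [Locus("L")]
    with pytest.raises(ValidationError):
        PopulationFrequencyTable(
            populations=["a"], loci=loci, freqs=[[np.array([0.7, 0.4])]],
            sizes=np.array([[10]]),
        )
    with pytest.raises(ValidationError):
        PopulationFrequencyTable(
            populations=["a"], loci=loci, freqs=[[np.array([0.5, 0.5])]],
            sizes=np.array([[0]]),
        )
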