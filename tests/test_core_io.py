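"""Loaders, writers, fixtures, and the merge/round-trip invariants."""

import numpy as np
import pytest

from herbnet.core_io import (
    GeneSet,
    GeneSetCollection,
    InteractionNetwork,
    load_anti_ra_overlap,
    load_compound_catalogue,
    load_known_targets,
    load_omim_ra_targets,
    load_panel,
    load_ppi,
    read_gmt,
    read_graphml,
    write_compound_catalogue,
    write_gmt,
    write_graphml,
    write_panel,
)
from herbnet.synth import PRESETS, generate_bundle

from conftest import make_network, random_network


# ---------------------------------------------------------------------------
# compound catalogue
# ---------------------------------------------------------------------------


def _write_catalogue(path, rows):
    lines = ["compound_id\therb\tname\tfingerprint"]
    lines += [f"{cid}\t{herb}\t{name}\t{fp}" for cid, herb, name, fp in rows]
    path.write_text("\n".join(lines) + "\n")


def test_catalogue_per_herb_counts_sum_to_total(tmp_path):
    """A five-herb catalogue with counts 22/122/39/65/203 totals 451."""
    counts = {"h1": 22, "h2": 122, "h3": 39, "h4": 65, "h5": 203}
    rows = []
    i = 0
    for herb, n in counts.items():
        for _ in range(n):
            rows.append((f"c{i}", herb, "", "0;1"))
            i += 1
    p = tmp_path / "cat.tsv"
    _write_catalogue(p, rows)
    records, summary = load_compound_catalogue(p, fingerprint_length=8)
    assert summary["per_herb"] == counts
    assert summary["total"] == 451 == len(records)


def test_catalogue_empty_file(tmp_path):
    p = tmp_path / "cat.tsv"
    p.write_text("compound_id\therb\tfingerprint\n")
    records, summary = load_compound_catalogue(p, fingerprint_length=8)
    assert records == [] and summary["total"] == 0


def test_catalogue_duplicate_id_names_offender(tmp_path):
    p = tmp_path / "cat.tsv"
    _write_catalogue(p, [("c1", "h", "", "0"), ("c1", "h", "", "1")])
    with pytest.raises(ValueError, match="c1"):
        load_compound_catalogue(p, fingerprint_length=8)


def test_catalogue_out_of_range_bit_names_row(tmp_path):
    p = tmp_path / "cat.tsv"
    _write_catalogue(p, [("c1", "h", "", "0"), ("c2", "h", "", "99")])
    with pytest.raises(ValueError, match="row 3"):
        load_compound_catalogue(p, fingerprint_length=8)


def test_catalogue_round_trip(tmp_path):
    bundle = generate_bundle(PRESETS["toy"])
    p = tmp_path / "cat.tsv"
    write_compound_catalogue(bundle.compounds, p)
    records, _ = load_compound_catalogue(p, bundle.config.fingerprint_length)
    assert records == bundle.compounds


# ---------------------------------------------------------------------------
# PPI merging
# ---------------------------------------------------------------------------


def test_ppi_merge_dedups_and_unions_provenance(tmp_path):
    f1 = tmp_path / "F1.tsv"
    f1.write_text("a\tb\n")
    f2 = tmp_path / "F2.tsv"
    f2.write_text("b\ta\nb\tc\n")
    net = load_ppi([f1, f2])
    assert net.edges == {frozenset({"A", "B"}), frozenset({"B", "C"})}
    assert net.edge_sources("a", "b") == {"F1", "F2"}
    assert net.edge_sources("b", "c") == {"F2"}


def test_ppi_self_loops_dropped_and_counted(tmp_path):
    f = tmp_path / "F.tsv"
    f.write_text("a\ta\na\tb\n")
    net = load_ppi([f])
    assert net.edges == {frozenset({"A", "B"})}
    assert net.dropped_self_loops == 1


def test_ppi_disjoint_files_sum_edge_counts(tmp_path):
    files = []
    for i, (u, v) in enumerate([("a", "b"), ("c", "d"), ("e", "f")]):
        f = tmp_path / f"f{i}.tsv"
        f.write_text(f"{u}\t{v}\n")
        files.append(f)
    assert load_ppi(files).number_of_edges() == 3


def test_ppi_merge_idempotent_and_order_independent(tmp_path):
    f1 = tmp_path / "F1.tsv"
    f1.write_text("a\tb\nb\tc\n")
    f2 = tmp_path / "F2.tsv"
    f2.write_text("a\tb\nc\td\n")
    assert load_ppi([f1, f2]) == load_ppi([f2, f1])
    assert load_ppi([f1, f1]) == load_ppi([f1])


def test_ppi_sif_and_unparseable_line(tmp_path):
    sif = tmp_path / "net.sif"
    sif.write_text("a interacts b c\nlonely\n")
    net = load_ppi([sif])
    assert net.edges == {frozenset({"A", "B"}), frozenset({"A", "C"})}
    assert "LONELY" in net.nodes
    bad = tmp_path / "bad.tsv"
    bad.write_text("a\tb\nonly_one_field_is_a_sif_problem\ta\tb\tc\td\n")
    with pytest.raises(ValueError, match="bad.tsv:2"):
        load_ppi([bad])


# ---------------------------------------------------------------------------
# known-target sets
# ---------------------------------------------------------------------------


def test_known_targets_union_and_provenance(tmp_path):
    a = tmp_path / "a.txt"
    a.write_text("x\ny\n")
    b = tmp_path / "b.txt"
    b.write_text("Y\nz\n")
    kts = load_known_targets([("A", a), ("B", b)])
    assert kts.members == {"X", "Y", "Z"}
    assert kts.source_tags["Y"] == {"A", "B"}
    assert kts.per_source_counts == {"A": 2, "B": 2}


def test_known_targets_idempotent(tmp_path):
    a = tmp_path / "a.txt"
    a.write_text("x\ny\n")
    once = load_known_targets([("A", a)])
    twice = load_known_targets([("A", a), ("A", a)])
    assert once.members == twice.members and once.source_tags == twice.source_tags


def test_known_targets_empty_union_warns_not_raises(tmp_path):
    a = tmp_path / "a.txt"
    a.write_text("# nothing\n")
    kts = load_known_targets([("A", a)])
    assert len(kts) == 0


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


def test_anti_ra_overlap_fixture_has_22_distinct_targets():
    rows, distinct = load_anti_ra_overlap()
    assert distinct == 22
    successful = [r for r in rows if r.target_class == "Successful target"]
    assert 0 < len(successful) <= 22
    assert [r for r in rows if r.target_class == "No such class"] == []


def test_omim_fixture_has_seven_symbols():
    kts = load_omim_ra_targets()
    assert len(kts) == 7
    assert "CD244" in kts.members and kts.source_tags["CD244"] == {"OMIM"}


# ---------------------------------------------------------------------------
# round trips
# ---------------------------------------------------------------------------


def test_graphml_round_trip_small_cases(tmp_path):
    path3 = make_network([("a", "b"), ("b", "c")])
    empty = InteractionNetwork()
    for i, net in enumerate([path3, empty]):
        p = tmp_path / f"n{i}.graphml"
        write_graphml(net, p)
        assert read_graphml(p) == net


def test_round_trip_fidelity_randomised():
    """write(load(x)) == x on 100 seeded random networks and gene sets."""
    import tempfile
    from pathlib import Path

    rng = np.random.default_rng(42)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        for i in range(100):
            net = random_network(rng)
            p = tmp / f"net{i}.graphml"
            write_graphml(net, p)
            assert read_graphml(p) == net

            n_sets = int(rng.integers(1, 4))
            coll = GeneSetCollection(
                sets=[
                    GeneSet(
                        set_id=f"S{j}",
                        name=f"set {j}",
                        members=frozenset(
                            f"G{int(g)}" for g in rng.integers(0, 50, size=rng.integers(1, 8))
                        ),
                    )
                    for j in range(n_sets)
                ]
            )
            g = tmp / f"sets{i}.gmt"
            write_gmt(coll, g)
            back = read_gmt(g)
            assert [(s.set_id, s.members) for s in back] == [
                (s.set_id, s.members) for s in coll
            ]


def test_panel_round_trip(tmp_path, toy_bundle):
    p = tmp_path / "panel.tsv"
    write_panel(toy_bundle.panel, p)
    assert load_panel(p, toy_bundle.config.fingerprint_length) == toy_bundle.panel
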