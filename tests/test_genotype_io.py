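"""Genotype/pedigree I/O and SNP quality control."""

import numpy as np
import pandas as pd
import pytest

from recombscape.genotype_io import (
    MISSING,
    GenotypeMatrix,
    ParseError,
    build_half_sib_families,
    fill_missing_genotypes,
    mendelian_inconsistency_rate,
    qc_filter_snps,
    read_genotypes,
    read_pedigree,
    write_genotypes,
)

from conftest import make_pedigree


MAP3 = "1 m1 0 100\n1 m2 0 200\n2 m3 0 50\n2 m4 0 90\n"


def write_pedmap(tmp_path, ped_lines, map_text=MAP3):
    (tmp_path / "g.map").write_text(map_text)
    (tmp_path / "g.ped").write_text("\n".join(ped_lines) + "\n")
    return tmp_path / "g.ped"


class TestReadGenotypes:
    def test_pedmap_transcription(self, tmp_path):
        ped = [
            "0 i1 0 0 1 -9 1 1 1 2 2 2 1 1",
            "0 i2 0 0 2 -9 1 2 2 2 1 2 1 2",
            "0 i3 0 0 1 -9 2 2 1 1 1 1 2 2",
        ]
        G = read_genotypes(write_pedmap(tmp_path, ped))
        assert G.individuals == ["i1", "i2", "i3"]
        # dosage counts the lexicographically larger allele ("2")
        expected = np.array([[0, 1, 2, 0], [1, 2, 1, 1], [2, 0, 0, 2]])
        np.testing.assert_array_equal(G.calls, expected)

    def test_missing_call_preserved(self, tmp_path):
        ped = ["0 i1 0 0 1 -9 0 0 1 2 2 2 1 1", "0 i2 0 0 1 -9 1 1 1 1 1 1 1 1"]
        G = read_genotypes(write_pedmap(tmp_path, ped))
        assert G.calls[0, 0] == MISSING

    def test_unsorted_map_is_sorted(self, tmp_path):
        shuffled = "2 m3 0 50\n1 m2 0 200\n1 m1 0 100\n2 m4 0 90\n"
        ped = ["0 i1 0 0 1 -9 1 2 2 2 1 1 1 2"]
        G = read_genotypes(write_pedmap(tmp_path, ped, shuffled))
        # independent sort oracle over (chromosome, position)
        expected_order = sorted(
            [("1", 100, "m1"), ("1", 200, "m2"), ("2", 50, "m3"), ("2", 90, "m4")]
        )
        assert list(G.markers["marker_id"]) == [m for _, _, m in expected_order]
        # permutation recorded: dosages follow their markers
        assert G.calls[0, list(G.markers["marker_id"]).index("m3")] == 1

    def test_malformed_line_names_line_number(self, tmp_path):
        ped = ["0 i1 0 0 1 -9 1 1 1 2 2 2 1 1", "0 i2 0 0 1 -9 1 1"]
        with pytest.raises(ParseError, match=":2"):
            read_genotypes(write_pedmap(tmp_path, ped))

    def test_duplicate_marker_error(self, tmp_path):
        bad_map = "1 m1 0 100\n1 m1 0 200\n1 m3 0 300\n1 m4 0 400\n"
        ped = ["0 i1 0 0 1 -9 1 1 1 2 2 2 1 1"]
        with pytest.raises(ParseError, match="duplicate"):
            read_genotypes(write_pedmap(tmp_path, ped, bad_map))

    def test_matrix_roundtrip(self, tmp_path, rng):
        calls = rng.integers(0, 3, size=(4, 6)).astype(np.int8)
        calls[0, 0] = MISSING
        markers = pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(6)],
                "chromosome": ["1"] * 3 + ["2"] * 3,
                "position": [10, 20, 30, 10, 20, 30],
            }
        )
        G = GenotypeMatrix([f"i{k}" for k in range(4)], markers, calls)
        write_genotypes(G, tmp_path / "x", dialect="matrix")
        G2 = read_genotypes(tmp_path / "x", dialect="matrix")
        np.testing.assert_array_equal(G.calls, G2.calls)
        assert G2.individuals == G.individuals


class TestReadPedigree:
    def test_trio_topological(self, tmp_path):
        (tmp_path / "p.tsv").write_text(
            "individual\tsire\tdam\tsex\nkid\ts1\td1\tM\ns1\t0\t0\tM\nd1\t0\t0\tF\n"
        )
        ped = read_pedigree(tmp_path / "p.tsv")
        order = list(ped["individual"])
        assert order.index("kid") > order.index("s1")
        assert order.index("kid") > order.index("d1")

    def test_self_parent_cycle(self, tmp_path):
        (tmp_path / "p.tsv").write_text("individual\tsire\tdam\tsex\nx\tx\t0\tM\n")
        with pytest.raises(ParseError, match="cycle"):
            read_pedigree(tmp_path / "p.tsv")

    def test_unknown_sex_code(self, tmp_path):
        (tmp_path / "p.tsv").write_text("individual\tsire\tdam\tsex\nx\t0\t0\tQ\n")
        with pytest.raises(ParseError, match="sex"):
            read_pedigree(tmp_path / "p.tsv")

    def test_order_invariance(self, tmp_path, rng):
        rows = ["individual\tsire\tdam\tsex", "a\t0\t0\tM", "b\t0\t0\tF",
                "c\ta\tb\tM", "d\ta\tb\tF", "e\tc\td\tM"]
        (tmp_path / "p1.tsv").write_text("\n".join(rows) + "\n")
        shuffled = [rows[0]] + [rows[i] for i in [5, 2, 4, 1, 3]]
        (tmp_path / "p2.tsv").write_text("\n".join(shuffled) + "\n")
        p1 = read_pedigree(tmp_path / "p1.tsv")
        p2 = read_pedigree(tmp_path / "p2.tsv")
        for ped in (p1, p2):
            pos = {r.individual: i for i, r in enumerate(ped.itertuples())}
            for r in ped.itertuples():
                for parent in (r.sire, r.dam):
                    if parent != "0":
                        assert pos[parent] < pos[r.individual]
        assert set(p1["individual"]) == set(p2["individual"])


def _cohort(rng, n_ind=12, n_mark=8):
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(n_mark)],
            "chromosome": ["1"] * n_mark,
            "position": np.arange(1, n_mark + 1) * 100,
        }
    )
    calls = rng.integers(0, 3, size=(n_ind, n_mark)).astype(np.int8)
    return GenotypeMatrix([f"i{k}" for k in range(n_ind)], markers, calls)


class TestQC:
    def test_low_maf_removed(self, rng):
        G = _cohort(rng, n_ind=100)
        G.calls[:, 2] = 0
        G.calls[:2, 2] = 1  # MAF = 2/200 = 0.01 < 0.025
        _, report = qc_filter_snps(G, None)
        assert report.loc[2, "removed"] and "maf" in report.loc[2, "reason"]

    def test_all_pass_identity(self, rng):
        G = _cohort(rng, n_ind=200)
        # force healthy MAF everywhere
        G.calls[:100] = 1
        out, report = qc_filter_snps(G, None)
        assert not report["removed"].any()
        np.testing.assert_array_equal(out.calls, G.calls)

    def test_mendelian_rule_threshold(self):
        # 40 parent-offspring pairs, 3 impossible at marker 0 (0.075 > 0.05)
        n_pairs = 40
        inds, rows = [], []
        calls = []
        for k in range(n_pairs):
            inds += [f"p{k}", f"o{k}"]
            rows += [(f"p{k}", "0", "0", "M"), (f"o{k}", f"p{k}", "0", "F")]
            bad = k < 3
            calls += [[0, 1], [2 if bad else 1, 1]]
        markers = pd.DataFrame(
            {"marker_id": ["mA", "mB"], "chromosome": ["1", "1"], "position": [10, 20]}
        )
        G = GenotypeMatrix(inds, markers, np.array(calls, dtype=np.int8))
        ped = make_pedigree(rows)
        rate = mendelian_inconsistency_rate(G, ped)
        assert rate[0] == pytest.approx(3 / 40)
        _, report = qc_filter_snps(G, ped, call_rate_min=0.0, maf_min=0.0)
        assert report.loc[0, "removed"] and "mendel" in report.loc[0, "reason"]
        assert not report.loc[1, "removed"]

    def test_idempotent_and_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            markers = pd.DataFrame(
                {
                    "marker_id": [f"m{i}" for i in range(50)],
                    "chromosome": ["1"] * 50,
                    "position": np.arange(1, 51) * 10,
                }
            )
            calls = rng.choice([-1, 0, 1, 2], p=[0.1, 0.3, 0.3, 0.3], size=(50, 50))
            G = GenotypeMatrix([f"i{k}" for k in range(50)], markers, calls.astype(np.int8))
            once, rep = qc_filter_snps(G, None)
            twice, rep2 = qc_filter_snps(once, None)
            np.testing.assert_array_equal(once.calls, twice.calls)
            assert not rep2["removed"].any()
            # brute-force per-marker tallies
            for j in range(50):
                col = calls[:, j]
                obs = col[col >= 0]
                cr = len(obs) / 50
                assert rep.loc[j, "call_rate"] == pytest.approx(cr)
                if len(obs):
                    p = obs.sum() / (2 * len(obs))
                    assert rep.loc[j, "maf"] == pytest.approx(min(p, 1 - p))


class TestHalfSibFamilies:
    def test_sire_family_dam_ungenotyped(self):
        ped = make_pedigree(
            [("s", "0", "0", "M"), ("d", "0", "0", "F")]
            + [(f"o{k}", "s", "d", "M") for k in range(3)]
        )
        fams = build_half_sib_families(ped, {"s", "o0", "o1", "o2"})
        assert len(fams) == 1
        assert fams[0].focal_sex == "sire" and fams[0].n_offspring == 3
        assert all(mate is None for _, mate in fams[0].pairs)

    def test_min_offspring_rule(self):
        ped = make_pedigree([("s", "0", "0", "M"), ("o", "s", "0", "F")])
        assert build_half_sib_families(ped, {"s", "o"}) == []

    def test_nuclear_family_counts_for_both_parents(self):
        ped = make_pedigree(
            [("s", "0", "0", "M"), ("d", "0", "0", "F"),
             ("o1", "s", "d", "M"), ("o2", "s", "d", "F")]
        )
        fams = build_half_sib_families(ped, {"s", "d", "o1", "o2"})
        assert {f.focal_sex for f in fams} == {"sire", "dam"}

    def test_pair_count_matches_pedigree_walk(self, rng):
        # random pedigree; compare against exhaustive link counting
        rows = [(f"f{k}", "0", "0", "M" if k % 2 else "F") for k in range(8)]
        for k in range(30):
            s = f"f{rng.integers(0, 4) * 2}"
            d = f"f{rng.integers(0, 4) * 2 + 1}"
            rows.append((f"o{k}", s, d, "M"))
        ped = make_pedigree(rows)
        genotyped = {r[0] for r in rows if rng.random() < 0.8}
        fams = build_half_sib_families(ped, genotyped, min_offspring=2)
        got = sum(f.n_offspring for f in fams)
        counts = {}
        for r in ped.itertuples():
            if r.individual in genotyped:
                for p in (r.sire, r.dam):
                    if p != "0" and p in genotyped:
                        counts[p] = counts.get(p, 0) + 1
        expected = sum(v for v in counts.values() if v >= 2)
        assert got == expected


class TestFillMissing:
    def test_mendelian_forced(self):
        ped = make_pedigree(
            [("s", "0", "0", "M"), ("d", "0", "0", "F"), ("o", "s", "d", "M")]
        )
        markers = pd.DataFrame(
            {"marker_id": ["m0"], "chromosome": ["1"], "position": [10]}
        )
        G = GenotypeMatrix(
            ["s", "d", "o"], markers, np.array([[0], [0], [MISSING]], dtype=np.int8)
        )
        out = fill_missing_genotypes(G, ped)
        assert out.calls[2, 0] == 0

    def test_mean_dosage_fallback(self):
        ped = make_pedigree([(f"i{k}", "0", "0", "M") for k in range(6)])
        markers = pd.DataFrame(
            {"marker_id": ["m0"], "chromosome": ["1"], "position": [10]}
        )
        calls = np.array([[2], [2], [1], [1], [0], [MISSING]], dtype=np.int8)
        out = fill_missing_genotypes(G := GenotypeMatrix([f"i{k}" for k in range(6)], markers, calls), ped)
        # mean dosage 6/5 = 1.2 -> rounds to 1
        assert out.calls[5, 0] == 1

    def test_no_missing_identity(self, rng):
        G = _cohort(rng)
        ped = make_pedigree([(i, "0", "0", "M") for i in G.individuals])
        out = fill_missing_genotypes(G, ped)
        np.testing.assert_array_equal(out.calls, G.calls)
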