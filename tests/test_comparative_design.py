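"""Alignment mapping, distance shells, grouping and the insertion rule."""
import numpy as np
import pytest

from thermoshift import comparative_design as cd
from thermoshift import synthetic_data as sd

from conftest import brute_force_distance_map, random_alignment_and_structure


def cols_from(row_a: str, row_b: str) -> cd.PairwiseAlignmentMap:
    cols, pa, pb = [], 0, 0
    for a, b in zip(row_a, row_b):
        ra = None if a == "-" else a
        rb = None if b == "-" else b
        pa += ra is not None
        pb += rb is not None
        cols.append(cd.AlignmentColumn(ra, rb, pa if ra else None,
                                       pb if rb else None))
    return cd.PairwiseAlignmentMap("A", "B", cols)


class TestAlignGlobal:
    def test_identity_alignment(self):
        aln = cd.align_global("ACDE", "ACDE")
        s = cd.summarize_alignment(aln)
        assert (s.identical, s.different, s.insertions_in_B) == (4, 0, 0)

    def test_single_deletion_in_b(self):
        aln = cd.align_global("ACDE", "ACE")
        gaps_in_b = sum(1 for c in aln.columns if c.b is None)
        gaps_in_a = sum(1 for c in aln.columns if c.a is None)
        assert (gaps_in_b, gaps_in_a) == (1, 0)
        assert len(aln.columns) == 4

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            cd.align_global("ACDE", "AC1E")
        with pytest.raises(ValueError, match="empty"):
            cd.align_global("", "ACDE")

    def test_positions_strictly_increasing(self):
        aln = cd.align_global("MKVLATTAC", "MKTTAC")
        aln.validate()  # raises on violation


class TestSummarizeAlignment:
    def test_mismatch_counting(self):
        s = cd.summarize_alignment(cols_from("ACDE", "AXDE"))
        assert (s.identical, s.different) == (3, 1)
        assert s.aligned_length == 4

    def test_insertions_in_b_counted_as_residues(self):
        # B carries a two-residue insertion relative to A
        s = cd.summarize_alignment(cols_from("AC--DE", "ACWWDE"))
        assert s.insertions_in_B == 2
        assert s.aligned_length == 4

    def test_invariant_identical_plus_different(self):
        s = cd.summarize_alignment(cols_from("ACD-E", "AXDWE"))
        assert s.identical + s.different == s.aligned_length


class TestDistanceMap:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pdb_text, _ = sd.random_toy_structure(rng, n_residues=7)
            st = cd.parse_structure(pdb_text)
            dmap = cd.compute_distance_map(st, ["IPM", "NAD"])
            oracle = brute_force_distance_map(pdb_text, ["IPM", "NAD"])
            assert set(dmap.entries) == set(oracle)
            for key in oracle:
                for lig in ("IPM", "NAD"):
                    assert dmap.entries[key][lig] == pytest.approx(
                        oracle[key][lig], abs=1e-9)

    def test_no_lower_bound_clamping(self):
        specs = [sd.ResidueSpec("A", 1, "ALA", 1.2)]
        st = cd.parse_structure(sd.make_toy_structure(specs, ["IPM"]))
        dmap = cd.compute_distance_map(st, ["IPM"])
        assert dmap.entries[("A", 1, "ALA")]["IPM"] == pytest.approx(1.2, abs=0.01)

    def test_minimum_over_ligand_copies_across_chains(self):
        # two copies of NAD in different chains; residue is 3 A from one,
        # 20 A from the other -> the map must report 3 A
        base = sd.make_toy_structure(
            [sd.ResidueSpec("A", 1, "ALA", 3.0, direction=(1, 0, 0))], ["NAD"])
        far_copy = ("HETATM  999  C1 NAD B 901      50.000  30.000  30.000"
                    "  1.00  0.00           C\n")
        pdb_text = base.replace("END\n", far_copy + "END\n")
        st = cd.parse_structure(pdb_text)
        dmap = cd.compute_distance_map(st, ["NAD"])
        assert dmap.entries[("A", 1, "ALA")]["NAD"] == pytest.approx(3.0, abs=0.01)

    def test_missing_ligand_lists_available_groups(self):
        st = cd.parse_structure(sd.make_toy_structure(
            [sd.ResidueSpec("A", 1, "ALA", 5.0)], ["IPM"]))
        with pytest.raises(ValueError, match="NAD"):
            cd.compute_distance_map(st, ["NAD"])


class TestShellSelection:
    def test_identical_columns_never_selected(self):
        rng = np.random.default_rng(11)
        pdb_text, specs = sd.random_toy_structure(rng, 6)
        seq = "".join(sd.AA1[s.resname] for s in specs)
        aln = cols_from(seq, seq)
        dmap = cd.compute_distance_map(cd.parse_structure(pdb_text),
                                       ["IPM", "NAD"])
        assert cd.select_shell_sites(aln, dmap, radius=100.0) == []

    def test_threshold_boundary(self):
        specs = [sd.ResidueSpec("A", 1, "VAL", 10.0)]
        pdb = sd.make_toy_structure(specs, ["IPM"])
        dmap = cd.compute_distance_map(cd.parse_structure(pdb), ["IPM"])
        aln = cols_from("V", "A")
        assert cd.select_shell_sites(aln, dmap, 8.0) == []
        sel12 = cd.select_shell_sites(aln, dmap, 12.0)
        assert [s.position_a for s in sel12] == [1]

    def test_shell_nesting_on_random_structures(self):
        """selected(8 A) is a subset of selected(12 A), vs brute force."""
        rng = np.random.default_rng(23)
        for _ in range(100):
            aln, pdb_text, specs = random_alignment_and_structure(rng, 8)
            dmap = cd.compute_distance_map(cd.parse_structure(pdb_text),
                                           ["IPM", "NAD"])
            s8 = {c.position_a for c in cd.select_shell_sites(aln, dmap, 8.0)}
            s12 = {c.position_a for c in cd.select_shell_sites(aln, dmap, 12.0)}
            assert s8 <= s12
            # brute-force filter from the generating spec distances
            oracle8 = {s.resnum for s, col in zip(specs, aln.columns)
                       if col.a != col.b and s.distance <= 8.0 + 0.01}
            oracle8_strict = {s.resnum for s, col in zip(specs, aln.columns)
                              if col.a != col.b and s.distance <= 8.0 - 0.01}
            assert oracle8_strict <= s8 <= oracle8

    def test_position_absent_from_structure_warns_and_skips(self):
        specs = [sd.ResidueSpec("A", 1, "VAL", 5.0)]
        dmap = cd.compute_distance_map(
            cd.parse_structure(sd.make_toy_structure(specs, ["IPM"])), ["IPM"])
        aln = cols_from("VC", "AD")  # position 2 has no structure residue
        with pytest.warns(UserWarning, match="absent"):
            sel = cd.select_shell_sites(aln, dmap, 8.0)
        assert [s.position_a for s in sel] == [1]


def place(resnum, resname, xy):
    """Residue at a controlled offset (in the xy plane) from the ligand."""
    v = np.asarray((*xy, 0.0), dtype=float)
    n = np.linalg.norm(v)
    return sd.ResidueSpec("A", resnum, resname, float(n),
                          direction=tuple(v / n))


class TestGrouping:
    def build(self, specs):
        pdb = sd.make_toy_structure(specs, ["IPM"])
        st = cd.parse_structure(pdb)
        dmap = cd.compute_distance_map(st, ["IPM"])
        aln = cols_from("".join(sd.AA1[s.resname] for s in specs),
                        "G" * len(specs))
        cands = cd.select_shell_sites(aln, dmap, radius=1000.0)
        return st, cands

    def test_close_pair_becomes_one_design(self):
        st, cands = self.build([place(1, "VAL", (5, 0)), place(2, "HIS", (8, 0))])
        designs = cd.group_sites(cands, st, link_threshold=6.0)
        assert len(designs) == 1
        assert len(designs[0].substitutions) == 2

    def test_distant_pair_stays_separate(self):
        st, cands = self.build([place(1, "VAL", (5, 0)), place(2, "HIS", (-15, 0))])
        designs = cd.group_sites(cands, st, link_threshold=6.0)
        assert [len(d.substitutions) for d in designs] == [1, 1]

    def test_single_linkage_chains_three_sites(self):
        # A-B 5 A, B-C 5 A, A-C ~9.5 A: single linkage joins all three
        st, cands = self.build([
            place(1, "VAL", (6, 0)),
            place(2, "HIS", (6, 4.2)),  # ~4.2+ A from both neighbours
            place(3, "LEU", (6, 8.4)),
        ])
        designs = cd.group_sites(cands, st, link_threshold=6.0)
        assert len(designs) == 1
        assert len(designs[0].substitutions) == 3

    def test_matches_connected_components_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            aln, pdb_text, specs = random_alignment_and_structure(rng, 8)
            st = cd.parse_structure(pdb_text)
            dmap = cd.compute_distance_map(st, ["IPM", "NAD"])
            cands = cd.select_shell_sites(aln, dmap, 1000.0)
            designs = cd.group_sites(cands, st, link_threshold=6.0)
            # oracle: exhaustive transitive closure over pairwise distances
            oracle_d = brute_force_distance_map(pdb_text, [])
            coords = {}
            for line in pdb_text.splitlines():
                if line.startswith("ATOM"):
                    coords.setdefault(int(line[22:26]), []).append(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])])
            nums = [c.resnum for c in cands]
            parent = {n: n for n in nums}

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            for i in nums:
                for j in nums:
                    if i < j:
                        a, b = np.asarray(coords[i]), np.asarray(coords[j])
                        d = np.sqrt(((a[:, None] - b[None]) ** 2).sum(-1)).min()
                        if d <= 6.0:
                            parent[find(i)] = find(j)
            oracle_groups = {}
            for n in nums:
                oracle_groups.setdefault(find(n), set()).add(n)
            got = {frozenset(p for p, _, _ in d.substitutions) for d in designs}
            want = {frozenset(g) for g in oracle_groups.values()}
            assert got == want

    def test_grouping_partitions_candidates(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            aln, pdb_text, _ = random_alignment_and_structure(rng, 10)
            st = cd.parse_structure(pdb_text)
            dmap = cd.compute_distance_map(st, ["IPM", "NAD"])
            cands = cd.select_shell_sites(aln, dmap, 12.0)
            designs = cd.group_sites(cands, st, 6.0)
            seen = [p for d in designs for p, _, _ in d.substitutions]
            assert sorted(seen) == sorted(c.position_a for c in cands)


class TestInsertionRule:
    def test_insertion_adjacent_to_substitution_attached(self):
        aln = cols_from("AC-DE", "AGWDE")  # substitution at pos 2, insertion after
        designs = [cd.MutantDesign("m1", substitutions=[(2, "C", "G")])]
        out = cd.apply_insertion_rule(designs, aln)
        assert out[0].insertions == [(2, "W")]

    def test_unflanked_insertion_never_attached(self):
        aln = cols_from("AC-DE", "ACWDE")  # flanks identical
        designs = [cd.MutantDesign("m1", substitutions=[(5, "E", "G")])]
        out = cd.apply_insertion_rule(designs, aln)
        assert out[0].insertions == []

    def test_insertion_flanked_by_two_designs_attached_to_both(self, caplog):
        import logging
        # subs at A-positions 2 (C->G) and 3 (D->Y) flank the insertion
        aln = cols_from("AC-DE", "AGWYE")
        designs = [cd.MutantDesign("m1", substitutions=[(2, "C", "G")]),
                   cd.MutantDesign("m2", substitutions=[(3, "D", "Y")])]
        with caplog.at_level(logging.WARNING):
            out = cd.apply_insertion_rule(designs, aln)
        assert out[0].insertions == [(2, "W")]
        assert out[1].insertions == [(2, "W")]
        assert "attached to all" in caplog.text

    def test_multi_residue_insertion_run(self):
        aln = cols_from("AC--DE", "AGWWDE")
        designs = [cd.MutantDesign("m1", substitutions=[(2, "C", "G")])]
        out = cd.apply_insertion_rule(designs, aln)
        assert out[0].insertions == [(2, "WW")]


class TestCombineDesigns:
    def test_best_mutant_combination_has_three_substitutions(self):
        mut9 = cd.MutantDesign("mut#9", substitutions=[(272, "V", "A"),
                                                       (273, "H", "G")])
        mut21 = cd.MutantDesign("mut#21", substitutions=[(220, "A", "T")])
        combined = cd.combine_designs(mut9, mut21)
        assert combined.name == "mut9/21"
        assert len(combined.substitutions) == 3
        assert combined.mutation_strings() == ["A220T", "V272A", "H273G"]

    def test_idempotence(self):
        m = cd.MutantDesign("mut#9", substitutions=[(272, "V", "A")])
        c = cd.combine_designs(m, m)
        assert c.substitutions == m.substitutions
        assert c.name == m.name

    def test_conflicting_targets_rejected(self):
        a = cd.MutantDesign("a", substitutions=[(10, "A", "G")])
        b = cd.MutantDesign("b", substitutions=[(10, "A", "S")])
        with pytest.raises(ValueError, match="conflict"):
            cd.combine_designs(a, b)


class TestDesignOutputs:
    def test_candidates_tsv_and_designs_json_round_trip(self):
        import json
        rng = np.random.default_rng(2)
        aln, pdb_text, _ = random_alignment_and_structure(rng, 6)
        st = cd.parse_structure(pdb_text)
        dmap = cd.compute_distance_map(st, ["IPM", "NAD"])
        cands = cd.select_shell_sites(aln, dmap, 12.0)
        tsv = cd.candidates_to_tsv(cands, dmap, 12.0)
        assert tsv.startswith("position\tfromAA\ttoAA")
        assert len(tsv.strip().splitlines()) == len(cands) + 1
        designs = cd.group_sites(cands, st, 6.0)
        parsed = json.loads(cd.designs_to_json(designs))
        assert len(parsed) == len(designs)
        for d in parsed:
            assert set(d) == {"name", "substitutions", "insertions", "shell_A"}
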