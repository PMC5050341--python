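"""Alignment/identity against an independent DP oracle, NJ on additive
matrices, Robinson-Foulds (cross-checked with dendropy) and incongruence."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from inteinscan.block_models import AA
from inteinscan.intein_caller import scan_protein
from inteinscan.sequence_io import SequenceRecord
from inteinscan.synthetic_data import build_intein, plant_intein, simulate_extein, simulate_hgt
from inteinscan.transfer_analysis import (
    AlignParams,
    IdentityResult,
    PairwiseAlignment,
    TreeTopology,
    detect_incongruence,
    excise_splicing_domain,
    flag_transfer_candidates,
    global_align,
    nj_tree,
    pairwise_identity,
    percent_identity,
    rf_distance,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_score(a, b, open_=11.0, ext=1.0):
    """Independent affine-gap global DP (first gap position costs `open_`,
    each further position `ext`)."""
    NEG = -1e9
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (deletion from a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_ - (i - 1) * ext
    for j in range(1, m + 1):
        Y[0, j] = -open_ - (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - open_, X[i - 1, j] - ext, Y[i - 1, j] - open_)
            Y[i, j] = max(M[i, j - 1] - open_, Y[i, j - 1] - ext, X[i, j - 1] - open_)
    return max(M[n, m], X[n, m], Y[n, m])


class TestGlobalAlign:
    def test_identical_sequences_no_gaps(self, rng):
        seq = "".join(AA[i] for i in rng.integers(0, 20, 30))
        aln = global_align(seq, seq)
        assert "-" not in aln.a and "-" not in aln.b
        assert percent_identity(aln)[0] == 100.0

    def test_single_deletion_column(self):
        aln = global_align("ACDEFG", "ACEFG")
        gapless = sum(1 for x, y in zip(aln.a, aln.b) if x == y and x != "-")
        assert aln.a.count("-") + aln.b.count("-") == 1
        assert gapless == 5

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACD")

    @pytest.mark.parametrize("case", range(50))
    def test_score_matches_independent_dp(self, case):
        rng = np.random.default_rng(7000 + case)
        a = "".join(AA[i] for i in rng.integers(0, 20, int(rng.integers(10, 60))))
        b = "".join(AA[i] for i in rng.integers(0, 20, int(rng.integers(10, 60))))
        aln = global_align(a, b)
        assert aln.score == pytest.approx(gotoh_score(a, b), abs=1e-6)


class TestPercentIdentity:
    def test_hand_arithmetic(self):
        aln = PairwiseAlignment(a="ABCDEFGHIJ", b="ABCDEZZZZZ", score=0.0)
        assert percent_identity(aln)[0] == 50.0

    def test_flank_pair_arithmetic(self):
        """40-nucleotide flank windows differing at 10 positions give 75%."""
        rng = np.random.default_rng(1)
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        other = list(flank)
        for pos in rng.choice(40, size=10, replace=False):
            other[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[pos]]
        aln = PairwiseAlignment(a=flank, b="".join(other), score=0.0)
        assert percent_identity(aln)[0] == 75.0

    def test_symmetry(self, rng):
        a = "".join(AA[i] for i in rng.integers(0, 20, 40))
        b = "".join(AA[i] for i in rng.integers(0, 20, 45))
        r1 = pairwise_identity("a", a, "b", b)
        r2 = pairwise_identity("b", b, "a", a)
        assert r1.percent_identity == pytest.approx(r2.percent_identity)

    def test_overhangs_excluded(self):
        aln = PairwiseAlignment(a="--ABCD", b="XYABCD", score=0.0)
        pid, cols = percent_identity(aln)
        assert cols == 4 and pid == 100.0


class TestExciseSplicingDomain:
    def test_hen_removed_linker_math(self, splicing_models, references, rng):
        host = simulate_extein(references["RecB"], 0.0, rng, frozen={0, 125})
        intein, layout = build_intein("class1", True, "H", 0.0, rng)
        precursor, truth = plant_intein(host, 124, intein)
        prot = SequenceRecord("p", "", precursor.seq, "protein")
        call = scan_protein(prot, splicing_models)[0]
        spliced_domains = excise_splicing_domain(call)
        expected_len = call.length - (layout["f_start"] - layout["b_end"])
        assert len(spliced_domains) == expected_len

    def test_requires_blocks(self, splicing_models, references, rng):
        host = simulate_extein(references["RecB"], 0.0, rng, frozen={0, 125})
        intein, _ = build_intein("class1", False, "H", 0.0, rng)
        precursor, _ = plant_intein(host, 124, intein)
        call = scan_protein(SequenceRecord("p", "", precursor.seq, "protein"),
                            splicing_models)[0]
        del call.blocks["F"]
        with pytest.raises(ValueError):
            excise_splicing_domain(call)

    def test_sibling_identity_rises_after_hen_removal(self, splicing_models,
                                                      references):
        """Two inteins with identical splicing domains but independently random
        HEN regions look more alike once the HEN region is excised."""
        rng = np.random.default_rng(21)
        host = simulate_extein(references["RecB"], 0.0, rng, frozen={0, 125})
        intein, layout = build_intein("class1", True, "H", 0.0, rng)
        # sibling: same splicing domains, fresh random B-F insert of equal length
        insert_len = layout["f_start"] - layout["b_end"]
        fresh = "".join(AA[i] for i in rng.integers(0, 20, insert_len))
        sibling_seq = (intein.seq[:layout["b_end"]] + fresh
                       + intein.seq[layout["f_start"]:])
        calls = []
        for name, iseq in (("p1", intein.seq), ("p2", sibling_seq)):
            rec = SequenceRecord(name + "_i", "", iseq, "protein")
            precursor, _ = plant_intein(host, 124, rec)
            calls.append(scan_protein(
                SequenceRecord(name, "", precursor.seq, "protein"),
                splicing_models)[0])
        full = pairwise_identity("a", calls[0].sequence, "b", calls[1].sequence)
        dom = pairwise_identity("a", excise_splicing_domain(calls[0]),
                                "b", excise_splicing_domain(calls[1]),
                                mode="splicing_only")
        assert dom.percent_identity >= full.percent_identity
        assert dom.percent_identity == 100.0


class TestTransferFlags:
    def _res(self, pid):
        return IdentityResult("a", "b", "full", pid, 200)

    def test_reported_identity_thresholding(self):
        flags = flag_transfer_candidates([self._res(39.9)], threshold=35.0)
        assert flags[0].flagged is True
        flags = flag_transfer_candidates([self._res(30.8)], threshold=35.0)
        assert flags[0].flagged is False

    def test_empty_input(self):
        assert flag_transfer_candidates([]) == []

    def test_mixed_modes_rejected(self):
        with pytest.raises(ValueError):
            flag_transfer_candidates([
                IdentityResult("a", "b", "full", 50, 10),
                IdentityResult("a", "c", "splicing_only", 50, 10)])

    def test_threshold_monotonicity(self):
        results = [IdentityResult("a", str(i), "full", float(i), 100)
                    for i in range(20, 70, 5)]
        counts = [sum(f.flagged for f in flag_transfer_candidates(results, t))
                  for t in (25.0, 35.0, 45.0)]
        assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# trees

def random_additive_tree(rng, n):
    """Random unrooted binary topology with branch lengths; returns (newick,
    taxa, leaf-to-leaf distance matrix)."""
    taxa = [f"t{i}" for i in range(n)]
    nodes = {t: (t, 0.0) for t in taxa}  # name -> (newick, dummy)
    dist = {(a, b): 0.0 for a, b in itertools.permutations(taxa, 2)}
    members = {t: [t] for t in taxa}
    height = {t: {t: 0.0} for t in taxa}  # node -> leaf -> distance to node
    alive = list(taxa)
    while len(alive) > 2:
        i, j = sorted(rng.choice(len(alive), size=2, replace=False))
        a, b = alive[i], alive[j]
        la, lb = float(rng.uniform(0.5, 2.0)), float(rng.uniform(0.5, 2.0))
        new = f"({nodes[a][0]}:{la},{nodes[b][0]}:{lb})"
        name = a + b
        nodes[name] = (new, 0.0)
        height[name] = {}
        for leaf, d in height[a].items():
            height[name][leaf] = d + la
        for leaf, d in height[b].items():
            height[name][leaf] = d + lb
        for x in height[a]:
            for y in height[b]:
                dist[(x, y)] = dist[(y, x)] = height[a][x] + la + height[b][y] + lb
        members[name] = members[a] + members[b]
        alive = [x for x in alive if x not in (a, b)] + [name]
    a, b = alive
    lab = float(rng.uniform(0.5, 2.0))
    for x in height[a]:
        for y in height[b]:
            dist[(x, y)] = dist[(y, x)] = height[a][x] + height[b][y] + lab
    newick = f"({nodes[a][0]},{nodes[b][0]}:{lab});"
    dm = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for (x, y), d in dist.items():
        dm.loc[x, y] = d
    return newick, taxa, dm


class TestNjTree:
    def test_three_taxa_unique_topology(self):
        dm = pd.DataFrame([[0, 2, 3], [2, 0, 3], [3, 3, 0]],
                          index=list("abc"), columns=list("abc"), dtype=float)
        tree = nj_tree(dm)
        assert tree.taxa == frozenset("abc")

    def test_asymmetric_matrix_rejected(self):
        dm = pd.DataFrame([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]],
                          index=list("abc"), columns=list("abc"), dtype=float)
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_four_taxon_additive_split_recovered(self):
        # ((A,B),(C,D)) with internal edge 3
        taxa = list("ABCD")
        dm = pd.DataFrame(0.0, index=taxa, columns=taxa)
        d = {("A", "B"): 2, ("C", "D"): 2, ("A", "C"): 8, ("A", "D"): 8,
             ("B", "C"): 8, ("B", "D"): 8}
        for (x, y), v in d.items():
            dm.loc[x, y] = dm.loc[y, x] = float(v)
        tree = nj_tree(dm)
        truth = TreeTopology(newick="((A:1,B:1):3,(C:1,D:1):3);",
                             taxa=frozenset(taxa))
        assert rf_distance(tree, truth) == 0

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_additive_matrices_recover_topology(self, n):
        for rep in range(6):
            rng = np.random.default_rng(100 * n + rep)
            newick, taxa, dm = random_additive_tree(rng, n)
            truth = TreeTopology(newick=newick, taxa=frozenset(taxa))
            tree = nj_tree(dm)
            assert rf_distance(tree, truth) == 0


class TestRfDistance:
    def test_identical_trees_zero(self):
        t = TreeTopology("((a,b),(c,d));", frozenset("abcd"))
        assert rf_distance(t, t) == 0

    def test_two_resolved_four_taxon_topologies(self):
        t1 = TreeTopology("((a,b),(c,d));", frozenset("abcd"))
        t2 = TreeTopology("((a,c),(b,d));", frozenset("abcd"))
        assert rf_distance(t1, t2) == 2

    def test_star_vs_resolved(self):
        star = TreeTopology("(a,b,c,d);", frozenset("abcd"))
        resolved = TreeTopology("((a,b),(c,d));", frozenset("abcd"))
        assert rf_distance(star, resolved) == 1

    def test_taxon_mismatch_rejected(self):
        t1 = TreeTopology("((a,b),(c,d));", frozenset("abcd"))
        t2 = TreeTopology("((a,b),(c,e));", frozenset("abce"))
        with pytest.raises(ValueError):
            rf_distance(t1, t2)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dendropy(self, seed):
        import dendropy

        rng = np.random.default_rng(9000 + seed)
        n = int(rng.integers(5, 9))
        nw1, taxa, _ = random_additive_tree(rng, n)
        nw2, _, _ = random_additive_tree(np.random.default_rng(seed), n)
        t1 = TreeTopology(nw1, frozenset(taxa))
        t2 = TreeTopology(nw2, frozenset(taxa))
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=nw1, schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=nw2, schema="newick", taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert rf_distance(t1, t2) == expected


class TestIncongruence:
    def test_identical_topologies_congruent(self):
        t = TreeTopology("((a,b),(c,d),(e,f));", frozenset("abcdef"))
        report = detect_incongruence(t, t, {"a", "b"})
        assert report.status == "congruent"

    def test_focal_in_neither_tree_no_signal(self):
        t1 = TreeTopology("((a,c),(b,e),(d,f));", frozenset("abcdef"))
        t2 = TreeTopology("((a,d),(b,f),(c,e));", frozenset("abcdef"))
        assert detect_incongruence(t1, t2, {"a", "b"}).status == "no_signal"

    def test_single_focal_taxon_rejected(self):
        t = TreeTopology("((a,b),(c,d));", frozenset("abcd"))
        with pytest.raises(ValueError):
            detect_incongruence(t, t, {"a"})

    def test_simulated_transfer_is_incongruent(self):
        from inteinscan.pipeline import detect_hgt

        scenario = simulate_hgt(seed=77, events=[("T2", "T7", 0.05)])
        det = detect_hgt(scenario.intein_seqs, scenario.extein_seqs)
        assert det.detected
        assert any(set(p) == {"T2", "T7"} for p in det.incongruent_pairs)
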