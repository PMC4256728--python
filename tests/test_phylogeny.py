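from itertools import combinations

import numpy as np
import pytest

from repeatscape import (
    DistanceMatrix,
    assign_clades,
    bootstrap_support,
    build_nj_tree,
    pairwise_distances,
    progressive_align,
    select_rt_representative,
)
from repeatscape.clustering import Contig
from repeatscape._dna import random_dna, revcomp


# ---- tree-simulation helpers (the additive-matrix oracle) -------------------


def random_topology(n_taxa, rng):
    """Random unrooted binary tree as an edge list with branch lengths."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    edges = {}  # (u, v) -> length
    nxt = [n_taxa]

    def new_node():
        nxt[0] += 1
        return f"n{nxt[0]}"

    center = "n0"
    for t in taxa[:3]:
        edges[(center, t)] = float(rng.uniform(0.1, 2.0))
    for t in taxa[3:]:
        u, v = list(edges)[rng.integers(0, len(edges))]
        length = edges.pop((u, v))
        mid = new_node()
        split = float(rng.uniform(0.2, 0.8))
        edges[(u, mid)] = length * split
        edges[(mid, v)] = length * (1 - split)
        edges[(mid, t)] = float(rng.uniform(0.1, 2.0))
    return taxa, edges


def path_distances(taxa, edges):
    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    n = len(taxa)
    d = np.zeros((n, n))
    for i, src in enumerate(taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nb, w in adj[cur]:
                if nb not in dist:
                    dist[nb] = dist[cur] + w
                    stack.append(nb)
        for j, dst in enumerate(taxa):
            d[i, j] = dist[dst]
    return d


def true_bipartitions(taxa, edges):
    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    anchor = min(taxa)
    out = set()
    for (u, v), w in edges.items():
        # leaves on v's side when edge (u, v) is cut
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            cur = stack.pop()
            if cur in taxa:
                side.add(cur)
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if 1 < len(side) < len(taxa) - 1:
            canon = frozenset(side if anchor not in side else set(taxa) - side)
            out.add(canon)
    return out


def all_topologies(taxa):
    """Every unrooted binary topology (as edge-set skeletons) over taxa."""
    trees = [{("x0", taxa[0]), ("x0", taxa[1]), ("x0", taxa[2])}]
    for k, t in enumerate(taxa[3:], start=1):
        new = []
        for edges in trees:
            for u, v in edges:
                mid = f"y{k}{len(new)}"
                grown = set(edges)
                grown.remove((u, v))
                grown |= {(u, mid), (mid, v), (mid, t)}
                new.append(grown)
        trees = new
    return trees


def least_squares_fit(taxa, topology, d):
    """Nonnegative LS branch lengths for a fixed topology; returns SSE."""
    from scipy.optimize import nnls

    edges = sorted(topology)
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def path(a, b):
        prev = {a: None}
        stack = [a]
        while stack:
            cur = stack.pop()
            if cur == b:
                break
            for nb in adj[cur]:
                if nb not in prev:
                    prev[nb] = cur
                    stack.append(nb)
        out = []
        cur = b
        while prev[cur] is not None:
            out.append(tuple(sorted((cur, prev[cur]))))
            cur = prev[cur]
        return out

    pairs = list(combinations(range(len(taxa)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([d[i, j] for i, j in pairs])
    index = {tuple(sorted(e)): k for k, e in enumerate(edges)}
    for row, (i, j) in enumerate(pairs):
        for e in path(taxa[i], taxa[j]):
            A[row, index[e]] = 1.0
    _, rnorm = nnls(A, y)
    return rnorm**2


# ---- tests ------------------------------------------------------------------


class TestDistances:
    def test_identical_sequences_zero(self):
        aln = [("a", "MKV"), ("b", "MKV"), ("c", "MKV")]
        assert (pairwise_distances(aln).d == 0).all()

    def test_half_different(self):
        aln = [("a", "AC"), ("b", "AD"), ("c", "AC")]
        dm = pairwise_distances(aln)
        assert dm.d[0, 1] == 0.5

    def test_gap_columns_excluded_pairwise(self):
        aln = [("a", "A-CD"), ("b", "ABCD"), ("c", "AB-D")]
        dm = pairwise_distances(aln)
        assert dm.d[0, 2] == 0.0  # only columns 1 and 4 compare... none differ

    def test_matches_brute_force_column_scan(self):
        rng = np.random.default_rng(41)
        alpha = "ACDEFGHIKL-"
        aln = [
            (f"s{i}", "".join(rng.choice(list(alpha), size=60))) for i in range(5)
        ]
        try:
            dm = pairwise_distances(aln)
        except ValueError:
            return
        for i, j in combinations(range(5), 2):
            cols = [
                (a, b)
                for a, b in zip(aln[i][1], aln[j][1])
                if a != "-" and b != "-"
            ]
            expect = sum(a != b for a, b in cols) / len(cols)
            assert dm.d[i, j] == pytest.approx(expect)

    def test_no_comparable_columns_error(self):
        aln = [("a", "A-"), ("b", "-B"), ("c", "AB")]
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distances(aln)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float)
        tree = build_nj_tree(DistanceMatrix(["a", "b", "c"], d))
        lengths = {
            child.name: length for child, length in tree.root.children
        }
        assert lengths["a"] == pytest.approx((5 + 9 - 8) / 2)
        assert lengths["b"] == pytest.approx((5 + 8 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 8 - 5) / 2)

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_additive_matrices_recover_topology_and_lengths(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        for rep in range(12):
            taxa, edges = random_topology(n_taxa, rng)
            d = path_distances(taxa, edges)
            tree = build_nj_tree(DistanceMatrix(list(taxa), d))
            assert set(tree.bipartitions()) == true_bipartitions(taxa, edges)
            # additive input: NJ reproduces the generating path metric exactly
            rebuilt = _tree_path_metric(tree)
            for i, j in combinations(range(len(taxa)), 2):
                assert rebuilt[(taxa[i], taxa[j])] == pytest.approx(d[i, j])

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_agrees_with_brute_force_least_squares(self, n_taxa):
        rng = np.random.default_rng(200 + n_taxa)
        taxa, edges = random_topology(n_taxa, rng)
        d = path_distances(taxa, edges)
        sses = [least_squares_fit(taxa, t, d) for t in all_topologies(taxa)]
        best = int(np.argmin(sses))
        assert sses[best] == pytest.approx(0.0, abs=1e-12)
        # NJ picks the same (zero-residual) topology
        tree = build_nj_tree(DistanceMatrix(list(taxa), d))
        skeleton = all_topologies(taxa)[best]
        want = true_bipartitions(
            taxa, {e: 1.0 for e in skeleton}
        )
        assert set(tree.bipartitions()) == want

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(7)
        taxa, edges = random_topology(6, rng)
        d = path_distances(taxa, edges)
        tree1 = build_nj_tree(DistanceMatrix(list(taxa), d))
        perm = list(rng.permutation(len(taxa)))
        tree2 = build_nj_tree(
            DistanceMatrix([taxa[i] for i in perm], d[np.ix_(perm, perm)])
        )
        assert set(tree1.bipartitions()) == set(tree2.bipartitions())

    def test_agrees_with_skbio(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj

        rng = np.random.default_rng(8)
        taxa, edges = random_topology(7, rng)
        d = path_distances(taxa, edges)
        d = (d + d.T) / 2  # exact symmetry despite float summation order
        mine = build_nj_tree(DistanceMatrix(list(taxa), d))
        sk = nj(SkDM(d, ids=taxa))
        anchor = min(taxa)
        sk_bps = set()
        for node in sk.non_tips():
            side = {t.name for t in node.tips()}
            if 1 < len(side) < len(taxa) - 1:
                sk_bps.add(
                    frozenset(side if anchor not in side else set(taxa) - side)
                )
        assert set(mine.bipartitions()) == sk_bps

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], d)


def _tree_path_metric(tree):
    adj = {}
    counter = [0]
    leaf_of = {}

    def walk(node):
        nid = counter[0]
        counter[0] += 1
        adj.setdefault(nid, [])
        if node.name:
            leaf_of[node.name] = nid
        for child, length in node.children:
            cid = walk(child)
            adj[nid].append((cid, length))
            adj[cid].append((nid, length))
        return nid

    walk(tree.root)
    out = {}
    for a in tree.taxa:
        dist = {leaf_of[a]: 0.0}
        stack = [leaf_of[a]]
        while stack:
            cur = stack.pop()
            for nb, w in adj[cur]:
                if nb not in dist:
                    dist[nb] = dist[cur] + w
                    stack.append(nb)
        for b in tree.taxa:
            out[(a, b)] = dist[leaf_of[b]]
    return out


class TestBootstrap:
    def _clade_alignment(self, n_cols=200, seed=5):
        """Two clearly separated clades of 3 sequences each."""
        rng = np.random.default_rng(seed)
        alpha = list("ACDEFGHIKLMNPQRSTVWY")
        base1 = rng.choice(alpha, size=n_cols)
        base2 = base1.copy()
        flip = rng.random(n_cols) < 0.5
        base2[flip] = rng.choice(alpha, size=int(flip.sum()))
        aln = []
        for k, base in (("a", base1), ("b", base2)):
            for i in range(3):
                seq = base.copy()
                noise = rng.random(n_cols) < 0.01
                seq[noise] = rng.choice(alpha, size=int(noise.sum()))
                aln.append((f"{k}{i}", "".join(seq)))
        return aln

    def test_identical_columns_give_full_support(self):
        # every column is the same, so each replicate reproduces the exact
        # distance matrix and therefore the exact point tree
        aln = [("a", "A" * 40), ("b", "C" * 40), ("c", "D" * 40), ("d", "E" * 40)]
        tree = bootstrap_support(aln, n_replicates=25, seed=0)
        assert all(v == 100.0 for v in tree.supports.values())

    def test_separated_clades_strongly_supported(self):
        aln = self._clade_alignment()
        tree = bootstrap_support(aln, n_replicates=100, seed=3)
        split = frozenset({"b0", "b1", "b2"})
        assert split in tree.supports
        assert tree.supports[split] >= 95

    def test_zero_replicates_returns_point_tree(self):
        aln = self._clade_alignment(n_cols=50)
        tree = bootstrap_support(aln, n_replicates=0, seed=0)
        assert tree.supports == {}

    def test_reproducible_under_seed(self):
        aln = self._clade_alignment()
        t1 = bootstrap_support(aln, 50, seed=11)
        t2 = bootstrap_support(aln, 50, seed=11)
        assert t1.supports == t2.supports


class TestRtSelection:
    def test_exact_rt_copy_selected_and_extracted(self):
        rng = np.random.default_rng(70)
        # a peptide encoded into DNA, embedded in a contig
        ref_pep = "MGLTDKQVLELAWENIRQAGGKYVPRGVNHLVSK"
        codons = {
            "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
            "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
            "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
            "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
        }
        dna = "".join(codons[a] for a in ref_pep)
        contig_seq = random_dna(rng, 90) + dna + random_dna(rng, 90)
        good = Contig("CL1c1", contig_seq, 10)
        satellite = Contig("CL2c1", "ACGT" * 60, 8)
        reps, dropped = select_rt_representative(
            {"CL1": [good], "CL2": [satellite]}, [("RT_ref", ref_pep)]
        )
        assert dropped == ["CL2"]
        assert reps["CL1"].contig_id == "CL1c1"
        assert ref_pep in reps["CL1"].rt_peptide

    def test_reverse_strand_rt_found(self):
        ref_pep = "MGLTDKQVLELAWENIRQAGGKYVPRG"
        codons = {a: c for a, c in zip(
            "ACDEFGHIKLMNPQRSTVWY",
            ["GCT", "TGT", "GAT", "GAA", "TTT", "GGT", "CAT", "ATT", "AAA",
             "CTT", "ATG", "AAT", "CCT", "CAA", "CGT", "TCT", "ACT", "GTT",
             "TGG", "TAT"],
        )}
        dna = "".join(codons[a] for a in ref_pep)
        contig = Contig("c", revcomp("AC" + dna + "GT"), 5)
        reps, dropped = select_rt_representative(
            {"F": [contig]}, [("RT_ref", ref_pep)]
        )
        assert "F" in reps

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            select_rt_representative({}, [])


class TestAlignmentAndClades:
    def test_progressive_alignment_of_identical_seqs_is_gapless(self):
        seqs = [(f"s{i}", "MKVLITGGAGFIG") for i in range(4)]
        aln = progressive_align(seqs)
        assert all(s == "MKVLITGGAGFIG" for _, s in aln)

    def test_indel_placed_as_gap(self):
        seqs = [
            ("a", "MKVLITGGAGFIG"),
            ("b", "MKVLITGGAGFIG"),
            ("c", "MKVLITGGFIG"),  # two residues missing
        ]
        aln = dict(progressive_align(seqs))
        width = len(aln["a"])
        assert all(len(s) == width for s in aln.values())
        assert aln["c"].count("-") == 2

    def test_clade_assignment_follows_nearest_reference(self):
        d = np.array(
            [
                [0.0, 0.1, 0.8, 0.8],
                [0.1, 0.0, 0.8, 0.8],
                [0.8, 0.8, 0.0, 0.1],
                [0.8, 0.8, 0.1, 0.0],
            ]
        )
        tree = build_nj_tree(
            DistanceMatrix(["fam1", "refA", "fam2", "refB"], d)
        )
        clades = assign_clades(tree, {"refA": "Tekay", "refB": "CRM"})
        assert clades == {"fam1": "Tekay", "fam2": "CRM"}
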