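"""Retroelement phylogenetics from reverse-transcriptase (RT) domains.

LTR retrotransposon families are classified into clades (SIRE1/Maximus,
Tekay, CRM, Tat, ...) by the phylogeny of their RT coding domain. For each
family, the contig with the strongest six-frame-translated similarity to a
reference RT peptide set represents the family; the extracted peptides are
progressively aligned, pairwise p-distances computed with pairwise gap
deletion, and an unrooted neighbor-joining tree built, with bipartition
support from bootstrap resampling of alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from ._dna import revcomp


@dataclass
class RtRepresentative:
    """The contig chosen to stand for one family in the phylogeny."""

    family_id: str
    contig_id: str
    rt_peptide: str
    reference_hit_score: float


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances over an ordered taxon list."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")


class TreeNode:
    """Minimal unrooted-tree node (root is an arbitrary trifurcation)."""

    __slots__ = ("name", "children", "min_leaf")

    def __init__(self, name: str | None = None):
        self.name = name
        self.children: list[tuple[TreeNode, float]] = []
        self.min_leaf = name or ""

    def add(self, child: "TreeNode", length: float) -> None:
        self.children.append((child, length))
        self.min_leaf = min(filter(None, (self.min_leaf, child.min_leaf)), default="")

    def leaves(self) -> list[str]:
        if self.name is not None:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """An unrooted tree with optional bootstrap supports per bipartition.

    Bipartitions are canonicalized as the leaf subset not containing the
    alphabetically first taxon, which makes trees comparable regardless of
    where the trifurcating root happens to sit.
    """

    root: TreeNode
    taxa: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)

    def bipartitions(self) -> dict[frozenset, float]:
        """Internal-edge bipartitions -> branch length."""
        anchor = min(self.taxa)
        full = set(self.taxa)
        out: dict[frozenset, float] = {}

        def walk(node: TreeNode) -> set[str]:
            below: set[str] = set()
            for child, length in node.children:
                sub = walk(child)
                if 1 < len(sub) < len(full) - 1:
                    side = sub if anchor not in sub else full - sub
                    out[frozenset(side)] = length
                below |= sub
            if node.name is not None:
                below.add(node.name)
            return below

        walk(self.root)
        return out

    def newick(self, with_support: bool = False) -> str:
        anchor = min(self.taxa)
        full = set(self.taxa)

        def fmt(node: TreeNode) -> str:
            if node.name is not None:
                return node.name
            inner = ",".join(
                f"{fmt(child)}:{length:.6f}" for child, length in node.children
            )
            label = ""
            if with_support:
                sub = set(node.leaves())
                side = sub if anchor not in sub else full - sub
                sup = self.supports.get(frozenset(side))
                if sup is not None:
                    label = f"{sup:.0f}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"


# --- RT representative selection -------------------------------------------

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _peptide_aligner(local: bool = True) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local" if local else "global"
    return aligner


def six_frame_translations(seq: str) -> list[str]:
    """All six conceptual translations; stops become X for scoring."""
    out = []
    for s in (seq, revcomp(seq)):
        for frame in range(3):
            sub = s[frame : frame + 3 * ((len(s) - frame) // 3)]
            if len(sub) >= 3:
                pep = str(Seq(sub).translate())
                out.append("".join(c if c in _STANDARD_AA else "X" for c in pep))
    return out


def select_rt_representative(
    family_contigs: dict[str, list],
    rt_references: list[tuple[str, str]],
    min_score: float = 60.0,
) -> tuple[dict[str, RtRepresentative], list[str]]:
    """Pick each family's most RT-conserved contig and extract its peptide.

    Each contig is translated in six frames and locally aligned to every
    reference RT peptide; the family's top-scoring contig wins and the
    aligned peptide segment becomes the family's ``rt_peptide``. Families
    whose best score stays below ``min_score`` carry no usable RT signal
    (satellites, short fragments) and are dropped from the phylogeny.

    Returns (representatives by family, dropped family ids).
    """
    if not rt_references:
        raise ValueError("RT reference set is empty")
    aligner = _peptide_aligner(local=True)
    chosen: dict[str, RtRepresentative] = {}
    dropped: list[str] = []
    for family_id, contigs in family_contigs.items():
        best: RtRepresentative | None = None
        for contig in contigs:
            for pep in six_frame_translations(contig.sequence):
                if len(pep) < 10:
                    continue
                for _, ref_pep in rt_references:
                    alns = aligner.align(pep, ref_pep)
                    score = alns.score
                    if best is not None and score <= best.reference_hit_score:
                        continue
                    aln = alns[0]
                    q0, q1 = aln.aligned[0][0][0], aln.aligned[0][-1][1]
                    best = RtRepresentative(
                        family_id=family_id,
                        contig_id=contig.contig_id,
                        rt_peptide=pep[q0:q1],
                        reference_hit_score=float(score),
                    )
        if best is None or best.reference_hit_score < min_score:
            dropped.append(family_id)
        else:
            chosen[family_id] = best
    return chosen, dropped


# --- multiple alignment ------------------------------------------------------


def progressive_align(seqs: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Deterministic center-star progressive peptide alignment.

    The center is the sequence with the greatest summed pairwise score;
    the rest join in descending score-to-center order under the classic
    once-a-gap-always-a-gap merge. Adequate for the short, conserved RT
    segments this pipeline aligns; not a general-purpose aligner.
    """
    if len(seqs) < 2:
        return list(seqs)
    aligner = _peptide_aligner(local=False)
    names = [n for n, _ in seqs]
    raw = {n: s for n, s in seqs}
    score_sum = {n: 0.0 for n in names}
    pair_score = {}
    for a, b in combinations(names, 2):
        s = aligner.align(raw[a], raw[b]).score
        pair_score[(a, b)] = pair_score[(b, a)] = s
        score_sum[a] += s
        score_sum[b] += s
    center = max(names, key=lambda n: (score_sum[n], n))
    order = sorted(
        (n for n in names if n != center),
        key=lambda n: (-pair_score[(center, n)], n),
    )

    msa: dict[str, str] = {center: raw[center]}
    center_aln = raw[center]  # the center row with accumulated gaps
    for name in order:
        aln = aligner.align(raw[center], raw[name])[0]
        a_center, a_new = str(aln[0]), str(aln[1])
        # merge a_center (gaps vs new seq) with center_aln (gaps vs MSA)
        merged_rows = {n: [] for n in msa}
        merged_new: list[str] = []
        i = j = 0
        while i < len(center_aln) or j < len(a_center):
            ci = center_aln[i] if i < len(center_aln) else None
            cj = a_center[j] if j < len(a_center) else None
            if ci == "-" and cj != "-":
                for n in msa:
                    merged_rows[n].append(msa[n][i])
                merged_new.append("-")
                i += 1
            elif cj == "-" and (ci != "-" or ci is None):
                for n in msa:
                    merged_rows[n].append("-")
                merged_new.append(a_new[j])
                j += 1
            else:  # both consume a center residue (or both gap columns)
                for n in msa:
                    merged_rows[n].append(msa[n][i] if i < len(msa[n]) else "-")
                merged_new.append(a_new[j] if j < len(a_new) else "-")
                i += 1
                j += 1
        msa = {n: "".join(r) for n, r in merged_rows.items()}
        msa[name] = "".join(merged_new)
        center_aln = msa[center]
    width = max(len(s) for s in msa.values())
    return [(n, msa[n].ljust(width, "-")) for n in names]


# --- distances and neighbor joining -----------------------------------------


def pairwise_distances(aligned: list[tuple[str, str]]) -> DistanceMatrix:
    """p-distances on a multiple alignment with pairwise gap deletion.

    d(i, j) = differing columns / columns where both sequences have a
    residue. A pair with no comparable columns is an error.
    """
    if len(aligned) < 3:
        raise ValueError("need >= 3 aligned sequences")
    names = [n for n, _ in aligned]
    seqs = [s for _, s in aligned]
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("sequences are not aligned to a common length")
    n = len(names)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        comparable = differ = 0
        for a, b in zip(seqs[i], seqs[j]):
            if a != "-" and b != "-":
                comparable += 1
                if a != b:
                    differ += 1
        if comparable == 0:
            raise ValueError(f"no comparable columns for {names[i]} vs {names[j]}")
        d[i, j] = d[j, i] = differ / comparable
    return DistanceMatrix(taxa=list(names), d=d)


def build_nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Classical Saitou-Nei neighbor joining.

    At each step the pair minimizing Q(i, j) = (n - 2) d(i, j) - r_i - r_j
    is joined, with the standard branch-length split
    l_i = d(i, j) / 2 + (r_i - r_j) / (2 (n - 2)) and reduction
    d(u, k) = (d(i, k) + d(j, k) - d(i, j)) / 2. Q-ties break on the
    smallest (minimum descendant leaf) label pair, so the result does not
    depend on input order; negative branch lengths are clamped to 0.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    nodes: dict[int, TreeNode] = {i: TreeNode(t) for i, t in enumerate(dm.taxa)}
    d: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(n), 2):
        d[(i, j)] = d[(j, i)] = float(dm.d[i, j])
    active = list(range(n))
    next_id = n

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[(i, k)] for k in active if k != i) for i in active}
        best = None
        for i, j in combinations(active, 2):
            q = (m - 2) * d[(i, j)] - r[i] - r[j]
            key = tuple(sorted((nodes[i].min_leaf, nodes[j].min_leaf)))
            cand = (q, key, i, j)
            if best is None or cand[:2] < best[:2]:
                best = cand
        _, _, i, j = best
        li = d[(i, j)] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[(i, j)] - li
        parent = TreeNode()
        parent.add(nodes[i], max(0.0, li))
        parent.add(nodes[j], max(0.0, lj))
        for k in active:
            if k in (i, j):
                continue
            d[(next_id, k)] = d[(k, next_id)] = (
                d[(i, k)] + d[(j, k)] - d[(i, j)]
            ) / 2
        nodes[next_id] = parent
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    root = TreeNode()
    li = (d[(i, j)] + d[(i, k)] - d[(j, k)]) / 2
    lj = (d[(i, j)] + d[(j, k)] - d[(i, k)]) / 2
    lk = (d[(i, k)] + d[(j, k)] - d[(i, j)]) / 2
    for idx, length in ((i, li), (j, lj), (k, lk)):
        root.add(nodes[idx], max(0.0, length))
    return PhyloTree(root=root, taxa=sorted(dm.taxa))


def bootstrap_support(
    aligned: list[tuple[str, str]], n_replicates: int = 100, seed: int = 0
) -> PhyloTree:
    """NJ point tree with bootstrap supports on its internal bipartitions.

    Alignment columns are resampled with replacement per replicate; each
    replicate's p-distance NJ tree is scanned for the point tree's
    bipartitions, and support is the percentage of replicates containing
    each. A replicate pair left with no comparable columns contributes the
    maximal distance 1 for that pair.
    """
    width = len(aligned[0][1])
    if width < 10:
        raise ValueError("alignment too short to bootstrap (need >= 10 columns)")
    tree = build_nj_tree(pairwise_distances(aligned))
    if n_replicates <= 0:
        return tree
    names = [n for n, _ in aligned]
    mat = np.array([list(s) for _, s in aligned])
    rng = np.random.default_rng(seed)
    target = set(tree.bipartitions())
    hits = {bp: 0 for bp in target}
    n = len(names)
    for _ in range(n_replicates):
        cols = rng.integers(0, width, size=width)
        sub = mat[:, cols]
        d = np.zeros((n, n))
        for i, j in combinations(range(n), 2):
            both = (sub[i] != "-") & (sub[j] != "-")
            comparable = int(both.sum())
            if comparable == 0:
                dist = 1.0
            else:
                dist = float(((sub[i] != sub[j]) & both).sum()) / comparable
            d[i, j] = d[j, i] = dist
        rep = build_nj_tree(DistanceMatrix(taxa=list(names), d=d))
        rep_bps = set(rep.bipartitions())
        for bp in target:
            if bp in rep_bps:
                hits[bp] += 1
    tree.supports = {bp: 100.0 * c / n_replicates for bp, c in hits.items()}
    return tree


def assign_clades(
    tree: PhyloTree, reference_clades: dict[str, str]
) -> dict[str, str]:
    """Clade of each non-reference leaf = clade of its nearest reference leaf.

    Distance is the path length along the tree. ``reference_clades`` maps
    reference leaf names to clade labels.
    """
    adj: dict[int, list[tuple[int, float]]] = {}
    leaf_node: dict[str, int] = {}
    counter = [0]

    def walk(node: TreeNode) -> int:
        nid = counter[0]
        counter[0] += 1
        adj.setdefault(nid, [])
        if node.name is not None:
            leaf_node[node.name] = nid
        for child, length in node.children:
            cid = walk(child)
            adj[nid].append((cid, length))
            adj[cid].append((nid, length))
        return nid

    walk(tree.root)

    import heapq

    out = {}
    for leaf in tree.taxa:
        if leaf in reference_clades:
            continue
        dist = {leaf_node[leaf]: 0.0}
        heap = [(0.0, leaf_node[leaf])]
        best = None
        ref_nodes = {leaf_node[r]: r for r in reference_clades if r in leaf_node}
        while heap:
            cur, nid = heapq.heappop(heap)
            if cur > dist.get(nid, float("inf")):
                continue
            if nid in ref_nodes:
                best = ref_nodes[nid]
                break
            for nb, w in adj[nid]:
                nd = cur + w
                if nd < dist.get(nb, float("inf")):
                    dist[nb] = nd
                    heapq.heappush(heap, (nd, nb))
        out[leaf] = reference_clades[best] if best else "unassigned"
    return out
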