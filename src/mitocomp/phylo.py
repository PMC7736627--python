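"""Concatenated-PCG supermatrix, pairwise distances (p, TN93),
neighbor-joining with bootstrap, Newick I/O, and topology constraint checks.

The tree here is a distance surrogate for likelihood/Bayesian phylogenetics:
its acceptance surface is topology (which clades are bipartitions), not
branch support machinery. NJ is the Saitou–Nei agglomeration with the
Q-criterion, made fully deterministic by breaking Q ties on the
lexicographically smallest (cluster, cluster) label pair; negative branch
lengths are clamped to zero and the clamped deficit recorded. TN93 is the
Tamura–Nei (1993) closed-form distance with empirical base frequencies;
gamma/invariant-site rate corrections are deliberately omitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO

import dendropy
import numpy as np

from .codon_usage import extract_coding_record
from .genome_model import Mitogenome
from .registry import PCG_NAMES
from .divergence import p_distance

# ---------------------------------------------------------------------------
# Supermatrix


@dataclass
class Supermatrix:
    """Concatenated 13-PCG alignment: equal-length rows, one per taxon."""

    taxa: list[str]
    alignment: dict[str, str]
    gene_boundaries: dict[str, tuple[int, int]]  # gene -> [start, end) columns

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.alignment.values())))

    def gene_slice(self, gene: str, taxon: str) -> str:
        lo, hi = self.gene_boundaries[gene]
        return self.alignment[taxon][lo:hi]

    def resample_columns(self, rng: np.random.Generator) -> "Supermatrix":
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        aln = {t: "".join(s[c] for c in cols) for t, s in self.alignment.items()}
        return Supermatrix(list(self.taxa), aln, dict(self.gene_boundaries))


def build_supermatrix(genomes: dict[str, Mitogenome]) -> Supermatrix:
    """Concatenate the 13 PCGs (canonical order, coding strand, incomplete
    stops trimmed) across taxa whose per-gene lengths agree exactly.

    Cross-taxon length differences raise with an instruction to align
    externally; this builder is for congeneric, length-identical gene sets."""
    taxa = list(genomes)
    if not taxa:
        raise ValueError("no genomes given")
    per_gene: dict[str, dict[str, str]] = {}
    for gene in PCG_NAMES:
        seqs = {}
        for taxon, genome in genomes.items():
            if gene not in genome.table:
                raise ValueError(f"genome {taxon!r} is missing PCG {gene}")
            record = extract_coding_record(genome, genome.table[gene])
            seq = "".join(record.codons)
            if len(record.stop_codon) == 3:
                seq += record.stop_codon
            seqs[taxon] = seq
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"{gene}: unequal lengths across taxa {sorted(lengths)}; "
                "align externally before building a supermatrix")
        per_gene[gene] = seqs
    boundaries: dict[str, tuple[int, int]] = {}
    rows = {t: [] for t in taxa}
    col = 0
    for gene in PCG_NAMES:
        width = len(per_gene[gene][taxa[0]])
        boundaries[gene] = (col, col + width)
        col += width
        for t in taxa:
            rows[t].append(per_gene[gene][t])
    return Supermatrix(taxa=taxa,
                       alignment={t: "".join(rows[t]) for t in taxa},
                       gene_boundaries=boundaries)


# ---------------------------------------------------------------------------
# Distances


def tn93_distance(a: str, b: str, strict: bool = False) -> tuple[float, bool]:
    """Tamura–Nei 1993 distance; returns (distance, saturated_flag).

    Uses empirical base frequencies averaged over both sequences and the
    closed form in terms of the purine-transition (P1), pyrimidine-transition
    (P2) and transversion (Q) proportions. When a logarithm argument is
    non-positive (saturation) the p-distance is returned with the flag set,
    or a ValueError is raised if ``strict``."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    ok = set("ACGT")
    pairs = [(x, y) for x, y in zip(a, b) if x in ok and y in ok]
    n = len(pairs)
    if n == 0:
        raise ValueError("zero comparable sites")
    counts = {base: 0 for base in "ACGT"}
    p1 = p2 = q = 0
    for x, y in pairs:
        counts[x] += 1
        counts[y] += 1
        if x != y:
            if {x, y} == {"A", "G"}:
                p1 += 1
            elif {x, y} == {"C", "T"}:
                p2 += 1
            else:
                q += 1
    gA, gC, gG, gT = (counts[base] / (2 * n) for base in "ACGT")
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = p1 / n, p2 / n, q / n
    p_obs = (p1 + p2 + q) / n
    if min(gA, gC, gG, gT) == 0:
        if strict:
            raise ValueError("TN93 undefined: a base frequency is zero")
        return p_obs, True
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1 - P1 / k1 - Q / (2 * gR)
    w2 = 1 - P2 / k2 - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        if strict:
            raise ValueError("TN93 undefined: logarithm argument <= 0 (saturation)")
        return p_obs, True
    d = -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    return d, False


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with named taxa."""

    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if np.isnan(self.matrix).any():
            raise ValueError("NaN distances are forbidden")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0):
            raise ValueError("diagonal must be zero")

    def get(self, t1: str, t2: str) -> float:
        return float(self.matrix[self.taxa.index(t1), self.taxa.index(t2)])


def distance_matrix(sm: Supermatrix, method: str = "tn93") -> DistanceMatrix:
    n = len(sm.taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sm.alignment[sm.taxa[i]], sm.alignment[sm.taxa[j]]
            if method == "tn93":
                d, _sat = tn93_distance(a, b)
            elif method == "p":
                d, _sites = p_distance(a, b)
            else:
                raise ValueError(f"unknown method {method!r}")
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(taxa=list(sm.taxa), matrix=mat)


# ---------------------------------------------------------------------------
# Trees


@dataclass
class _Node:
    children: list[tuple["_Node", float]] = field(default_factory=list)
    taxon: str | None = None
    support: float | None = None

    def leaves(self) -> list[str]:
        if self.taxon is not None:
            return [self.taxon]
        out = []
        for child, _bl in self.children:
            out.extend(child.leaves())
        return out


class PhyloTree:
    """An unrooted tree stored with an arbitrary internal root (the final NJ
    trifurcation); bipartition-based operations are root-invariant."""

    def __init__(self, root: _Node):
        self.root = root
        self.taxa = sorted(root.leaves())

    # -- construction / serialization

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)

        def convert(node) -> _Node:
            if node.is_leaf():
                return _Node(taxon=node.taxon.label)
            inner = _Node(children=[(convert(c), c.edge.length or 0.0)
                                    for c in node.child_nodes()])
            if node.label is not None:
                try:
                    inner.support = float(node.label)
                except ValueError:
                    pass
            return inner

        return cls(convert(dtree.seed_node))

    def to_newick(self, decimals: int = 9) -> str:
        def fmt(node: _Node) -> str:
            if node.taxon is not None:
                return node.taxon
            inner = ",".join(f"{fmt(c)}:{bl:.{decimals}f}"
                             for c, bl in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}"
        return fmt(self.root) + ";"

    # -- topology

    def bipartitions(self) -> set[frozenset[str]]:
        """Internal-edge bipartitions, each canonicalized as the side *not*
        containing the alphabetically first taxon."""
        ref = self.taxa[0]
        all_taxa = frozenset(self.taxa)
        out: set[frozenset[str]] = set()

        def walk(node: _Node) -> frozenset[str]:
            if node.taxon is not None:
                return frozenset([node.taxon])
            below = frozenset().union(*(walk(c) for c, _bl in node.children))
            if 1 < len(below) < len(self.taxa):
                out.add(below if ref not in below else all_taxa - below)
            return below

        walk(self.root)
        return out

    def edge_supports(self) -> dict[frozenset[str], float | None]:
        ref = self.taxa[0]
        all_taxa = frozenset(self.taxa)
        out: dict[frozenset[str], float | None] = {}

        def walk(node: _Node) -> frozenset[str]:
            if node.taxon is not None:
                return frozenset([node.taxon])
            below = frozenset().union(*(walk(c) for c, _bl in node.children))
            if 1 < len(below) < len(self.taxa):
                key = below if ref not in below else all_taxa - below
                out[key] = node.support
            return below

        walk(self.root)
        return out

    def is_clade(self, taxa: set[str]) -> bool:
        """True iff ``taxa`` forms one side of an edge of the unrooted tree
        (monophyly relative to everything else, outgroup included)."""
        unknown = set(taxa) - set(self.taxa)
        if unknown:
            raise ValueError(f"unknown taxa: {sorted(unknown)}")
        clade = frozenset(taxa)
        if len(clade) in (0, len(self.taxa)):
            raise ValueError("constraint must be a proper non-empty subset")
        if len(clade) == 1 or len(clade) == len(self.taxa) - 1:
            return True  # pendant edges always exist
        ref = self.taxa[0]
        canon = clade if ref not in clade else frozenset(self.taxa) - clade
        return canon in self.bipartitions()


def check_constraints(tree: PhyloTree, constraints: list[set[str]]) -> list[bool]:
    """Evaluate clade constraints against an unrooted tree."""
    return [tree.is_clade(c) for c in constraints]


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic lexicographic tie-breaks
    and negative branch lengths clamped to zero."""
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    # active clusters: label (lexicographically smallest leaf) -> node
    nodes: dict[str, _Node] = {t: _Node(taxon=t) for t in dm.taxa}
    dist: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((dm.taxa[i], dm.taxa[j]))] = dm.matrix[i, j]

    def d(x: str, y: str) -> float:
        return 0.0 if x == y else dist[frozenset((x, y))]

    active = sorted(nodes)
    while len(active) > 3:
        r = len(active)
        row_sum = {x: sum(d(x, y) for y in active) for x in active}
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                x, y = active[ii], active[jj]
                qv = (r - 2) * d(x, y) - row_sum[x] - row_sum[y]
                key = (qv, x, y)
                if best is None or key < best:
                    best = key
        _q, x, y = best
        dxy = d(x, y)
        lx = dxy / 2 + (row_sum[x] - row_sum[y]) / (2 * (r - 2))
        ly = dxy - lx
        lx, ly = max(lx, 0.0), max(ly, 0.0)
        new = _Node(children=[(nodes[x], lx), (nodes[y], ly)])
        label = min(x, y)
        for z in active:
            if z in (x, y):
                continue
            dist[frozenset((label, z))] = (d(x, z) + d(y, z) - dxy) / 2
        nodes.pop(x), nodes.pop(y)
        nodes[label] = new
        active = sorted(nodes)

    x, y, z = active
    lx = max((d(x, y) + d(x, z) - d(y, z)) / 2, 0.0)
    ly = max((d(x, y) + d(y, z) - d(x, z)) / 2, 0.0)
    lz = max((d(x, z) + d(y, z) - d(x, y)) / 2, 0.0)
    root = _Node(children=[(nodes[x], lx), (nodes[y], ly), (nodes[z], lz)])
    return PhyloTree(root)


def bootstrap_support(sm: Supermatrix, reps: int = 100, seed: int = 0,
                      method: str = "tn93") -> PhyloTree:
    """NJ tree from the full supermatrix with bootstrap supports (percent of
    column-resampled replicates containing each internal bipartition)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    tree = neighbor_joining(distance_matrix(sm, method))
    counts = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        rep_tree = neighbor_joining(distance_matrix(sm.resample_columns(rng), method))
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    ref = tree.taxa[0]
    all_taxa = frozenset(tree.taxa)

    def annotate(node: _Node) -> frozenset[str]:
        if node.taxon is not None:
            return frozenset([node.taxon])
        below = frozenset().union(*(annotate(c) for c, _bl in node.children))
        if 1 < len(below) < len(tree.taxa):
            key = below if ref not in below else all_taxa - below
            node.support = 100.0 * counts[key] / reps
        return below

    annotate(tree.root)
    return tree
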