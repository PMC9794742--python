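"""Distance phylogeny, OTU classification and insertion-age inference.

Distances are Poisson-corrected amino-acid distances, d = -ln(1 - p),
with p the mismatch fraction over aligned (non-gap) columns of a pairwise
global alignment. Trees are built with neighbor-joining (Saitou-Nei
Q-criterion, deterministic lowest-index tie-breaking); bootstrap support
resamples alignment columns. Candidate representatives are classified to
the OTU of their nearest library reference (a clade-based method is also
provided), and the minimum insertion age of a cluster is the divergence
time of its most distantly related pair of host taxa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from . import align
from .refdata import DivergenceTable, HostTaxonomy, MissingDivergenceError, ReferenceRT

logger = logging.getLogger(__name__)

P_CLAMP = 0.95  # saturation guard for the Poisson correction
OTU_DISTANCE_CEILING = 0.5  # beyond this, a representative is "unclassified"


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance -ln(1-p); p is clamped at 0.95."""
    if p < 0:
        raise ValueError("p must be >= 0")
    if p >= P_CLAMP:
        logger.warning("p-distance %.3f clamped to %.2f (saturated)", p, P_CLAMP)
        p = P_CLAMP
    return -math.log(1.0 - p)


def sequence_distance(a: str, b: str) -> float:
    """Poisson distance between two unaligned peptides (pairwise global
    alignment, gap columns excluded)."""
    return poisson_distance(align.p_distance(a, b))


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.d):
                fh.write(label + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def pairwise_distances(items) -> DistanceMatrix:
    """Poisson distance matrix for >=2 peptides ((id, seq) pairs or objects
    with ``id``/``aa_seq``)."""
    pairs = [(x.id, x.aa_seq) if hasattr(x, "aa_seq") else tuple(x) for x in items]
    if len(pairs) < 2:
        raise ValueError("need at least two peptides")
    labels = [p[0] for p in pairs]
    n = len(pairs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sequence_distance(pairs[i][1], pairs[j][1])
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining (Saitou-Nei) tree; unrooted, returned as a trifurcating
    root. Ties in the Q-criterion resolve to the lowest (i, j) index pair in
    the current matrix ordering; negative branch lengths are clamped to 0."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes = [TreeNode(name=label) for label in dm.labels]
    d = dm.d.copy()
    if n == 2:
        for node in nodes:
            node.length = max(d[0, 1] / 2.0, 0.0)
        return TreeNode(children=nodes)
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        q[np.tril_indices(m)] = np.inf
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[1:, 1:] = d[np.ix_(keep, keep)]
        d2[0, 1:] = d2[1:, 0] = dnew[keep]
        d = d2
        nodes = [parent] + [nodes[k] for k in keep]
    a, b, c = d[0, 1], d[0, 2], d[1, 2]
    lengths = [(a + b - c) / 2.0, (a + c - b) / 2.0, (b + c - a) / 2.0]
    for node, length in zip(nodes, lengths):
        node.length = max(length, 0.0)
    return TreeNode(children=nodes)


def tree_splits(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of tip names, normalised to the
    side not containing the lexicographically first tip."""
    all_tips = sorted(t.name for t in tree.tips())
    ref = all_tips[0]
    universe = frozenset(all_tips)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(universe) - 1:
            if ref in side:
                side = universe - side
            splits.add(side)
    return splits


# ---------------------------------------------------------------------------
# bootstrap

def _star_align(seqs: list[str]) -> np.ndarray:
    """Crude MSA: project every sequence onto the columns of the longest
    (insertions relative to it are dropped). Adequate for resampling
    columns of near-equal-length RT domains."""
    ref_idx = max(range(len(seqs)), key=lambda i: (len(seqs[i]), -i))
    ref = seqs[ref_idx]
    ncol = len(ref)
    msa = np.full((len(seqs), ncol), ord("-"), dtype=np.uint8)
    for i, seq in enumerate(seqs):
        if i == ref_idx:
            msa[i] = np.frombuffer(ref.encode(), dtype=np.uint8)
            continue
        aln = align.global_align(ref, seq)
        ref_blocks, seq_blocks = aln.aligned
        for (rs, re), (ss, se) in zip(ref_blocks, seq_blocks):
            msa[i, rs:re] = np.frombuffer(seq[ss:se].encode(), dtype=np.uint8)
    return msa


def _msa_distance_matrix(msa: np.ndarray, labels: list[str]) -> DistanceMatrix:
    n = msa.shape[0]
    gap = ord("-")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (msa[i] != gap) & (msa[j] != gap)
            total = int(valid.sum())
            if total == 0:
                raise ValueError(f"no shared columns between {labels[i]} and {labels[j]}")
            p = float((msa[i][valid] != msa[j][valid]).sum()) / total
            d[i, j] = d[j, i] = poisson_distance(p)
    return DistanceMatrix(labels, d)


def bootstrap_support(items, n_reps: int, seed: int = 0) -> TreeNode:
    """NJ tree with bootstrap supports (% of replicate trees containing each
    split), from column resampling. Equal-length inputs are treated as
    aligned; otherwise a star alignment to the longest sequence is used.
    Supports are stored as internal node names (0-100)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    pairs = [(x.id, x.aa_seq) if hasattr(x, "aa_seq") else tuple(x) for x in items]
    labels = [p[0] for p in pairs]
    seqs = [p[1] for p in pairs]
    if len(set(map(len, seqs))) == 1:
        msa = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
    else:
        msa = _star_align(seqs)
    ref_tree = nj_tree(_msa_distance_matrix(msa, labels))
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    ncol = msa.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_tree = nj_tree(_msa_distance_matrix(msa[:, cols], labels))
        for split in tree_splits(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    all_tips = sorted(labels)
    universe = frozenset(all_tips)
    ref = all_tips[0]
    for node in ref_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if not (1 < len(side) < len(universe) - 1):
            continue
        if ref in side:
            side = universe - side
        node.name = str(round(100.0 * counts.get(side, 0) / n_reps))
    return ref_tree


# ---------------------------------------------------------------------------
# OTU assignment


@dataclass(frozen=True)
class OTUAssignment:
    id: str
    otu: str
    support: float  # margin (d2 - d1) / d2 between best and next-best OTU
    method: str
    distance: float = float("nan")
    nearest_ref: str = ""


def assign_otu(
    rep_id: str,
    rep_peptide: str,
    library: list[ReferenceRT],
    ceiling: float = OTU_DISTANCE_CEILING,
) -> OTUAssignment:
    """Nearest-reference classification: the OTU of the minimum-distance
    library reference, or "unclassified" beyond the distance ceiling."""
    if not library:
        raise ValueError("empty reference library")
    scored = sorted(
        ((sequence_distance(rep_peptide, ref.aa_seq), ref.id, ref.otu) for ref in library),
        key=lambda t: (t[0], t[1]),
    )
    d1, ref1, otu1 = scored[0]
    d2 = next((d for d, _, otu in scored if otu != otu1), float("inf"))
    if d1 > ceiling:
        return OTUAssignment(rep_id, "unclassified", 0.0, "nearest_reference", d1, ref1)
    if math.isinf(d2) or d2 <= 0:
        support = 1.0 if d1 < d2 else 0.0
    else:
        support = max((d2 - d1) / d2, 0.0)
    return OTUAssignment(rep_id, otu1, support, "nearest_reference", d1, ref1)


def assign_otu_clade(rep_id: str, rep_peptide: str, library: list[ReferenceRT]) -> OTUAssignment:
    """Clade-based classification: build an NJ tree of the query with all
    references and assign the OTU of the smallest surrounding clade if its
    reference members are unanimous."""
    items = [(rep_id, rep_peptide)] + [(r.id, r.aa_seq) for r in library]
    tree = nj_tree(pairwise_distances(items))
    otu_by_ref = {r.id: r.otu for r in library}
    tip = next(t for t in tree.tips() if t.name == rep_id)
    node = tip.parent
    while node is not None:
        ref_otus = {otu_by_ref[t.name] for t in node.tips() if t.name != rep_id}
        if ref_otus:
            if len(ref_otus) == 1:
                return OTUAssignment(rep_id, ref_otus.pop(), 0.0, "clade")
            return OTUAssignment(rep_id, "unclassified", 0.0, "clade")
        node = node.parent
    return OTUAssignment(rep_id, "unclassified", 0.0, "clade")


# ---------------------------------------------------------------------------
# minimum insertion age


@dataclass
class AgeEstimate:
    cluster_id: str
    species_pair: tuple[str, str]
    age_my: float
    rank_used: str = "genus"
    flagged: bool = False
    unresolved: list[tuple[str, str]] = field(default_factory=list)


def min_age(cluster_id: str, hosts: list[HostTaxonomy], table: DivergenceTable) -> AgeEstimate:
    """Minimum insertion age of a cluster: the largest divergence time over
    unordered pairs of its member hosts. Lookup tries the genus pair first
    (divergence tables are usually genus-keyed), then the species pair.
    Pairs absent from the table are listed and the estimate flagged. A
    single-host cluster has age 0 by convention."""
    if not hosts:
        raise ValueError("cluster has no hosts")
    distinct = sorted({(h.species, h.genus) for h in hosts})
    if len(distinct) == 1:
        genus = distinct[0][1]
        return AgeEstimate(cluster_id, (genus, genus), 0.0)
    best: tuple[float, tuple[str, str], str] | None = None
    unresolved: list[tuple[str, str]] = []
    for i in range(len(distinct)):
        for j in range(i + 1, len(distinct)):
            (sp_a, g_a), (sp_b, g_b) = distinct[i], distinct[j]
            pair_g = tuple(sorted((g_a, g_b)))
            pair_s = tuple(sorted((sp_a, sp_b)))
            try:
                age, pair, rank = table.lookup(*pair_g), pair_g, "genus"
            except MissingDivergenceError:
                try:
                    age, pair, rank = table.lookup(*pair_s), pair_s, "species"
                except MissingDivergenceError:
                    unresolved.append(pair_s)
                    continue
            key = (age, pair, rank)
            if best is None or age > best[0] or (age == best[0] and pair < best[1]):
                best = key
    if best is None:
        return AgeEstimate(cluster_id, ("", ""), float("nan"), "none", True, unresolved)
    return AgeEstimate(
        cluster_id, best[1], best[0], best[2], flagged=bool(unresolved), unresolved=unresolved
    )
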