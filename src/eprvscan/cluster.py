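"""Greedy identity clustering of candidate RT peptides (CD-HIT semantics).

Identity between two peptides is the number of identical aligned positions
of their global alignment divided by the length of the shorter sequence
(the CD-HIT convention). Clustering is greedy-incremental: sequences are
processed longest first (ties broken by id), each sequence joins the first
existing cluster whose representative it matches at or above the
threshold, otherwise it founds a new cluster; the founding (longest)
member is the representative. No short-word filtering is used — every
comparison is an exact pairwise alignment.

Cluster100 groups of at least ``min_copies`` identical peptides within one
genome mark recent amplification events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import pairwise_identity

logger = logging.getLogger(__name__)

__all__ = [
    "pairwise_identity",
    "Cluster",
    "ClusterSet",
    "greedy_cluster",
    "find_amplification",
    "AmplificationCluster",
    "write_cluster_tsv",
    "write_representatives_fasta",
]


@dataclass
class Cluster:
    cluster_id: str
    members: list[str]
    representatives: list[str]
    sequences: dict[str, str]
    identity_to_rep: dict[str, float]

    @property
    def representative(self) -> str:
        return self.representatives[0]

    def __len__(self):
        return len(self.members)


@dataclass
class ClusterSet:
    threshold: float
    scope: str  # global | per_genome
    clusters: list[Cluster] = field(default_factory=list)

    def __len__(self):
        return len(self.clusters)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def membership(self) -> dict[str, str]:
        return {m: c.cluster_id for c in self.clusters for m in c.members}


def _as_items(candidates) -> list[tuple[str, str]]:
    items = []
    for c in candidates:
        if hasattr(c, "aa_seq"):
            items.append((c.id, c.aa_seq))
        else:
            items.append((c[0], c[1]))
    return items


def greedy_cluster(
    candidates,
    threshold: float,
    scope: str = "global",
    prefix: str = "cluster",
    allow_two_representatives: bool = False,
) -> ClusterSet:
    """CD-HIT-style greedy clustering at a fractional identity threshold.

    ``candidates`` are objects with ``id``/``aa_seq`` or (id, seq) pairs.
    With ``allow_two_representatives`` a cluster whose members split into
    two below-threshold subgroups gets a second representative (the member
    least similar to the founder) — mirrors the manual special case used
    for one heterogeneous survey cluster.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    items = _as_items(candidates)
    if not items:
        raise ValueError("no sequences to cluster")
    items.sort(key=lambda t: (-len(t[1]), t[0]))
    clusters: list[Cluster] = []
    for name, seq in items:
        placed = False
        for cl in clusters:
            ident = pairwise_identity(seq, cl.sequences[cl.representative])
            if ident >= threshold:
                cl.members.append(name)
                cl.sequences[name] = seq
                cl.identity_to_rep[name] = ident
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(
                    cluster_id=f"{prefix}{len(clusters)}",
                    members=[name],
                    representatives=[name],
                    sequences={name: seq},
                    identity_to_rep={name: 1.0},
                )
            )
    if allow_two_representatives:
        for cl in clusters:
            if len(cl) < 2:
                continue
            worst = min(
                (m for m in cl.members if m != cl.representative),
                key=lambda m: (cl.identity_to_rep[m], m),
                default=None,
            )
            if worst is not None and _has_split(cl, threshold):
                cl.representatives.append(worst)
    logger.info(
        "greedy_cluster: %d sequences -> %d clusters at %.0f%%",
        len(items), len(clusters), 100 * threshold,
    )
    return ClusterSet(threshold=threshold, scope=scope, clusters=clusters)


def _has_split(cl: Cluster, threshold: float) -> bool:
    """True if some member pair falls below the threshold (two subgroups)."""
    members = cl.members
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if pairwise_identity(cl.sequences[members[i]], cl.sequences[members[j]]) < threshold:
                return True
    return False


@dataclass
class AmplificationCluster:
    """A burst of identical RT copies within one genome."""

    genome: str
    cluster: Cluster
    otu: str | None = None

    @property
    def n_copies(self) -> int:
        return len(self.cluster)


def find_amplification(candidates, min_copies: int = 10, threshold: float = 1.0) -> list[AmplificationCluster]:
    """Per-genome clustering at 100% identity; report clusters with
    ``min_copies`` or more members (the restrictive recent-amplification
    criterion). ``candidates`` must carry a ``genome`` attribute."""
    by_genome: dict[str, list] = {}
    for c in candidates:
        by_genome.setdefault(c.genome, []).append(c)
    bursts: list[AmplificationCluster] = []
    for genome in sorted(by_genome):
        cset = greedy_cluster(by_genome[genome], threshold, scope="per_genome",
                              prefix=f"{genome}|c100-")
        for cl in cset.clusters:
            if len(cl) >= min_copies:
                bursts.append(AmplificationCluster(genome=genome, cluster=cl))
    bursts.sort(key=lambda b: (-b.n_copies, b.genome, b.cluster.cluster_id))
    return bursts


def write_cluster_tsv(cluster_set: ClusterSet, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("member_id\tcluster_id\trepresentative_flag\tidentity_to_rep\n")
        for cl in cluster_set.clusters:
            for m in cl.members:
                flag = 1 if m in cl.representatives else 0
                fh.write(f"{m}\t{cl.cluster_id}\t{flag}\t{cl.identity_to_rep[m]:.4f}\n")


def write_representatives_fasta(cluster_set: ClusterSet, path) -> None:
    with open(path, "w") as fh:
        for cl in cluster_set.clusters:
            for rep in cl.representatives:
                fh.write(f">{rep} {cl.cluster_id}\n{cl.sequences[rep]}\n")
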