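"""Summary tables, published-table consistency checks, recovery scoring.

Two packaged TSVs transcribe the published survey's cluster statistics:
``cluster60_survey.tsv`` (one row per 60%-identity cluster with its
taxonomic breadth and maximum insertion age) and ``cluster100_survey.tsv``
(100%-identity clusters of 10+ copies per genome). The consistency checker
recomputes all derivable totals from the rows and flags — without taking a
side — the genus totals whose printed values disagree with their own row
sums (a known feature of the source tables).

Recovery scoring compares pipeline candidates against the simulator's
truth ledger with a 50% reciprocal-overlap criterion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .cluster import ClusterSet
from .phylo import AgeEstimate, OTUAssignment
from .refdata import EPISOMAL_GENERA, HostTaxonomy, ReferenceRT
from .screen import CandidateRT
from .syngen import TruthRecord, TruthSet


def _data_path(name: str) -> str:
    return str(resources.files("eprvscan") / "data" / name)


# ---------------------------------------------------------------------------
# cluster summary table (Cluster60-statistics analog)


@dataclass(frozen=True)
class ClusterSummaryRow:
    otu: str
    cluster_id: str
    n_seqs: int
    n_classes: int
    n_orders: int
    n_families: int
    n_genera: int
    n_species: int
    age_pair: tuple[str, str]
    max_age_my: float


def build_cluster_table(
    cluster_set: ClusterSet,
    assignments: dict[str, OTUAssignment],
    ages: dict[str, AgeEstimate],
    taxonomy_by_member: dict[str, HostTaxonomy],
) -> list[ClusterSummaryRow]:
    """One summary row per cluster: distinct-value taxonomic-breadth counts
    over member hosts, the assigned OTU and the maximum insertion age.

    ``assignments`` and ``ages`` are keyed by cluster id; ``taxonomy_by_member``
    by member (candidate) id. A member without taxonomy is an error.
    """
    rows: list[ClusterSummaryRow] = []
    for cl in cluster_set.clusters:
        hosts = []
        for member in cl.members:
            try:
                hosts.append(taxonomy_by_member[member])
            except KeyError:
                raise KeyError(f"member {member!r} has no host taxonomy") from None
        assignment = assignments.get(cl.cluster_id)
        age = ages.get(cl.cluster_id)
        rows.append(
            ClusterSummaryRow(
                otu=assignment.otu if assignment else "unclassified",
                cluster_id=cl.cluster_id,
                n_seqs=len(cl),
                n_classes=len({h.class_ for h in hosts}),
                n_orders=len({h.order for h in hosts}),
                n_families=len({h.family for h in hosts}),
                n_genera=len({h.genus for h in hosts}),
                n_species=len({h.species for h in hosts}),
                age_pair=age.species_pair if age else ("", ""),
                max_age_my=age.age_my if age else float("nan"),
            )
        )
    rows.sort(key=lambda r: (r.otu, -r.n_seqs, r.cluster_id))
    return rows


SUMMARY_COLUMNS = [
    "otu", "cluster_id", "n_seqs", "n_classes", "n_orders", "n_families",
    "n_genera", "n_species", "host_a", "host_b", "max_age_my",
]


def cluster_table_to_frame(rows: list[ClusterSummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "otu": r.otu, "cluster_id": r.cluster_id, "n_seqs": r.n_seqs,
                "n_classes": r.n_classes, "n_orders": r.n_orders,
                "n_families": r.n_families, "n_genera": r.n_genera,
                "n_species": r.n_species, "host_a": r.age_pair[0],
                "host_b": r.age_pair[1], "max_age_my": r.max_age_my,
            }
            for r in rows
        ],
        columns=SUMMARY_COLUMNS,
    )


def cluster_table_to_markdown(rows: list[ClusterSummaryRow]) -> str:
    df = cluster_table_to_frame(rows)
    return df.to_markdown(index=False)


# ---------------------------------------------------------------------------
# published-table consistency checks


def check_published_tables(table1_path=None, table3_path=None) -> dict:
    """Recompute all derivable statistics from the packaged survey-table
    transcriptions and compare them with the printed genus totals.

    Returns a JSON-serialisable report. Genus totals that disagree with
    their row sums are listed under ``flagged_totals`` (reported, not
    asserted either way); totals that agree are in ``consistent_totals``.
    """
    t1 = pd.read_csv(table1_path or _data_path("cluster60_survey.tsv"), sep="\t")
    totals = pd.read_csv(_data_path("cluster60_totals.tsv"), sep="\t")
    t3 = pd.read_csv(table3_path or _data_path("cluster100_survey.tsv"), sep="\t")
    for frame, required in ((t1, {"otu", "cluster_name", "n_seqs"}),
                            (t3, {"cluster_n", "n_seqs", "genome", "otu_cluster"})):
        if not required.issubset(frame.columns):
            raise ValueError(f"malformed table: missing {sorted(required - set(frame.columns))}")

    per_genus = t1.groupby("otu")["n_seqs"].sum().to_dict()
    printed = dict(zip(totals["otu"], totals["printed_n_seqs"]))
    flagged, consistent = {}, {}
    for otu, printed_total in printed.items():
        row_sum = int(per_genus.get(otu, 0))
        if row_sum == printed_total:
            consistent[otu] = row_sum
        else:
            flagged[otu] = {"printed": int(printed_total), "row_sum": row_sum}

    clusters_per_otu = t1.groupby("otu")["cluster_name"].count().to_dict()
    episomal_clusters = int(sum(n for otu, n in clusters_per_otu.items() if otu in EPISOMAL_GENERA))

    t3_genome = t3.groupby("genome")["n_seqs"].sum().to_dict()
    t3_otu = (
        t3.assign(otu=t3["otu_cluster"].str.split("-").str[0])
        .groupby("otu")["n_seqs"].sum().to_dict()
    )
    capsicum = t3[t3["genome"] == "Capsicum annuum"]
    capsicum_solendo = capsicum[capsicum["otu_cluster"].str.startswith("Solendovirus")]

    return {
        "cluster60": {
            "n_clusters": int(len(t1)),
            "n_otus": int(t1["otu"].nunique()),
            "episomal_genus_clusters": episomal_clusters,
            "clusters_per_otu": {k: int(v) for k, v in sorted(clusters_per_otu.items())},
            "seqs_per_otu_row_sum": {k: int(v) for k, v in sorted(per_genus.items())},
            "consistent_totals": consistent,
            "flagged_totals": flagged,
        },
        "cluster100": {
            "n_clusters": int(len(t3)),
            "total_seqs": int(t3["n_seqs"].sum()),
            "max_copies": int(t3["n_seqs"].max()),
            "n_genomes": int(t3["genome"].nunique()),
            "seqs_per_genome": {k: int(v) for k, v in sorted(t3_genome.items())},
            "seqs_per_otu": {k: int(v) for k, v in sorted(t3_otu.items())},
            "capsicum_total": int(capsicum["n_seqs"].sum()),
            "capsicum_solendovirus": int(capsicum_solendo["n_seqs"].sum()),
        },
    }


def write_consistency_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# recovery against simulation truth


@dataclass
class RecoveryReport:
    sensitivity: dict[str, float]
    confusion: dict[str, dict[str, int]]
    precision: float  # NaN when no predictions
    otu_accuracy: float  # NaN when nothing recovered
    n_candidates: int
    matches: dict[int, str] = field(default_factory=dict)  # truth index -> candidate id


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def evaluate_recovery(
    truth: TruthSet,
    candidates: list[CandidateRT],
    library: list[ReferenceRT],
    assignments: dict[str, OTUAssignment] | None = None,
    min_overlap: float = 0.5,
) -> RecoveryReport:
    """Score candidates against the planted-element truth ledger.

    A truth element is recovered when some candidate on the same contig
    overlaps it reciprocally by at least ``min_overlap``. Sensitivity is
    reported per scoring class (intact dispersed, intact tandem,
    internal_stop, frameshift, decoy); OTU accuracy is the fraction of
    recovered intact elements whose cluster/candidate OTU assignment
    matches the OTU of the planted source reference.
    """
    otu_by_ref = {r.id: r.otu for r in library}
    matches: dict[int, str] = {}
    truth_list = list(truth)
    for t_idx, t in enumerate(truth_list):
        for c in candidates:
            if c.contig != t.contig:
                continue
            if _reciprocal_overlap(t.start, t.end, c.start_bp, c.end_bp) >= min_overlap:
                matches[t_idx] = c.id
                break
    by_class = truth.by_class()
    index_of = {id(rec): i for i, rec in enumerate(truth_list)}
    sensitivity, confusion = {}, {}
    for cls, records in sorted(by_class.items()):
        recovered = sum(1 for rec in records if index_of[id(rec)] in matches)
        sensitivity[cls] = recovered / len(records)
        confusion[cls] = {"recovered": recovered, "total": len(records)}

    if candidates:
        intact_hits = 0
        for c in candidates:
            ok = any(
                t.degeneration == "intact"
                and t.contig == c.contig
                and _reciprocal_overlap(t.start, t.end, c.start_bp, c.end_bp) >= min_overlap
                for t in truth_list
            )
            intact_hits += ok
        precision = intact_hits / len(candidates)
    else:
        precision = float("nan")

    otu_accuracy = float("nan")
    if assignments is not None:
        scored = []
        for t_idx, cand_id in matches.items():
            t = truth_list[t_idx]
            if t.degeneration != "intact" or t.lineage_class != "caulimoviridae":
                continue
            assignment = assignments.get(cand_id)
            if assignment is None:
                continue
            scored.append(assignment.otu == otu_by_ref[t.source_ref_id])
        if scored:
            otu_accuracy = sum(scored) / len(scored)

    return RecoveryReport(
        sensitivity=sensitivity,
        confusion=confusion,
        precision=precision,
        otu_accuracy=otu_accuracy,
        n_candidates=len(candidates),
        matches=matches,
    )


def recovery_to_json(report: RecoveryReport) -> dict:
    def clean(x):
        return None if isinstance(x, float) and math.isnan(x) else x

    return {
        "sensitivity": report.sensitivity,
        "confusion": report.confusion,
        "precision": clean(report.precision),
        "otu_accuracy": clean(report.otu_accuracy),
        "n_candidates": report.n_candidates,
    }
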