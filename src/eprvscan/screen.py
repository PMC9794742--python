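"""Screening: reduce raw search hits to intact, non-redundant, Caulimoviridae
candidate RT domains.

Three fixed stages, in order:

1. intactness — keep hits whose subject peptide is at least ``min_aa``
   residues (default 300) with no stop codons and no indels in the subject
   row of the alignment (a single-frame, gap-free match is the operational
   reading of "no frameshifts");
2. proximity dedup — within a contig, hits whose inter-interval gap is
   less than ``window_bp`` (default 1500) are collapsed to the
   higher-scoring member, left to right (targets tandem/nested arrays);
3. lineage triage — each surviving peptide is scored by global alignment
   against every library reference; hits nearest a retroelement
   (Ty3/Gypsy or Retroviridae) reference are discarded, hits nearest a
   Caulimoviridae reference become :class:`CandidateRT` records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import align
from .fileio import Gff3Record, write_gff3
from .homsearch import RawHit
from .refdata import HostTaxonomy, ReferenceRT

logger = logging.getLogger(__name__)

MIN_AA_DEFAULT = 300
DEDUP_BP_DEFAULT = 1500


@dataclass(frozen=True)
class CandidateRT:
    """A screened, intact candidate RT-domain locus."""

    id: str
    contig: str
    start_bp: int
    end_bp: int
    strand: str
    frame: int
    aa_seq: str
    best_query_id: str
    best_ref_id: str
    score_bits: float
    host: HostTaxonomy
    genome: str
    provisional_class: str = "caulimoviridae"

    def __post_init__(self):
        if "*" in self.aa_seq:
            raise ValueError(f"{self.id}: candidate peptide contains a stop")


def filter_intact(hits: list[RawHit], min_aa: int = MIN_AA_DEFAULT) -> list[RawHit]:
    """Keep hits with >= min_aa subject residues, no stops, no subject gaps."""
    kept = [
        h
        for h in hits
        if len(h.matched_peptide) >= min_aa
        and "*" not in h.matched_peptide
        and "-" not in h.aligned_subject_aa
    ]
    logger.info("filter_intact: %d -> %d hits", len(hits), len(kept))
    return kept


def dedup_proximity(hits: list[RawHit], window_bp: int = DEDUP_BP_DEFAULT) -> list[RawHit]:
    """Collapse hits closer than ``window_bp`` (inter-interval gap, strict)
    to one survivor per conflict: the higher bit-score, leftmost on ties.
    Applied transitively left to right within each contig."""
    by_contig: dict[str, list[RawHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig, []).append(h)
    survivors: list[RawHit] = []
    for contig in sorted(by_contig):
        chits = sorted(by_contig[contig], key=lambda h: (h.start_bp, h.end_bp))
        # chains of proximity: consecutive hits (by start) whose gap to the
        # rightmost end seen so far is < window_bp belong to one conflict
        # group (a tandem/nested array); one survivor per group
        chains: list[list[RawHit]] = []
        max_end = None
        for h in chits:
            if max_end is None or h.start_bp - max_end >= window_bp:
                chains.append([h])
            else:
                chains[-1].append(h)
            max_end = h.end_bp if max_end is None else max(max_end, h.end_bp)
        for chain in chains:
            survivors.append(
                max(chain, key=lambda h: (h.score_bits, -h.start_bp, -h.end_bp))
            )
    logger.info("dedup_proximity: %d -> %d hits", len(hits), len(survivors))
    return survivors


def _best_class(peptide: str, library: list[ReferenceRT]) -> tuple[str, str]:
    """(lineage_class, best_ref_id) for a peptide by global-alignment score.

    Ties between classes are resolved by the higher sum of the top-3 scores
    per class, then lexicographically by class name (deterministic).
    """
    scored: dict[str, list[tuple[float, str]]] = {"caulimoviridae": [], "retroelement": []}
    for ref in library:
        scored[ref.lineage_class].append((align.global_score(peptide, ref.aa_seq), ref.id))
    for cls, entries in scored.items():
        if not entries:
            raise ValueError(f"library has no {cls} references; cannot triage")
        entries.sort(key=lambda t: (-t[0], t[1]))
    best_c, best_r = scored["caulimoviridae"][0], scored["retroelement"][0]
    if best_c[0] > best_r[0]:
        winner = "caulimoviridae"
    elif best_r[0] > best_c[0]:
        winner = "retroelement"
    else:
        top3 = {cls: sum(s for s, _ in entries[:3]) for cls, entries in scored.items()}
        if top3["caulimoviridae"] >= top3["retroelement"]:
            winner = "caulimoviridae"
        else:
            winner = "retroelement"
    return winner, scored[winner][0][1]


def triage_lineage(
    hits: list[RawHit],
    library: list[ReferenceRT],
    host: HostTaxonomy,
    genome: str | None = None,
) -> list[CandidateRT]:
    """Score each hit against the full reference library and keep only
    those closer to Caulimoviridae than to retroelements."""
    genome = genome or host.species
    candidates: list[CandidateRT] = []
    for h in hits:
        cls, ref_id = _best_class(h.matched_peptide, library)
        if cls != "caulimoviridae":
            continue
        cid = f"{h.contig}:{h.start_bp}-{h.end_bp}:{h.strand}"
        candidates.append(
            CandidateRT(
                id=cid,
                contig=h.contig,
                start_bp=h.start_bp,
                end_bp=h.end_bp,
                strand=h.strand,
                frame=h.frame,
                aa_seq=h.matched_peptide,
                best_query_id=h.query_id,
                best_ref_id=ref_id,
                score_bits=h.score_bits,
                host=host,
                genome=genome,
            )
        )
    logger.info("triage_lineage: %d -> %d caulimoviridae candidates", len(hits), len(candidates))
    return candidates


def screen_hits(
    hits: list[RawHit],
    library: list[ReferenceRT],
    host: HostTaxonomy,
    genome: str | None = None,
    min_aa: int = MIN_AA_DEFAULT,
    window_bp: int = DEDUP_BP_DEFAULT,
) -> list[CandidateRT]:
    """Full screen: intactness -> proximity dedup -> lineage triage."""
    return triage_lineage(
        dedup_proximity(filter_intact(hits, min_aa=min_aa), window_bp=window_bp),
        library,
        host,
        genome=genome,
    )


# ---------------------------------------------------------------------------
# writers


def write_candidates_fasta(candidates, path) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f">{c.id}\n{c.aa_seq}\n")


def write_candidates_gff3(candidates, path, header_lines=()) -> None:
    records = [
        Gff3Record(
            seqid=c.contig,
            type="EPRV_RT_candidate",
            start=c.start_bp,
            end=c.end_bp,
            strand=c.strand,
            score=format(c.score_bits, ".1f"),
            attributes={
                "ID": c.id,
                "best_query_id": c.best_query_id,
                "best_ref_id": c.best_ref_id,
                "genome": c.genome,
            },
        )
        for c in candidates
    ]
    write_gff3(records, path, header_lines=header_lines)


def read_candidates_tsv(path, taxonomy: dict[str, HostTaxonomy]) -> list[CandidateRT]:
    """Read a candidates TSV back; hosts are resolved from ``taxonomy`` by
    the genome column."""
    candidates = []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if header is None:
                header = line.rstrip("\n").split("\t")
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            candidates.append(
                CandidateRT(
                    id=row["id"],
                    contig=row["contig"],
                    start_bp=int(row["start_bp"]),
                    end_bp=int(row["end_bp"]),
                    strand=row["strand"],
                    frame=int(row["frame"]),
                    aa_seq=row["aa_seq"],
                    best_query_id=row["best_query_id"],
                    best_ref_id=row["best_ref_id"],
                    score_bits=float(row["score_bits"]),
                    host=taxonomy[row["genome"]],
                    genome=row["genome"],
                )
            )
    return candidates


CANDIDATE_TSV_COLUMNS = [
    "id", "contig", "start_bp", "end_bp", "strand", "frame", "genome",
    "best_query_id", "best_ref_id", "score_bits", "aa_seq",
]


def write_candidates_tsv(candidates, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(CANDIDATE_TSV_COLUMNS) + "\n")
        for c in candidates:
            values = [
                c.id, c.contig, c.start_bp, c.end_bp, c.strand, c.frame, c.genome,
                c.best_query_id, c.best_ref_id, format(c.score_bits, ".2f"), c.aa_seq,
            ]
            fh.write("\t".join(str(v) for v in values) + "\n")
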