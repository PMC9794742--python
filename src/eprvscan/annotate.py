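"""Element architecture around candidate RT loci: ORFs, domains, wendovirus.

The element window (candidate RT locus extended by a few kb) is scanned in
the three forward frames (elements are oriented RT-forward). An ORF runs
from the first ATG after a stop (or the window start) to the next stop or
the window end, and must encode at least ``min_orf_aa`` residues. Domain
presence uses the packaged position-constrained motifs.

The wendovirus architecture call requires: at least four ORFs; a
zinc-finger ORF (coat-protein-like); an ORF carrying a movement protein
and an aspartic proteinase; a distinct downstream ORF carrying a second
aspartic proteinase followed by the reverse transcriptase and then RNase
H; and at least two aspartic-proteinase-bearing ORFs in total. Either
proteinase motif may satisfy either position (the motifs are surrogates
for two distinct proteinase families). Elements with the full domain
complement but a broken ORF layout are flagged "unresolved" rather than
forced into either call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .dna import translate
from .fileio import Gff3Record, write_gff3
from .refdata import DomainMotif, load_motifs

logger = logging.getLogger(__name__)

MIN_ORF_AA_DEFAULT = 100
WINDOW_BP_DEFAULT = 5000

_AP_MOTIFS = {"aspartic_proteinase_1", "aspartic_proteinase_2"}


@dataclass(frozen=True)
class OrfRecord:
    """An ATG-initiated open reading frame, element-relative coordinates
    (0-based half-open nucleotides, stop codon included when present)."""

    start: int
    end: int
    frame: int
    peptide: str

    def __post_init__(self):
        if not self.peptide.startswith("M"):
            raise ValueError("ORF peptide must start with M")


@dataclass(frozen=True)
class DomainHit:
    orf_index: int
    motif: str
    aa_offset: int
    score: int


@dataclass
class ElementAnnotation:
    element_id: str
    orfs: list[OrfRecord] = field(default_factory=list)
    domain_hits: list[DomainHit] = field(default_factory=list)
    architecture_call: str = "other"  # wendovirus_like | other | unresolved

    def motifs_by_orf(self) -> dict[int, list[DomainHit]]:
        out: dict[int, list[DomainHit]] = {}
        for hit in self.domain_hits:
            out.setdefault(hit.orf_index, []).append(hit)
        for hits in out.values():
            hits.sort(key=lambda h: h.aa_offset)
        return out


def find_orfs(element_dna: str, min_orf_aa: int = MIN_ORF_AA_DEFAULT) -> list[OrfRecord]:
    """ATG-to-stop ORFs in the three forward frames.

    Within each frame, each run between stop codons (or window edges)
    contributes at most one ORF: from its first ATG to the closing stop or
    the element end. Overlapping ORFs in different frames are all reported.
    """
    orfs: list[OrfRecord] = []
    for frame in range(3):
        peptide = translate(element_dna, frame)
        segment_start = 0  # codon index where the current stop-free run began
        pos = 0
        while pos <= len(peptide):
            if pos == len(peptide) or peptide[pos] == "*":
                segment = peptide[segment_start:pos]
                m_idx = segment.find("M")
                if m_idx >= 0:
                    orf_pep = segment[m_idx:]
                    if len(orf_pep) >= min_orf_aa:
                        start_codon = segment_start + m_idx
                        has_stop = pos < len(peptide)
                        end_codon = pos + 1 if has_stop else pos
                        orfs.append(
                            OrfRecord(
                                start=frame + 3 * start_codon,
                                end=frame + 3 * end_codon,
                                frame=frame,
                                peptide=orf_pep,
                            )
                        )
                segment_start = pos + 1
            pos += 1
    orfs.sort(key=lambda o: (o.start, o.frame))
    return orfs


def scan_domains(orfs: list[OrfRecord], motifs: list[DomainMotif] | None = None) -> list[DomainHit]:
    """All motif occurrences at or above each motif's score threshold."""
    if motifs is None:
        motifs = load_motifs()
    hits: list[DomainHit] = []
    for idx, orf in enumerate(orfs):
        for motif in motifs:
            for offset, score in motif.scan(orf.peptide):
                hits.append(DomainHit(idx, motif.name, offset, score))
    hits.sort(key=lambda h: (h.orf_index, h.aa_offset, h.motif))
    return hits


def classify_architecture(annotation: ElementAnnotation) -> str:
    """Apply the wendovirus diagnostic rule to an annotated element."""
    by_orf = annotation.motifs_by_orf()
    orfs = annotation.orfs

    def orf_motifs(i) -> set[str]:
        return {h.motif for h in by_orf.get(i, [])}

    zf_orfs = [i for i in range(len(orfs)) if "zinc_finger" in orf_motifs(i)]
    ap_orfs = [i for i in range(len(orfs)) if orf_motifs(i) & _AP_MOTIFS]
    mp_ap_orfs = [
        i for i in range(len(orfs))
        if "movement_protein" in orf_motifs(i) and orf_motifs(i) & _AP_MOTIFS
    ]

    def ap_rt_rh_ordered(i) -> bool:
        hits = by_orf.get(i, [])
        ap_off = [h.aa_offset for h in hits if h.motif in _AP_MOTIFS]
        rt_off = [h.aa_offset for h in hits if h.motif == "reverse_transcriptase"]
        rh_off = [h.aa_offset for h in hits if h.motif == "rnaseh"]
        if not (ap_off and rt_off and rh_off):
            return False
        return any(
            a < r < h for a in ap_off for r in rt_off for h in rh_off
        )

    pol_orfs = [i for i in range(len(orfs)) if ap_rt_rh_ordered(i)]
    full_rule = (
        len(orfs) >= 4
        and zf_orfs
        and any(
            orfs[p].start > orfs[m].start
            for m in mp_ap_orfs
            for p in pol_orfs
            if p != m
        )
        and len(ap_orfs) >= 2
    )
    if full_rule:
        return "wendovirus_like"
    # full domain complement but broken ORF layout -> unresolved
    all_motifs = {h.motif for h in annotation.domain_hits}
    if (
        len(ap_orfs) >= 2
        and zf_orfs
        and "reverse_transcriptase" in all_motifs
        and "rnaseh" in all_motifs
        and "movement_protein" in all_motifs
    ):
        return "unresolved"
    return "other"


def annotate_element(
    element_id: str,
    element_dna: str,
    motifs: list[DomainMotif] | None = None,
    min_orf_aa: int = MIN_ORF_AA_DEFAULT,
) -> ElementAnnotation:
    """Full annotation: ORFs, domain hits and the architecture call."""
    orfs = find_orfs(element_dna, min_orf_aa=min_orf_aa)
    ann = ElementAnnotation(element_id=element_id, orfs=orfs)
    ann.domain_hits = scan_domains(orfs, motifs)
    ann.architecture_call = classify_architecture(ann)
    return ann


def annotations_to_gff3(annotations: list[tuple[str, int, ElementAnnotation]], path,
                        header_lines=()) -> None:
    """Write annotations as GFF3. Each item is (contig, element_start, ann)
    with ORFs as CDS features and domains as protein_match children."""
    records = []
    for contig, offset, ann in annotations:
        for idx, orf in enumerate(ann.orfs):
            orf_id = f"{ann.element_id}.orf{idx}"
            records.append(
                Gff3Record(
                    seqid=contig, type="CDS",
                    start=offset + orf.start, end=offset + orf.end,
                    strand="+", phase="0",
                    attributes={
                        "ID": orf_id,
                        "Parent": ann.element_id,
                        "frame": str(orf.frame),
                        "architecture_call": ann.architecture_call,
                    },
                )
            )
        for hit in ann.domain_hits:
            orf = ann.orfs[hit.orf_index]
            start = offset + orf.start + 3 * hit.aa_offset
            records.append(
                Gff3Record(
                    seqid=contig, type="protein_match",
                    start=start, end=start + 3,
                    strand="+",
                    attributes={
                        "Parent": f"{ann.element_id}.orf{hit.orf_index}",
                        "motif": hit.motif,
                        "aa_offset": str(hit.aa_offset),
                        "score": str(hit.score),
                    },
                )
            )
    write_gff3(records, path, header_lines=header_lines)
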