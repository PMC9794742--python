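"""Translated homology search: protein queries against six-frame genomes.

A self-contained tBLASTn surrogate. Each contig is translated in all six
frames; candidate regions are located by exact 4-mer peptide seeds (two or
more seeds on nearby diagonals), then scored with an optimal local
Smith-Waterman alignment (BLOSUM62, gap open 11 / extend 1) restricted to
the seeded window. Multiple non-overlapping alignments per window are
recovered by recursing on the flanks of each reported hit. Because the
window alignment itself is exact, the reported score of any planted
homology equals the full Smith-Waterman optimum; ``method="exhaustive"``
skips seeding and aligns whole frames (the slow oracle path).

E-values use Karlin-Altschul statistics with fixed gapped BLOSUM62
parameters and a search space of query length x total translated residues;
they are comparable, not bit-identical, to the external tool's values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import align
from .dna import revcomp, translate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RawHit:
    """One local protein-to-translated-genome alignment."""

    contig: str
    start_bp: int  # 0-based half-open, forward strand
    end_bp: int
    strand: str  # + | -
    frame: int  # 0..2 within the strand
    query_id: str
    aligned_query_aa: str
    aligned_subject_aa: str
    matched_peptide: str  # ungapped subject peptide; may contain '*'
    score_raw: float
    score_bits: float
    evalue: float

    def __post_init__(self):
        if self.end_bp <= self.start_bp:
            raise ValueError("end_bp must exceed start_bp")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class SearchParams:
    evalue_max: float = 1e-10
    score_min: float = 50.0
    seed_k: int = 4
    min_seeds: int = 2
    diag_band: int = 16
    matrix: str = align.DEFAULT_MATRIX
    gap_open: int = align.DEFAULT_GAP_OPEN
    gap_extend: int = align.DEFAULT_GAP_EXTEND


def six_frame_translate(dna: str) -> list[str]:
    """Peptides for frames 0-2 (forward) and 3-5 (reverse complement)."""
    rc = revcomp(dna)
    return [translate(dna, f) for f in range(3)] + [translate(rc, f) for f in range(3)]


# ---------------------------------------------------------------------------
# seeding

_AA_IDX = np.full(256, 20, dtype=np.int64)
for _i, _a in enumerate(align.AA20):
    _AA_IDX[ord(_a)] = _i


def _kmer_codes(peptide: str) -> np.ndarray:
    """Base-21 codes of all 4-mers; -1 where any residue is non-canonical."""
    v = _AA_IDX[np.frombuffer(peptide.encode("ascii"), dtype=np.uint8)]
    if v.size < 4:
        return np.empty(0, dtype=np.int64)
    code = ((v[:-3] * 21 + v[1:-2]) * 21 + v[2:-1]) * 21 + v[3:]
    valid = (v[:-3] < 20) & (v[1:-2] < 20) & (v[2:-1] < 20) & (v[3:] < 20)
    return np.where(valid, code, -1)


def _seed_windows(query: str, subject_codes: np.ndarray, params: SearchParams) -> list[tuple[int, int]]:
    """Candidate subject windows from two-seed diagonal clustering."""
    qcodes = _kmer_codes(query)
    if qcodes.size == 0 or subject_codes.size == 0:
        return []
    qpos_by_code: dict[int, list[int]] = {}
    for qp, code in enumerate(qcodes):
        if code >= 0:
            qpos_by_code.setdefault(int(code), []).append(qp)
    unique_q = np.fromiter(qpos_by_code.keys(), dtype=np.int64, count=len(qpos_by_code))
    hits_mask = np.isin(subject_codes, unique_q)
    spositions = np.nonzero(hits_mask)[0]
    if spositions.size == 0:
        return []
    diags, spos_list = [], []
    for sp in spositions:
        for qp in qpos_by_code[int(subject_codes[sp])]:
            diags.append(int(sp) - qp)
            spos_list.append(int(sp))
    order = np.lexsort((spos_list, diags))
    diags_arr = np.asarray(diags)[order]
    spos_arr = np.asarray(spos_list)[order]
    qlen = len(query)
    windows: list[tuple[int, int]] = []
    group_start = 0
    for i in range(1, diags_arr.size + 1):
        if i == diags_arr.size or diags_arr[i] - diags_arr[i - 1] > params.diag_band:
            group = spos_arr[group_start:i]
            if group.size >= params.min_seeds:
                windows.append((max(0, int(group.min()) - qlen - 10), int(group.max()) + qlen + 10))
            group_start = i
    if not windows:
        return []
    windows.sort()
    merged = [windows[0]]
    for s, e in windows[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# alignment extraction


def _frame_to_forward(frame_idx: int, contig_len: int, ps: int, pe: int) -> tuple[int, int, str, int]:
    """Map a peptide interval [ps, pe) in frame ``frame_idx`` to forward-strand
    nucleotide coordinates. Frames 0-2 are forward, 3-5 reverse-complement."""
    if frame_idx < 3:
        f = frame_idx
        return f + 3 * ps, f + 3 * pe, "+", f
    rf = frame_idx - 3
    start = contig_len - rf - 3 * pe
    end = contig_len - rf - 3 * ps
    return start, end, "-", rf


def _extract_hits(query_id, query, subject, offset, contig, contig_len,
                  frame_idx, search_space, params, out):
    if len(subject) < len(query) // 4 or not subject:
        return
    aln = align.local_align(subject, query)
    if aln is None:
        return
    raw = float(aln.score)
    if raw < params.score_min:
        return
    t0, t1 = int(aln.coordinates[0, 0]), int(aln.coordinates[0, -1])
    bits = align.bit_score(raw)
    ev = align.evalue(raw, len(query), search_space)
    if ev <= params.evalue_max:
        start_bp, end_bp, strand, frame = _frame_to_forward(
            frame_idx, contig_len, offset + t0, offset + t1
        )
        out.append(
            RawHit(
                contig=contig,
                start_bp=start_bp,
                end_bp=end_bp,
                strand=strand,
                frame=frame,
                query_id=query_id,
                aligned_query_aa=str(aln[1]),
                aligned_subject_aa=str(aln[0]),
                matched_peptide=subject[t0:t1],
                score_raw=raw,
                score_bits=bits,
                evalue=ev,
            )
        )
    # non-overlapping secondary alignments in the flanks
    _extract_hits(query_id, query, subject[:t0], offset, contig, contig_len,
                  frame_idx, search_space, params, out)
    _extract_hits(query_id, query, subject[t1:], offset + t1, contig, contig_len,
                  frame_idx, search_space, params, out)


def search(queries, assembly: dict[str, str], params: SearchParams | None = None,
           method: str = "seed") -> list[RawHit]:
    """Search protein queries against all six frames of an assembly.

    ``queries`` is a list of objects with ``id`` and ``aa_seq`` attributes
    (e.g. :class:`~eprvscan.refdata.ReferenceRT`) or (id, seq) tuples.
    Returns hits with ``evalue <= params.evalue_max`` and
    ``score_raw >= params.score_min``, mapped to forward-strand coordinates.
    """
    if params is None:
        params = SearchParams()
    if method not in ("seed", "exhaustive"):
        raise ValueError(f"unknown search method {method!r}")
    qlist = [(q.id, q.aa_seq) if hasattr(q, "id") else tuple(q) for q in queries]
    if not qlist:
        raise ValueError("no queries")

    frames_by_contig: dict[str, list[str]] = {}
    for contig, seq in assembly.items():
        if len(seq) < 3:
            logger.warning("contig %s shorter than one codon; skipped", contig)
            continue
        frames_by_contig[contig] = six_frame_translate(seq)
    search_space = sum(
        len(pep) for frames in frames_by_contig.values() for pep in frames
    )

    hits: list[RawHit] = []
    for contig, frames in frames_by_contig.items():
        contig_len = len(assembly[contig])
        frame_codes = [_kmer_codes(pep) for pep in frames] if method == "seed" else None
        for frame_idx, pep in enumerate(frames):
            for query_id, query_seq in qlist:
                if method == "seed":
                    windows = _seed_windows(query_seq, frame_codes[frame_idx], params)
                else:
                    windows = [(0, len(pep))]
                for ws, we in windows:
                    _extract_hits(
                        query_id, query_seq, pep[ws:we], ws, contig, contig_len,
                        frame_idx, search_space, params, hits,
                    )
    hits.sort(key=lambda h: (h.contig, h.start_bp, h.end_bp, -h.score_raw, h.query_id))
    logger.info("search: %d hits over %d contigs", len(hits), len(frames_by_contig))
    return hits


# ---------------------------------------------------------------------------
# external tabular adapter and writers

_TAB_COLUMNS = 12  # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore


def parse_external_hits(tabular_path) -> list[RawHit]:
    """Adapt 12+-column external tabular search output (optionally with a
    13th subject-peptide column) to :class:`RawHit` records.

    Subject coordinates are converted from 1-based inclusive to 0-based
    half-open forward-strand; strand is inferred from sstart > send. The
    reading frame within the hit strand is not present in the tabular
    format and is recorded as ``start_bp % 3`` (forward) or 0 (reverse).
    """
    hits: list[RawHit] = []
    with open(tabular_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < _TAB_COLUMNS:
                raise ValueError(f"line {lineno}: expected >= 12 columns, got {len(fields)}")
            try:
                qseqid, sseqid = fields[0], fields[1]
                sstart, send = int(fields[8]), int(fields[9])
                ev, bits = float(fields[10]), float(fields[11])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            peptide = fields[12].replace("-", "") if len(fields) > 12 else ""
            if sstart <= send:
                start_bp, end_bp, strand = sstart - 1, send, "+"
                frame = start_bp % 3
            else:
                start_bp, end_bp, strand = send - 1, sstart, "-"
                frame = 0
            hits.append(
                RawHit(
                    contig=sseqid,
                    start_bp=start_bp,
                    end_bp=end_bp,
                    strand=strand,
                    frame=frame,
                    query_id=qseqid,
                    aligned_query_aa="",
                    aligned_subject_aa=peptide,
                    matched_peptide=peptide,
                    score_raw=float("nan"),
                    score_bits=bits,
                    evalue=ev,
                )
            )
    return hits


HIT_TSV_COLUMNS = [
    "contig", "start_bp", "end_bp", "strand", "frame", "query_id",
    "score_raw", "score_bits", "evalue", "matched_peptide",
    "aligned_query_aa", "aligned_subject_aa",
]


def write_hits_tsv(hits, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(HIT_TSV_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    str(getattr(h, c)) if c not in ("score_raw", "score_bits", "evalue")
                    else format(getattr(h, c), ".6g")
                    for c in HIT_TSV_COLUMNS
                )
                + "\n"
            )


def read_hits_tsv(path) -> list[RawHit]:
    hits = []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if header is None:
                header = line.rstrip("\n").split("\t")
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            hits.append(
                RawHit(
                    contig=row["contig"],
                    start_bp=int(row["start_bp"]),
                    end_bp=int(row["end_bp"]),
                    strand=row["strand"],
                    frame=int(row["frame"]),
                    query_id=row["query_id"],
                    aligned_query_aa=row["aligned_query_aa"],
                    aligned_subject_aa=row["aligned_subject_aa"],
                    matched_peptide=row["matched_peptide"],
                    score_raw=float(row["score_raw"]),
                    score_bits=float(row["score_bits"]),
                    evalue=float(row["evalue"]),
                )
            )
    return hits


def write_hits_bed(hits, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.contig}\t{h.start_bp}\t{h.end_bp}\t{h.query_id}\t"
                f"{int(min(1000, h.score_bits))}\t{h.strand}\n"
            )
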