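"""Reference data: RT-domain library, host taxonomy, divergence times, motifs.

The pipeline classifies candidate loci against a labelled library of
reverse-transcriptase central-domain proteins: sequences from the eleven
episomal Caulimoviridae genera and the exclusively endogenous OTUs
(lineage class ``caulimoviridae``), plus Ty3/Gypsy LTR-retrotransposon and
Retroviridae RTs that serve as decoy outgroups (lineage class
``retroelement``). Host taxonomy and a species/genus divergence-time table
support minimum insertion-age inference, and a small set of
position-constrained domain motifs supports element-architecture calls.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AA20

logger = logging.getLogger(__name__)

EPISOMAL_GENERA = (
    "Badnavirus",
    "Caulimovirus",
    "Vaccinivirus",
    "Soymovirus",
    "Cavemovirus",
    "Solendovirus",
    "Dioscovirus",
    "Rosadnavirus",
    "Tungrovirus",
    "Petuvirus",
    "Ruflodivirus",
)
ENDOGENOUS_OTUS = (
    "Florendovirus",
    "Xendovirus",
    "Yendovirus",
    "Zendovirus",
    "Gymnendovirus",
    "Fernendovirus",
)
CAULIMOVIRIDAE_OTUS = EPISOMAL_GENERA + ENDOGENOUS_OTUS + ("Wendovirus",)
RETROELEMENT_FAMILIES = (
    "Athila",
    "CRM",
    "Galadriel",
    "Ogre",
    "Reina",
    "Retand",
    "Tekay",
    "Retroviridae",
)

MOTIF_NAMES = (
    "zinc_finger",
    "movement_protein",
    "aspartic_proteinase_1",
    "aspartic_proteinase_2",
    "reverse_transcriptase",
    "rnaseh",
)


class RefDataError(ValueError):
    """Malformed or inconsistent reference data."""


class MissingDivergenceError(KeyError):
    """A host pair required for age inference is absent from the table."""


@dataclass(frozen=True)
class ReferenceRT:
    """A labelled RT central-domain protein sequence."""

    id: str
    lineage_class: str  # "caulimoviridae" | "retroelement"
    otu: str
    aa_seq: str

    def __post_init__(self):
        if self.lineage_class not in ("caulimoviridae", "retroelement"):
            raise RefDataError(f"{self.id}: bad lineage_class {self.lineage_class!r}")
        if not self.otu:
            raise RefDataError(f"{self.id}: empty OTU label")
        if self.lineage_class == "retroelement":
            if self.otu not in RETROELEMENT_FAMILIES:
                raise RefDataError(
                    f"{self.id}: retroelement OTU must be a retroelement family, got {self.otu!r}"
                )
        elif self.otu not in CAULIMOVIRIDAE_OTUS:
            raise RefDataError(f"{self.id}: unknown Caulimoviridae OTU {self.otu!r}")
        if len(self.aa_seq) < 100:
            raise RefDataError(f"{self.id}: RT domain shorter than 100 aa")
        bad = set(self.aa_seq) - set(AA20)
        if bad:
            raise RefDataError(f"{self.id}: invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class HostTaxonomy:
    """Taxonomic ranks of one assembly's host species."""

    species: str
    genus: str
    family: str
    order: str
    class_: str
    kingdom: str

    def __post_init__(self):
        for rank in ("species", "genus", "family", "order", "class_", "kingdom"):
            if not getattr(self, rank):
                raise RefDataError(f"host taxonomy: empty rank {rank}")


def load_reference_library(fasta_path, metadata_path) -> list[ReferenceRT]:
    """Load the RT reference library from FASTA + TSV metadata.

    Metadata columns: ``id``, ``lineage_class``, ``otu``; FASTA ids must
    match metadata rows one-to-one.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise RefDataError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise RefDataError(f"no records in {fasta_path}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"id", "lineage_class", "otu"}
    if not required.issubset(meta.columns):
        raise RefDataError(f"metadata must have columns {sorted(required)}")
    if meta["id"].duplicated().any():
        dup = meta.loc[meta["id"].duplicated(), "id"].iloc[0]
        raise RefDataError(f"duplicate metadata id {dup!r}")
    meta_ids = set(meta["id"])
    if meta_ids != set(seqs):
        missing = sorted(set(seqs) - meta_ids)[:3] + sorted(meta_ids - set(seqs))[:3]
        raise RefDataError(f"FASTA/metadata id mismatch, e.g. {missing}")
    records = [
        ReferenceRT(row.id, row.lineage_class, row.otu, seqs[row.id])
        for row in meta.itertuples()
    ]
    counts = Counter(r.lineage_class for r in records)
    logger.info(
        "reference library: %d records (%s)",
        len(records),
        ", ".join(f"{k}={v}" for k, v in sorted(counts.items())),
    )
    return records


def write_reference_library(records, fasta_path, metadata_path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.aa_seq), id=r.id, description="") for r in records),
        str(fasta_path),
        "fasta",
    )
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "lineage_class": [r.lineage_class for r in records],
            "otu": [r.otu for r in records],
        }
    ).to_csv(metadata_path, sep="\t", index=False)


def load_host_taxonomy(tsv_path) -> dict[str, HostTaxonomy]:
    """Load per-assembly host taxonomy keyed by species name.

    TSV columns: species, genus, family, order, class, kingdom.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    df = df.rename(columns={"class": "class_"})
    required = {"species", "genus", "family", "order", "class_", "kingdom"}
    if not required.issubset(df.columns):
        raise RefDataError(f"taxonomy must have columns {sorted(required)}")
    if df["species"].duplicated().any():
        raise RefDataError("duplicate species in taxonomy table")
    return {
        row.species: HostTaxonomy(
            row.species, row.genus, row.family, row.order, row.class_, row.kingdom
        )
        for row in df.itertuples()
    }


class DivergenceTable:
    """Symmetric lookup of divergence times (million years) for taxon pairs.

    Keys may be species or genus names; self-pairs are always 0. A missing
    pair raises :class:`MissingDivergenceError` rather than defaulting.
    """

    def __init__(self):
        self._pairs: dict[frozenset, float] = {}

    @classmethod
    def from_tsv(cls, tsv_path) -> "DivergenceTable":
        df = pd.read_csv(tsv_path, sep="\t")
        required = {"taxonA", "taxonB", "divergence_my"}
        if not required.issubset(df.columns):
            raise RefDataError(f"divergence table must have columns {sorted(required)}")
        table = cls()
        for row in df.itertuples():
            table.add(str(row.taxonA), str(row.taxonB), float(row.divergence_my))
        return table

    def add(self, a: str, b: str, divergence_my: float) -> None:
        if divergence_my < 0:
            raise RefDataError(f"negative divergence for ({a}, {b})")
        if a == b:
            if divergence_my != 0:
                raise RefDataError(f"self-pair ({a}, {a}) must have divergence 0")
            return
        key = frozenset((a, b))
        if key in self._pairs and self._pairs[key] != divergence_my:
            raise RefDataError(
                f"conflicting divergence for ({a}, {b}): "
                f"{self._pairs[key]} vs {divergence_my}"
            )
        self._pairs[key] = divergence_my

    def lookup(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        key = frozenset((a, b))
        try:
            return self._pairs[key]
        except KeyError:
            raise MissingDivergenceError(f"no divergence entry for ({a}, {b})") from None

    def __contains__(self, pair) -> bool:
        a, b = pair
        return a == b or frozenset((a, b)) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def pairs(self):
        for key, my in sorted(self._pairs.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(key)
            yield a, b, my

    def to_tsv(self, tsv_path) -> None:
        pd.DataFrame(list(self.pairs()), columns=["taxonA", "taxonB", "divergence_my"]).to_csv(
            tsv_path, sep="\t", index=False
        )


load_divergence_table = DivergenceTable.from_tsv


_TOKEN_RE = re.compile(r"^(?:(?P<lit>[A-Z])|\[(?P<set>[A-Z]+)\]|x(?:\((?P<n>\d+)\))?)$")


@dataclass(frozen=True)
class DomainMotif:
    """A position-constrained protein motif with a score threshold.

    ``pattern`` uses a Prosite-like syntax: dash-separated tokens that are a
    literal residue (``D``), a residue set (``[LIVM]``), or a wildcard
    (``x`` or ``x(4)``). The score of an occurrence is the number of
    constrained (non-wildcard) positions; all constrained positions must
    match. These are deliberately simple surrogates for profile models —
    the pipeline only needs domain presence and order.
    """

    name: str
    pattern: str
    consensus: str
    min_score: int
    _regex: re.Pattern = field(init=False, repr=False, compare=False)
    _n_constrained: int = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        parts = []
        n_constrained = 0
        for token in self.pattern.split("-"):
            m = _TOKEN_RE.match(token)
            if not m:
                raise RefDataError(f"motif {self.name}: bad token {token!r}")
            if m.group("lit"):
                parts.append(m.group("lit"))
                n_constrained += 1
            elif m.group("set"):
                parts.append(f"[{m.group('set')}]")
                n_constrained += 1
            else:
                parts.append("." * int(m.group("n") or 1))
        # overlapping occurrences via lookahead
        regex = re.compile(f"(?=({''.join(parts)}))")
        object.__setattr__(self, "_regex", regex)
        object.__setattr__(self, "_n_constrained", n_constrained)
        if self.min_score > n_constrained:
            raise RefDataError(
                f"motif {self.name}: min_score {self.min_score} exceeds "
                f"{n_constrained} constrained positions"
            )

    def scan(self, peptide: str) -> list[tuple[int, int]]:
        """All occurrences as (offset, score), score = constrained positions."""
        hits = []
        for m in self._regex.finditer(peptide):
            if self._n_constrained >= self.min_score:
                hits.append((m.start(), self._n_constrained))
        return hits

    def matches_consensus(self) -> bool:
        return any(off == 0 for off, _ in self.scan(self.consensus))


def builtin_motifs_path() -> Path:
    return Path(str(resources.files("eprvscan") / "data" / "motifs.yaml"))


def load_motifs(path=None) -> list[DomainMotif]:
    """Load the domain-motif set (packaged set by default) and validate it.

    Every motif must match its own consensus and all six domain roles must
    be represented.
    """
    path = builtin_motifs_path() if path is None else Path(path)
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    motifs = [
        DomainMotif(m["name"], m["pattern"], m["consensus"], int(m["min_score"]))
        for m in spec["motifs"]
    ]
    names = {m.name for m in motifs}
    missing = set(MOTIF_NAMES) - names
    if missing:
        raise RefDataError(f"motif set missing roles: {sorted(missing)}")
    for m in motifs:
        if not m.matches_consensus():
            raise RefDataError(f"motif {m.name} does not match its own consensus")
    return motifs
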