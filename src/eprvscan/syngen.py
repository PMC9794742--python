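"""Synthetic genome assemblies with a planted-EPRV truth ledger.

The simulator emulates the statistical structure the discovery pipeline
assumes: neutral background DNA with occasional N runs, reverse-translated
RT-domain implants at controlled amino-acid divergence, degenerate copies
(internal stop codons, frameshifting indels), tandem arrays closer than
the proximity-dedup window, bursts of identical copies marking recent
amplification, and Ty3/Gypsy retrotransposon decoys that the lineage
triage must reject. Every implant is recorded in a :class:`TruthSet`
that round-trips through GFF3, so recovery can be scored exactly.

All randomness flows through ``numpy.random.default_rng`` seeded from the
caller; identical (seed, config) pairs give byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .dna import AA_TO_CODONS, revcomp, translate
from .align import AA20
from .fileio import Gff3Record, read_gff3, write_gff3
from .refdata import (
    CAULIMOVIRIDAE_OTUS,
    ENDOGENOUS_OTUS,
    EPISOMAL_GENERA,
    RETROELEMENT_FAMILIES,
    DivergenceTable,
    HostTaxonomy,
    ReferenceRT,
    load_motifs,
)

# ---------------------------------------------------------------------------
# background sequence


def generate_background(
    n_contigs: int,
    length_bp: int,
    gc_fraction: float = 0.40,
    n_run_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Random assembly: ``n_contigs`` contigs of ``length_bp`` each.

    Bases are i.i.d. with P(G)=P(C)=gc_fraction/2. ``n_run_rate`` is the
    expected number of N runs per base (runs are 50-500 bp, overwriting
    background); assemblies mimic draft genomes with masked/unknown gaps.
    """
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    assembly: dict[str, str] = {}
    for i in range(n_contigs):
        bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length_bp, p=p)
        if n_run_rate > 0:
            n_runs = rng.poisson(n_run_rate * length_bp)
            for _ in range(n_runs):
                run_len = int(rng.integers(50, 501))
                start = int(rng.integers(0, max(1, length_bp - run_len)))
                bases[start : start + run_len] = ord("N")
        assembly[f"contig{i + 1}"] = bases.tobytes().decode("ascii")
    return assembly


# ---------------------------------------------------------------------------
# coding-sequence construction


def reverse_translate(
    aa_seq: str, codon_policy: str = "uniform", seed: int | np.random.Generator = 0
) -> str:
    """Encode a protein as DNA. ``uniform`` draws synonymous codons uniformly
    at random; ``first`` always takes the alphabetically first codon."""
    if "*" in aa_seq:
        raise ValueError("aa_seq must not contain stop characters")
    rng = np.random.default_rng(seed)
    codons = []
    for aa in aa_seq:
        try:
            options = AA_TO_CODONS[aa]
        except KeyError:
            raise ValueError(f"invalid amino acid {aa!r}") from None
        if codon_policy == "uniform":
            codons.append(options[int(rng.integers(len(options)))])
        elif codon_policy == "first":
            codons.append(options[0])
        else:
            raise ValueError(f"unknown codon_policy {codon_policy!r}")
    return "".join(codons)


def mutate_protein(aa_seq: str, n_substitutions: int, rng: np.random.Generator) -> str:
    """Substitute ``n_substitutions`` distinct positions with different residues."""
    if n_substitutions > len(aa_seq):
        raise ValueError("more substitutions than positions")
    positions = rng.choice(len(aa_seq), size=n_substitutions, replace=False)
    seq = list(aa_seq)
    for pos in positions:
        current = seq[pos]
        alternatives = [a for a in AA20 if a != current]
        seq[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(seq)


def mutate_coding(
    dna: str, target_aa_divergence: float, seed: int | np.random.Generator = 0
) -> str:
    """Mutate a stop-free coding sequence to a target amino-acid divergence.

    Exactly ``round(target * n_aa)`` codons are replaced by codons of a
    different (non-stop) amino acid, so the realised divergence matches the
    target to within rounding. No stop codons are ever introduced.
    """
    if len(dna) % 3 != 0:
        raise ValueError("coding sequence length must be divisible by 3")
    peptide = translate(dna)
    if "*" in peptide:
        raise ValueError("input encodes a stop codon")
    if not 0.0 <= target_aa_divergence <= 0.95:
        raise ValueError("target_aa_divergence must be in [0, 0.95]")
    rng = np.random.default_rng(seed)
    n_aa = len(peptide)
    k = round(target_aa_divergence * n_aa)
    if k == 0:
        return dna
    positions = rng.choice(n_aa, size=k, replace=False)
    codons = [dna[3 * i : 3 * i + 3] for i in range(n_aa)]
    for pos in positions:
        current = peptide[pos]
        alternatives = [a for a in AA20 if a != current]
        new_aa = alternatives[int(rng.integers(len(alternatives)))]
        options = AA_TO_CODONS[new_aa]
        codons[pos] = options[int(rng.integers(len(options)))]
    return "".join(codons)


# ---------------------------------------------------------------------------
# implant specification and truth ledger

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class ImplantSpec:
    """One planting request: n copies of a reference RT with controlled
    divergence, degeneration and placement."""

    source_ref_id: str
    n_copies: int = 1
    aa_divergence: float = 0.0
    degeneration: str = "intact"  # intact | internal_stop | frameshift
    placement: str = "dispersed"  # dispersed | tandem
    tandem_gap_bp: int = 200
    strand_policy: str = "random"  # random | plus | minus

    def __post_init__(self):
        if self.degeneration not in ("intact", "internal_stop", "frameshift"):
            raise ValueError(f"bad degeneration {self.degeneration!r}")
        if self.placement not in ("dispersed", "tandem"):
            raise ValueError(f"bad placement {self.placement!r}")
        if self.strand_policy not in ("random", "plus", "minus"):
            raise ValueError(f"bad strand_policy {self.strand_policy!r}")
        if self.tandem_gap_bp < 0:
            raise ValueError("tandem_gap_bp must be >= 0")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    contig: str
    start: int  # 0-based half-open, forward strand
    end: int
    strand: str
    source_ref_id: str
    degeneration: str
    copy_group_id: str
    placement: str = "dispersed"
    lineage_class: str = "caulimoviridae"

    def element_dna(self, assembly: dict[str, str]) -> str:
        seq = assembly[self.contig][self.start : self.end]
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class TruthSet:
    records: list[TruthRecord] = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_class(self) -> dict[str, list[TruthRecord]]:
        """Partition records into scoring classes: decoy, intact (dispersed),
        intact_tandem, internal_stop, frameshift."""
        out: dict[str, list[TruthRecord]] = {}
        for rec in self.records:
            if rec.lineage_class == "retroelement":
                key = "decoy"
            elif rec.degeneration == "intact" and rec.placement == "tandem":
                key = "intact_tandem"
            else:
                key = rec.degeneration
            out.setdefault(key, []).append(rec)
        return out

    def to_gff3(self, path, header_lines=()) -> None:
        records = [
            Gff3Record(
                seqid=r.contig,
                type="EPRV_truth",
                start=r.start,
                end=r.end,
                strand=r.strand,
                attributes={
                    "ID": f"truth{i}",
                    "source_ref_id": r.source_ref_id,
                    "degeneration": r.degeneration,
                    "copy_group_id": r.copy_group_id,
                    "placement": r.placement,
                    "lineage_class": r.lineage_class,
                },
            )
            for i, r in enumerate(self.records)
        ]
        write_gff3(records, path, header_lines=header_lines)

    @classmethod
    def from_gff3(cls, path) -> "TruthSet":
        records = []
        for g in read_gff3(path):
            if g.type != "EPRV_truth":
                continue
            records.append(
                TruthRecord(
                    contig=g.seqid,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    source_ref_id=g.attributes["source_ref_id"],
                    degeneration=g.attributes["degeneration"],
                    copy_group_id=g.attributes["copy_group_id"],
                    placement=g.attributes.get("placement", "dispersed"),
                    lineage_class=g.attributes.get("lineage_class", "caulimoviridae"),
                )
            )
        return cls(records)


class PlacementError(RuntimeError):
    """Could not place an implant without violating separation constraints."""


_INTACT_AA = 300  # the intactness threshold a lesion must defeat
# a local alignment can extend a few residues past a frameshift point on
# chance matches in the shifted sequence; keep fragments this far below the
# threshold so a lesion always defeats the >=300 aa criterion
_LESION_MARGIN_AA = 10


def _degenerate(dna: str, degeneration: str, rng: np.random.Generator) -> str:
    if degeneration == "intact":
        return dna
    n_codons = len(dna) // 3
    # middle 80%, further constrained so BOTH flanking fragments stay below
    # the intactness threshold minus the chance-extension margin (a lesion
    # near an end of a long element would otherwise leave one >=300 aa
    # gapless match)
    limit = _INTACT_AA - _LESION_MARGIN_AA
    lo = max(int(0.1 * n_codons), n_codons - limit)
    hi = min(int(0.9 * n_codons), limit - 1)
    if lo > hi:
        raise ValueError(
            f"element of {n_codons} codons too long to degenerate with one lesion"
        )
    if degeneration == "internal_stop":
        pos = int(rng.integers(lo, hi + 1))
        stop = STOP_CODONS[int(rng.integers(3))]
        return dna[: 3 * pos] + stop + dna[3 * pos + 3 :]
    # frameshift: 1- or 2-bp deletion
    del_len = int(rng.integers(1, 3))
    pos = int(rng.integers(3 * lo, 3 * hi))
    return dna[:pos] + dna[pos + del_len :]


def implant(
    assembly: dict[str, str],
    library: list[ReferenceRT],
    specs: list[ImplantSpec],
    seed: int | np.random.Generator = 0,
    min_separation: int = 2000,
    max_retries: int = 100,
) -> tuple[dict[str, str], TruthSet]:
    """Plant elements into a copy of ``assembly`` and return the truth ledger.

    Implants overwrite background bases (contig lengths are preserved).
    Placement units (a dispersed copy, or a whole tandem block) are kept at
    least ``min_separation`` bp from each other and from contig ends, so
    only deliberately tandem copies fall inside the proximity-dedup window.
    """
    rng = np.random.default_rng(seed)
    refs = {r.id: r for r in library}
    new_assembly = dict(assembly)
    contig_names = sorted(new_assembly)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_names}
    truth: list[TruthRecord] = []

    def conflicts(contig: str, start: int, end: int) -> bool:
        for s, e in occupied[contig]:
            if start < e + min_separation and s < end + min_separation:
                return True
        return False

    def place_unit(total_len: int) -> tuple[str, int]:
        for _ in range(max_retries):
            contig = contig_names[int(rng.integers(len(contig_names)))]
            clen = len(new_assembly[contig])
            if clen < total_len + 2 * min_separation:
                continue
            start = int(rng.integers(min_separation, clen - total_len - min_separation))
            if not conflicts(contig, start, start + total_len):
                occupied[contig].append((start, start + total_len))
                return contig, start
        raise PlacementError(f"no room for a {total_len} bp implant after {max_retries} tries")

    group_counter = 0
    for spec in specs:
        ref = refs[spec.source_ref_id]
        group_counter += 1
        group_id = f"grp{group_counter:03d}"
        copies = []
        for _ in range(spec.n_copies):
            dna = reverse_translate(ref.aa_seq, "uniform", rng)
            if spec.aa_divergence > 0:
                dna = mutate_coding(dna, spec.aa_divergence, rng)
            if spec.placement == "tandem" and copies:
                # tandem arrays are copies of the same insertion event
                dna = copies[0][0]
            dna = _degenerate(dna, spec.degeneration, rng)
            if spec.strand_policy == "random":
                strand = "+" if rng.random() < 0.5 else "-"
            else:
                strand = "+" if spec.strand_policy == "plus" else "-"
            copies.append((dna, strand))
        if spec.placement == "tandem":
            total = sum(len(d) for d, _ in copies) + spec.tandem_gap_bp * (len(copies) - 1)
            contig, start = place_unit(total)
            pos = start
            for dna, strand in copies:
                placed = revcomp(dna) if strand == "-" else dna
                seq = new_assembly[contig]
                new_assembly[contig] = seq[:pos] + placed + seq[pos + len(placed) :]
                truth.append(
                    TruthRecord(
                        contig, pos, pos + len(placed), strand, ref.id,
                        spec.degeneration, group_id, "tandem", ref.lineage_class,
                    )
                )
                pos += len(placed) + spec.tandem_gap_bp
        else:
            for dna, strand in copies:
                contig, start = place_unit(len(dna))
                placed = revcomp(dna) if strand == "-" else dna
                seq = new_assembly[contig]
                new_assembly[contig] = seq[:start] + placed + seq[start + len(placed) :]
                truth.append(
                    TruthRecord(
                        contig, start, start + len(placed), strand, ref.id,
                        spec.degeneration, group_id, "dispersed", ref.lineage_class,
                    )
                )
    truth.sort(key=lambda r: (r.contig, r.start))
    return new_assembly, TruthSet(truth)


# ---------------------------------------------------------------------------
# synthetic reference library

#: fixed seed: the synthetic library plays the role of a curated, static
#: reference collection, identical across runs and machines.
LIBRARY_SEED = 20220901
_ANCESTOR_LEN = 340
_OTU_DIVERGENCE = 0.35
_DECOY_DIVERGENCE = 0.45
_MEMBER_DIVERGENCE = 0.08

_EPISOMAL_COUNTS = dict(zip(EPISOMAL_GENERA, (10, 10, 10, 10, 10, 9, 9, 9, 9, 9, 9)))
_ENDOGENOUS_COUNTS = dict(zip(ENDOGENOUS_OTUS, (11, 11, 11, 10, 10, 10)))


def _ancestor_rt(rng: np.random.Generator) -> str:
    aa = "".join(rng.choice(list(AA20), size=_ANCESTOR_LEN))
    # embed the canonical polymerase YxDD box so reference RTs carry it
    box = "YVDDILGKA"
    mid = _ANCESTOR_LEN // 2
    return aa[:mid] + box + aa[mid + len(box) :]


def synthetic_reference_library(seed: int = LIBRARY_SEED) -> list[ReferenceRT]:
    """A 182-sequence labelled RT library emulating the composition of the
    survey's reference collection: 104 sequences from the 11 episomal
    Caulimoviridae genera, 63 from the 6 exclusively endogenous OTUs, 14
    Ty3/Gypsy retrotransposon RTs (7 families) and 1 Retroviridae RT.

    OTU consensus sequences diverge ~35% from a shared RT ancestor
    (pairwise OTU identity ~43%, safely below the 60% clustering cut-off);
    members sit ~8% from their OTU consensus. Decoy families diverge ~45%,
    far enough that lineage triage separates them, close enough that a
    translated search at E<=1e-10 still finds them.
    """
    rng = np.random.default_rng(seed)
    ancestor = _ancestor_rt(rng)
    records: list[ReferenceRT] = []

    def add_group(otu: str, count: int, lineage: str, consensus_div: float):
        consensus = mutate_protein(ancestor, round(consensus_div * _ANCESTOR_LEN), rng)
        for i in range(count):
            member = mutate_protein(consensus, round(_MEMBER_DIVERGENCE * _ANCESTOR_LEN), rng)
            records.append(ReferenceRT(f"{otu}_{i + 1:02d}", lineage, otu, member))

    for otu in EPISOMAL_GENERA:
        add_group(otu, _EPISOMAL_COUNTS[otu], "caulimoviridae", _OTU_DIVERGENCE)
    for otu in ENDOGENOUS_OTUS:
        add_group(otu, _ENDOGENOUS_COUNTS[otu], "caulimoviridae", _OTU_DIVERGENCE)
    for fam in RETROELEMENT_FAMILIES[:-1]:  # 7 Ty3/Gypsy families, 2 each
        add_group(fam, 2, "retroelement", _DECOY_DIVERGENCE)
    add_group("Retroviridae", 1, "retroelement", _DECOY_DIVERGENCE + 0.05)
    assert len(records) == 182
    return records


# ---------------------------------------------------------------------------
# wendovirus-architecture element

_FILLER_ALPHABET = [a for a in AA20 if a != "M"]


def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_FILLER_ALPHABET, size=n))


def build_wendovirus_element(seed: int = 11, flank_bp: int = 150) -> tuple[str, dict]:
    """Construct a DNA element with the wendovirus diagnostic architecture.

    Four partially overlapping ORFs in alternating frames: ORF1 carries a
    zinc-finger motif (coat-protein-like), ORF2 a movement protein plus the
    first aspartic proteinase, ORF3 the second aspartic proteinase followed
    by the reverse transcriptase and RNase H, and ORF4 a conserved protein
    with no known domains. Successive ORFs overlap by 4 bp (the downstream
    ORF overwrites the upstream stop codon, shifting frame), mimicking the
    compact overlapping-ORF organisation of the ~7.7 kb element.

    Returns (dna, info) where info records intended ORF starts and peptides.
    """
    rng = np.random.default_rng(seed)
    motifs = {m.name: m.consensus for m in load_motifs()}
    orf_peptides = [
        "M" + _filler(rng, 60) + motifs["zinc_finger"] + _filler(rng, 380),
        "M" + _filler(rng, 80) + motifs["movement_protein"] + _filler(rng, 120)
        + motifs["aspartic_proteinase_1"] + _filler(rng, 390),
        "M" + _filler(rng, 40) + motifs["aspartic_proteinase_2"] + _filler(rng, 150)
        + motifs["reverse_transcriptase"] + _filler(rng, 200)
        + motifs["rnaseh"] + _filler(rng, 450),
        "M" + _filler(rng, 520),
    ]
    flank5 = generate_background(1, flank_bp, 0.4, 0.0, rng)["contig1"]
    flank3 = generate_background(1, flank_bp, 0.4, 0.0, rng)["contig1"]
    seq = flank5
    starts = []
    for k, pep in enumerate(orf_peptides):
        orf_dna = reverse_translate(pep, "uniform", rng) + "TAA"
        pos = len(seq) if k == 0 else len(seq) - 4
        seq = seq[:pos] + orf_dna
        starts.append(pos)
    seq = seq + flank3
    info = {"orf_starts": starts, "orf_peptides": orf_peptides, "length": len(seq)}
    return seq, info


# ---------------------------------------------------------------------------
# default simulation scenario

SIM_SPECIES = "Simulatus hostus"


def simulated_taxonomy(species: str = SIM_SPECIES) -> dict[str, HostTaxonomy]:
    genus = species.split()[0]
    return {
        species: HostTaxonomy(
            species=species,
            genus=genus,
            family="Simulataceae",
            order="Simulales",
            class_="Magnoliopsida",
            kingdom="Plantae",
        )
    }


@dataclass
class SimulationBundle:
    assembly: dict[str, str]
    truth: TruthSet
    library: list[ReferenceRT]
    taxonomy: dict[str, HostTaxonomy]
    divergence: DivergenceTable
    species: str
    config: dict


def default_scenario_specs(library: list[ReferenceRT]) -> list[ImplantSpec]:
    """The standard validation scenario: 20 intact dispersed Caulimoviridae
    implants at 0-10% aa divergence, a 12-copy identical burst, a 5-copy
    tandem array with 200 bp gaps, 10 internal-stop and 10 frameshift
    copies, and 10 Ty3/Gypsy decoys."""
    by_otu: dict[str, list[ReferenceRT]] = {}
    for rec in library:
        by_otu.setdefault(rec.otu, []).append(rec)
    caulimo_otus = [o for o in CAULIMOVIRIDAE_OTUS if o in by_otu]
    decoy_fams = [f for f in RETROELEMENT_FAMILIES if f != "Retroviridae" and f in by_otu]

    def pick(otu_list, i, member=0):
        group = by_otu[otu_list[i % len(otu_list)]]
        return group[member % len(group)].id

    specs: list[ImplantSpec] = []
    divergences = np.linspace(0.0, 0.10, 20)
    for i, div in enumerate(divergences):
        specs.append(ImplantSpec(pick(caulimo_otus, i, member=1), 1, float(div), "intact"))
    specs.append(ImplantSpec(pick(caulimo_otus, 0, member=2), 12, 0.0, "intact"))
    specs.append(
        ImplantSpec(pick(caulimo_otus, 1, member=2), 5, 0.0, "intact", "tandem", 200)
    )
    for i in range(10):
        specs.append(ImplantSpec(pick(caulimo_otus, i, member=3), 1, 0.05, "internal_stop"))
    for i in range(10):
        specs.append(ImplantSpec(pick(caulimo_otus, i, member=4), 1, 0.05, "frameshift"))
    for i in range(10):
        specs.append(ImplantSpec(pick(decoy_fams, i, member=i // len(decoy_fams)), 1, 0.05))
    return specs


def default_scenario(
    seed: int = 0,
    n_contigs: int = 5,
    contig_bp: int = 400_000,
    gc_fraction: float = 0.40,
    n_run_rate: float = 2e-5,
) -> SimulationBundle:
    """Simulate the standard 2 Mb validation genome (5 x 400 kb contigs)."""
    rng = np.random.default_rng(seed)
    library = synthetic_reference_library()
    background = generate_background(n_contigs, contig_bp, gc_fraction, n_run_rate, rng)
    specs = default_scenario_specs(library)
    assembly, truth = implant(background, library, specs, rng)
    config = {
        "seed": seed,
        "n_contigs": n_contigs,
        "contig_bp": contig_bp,
        "gc_fraction": gc_fraction,
        "n_run_rate": n_run_rate,
        "n_specs": len(specs),
        "species": SIM_SPECIES,
    }
    return SimulationBundle(
        assembly=assembly,
        truth=truth,
        library=library,
        taxonomy=simulated_taxonomy(),
        divergence=DivergenceTable(),
        species=SIM_SPECIES,
        config=config,
    )
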