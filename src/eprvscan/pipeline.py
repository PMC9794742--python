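"""End-to-end pipeline: search -> screen -> cluster -> classify -> age -> annotate.

`run_pipeline` ties the stage modules together under a single
:class:`PipelineConfig` whose defaults are the survey's stated parameters
(E <= 1e-10, >= 300 aa intact, 1500 bp proximity dedup, 60%/100% identity
clustering, >= 10 identical copies for amplification). It writes one run
directory with per-stage TSV/GFF3/FASTA/Newick outputs, stage-level
funnel logging (counts in/out of every filter) and a manifest recording
config, seed, package versions and input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, annotate, cluster, homsearch, phylo, refdata, report, screen
from .dna import revcomp
from .fileio import Gff3Record, write_fasta_dict, write_gff3

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable pipeline parameters; defaults are the survey's stated values."""

    evalue_max: float = 1e-10
    score_min: float = 50.0
    min_aa: int = 300
    dedup_bp: int = 1500
    cluster_thresholds: tuple[float, float] = (0.60, 1.00)
    min_copies: int = 10
    bootstrap_reps: int = 0
    seed: int = 0
    window_bp: int = 5000
    min_orf_aa: int = 100
    otu_ceiling: float = phylo.OTU_DISTANCE_CEILING
    search_method: str = "seed"

    def __post_init__(self):
        for name in ("evalue_max", "min_aa", "dedup_bp", "min_copies", "window_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cluster_thresholds"] = list(self.cluster_thresholds)
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    outdir: Path
    hits: list
    candidates: list
    clusters60: cluster.ClusterSet
    clusters100: cluster.ClusterSet
    amplification: list
    cluster_assignments: dict[str, phylo.OTUAssignment]
    candidate_assignments: dict[str, phylo.OTUAssignment]
    ages: dict[str, phylo.AgeEstimate]
    annotations: list
    summary_rows: list
    tree_newick: str | None
    manifest: dict


def select_queries(library, per_otu: int = 1):
    """Default query set: the first ``per_otu`` members (by id) of every
    Caulimoviridae OTU present in the library."""
    by_otu: dict[str, list] = {}
    for rec in library:
        if rec.lineage_class == "caulimoviridae":
            by_otu.setdefault(rec.otu, []).append(rec)
    queries = []
    for otu in sorted(by_otu):
        queries.extend(sorted(by_otu[otu], key=lambda r: r.id)[:per_otu])
    return queries


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    assembly: dict[str, str],
    taxonomy: dict[str, refdata.HostTaxonomy],
    library: list[refdata.ReferenceRT],
    divergence_table: refdata.DivergenceTable | None,
    outdir,
    genome: str | None = None,
    input_paths: dict[str, str] | None = None,
) -> PipelineResult:
    """Run the full discovery pipeline on one assembly.

    ``genome`` names the assembly; with a single-species taxonomy it
    defaults to that species. A missing divergence table downgrades the
    age stage to a warning; any other stage failure raises
    :class:`StageError` (outputs of completed stages are retained).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if genome is None:
        if len(taxonomy) != 1:
            raise ValueError("genome must be named when taxonomy has several species")
        genome = next(iter(taxonomy))
    host = taxonomy[genome]

    run_id = hashlib.sha256(
        json.dumps({"config": config.to_dict(), "genome": genome}, sort_keys=True).encode()
    ).hexdigest()[:12]
    header = [f"run_id: {run_id}", f"eprvscan {__version__}"]
    stage_counts: dict[str, int] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - rethrown with stage context
                raise StageError(name, exc) from exc
        return wrap

    # -- search ------------------------------------------------------------
    def _search():
        queries = select_queries(library)
        params = homsearch.SearchParams(
            evalue_max=config.evalue_max, score_min=config.score_min
        )
        hits = homsearch.search(queries, assembly, params, method=config.search_method)
        homsearch.write_hits_tsv(hits, outdir / "hits.tsv", header)
        homsearch.write_hits_bed(hits, outdir / "hits.bed")
        return hits

    hits = stage("search")(_search)
    stage_counts["hits"] = len(hits)

    # -- screen ------------------------------------------------------------
    def _screen():
        cands = screen.screen_hits(
            hits, library, host, genome=genome,
            min_aa=config.min_aa, window_bp=config.dedup_bp,
        )
        screen.write_candidates_fasta(cands, outdir / "candidates.fa")
        screen.write_candidates_gff3(cands, outdir / "candidates.gff3", header)
        screen.write_candidates_tsv(cands, outdir / "candidates.tsv", header)
        return cands

    candidates = stage("screen")(_screen)
    stage_counts["candidates"] = len(candidates)

    # -- cluster -----------------------------------------------------------
    def _cluster():
        t60, t100 = config.cluster_thresholds
        c60 = cluster.greedy_cluster(candidates, t60, prefix="cluster60-") if candidates else \
            cluster.ClusterSet(t60, "global")
        c100 = cluster.greedy_cluster(candidates, t100, scope="per_genome",
                                      prefix="cluster100-") if candidates else \
            cluster.ClusterSet(t100, "per_genome")
        bursts = cluster.find_amplification(candidates, config.min_copies, t100) \
            if candidates else []
        cluster.write_cluster_tsv(c60, outdir / "clusters60.tsv", header)
        cluster.write_cluster_tsv(c100, outdir / "clusters100.tsv", header)
        with open(outdir / "amplification.tsv", "w") as fh:
            fh.write(f"# {header[0]}\ngenome\tcluster_id\tn_copies\totu\n")
            for b in bursts:
                fh.write(f"{b.genome}\t{b.cluster.cluster_id}\t{b.n_copies}\t{b.otu or ''}\n")
        return c60, c100, bursts

    clusters60, clusters100, amplification = stage("cluster")(_cluster)
    stage_counts["clusters60"] = len(clusters60)
    stage_counts["clusters100"] = len(clusters100)

    # -- classify ----------------------------------------------------------
    def _classify():
        cluster_assign: dict[str, phylo.OTUAssignment] = {}
        seq_of = {c.id: c.aa_seq for c in candidates}
        for cl in clusters60.clusters:
            rep = cl.representative
            cluster_assign[cl.cluster_id] = phylo.assign_otu(
                rep, seq_of[rep], library, ceiling=config.otu_ceiling
            )
        with open(outdir / "assignments.tsv", "w") as fh:
            fh.write(f"# {header[0]}\ncluster_id\trepresentative\totu\tsupport\tdistance\tnearest_ref\n")
            for cl in clusters60.clusters:
                a = cluster_assign[cl.cluster_id]
                fh.write(
                    f"{cl.cluster_id}\t{a.id}\t{a.otu}\t{a.support:.3f}\t"
                    f"{a.distance:.4f}\t{a.nearest_ref}\n"
                )
        return cluster_assign

    cluster_assignments = stage("classify")(_classify)
    membership = clusters60.membership()
    candidate_assignments = {
        member: cluster_assignments[cid] for member, cid in membership.items()
    }
    for b in amplification:
        rep = b.cluster.representative
        cid = membership.get(rep)
        if cid and cid in cluster_assignments:
            b.otu = cluster_assignments[cid].otu

    # -- tree --------------------------------------------------------------
    def _tree():
        reps = [(cl.representative, cl.sequences[cl.representative])
                for cl in clusters60.clusters]
        refs = [(r.id, r.aa_seq) for r in select_queries(library)]
        items = reps + refs
        if len(items) < 3:
            logger.warning("tree: fewer than 3 taxa, skipped")
            return None
        if config.bootstrap_reps > 0:
            tree = phylo.bootstrap_support(items, config.bootstrap_reps, seed=config.seed)
        else:
            tree = phylo.nj_tree(phylo.pairwise_distances(items))
        newick = str(tree).strip()
        (outdir / "tree.nwk").write_text(newick + "\n")
        return newick

    tree_newick = stage("tree")(_tree)

    # -- ages --------------------------------------------------------------
    ages: dict[str, phylo.AgeEstimate] = {}
    if divergence_table is None:
        logger.warning("no divergence table provided; ages.tsv skipped")
    else:
        def _ages():
            host_of = {c.id: c.host for c in candidates}
            out = {}
            for cl in clusters60.clusters:
                hosts = [host_of[m] for m in cl.members]
                out[cl.cluster_id] = phylo.min_age(cl.cluster_id, hosts, divergence_table)
            with open(outdir / "ages.tsv", "w") as fh:
                fh.write(f"# {header[0]}\ncluster_id\thost_a\thost_b\tage_my\trank\tflagged\n")
                for cid, age in out.items():
                    fh.write(
                        f"{cid}\t{age.species_pair[0]}\t{age.species_pair[1]}\t"
                        f"{age.age_my:g}\t{age.rank_used}\t{int(age.flagged)}\n"
                    )
            return out

        ages = stage("ages")(_ages)

    # -- annotate ----------------------------------------------------------
    def _annotate():
        motifs = refdata.load_motifs()
        annotations = []
        gff_records = []
        for c in candidates:
            contig_seq = assembly[c.contig]
            ws = max(0, c.start_bp - config.window_bp)
            we = min(len(contig_seq), c.end_bp + config.window_bp)
            window = contig_seq[ws:we]
            if c.strand == "-":
                window = revcomp(window)
            ann = annotate.annotate_element(c.id, window, motifs, config.min_orf_aa)
            annotations.append((c, ws, we, ann))
            for idx, orf in enumerate(ann.orfs):
                if c.strand == "+":
                    g_start, g_end = ws + orf.start, ws + orf.end
                else:
                    g_start, g_end = we - orf.end, we - orf.start
                gff_records.append(
                    Gff3Record(
                        seqid=c.contig, type="CDS", start=g_start, end=g_end,
                        strand=c.strand, phase="0",
                        attributes={
                            "ID": f"{c.id}.orf{idx}",
                            "Parent": c.id,
                            "frame": str(orf.frame),
                            "architecture_call": ann.architecture_call,
                        },
                    )
                )
        write_gff3(gff_records, outdir / "annotations.gff3", header)
        with open(outdir / "architecture.tsv", "w") as fh:
            fh.write(f"# {header[0]}\nelement_id\tarchitecture_call\tn_orfs\tdomains\n")
            for c, _, _, ann in annotations:
                domains = ",".join(
                    f"orf{h.orf_index}:{h.motif}@{h.aa_offset}" for h in ann.domain_hits
                )
                fh.write(f"{c.id}\t{ann.architecture_call}\t{len(ann.orfs)}\t{domains}\n")
        return annotations

    annotations = stage("annotate")(_annotate)

    # -- summary table -----------------------------------------------------
    def _summary():
        taxonomy_by_member = {c.id: c.host for c in candidates}
        rows = report.build_cluster_table(
            clusters60, cluster_assignments, ages, taxonomy_by_member
        )
        frame = report.cluster_table_to_frame(rows)
        with open(outdir / "table1_analog.tsv", "w") as fh:
            fh.write(f"# {header[0]}\n")
            frame.to_csv(fh, sep="\t", index=False)
        return rows

    summary_rows = stage("summary")(_summary)

    # -- manifest ----------------------------------------------------------
    write_fasta_dict(assembly, outdir / "assembly_used.fa")
    outputs = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "run_id": run_id,
        "config": config.to_dict(),
        "seed": config.seed,
        "genome": genome,
        "versions": {
            "eprvscan": __version__,
            "python": platform.python_version(),
        },
        "input_checksums": {
            name: _checksum(Path(p)) for name, p in (input_paths or {}).items()
        },
        "stage_counts": stage_counts,
        "outputs": outputs,
        "output_checksums": {name: _checksum(outdir / name) for name in outputs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        outdir=outdir,
        hits=hits,
        candidates=candidates,
        clusters60=clusters60,
        clusters100=clusters100,
        amplification=amplification,
        cluster_assignments=cluster_assignments,
        candidate_assignments=candidate_assignments,
        ages=ages,
        annotations=annotations,
        summary_rows=summary_rows,
        tree_newick=tree_newick,
        manifest=manifest,
    )
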