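# Methods

`eprvscan` re-implements, at desk scale and with full determinism, a
discovery-and-classification analysis for recently inserted endogenous
pararetroviruses (EPRVs): integrated copies of plant dsDNA
reverse-transcribing viruses (family *Caulimoviridae*) whose
reverse-transcriptase (RT) central domain is still complete and
uninterrupted. This note documents the models, parameters and numerical
choices, what the synthetic data does and does not emulate, and the known
limitations.

## The discovery model

The unit of analysis is an RT central domain of roughly 300–350 amino
acids. Recently inserted copies are operationally defined by three rules,
applied in a fixed order:

1. **Translated homology search.** Protein queries (one RT representative
   per Caulimoviridae OTU in the reference library, configurable) are
   compared against all six reading frames of each contig. Scoring is
   BLOSUM62 with affine gaps (open 11, extend 1; a gap of length *k* costs
   11 + *k*). Candidate regions are located with exact 4-mer peptide seeds
   — at least two seeds within a 16-diagonal band — and each seeded window
   is then aligned with an *optimal* local Smith–Waterman (Biopython's C
   aligner); secondary non-overlapping alignments are recovered by
   recursing on the flanks of each reported hit. Because the window
   alignment is exact, reported scores equal the full SW optimum for any
   seeded homology (the test suite checks this against an independent
   quadratic DP). E-values use Karlin–Altschul statistics with fixed
   gapped-BLOSUM62 parameters (λ = 0.267, K = 0.041) and a search space of
   query length × total translated residues; the default cutoff is
   **E ≤ 1e−10**. An adapter ingests 12+-column tabular output from an
   external search tool for users who prefer it.

2. **Intactness.** A hit survives only if its subject peptide is at least
   **300 aa**, contains no stop codon, and its alignment has no indel in
   the subject row (single-frame, gap-free — the operational reading of
   "no frameshifts": a frameshift splits a domain across frames and can
   never produce one gapless ≥300 aa single-frame match).

3. **Proximity dedup and lineage triage.** EPRVs frequently integrate as
   tandem or nested arrays. Hits on the same contig whose inter-interval
   gap is **< 1500 bp** (strict) form proximity chains — connected
   components of that relation — and each chain keeps exactly one
   survivor, the highest bit-score (leftmost on ties). Because Ty3/Gypsy
   LTR-retrotransposon RTs are similar enough to be found by the search,
   every surviving peptide is then scored by global alignment against the
   full labelled reference library (Caulimoviridae genera and endogenous
   OTUs vs retrotransposon/retrovirus decoys) and kept only when its best
   match is Caulimoviridae. Exact inter-class score ties resolve by the
   larger top-3 score sum per class, then in favour of Caulimoviridae, so
   triage is deterministic.

## Clustering and amplification

Surviving candidate peptides are clustered with CD-HIT semantics: greedy
incremental clustering, longest sequence first (ties by id), each
sequence joining the first cluster whose *representative* (the founding,
longest member) it matches at or above the threshold. Identity is
identical aligned positions of the pairwise global alignment divided by
the length of the shorter sequence — the CD-HIT convention, under which a
perfect substring scores 1.0. No short-word prefilter is used; every
comparison is an exact alignment. Thresholds: **0.60** ("cluster60", the
classification grain) and **1.00** ("cluster100"). Cluster100 is computed
per genome, and groups of **≥ 10** identical copies in one genome are
reported as recent amplification events — identical RT copies imply
integration too recent for substitutions to accumulate.

Clustering at 60% is global across genomes (the alternative — per-genome
clustering followed by a merge — is not specified precisely enough to
reproduce; the global choice is recorded here). A `--scope per-genome`
option exists. A cluster whose members split into two below-threshold
subgroups can optionally carry two representatives (off by default).

## Classification and dating

Distances between RT peptides are Poisson-corrected amino-acid distances
d = −ln(1 − p), with p the mismatch fraction over aligned (non-gap)
columns of the pairwise global alignment; p is clamped at 0.95 with a
warning (saturation). Trees are neighbor-joining (Saitou–Nei Q
criterion), deterministic via lowest-index tie-breaking, with negative
branch lengths clamped to zero; bootstrap support resamples alignment
columns (equal-length inputs are treated as aligned, otherwise a star
alignment onto the longest sequence is used — adequate for near-equal
RT domains, crude for anything else). Maximum-likelihood inference is
deliberately out of scope: nearest-reference classification is robust to
the tree method in the divergence regimes tested, and NJ keeps every run
deterministic and fast.

Each cluster60 representative is assigned the OTU of its
minimum-distance library reference (`nearest_reference`, the default),
with support (d₂ − d₁)/d₂ where d₂ is the best distance to a reference
of a *different* OTU; representatives farther than a distance ceiling
(default **0.5**, ≈ 39% mismatch) from every reference are
"unclassified". A clade-based method (smallest surrounding NJ clade with
unanimous reference OTU) is provided as an alternative.

The **minimum insertion age** of a cluster is the divergence time of its
most distantly related pair of host taxa, looked up in a local
divergence-time table (genus pair preferred, species pair as fallback;
the rank used is recorded). A single-host cluster has age 0 by
convention; pairs absent from the table are listed and the estimate
flagged rather than silently zeroed.

## Element architecture and the wendovirus rule

Around each candidate RT locus an element window (± 5 kb by default,
covering the ~7.7 kb genomes of the relevant elements) is scanned in the
three forward frames (elements are oriented RT-forward). ORFs are
ATG-initiated, run to the next stop or the window end, and must encode
≥ 100 aa. Domains are detected with packaged position-constrained motifs
— simplified surrogates for profile models, each carrying the canonical
residues of its domain (CCHC zinc knuckle, movement-protein core,
retropepsin D-T/S-G triads, the YxDD polymerase box, RNase H) — because
the analysis needs only domain presence and order, not scores.

An element is **wendovirus_like** iff it has ≥ 4 ORFs; some ORF carries a
zinc finger; some ORF carries a movement protein *and* an aspartic
proteinase; a distinct downstream ORF carries an aspartic proteinase
followed by the RT and then RNase H; and at least two ORFs carry
proteinase motifs. The two proteinase motifs are distinct patterns but
either may satisfy either position, since the motifs are surrogates for
two different proteinase families. Elements with the full domain
complement but a broken ORF layout are flagged **unresolved** (split or
shortened ORFs occur in real elements); anything else is **other**. The
rule is monotone: removing domain hits can never turn a negative call
positive.

## The synthetic-data generator

The simulator emulates exactly the statistical structure the analysis
assumes, with a ledger of every planted element (GFF3, lossless round
trip):

- **Background**: i.i.d. bases at a target GC (default 0.40), with N runs
  (50–500 bp) at a configurable per-base rate, mimicking assembly gaps.
- **Reference library**: a fixed, seeded 182-sequence RT collection
  mirroring the survey's composition — 104 sequences from the 11 episomal
  genera, 63 from the 6 endogenous OTUs, 14 Ty3/Gypsy (7 families × 2)
  and 1 retrovirus. OTU consensuses diverge ~35% from a common ancestor
  (pairwise OTU identity ≈ 43%, safely below the 60% clustering
  threshold), members sit ~8% from their consensus, and decoys diverge
  ~45% — far enough for triage to separate them, close enough that the
  search still finds them at E ≤ 1e−10, which is the property the decoy
  test needs.
- **Implants**: reverse-translated (uniform synonymous codons — the
  pipeline is codon-usage-agnostic) copies of library references, mutated
  to an exact target amino-acid divergence (substitution count =
  round(target × length); no stop is ever introduced), on either strand.
  Degenerate copies get either one internal stop codon or one 1–2 bp
  deletion. Lesion positions obey the middle-80% rule and additionally
  keep both flanking fragments ≤ 290 aa: a local alignment can extend a
  few residues past a frameshift on chance matches, so a 10-aa margin is
  required for a single lesion to *guarantee* failure of the ≥ 300 aa
  criterion. Elements longer than ~590 aa cannot be degenerated by a
  single lesion and are rejected.
- **Placement**: rejection sampling (100 retries), keeping every
  placement unit ≥ 2 kb from others and from contig ends, so only
  deliberate tandem arrays fall inside the dedup window. Implants
  overwrite background (contig lengths are preserved); minus-strand
  copies store the reverse complement, truth coordinates stay forward.
- **Standard scenario** (the validation genome): 5 × 400 kb contigs,
  GC 0.40, N-run rate 2 × 10⁻⁵/bp; 20 intact dispersed implants at
  divergences evenly spaced over 0–10% across OTUs; one 12-copy identical
  dispersed burst; one 5-copy identical tandem array with 200 bp gaps;
  10 internal-stop and 10 frameshift copies at 5% divergence; 10
  Ty3/Gypsy decoys at 5% divergence. The 0–10% range models recent
  insertions (the premise of the analysis); no empirical divergence
  distribution is asserted.

What the simulator does **not** emulate: host genes and realistic repeat
landscapes, nested (rather than tandem) element clusters, fragmented or
anciently degenerate EPRVs, sequencing error, codon-usage bias, and
biased amino-acid composition. Passing tests therefore demonstrate the
pipeline's selection logic and classification geometry under its own
assumptions — not sensitivity on real genomes, where assembly quality
and old, fragmented copies dominate the error budget.

## Numerical and scale choices

- All randomness flows through `numpy.random.default_rng` from explicit
  seeds; identical (seed, config) pairs give byte-identical outputs,
  including every pipeline file (the manifest records config, seed,
  versions and checksums).
- The pipeline's NJ tree uses cluster representatives plus one reference
  per OTU (not all 182) to keep the distance matrix quadratic in ~50
  taxa; OTU assignment still scores against the full library. Bootstrap
  is off by default in the pipeline (`bootstrap_reps = 0`) and available
  as a function.
- The validation genome is 2 Mb: large enough that the null search
  (random background) yields zero hits at E ≤ 1e−10 and that ~60 planted
  loci never collide, small enough that the full pipeline runs in about a
  minute on one core.
- Degenerate inputs: empty FASTA, contigs shorter than one codon, empty
  cluster input, single-host age queries, missing divergence pairs and
  saturated distances all have defined behaviour (error, warning-skip, or
  documented convention) rather than silent defaults.

## Known limitations

- E-values are comparable to, not bit-identical with, the external search
  tool's (fixed λ, K; no length corrections or composition adjustment).
- The star alignment behind bootstrap support drops insertions relative
  to the reference sequence; supports on highly length-variable inputs
  are approximate.
- Nearest-reference classification cannot discover OTUs absent from the
  library; genuinely novel lineages surface only as "unclassified".
- The published survey tables contain three genus totals that disagree
  with their own row sums; the consistency checker reports both numbers
  and takes no side.
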