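# Methods

This note documents the models, parameter choices and numerical decisions
behind `plastokit`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## The synthetic study

The generator (`plastokit.synthetic`) emits a circular plastome on the
canonical rotation `LSC + IRa + SSC + IRb`, with IRb the exact reverse
complement of IRa. Two named configurations exist:

- `study_spec()` — publication scale. Region lengths 91,210 / 14,058 /
  31,844 bp (genome 168,956 bp); region GC targets 33.47 / 30.17 / 40.06 %
  (overall 35.68 %); 107 unique genes (78 protein-coding, 25 tRNA, 4 rRNA);
  nine group-II introns in seven genes (*ycf3* and *clpP* carry two each,
  *atpF*, *rpoC1*, *rpl2*, *rps12*, *ndhA* one each; lengths drawn from
  500–1,200 bp); nine polycistronic units of sizes 4, 2, 3, 5, 2, 4, 3, 4
  and 8 genes built from the canonical plastid complexes (ATP synthase,
  PSII, PSI, NADH dehydrogenase, RNA polymerase, ribosomal proteins, with
  the eight-gene `rpl22…rpoA` S10-like unit); and 37 C→U editing sites
  (30 CDS, 1 intron, 6 intergenic).
- `scaled_spec(factor=20)` — an 8.4 kb miniature with the same
  architecture and reduced gene content, used for fast structural and
  property tests.

Specific modelling decisions:

- **Region GC is met by construction.** Intergenic fill is drawn as an
  exact-composition multiset sized to bring each region to its target GC
  count, so even the 702 bp scaled SSC stays within a fraction of a
  percentage point of its target.
- **Editing efficiencies are a fixed, skewed list** with minimum 0.21,
  median 0.93 and maximum 1.0 (most plastid sites are nearly fully edited;
  a few are partial). Each covering molecule is edited independently with
  probability equal to the site efficiency. The single intron-category site
  is planted fully edited — editing inside a group-II intron is only
  observable on unspliced molecules, which are the minority.
- **Intron retention.** Each intron is retained in a molecule independently
  with probability 0.2, emulating the incomplete splicing visible in
  chloroplast Iso-Seq. Retained molecules are what give intron-category
  editing sites coverage; spliced molecules are what support junctions.
- **Intergenic editing sites sit inside fixed 30 bp UTR extensions** at
  both ends of every transcription unit (kept ≥ 8 bp from the transcript
  tip so terminal alignment ambiguity cannot shadow them).
- **The error model is indel-dominated**: substitution : insertion :
  deletion = 1 : 2 : 2 at a configurable total rate (0.12 for genomic
  reads, 0.01 for cDNA), matching the error spectrum of raw long reads.
  Read lengths are log-normal (shape 0.5) truncated to [300 bp, 3× mean].
- **Boundary inextensibility.** The generator adjusts one flanking base per
  IR boundary (and per *ycf2* duplication) when a chance complement would
  let the maximal repeat extend past the planted coordinates, so
  planted-truth recovery can be asserted exactly rather than "within a few
  bases".
- **Junction unambiguity.** Planted introns carry the group-II boundary
  motif (5′ `GTGYG`, 3′ `AY`), the terminal Y is chosen to differ from the
  preceding exon base, and insertion points avoid a following `G`, so a
  1 bp junction slide is never score-neutral.
- All randomness flows from a single seed through spawned NumPy
  generators; every output file records its seed.

What the generator does **not** model: chimeric or 5′-degraded reads,
polyA tails, quality-score structure beyond a constant Q, base-composition
bias of errors, condition-dependent expression (transcripts are uniform
per unit), trans-splicing (*rps12* is planted as an ordinary cis-spliced
intron, unlike its real trans-spliced first intron), and genes inside the
IR (all genes are placed in single-copy regions, so transcript mapping is
never two-copy-ambiguous). Passing recovery tests therefore demonstrates
algorithmic correctness under realistic noise, not performance on every
pathology of real libraries.

## Quadripartite resolution

Inverted repeats are found by exact seed-and-extend: canonical 21-mers of
the doubled sequence are matched against the reverse complement, hits are
grouped by anti-diagonal (along an inverted match the sum of paired base
coordinates is constant), merged into runs, and extended to maximality.
Pairs are deduplicated modulo the genome length; a palindromic
`R·revcomp(R)` junction yields one pair and never self-pairs. The
partitioner takes the longest pair ≥ `min_ir` (default 1,000 bp; a
structured no-IR error otherwise, since some plastomes genuinely lack the
IR), calls the longer inter-copy arc the LSC (ties broken by
lexicographically smaller arc sequence) and rotates so position 0 is the
LSC start. On genomes ≤ 10 kb the finder is verified against an O(n²)
brute-force oracle; partition recovery is exact across ≥ 20 seeds and
invariant to rotation and strand.

GC is reported per region to two decimals, N excluded from numerator and
denominator; the overall value is the length-weighted mean of region GC.
Coverage counts deletions as covered reference positions and accrues
origin-wrapping alignments to both ends.

## Read fishing

Classification is shared-k-mer containment with strand-collapsed
(canonical) 15-mers: accept iff hits ≥ 25 and hits/(len−k+1) ≥ 0.02. The
defaults are derived from the error model: at 12 % error the expected
error-free 15-mer fraction is 0.88¹⁵ ≈ 0.15, seven-fold above the
acceptance fraction, while a 150 kb unrelated genome shares ≈ 2·10⁻³ of
random 15-mers. Measured on synthetic pools: sensitivity ≥ 99 % at 12 %
error, false-positive rate < 1 %, and exact monotonicity in both
thresholds. Decoys for specificity tests must be supplied by the caller;
no organelle-specific disambiguation beyond reference matching is
attempted.

## Spliced mapping

Exact 13-mer anchors against the doubled circular target (positions
normalised modulo n) are grouped into *bands* by a greedy query-ordered
scan that tracks the local diagonal (tolerance 25 bp against the band's
most recent anchor, so indel drift within an exon follows the band while a
≥ 50 bp intron jump always splits). A small dynamic program picks the
chain of bands maximising total anchor support under query/target ordering
constraints — a handful of anchors on a chance repeat cannot outvote a
well-supported exon. Anchor sets above 1,200 are thinned by query stride;
junction placement re-scans the gap between kept anchors, so thinning
costs no precision.

Each junction is placed jointly: the split point scans the window between
the flanking anchors; for each candidate the left flank is aligned
start-anchored and the right flank end-anchored (edlib SHW) so an indel
error near the junction cannot bias the boundary. Candidates are ranked by
total edit cost with a 2-edit bonus for a boundary carrying the group-II
motif, then by closeness of the implied intron length to the
anchor-diagonal length, then leftmost. Blocks are polished with edlib
(infix mode for free terminal ends, global between fixed junctions); the
parsed extended cigar provides the substitution list used by the editing
caller. Measured junction accuracy: 100 % base-exact on error-free
molecules; ≥ 95 % base-exact at 2 % error with no shift beyond a few
bases. No claim of equivalence with any external spliced aligner is made —
the contract is planted-truth recovery.

SAM output uses `=`/`X`/`I`/`D` plus `N` for introns, an MD tag for
mismatch reference bases, and `AS`/`NM` tags; an origin-wrapping alignment
becomes a primary plus a soft-clipped supplementary record and is rejoined
on reading. Blocks, strand and mismatches round-trip exactly; plain-M
cigars from external aligners are supported via MD.

## Feature calling

**Introns.** Junctions with ≥ 10 bp of aligned exon on both sides are
clustered within 10 bp; the modal exact (donor, acceptor) is the call
boundary, assigned to the containing gene. A call needs ≥ 3 supporting
molecules *and* support from ≥ 5 % of same-strand molecules covering a
junction flank. The relative-support floor exists because at hundreds-fold
coverage a rare recurrent mis-chaining (three molecules taking the same
wrong path across an intergenic chance repeat) can reach an absolute
count of 3 while remaining far below any plausible spliced fraction;
genuine introns are spliced in ~80 % of molecules here.

**Editing.** Candidates are all positions with ≥ 10 same-strand covering
molecules whose reference is C on that strand; per-molecule deletions are
subtracted from the denominator (pileup semantics — without this, deletion
errors bias every efficiency ~0.4 % low). A site is called when
efficiency ≥ 0.10 and the one-sided binomial tail P(X ≥ edited | n, 0.02)
survives Benjamini–Hochberg at α = 0.05 across all candidates. The
min-efficiency default sits below the smallest planted efficiency (0.21)
so the binomial filter, not the threshold, does the error control;
specificity is validated as zero false calls over 20 editing-free
simulations at 2 % error. CDS sites get codon position and amino-acid
consequence under translation table 11 (plastid/bacterial); intron
categorisation requires containment in an intron call; everything else is
intergenic.

*Coverage sizing:* the recovery experiments use 400 molecules per
transcription unit. A binomial efficiency estimate at the least favourable
planted efficiency (~0.5) has σ = 0.025 at n = 400, giving ~3σ headroom
inside the ±0.07 recovery band at each of 37 sites; the intron-category
site is covered by retained molecules only (0.2 × 400 = 80 ≥ the coverage
floor). Exploratory runs in `analysis/` use depth 60, where single-site
efficiency noise of ±0.1–0.2 is expected and documented in the scorecard.

**Operons.** A molecule covers a gene when its blocks overlap ≥ 50 % of
the gene's exonic span on the same strand; the ordered covered-gene set
(transcription direction) is the grouping key. Identical sets with ≥ 2
genes and ≥ 3 molecules become calls. Naming takes the lowercase
gene-family prefix of the first gene, title-cased, with `_1/_2` ordinals
in genome order when a family yields several calls — so the NADH
dehydrogenase unit led by *rps15* is named `Rps`, not `Ndh`; naming follows
the first transcribed gene, not the functional majority. Subset relations
(a processed sub-operon inside a longer unit) are reported as separate
calls with a `subset_of` cross-reference, never merged.

## Divergence

p-distance is mismatches over compared sites with pairwise deletion by
default (gap or N in either sequence excluded) — the default of the
standard distance software this mirrors; complete deletion is exposed as
an option. Variable sites count columns with ≥ 2 distinct bases and no gap
in any sequence, N treated as missing. Overall mean distance is the
unweighted mean over all pairs; ranking is stable, ties broken by variable
sites then name. The module consumes pre-aligned FASTA and never aligns:
reproducing any published distance table exactly depends on the alignment
that produced it, which is outside this module's contract. The synthetic
oracle plants disjoint per-taxon substitutions on a star phylogeny, so
every pairwise distance has a closed-form expected value matched exactly.

## Pipeline

`run_pipeline` executes simulate → fish → structure → map →
introns/editing/operons (→ divergence when an MSA directory is given),
validates its YAML config against a strict schema (unknown keys are
errors), and writes a manifest with SHA-256 checksums of every artifact.
Identical config + seed reproduces identical bytes (GenBank output pins
its date field to a constant for this reason). Internal coordinates are
0-based half-open everywhere; 1-based inclusive conversions happen only at
the GenBank/GFF3/SAM boundary, and every writer/parser pair round-trips.

## Known limitations

- Genes are never placed inside the IR, so the two-copy mapping ambiguity
  real IR genes create (and the paper's 19 IR genes) is untested.
- The operon model has no transcription start/termination structure; unit
  boundaries are gene spans plus fixed 30 bp UTRs.
- The editing caller assumes mismatch evidence from a single aligner pass;
  it does not remap or realign around candidate sites.
- Distance tables that depend on a specific alignment tool cannot be
  reproduced bit-for-bit from unaligned sequence; only ranking behaviour
  is asserted on published values.
- The spliced mapper targets organelle-scale references (≈ 0.1–0.5 Mb);
  it indexes the full doubled target in memory and is not intended for
  nuclear genomes.
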