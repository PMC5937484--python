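# Methods

This note documents the models, algorithms, and numerical choices behind
`motupipe`, and what its synthetic-data tests do and do not demonstrate
about real sequencing data.

## The pipeline

`motupipe` re-implements an OBITools-style community-DNA metabarcoding
workflow for two universal eukaryotic markers — the ~313-bp Leray fragment
of mitochondrial COI (amplified by the highly degenerate Leray-XT primer
set: forward `GGWACWRGWTGRACWITITAYCCYCC` with two inosines, reverse
jgHCO2198 `TAIACYTCIGGRTGICCRAARAAYCA`) and the ~110-bp V7 region of 18S
rRNA (`TTTGTCTGSTTAATTSCG` / `TCACAGACCTGTTATTGC`). Libraries are
tag-multiplexed: every sample's amplicons carry the same 8-nt tag at *both*
primers, preceded by 2–4 fully degenerate spacer bases that raise
early-cycle base diversity on the sequencer.

Stage order (marker policies in parentheses):

1. 3'-trim each mate to the longest prefix with median Phred > 30;
2. merge mates over their best 3' overlap; score = Σ over overlap columns of
   ±1 (match/mismatch) × mean column quality / 40, accept at score ≥ 40;
3. demultiplex on exact dual tags (mismatched known tags = inter-sample
   chimeras, rejected), primers matched IUPAC/inosine-aware with ≤ 2
   mismatches and stripped; both orientations tried, insert reported in
   forward-primer orientation;
4. length filter: closed windows 300–320 bp (COI), 75–180 bp (18S);
5. dereplicate with per-sample counts (18S: singletons removed here);
6. flag and drop de-novo chimeras (abundance-skew rule, below);
7. cluster into MOTUs with an abundance-greedy threshold clusterer
   (identity 0.97 COI / 0.99 18S); COI: drop MOTUs with < 5 reads;
8. LCA-assign each MOTU representative (best-hit equal-similarity set);
   COI: merge MOTUs assigned to the same species;
9. curation chain: blank filter (> 10% of a MOTU's reads in controls →
   MOTU removed), tag-switch abundance renormalization (per MOTU, zero
   ascending samples while the running cumulative stays < 3% of the MOTU
   total), minimal relative-abundance filter (keep only MOTUs exceeding
   0.01% in ≥ 1 sample, denominators recomputed after renormalization),
   non-target removal (root / non-eukaryote assignments), failed-sample
   removal (< 10,000 reads);
10. diversity layer: rarefied richness, Shannon, fourth-root Bray–Curtis,
    Mantel, nested PERMANOVA, non-metric MDS, fraction Venn partitions,
    ecological-category summaries.

All boundary semantics are strict as listed (`>`, `<`); intervals are
closed; internal coordinates are 0-based half-open.

## Design choices where the design was open

* **Pair-merge score.** The upstream tool's "paired-end alignment quality
  score of 40" has no published definition; we re-specified it as the
  quality-weighted match/mismatch tally above and kept 40 as the default
  threshold. At uniform Q40 the score equals matches − mismatches over the
  overlap, so the threshold reads as "≥ 40 net matching columns".
* **Trimming direction.** Median-quality trimming is 3'-only and
  prefix-maximal; 3' decay is the dominant Illumina failure mode. For even
  prefix lengths the median is the mean of the two central values.
* **Tag matching is exact.** With 8-nt tags, a 1-mismatch tolerance risks
  re-introducing the cross-talk the dual-tag design exists to kill.
* **Primer matching** allows ≤ 2 mismatches. (A 3'-anchor constraint was
  considered and not enabled by default; the simulator's reads carry
  primer concretizations drawn from the degeneracy sets, so site mismatches
  arise only from sequencing error.)
* **Clustering.** The published workflow used Bayesian clustering (CROP,
  l/u = 0.3/0.5 for 18S, 1.5/2.5 for COI). CROP is external prior work and
  its parameters have no derivable identity-threshold equivalent, so this
  package records l/u as provenance metadata and clusters with a documented
  greedy threshold algorithm (seeds in decreasing abundance, ties by
  lexicographic sequence; identity = matches / global-alignment length with
  indels as mismatches, computed with edlib). Every downstream filter and
  statistic is clustering-agnostic.
* **Assignment identity metric** is the same alignment identity as
  clustering, applied to MOTU representatives only. No minimum-identity
  floor by default (low-identity phylum-level assignments are informative);
  a `min_identity` option exists. Ties at the best hit all seed the
  candidate set — the most conservative, reproducible choice.
* **Renormalization boundary.** Whether the sample that straddles the 3%
  cumulative boundary is zeroed is unstated upstream; we zero strictly
  while the cumulative (candidate included) is `< 3%`, so the straddling
  sample survives. Ascending-sort ties break by sample id.
* **Shannon** uses natural log (configurable) on un-rarefied relative
  abundances; rarefaction applies to richness only. "Fourth square root"
  is x^(1/4).
* **PERMANOVA.** Sums of squares are partitioned from the squared distance
  matrix by group decomposition (SS among a grouping = SS total − Σ
  within-group SS), for the model {site, fraction, site×fraction,
  community(site), sample(community), residual}. Pseudo-F denominators
  follow nested-design expectations: site over community(site),
  community(site) over sample(community), everything else over the
  residual. Permutations are free for site, within site for fraction,
  site×fraction and community(site), and within community for
  sample(community); p = (1 + exceedances) / (n_perm + 1).
* **nmMDS** is SMACOF majorization alternating a Guttman transform with
  isotonic regression of configuration distances on dissimilarity ranks,
  minimizing Kruskal stress-1 = sqrt(Σ(d − d̂)² / Σd²); the best
  configuration seen is kept (so the reported stress sequence is
  non-increasing), with the first start seeded by classical metric scaling
  and further random restarts. Degenerate all-equal inputs are flagged and
  returned with their stress rather than erroring.

## The chimera rule

Working through uniques in decreasing abundance, a candidate is flagged as
a chimera when two already-accepted sequences — each ≥ 2× the candidate's
abundance — can be joined at a single interior breakpoint such that each
side matches its parent at ≥ 99% identity while the full candidate matches
neither parent at ≥ 99%. Sequences within 99% of an accepted sequence are
excluded as parents-of-evidence (a single parent can then never satisfy
both sides, because the two segment budgets sum to the full-sequence budget
it already exceeded). Only equal-length parents enter the positionwise
test: the generator's substitution-only model keeps template coordinates
aligned, and a gapped segment model would buy little on real data where
uchime-class tools are the standard. Consequence: a crossover whose
breakpoint sits in the outer ~10% of the fragment is within 99% of one
parent and is deliberately not flagged — it clusters into that parent's
MOTU and founds no spurious one. Detector performance quoted by the tests
(sensitivity ≥ 0.9, false-positive rate ≤ 0.05) is therefore over
*detectable* planted chimeras, i.e. those below 99% identity to every
parent.

One known cost of the plain segment rule: with sequencing error switched
on, a 1-read error variant of an abundant species can be flagged when two
accepted same-species variants happen to differ from it in complementary
halves. These false flags are essentially always singletons that would
otherwise have been absorbed into their species MOTU, so the meaningful
false-positive measure is read-weighted — falsely flagged reads as a
fraction of all reads — which the tests hold under 5% (about 2% at default
error rate). Tightening `segment_identity` or raising `min_parent_skew`
trades this against sensitivity.

## The synthetic-data generator

The generator emulates the study design the pipeline was built for: 8
communities split between two sites, 3 size fractions (A > 10 mm,
B 1–10 mm, C 63 µm–1 mm), 3 replicates, 2 control samples, one
tag-multiplexed library per marker.

* **Taxonomy**: a rooted tree with one node per rank (superkingdom …
  species) on every root-to-leaf path; eukaryotic species under
  "Eukaryota", optionally a parallel "Bacteria" branch so non-target
  removal has something to remove.
* **Sequences**: a random root amplicon evolved along the tree with
  per-site independent substitution (Jukes–Cantor-style uniform
  replacement) at 0.05 per site per edge — sister species then sit ~10%
  apart, a realistic COI barcoding gap — plus intraspecific variants at
  0.002. References carry concretized primer-binding flanks so the same
  records feed in-silico PCR.
* **Communities and abundances**: each species occupies one home community
  plus each other community with probability 0.25; within an occupied
  community its expected abundance is (between-species lognormal σ = 1) ×
  (community-level lognormal σ = 0.5) × (Dirichlet(α = 3) fraction
  affinity) × (replicate lognormal jitter σ = 0.25). These one-time
  choices make genuine per-sample occurrences comfortably stronger than
  tag-switch cross-talk while keeping species patchy across fractions —
  the regime the 3% renormalization filter was designed for.
* **Reads**: molecule = spacer(2–4 nt) + tag + primer + template +
  rc(primer/tag/spacer); per-read concretization of degenerate and inosine
  primer positions; substitution errors at 0.001/base; constant Q37
  qualities (optional decaying-tail profile for trimming tests). Chimeras
  (rate 0.01) are single-breakpoint two-parent crossovers within a sample.
  Tag switching (rate 0.01, our choice — the source study reports no
  measured rate) moves the intact tag pair to another sample. Blanks
  receive ~65 reads of carry-over, echoing the magnitude reported for real
  controls, dominated by a designated contaminant species that also
  trickles into real samples at 1e-4.
* **Determinism**: every draw flows from one integer seed through
  per-stage `numpy` Generator streams; equal configs give byte-identical
  FASTQ/FASTA/TSV outputs.

What passing synthetic tests does **not** show: robustness to indel
sequencing error (substitution-only model), PCR amplification bias and
copy-number variation (not modelled), real reference-database sparsity and
mislabelling, or chimera structures more complex than one breakpoint.

## Verification scale

The verification suite and `scripts/acceptance.py` run at desk scale:
1,000 random toy tables for filter fidelity, 500 queries × 200 references
for LCA-oracle equivalence, a 20-species / 6-sample / 1e5-read noise-free
library for end-to-end recovery, 10,000 templates for the primer-coverage
superset property, 2,000 exchangeable-null simulations (199 permutations
each) for PERMANOVA type-I calibration, and 200 repeats for the Mantel
null. Quantities that depend on the original multi-gigabase read deposit
(absolute MOTU counts, assignment percentages, published pseudo-F values)
are out of scope by design; the tests verify rules, oracles, and
calibration instead.
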