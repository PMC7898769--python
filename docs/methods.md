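# Methods

This note documents the models and procedures implemented in
`vmscreen`, the parameter choices that matter, what the synthetic data
generator does and does not emulate, and the numerical/tie-breaking
conventions needed to make the pipeline fully deterministic.

## Coordinates and conventions

All intervals are 0-based half-open (UCSC table convention). Strand
semantics are element-relative throughout: the 5′ end of a minus-strand
element is its genomic right end, and extracted LTR sequences are
reverse-complemented so they read 5′→3′ in element orientation.

## Repeat catalogue repair

**Structure classification.** An element's subelement rows are typed
LTR or internal via a registry of the 25 IAP subelement names. The
typing rule is name-based — internal iff the name ends in `-int` — with
one explicit exception (`IAPLTR4_I` is an internal portion despite its
name); the registry is a YAML-overridable object so corrections never
require code changes. For names outside the registry (the non-IAP
screen), the `-int` suffix rule applies. In element orientation:
internal flanked by LTRs at both ends → fully-structured (`FULL`); only
LTRs → solo LTR; an LTR at exactly one end → `FRAG_NO5`/`FRAG_NO3`;
internal only → `FRAG_INTERNAL_ONLY`; anything else (e.g. an LTR
sandwiched between internals) → `FRAG_OTHER`.

**Grouping guard rails.** RepeatMasker reuses element IDs across loci,
so one ID is split into separate elements on any chromosome or strand
change (logged) and on intra-ID gaps > 50 kb. Split-off groups receive
fresh IDs above the annotation's maximum.

**500 kb patch.** Two same-chromosome, same-strand elements, one ending
at an exact multiple of 500,000 and the other starting at that same
coordinate, are unified under one ID. The match is exact (slack 0): the
defect being repaired is a binning artefact, so its boundaries are
exact by construction. Chains across successive boundaries collapse in
one sweep.

**Mending heuristic.** Each fragmented element missing a 5′ LTR looks
5′-ward for a partner within `max_gap` (default 2000 bp) of its edge,
preferring in order (1) a fragment missing a 3′ LTR (internal-only
fragments qualify: they are missing both LTRs), (2) a solo LTR, (3) a
fully-structured element, which yields a double or higher-order
element. The symmetric procedure applies to a missing 3′ LTR;
internal-only elements are tried on both edges (5′ first). Merging
never crosses a chromosome or strand, and only element-ID grouping
changes — the feature multiset is conserved.

Determinism requires conventions the heuristic itself does not fix:

- *Scan order*: fragments are processed in genomic (chrom, start)
  order; each element takes part in at most one merge per pass; passes
  repeat until a fixpoint (this resolves chains of fragments).
- *Adjacency*: the gap is measured between the facing envelope
  boundaries; overlapping envelopes (gap ≤ 0) count as adjacent, since
  nested insertions of other elements can interleave annotations.
- *Tie-breaking*: among partners of equal heuristic rank, the nearest
  facing boundary wins (`max(gap,0)`, then `|gap|`, then the 5′-most
  partner). The merged element keeps the 5′-most constituent's ID.

Mending is idempotent, never increases the element count, and never
increases the *number* of fragmented elements. The fragmented
*fraction* can in principle tick up after a partial mend (an
internal-only fragment absorbing a solo LTR removes one element but
leaves one fragment), although it falls steeply on realistic
catalogues; the test suite asserts the count-based monotonicity.

**CpG density** is the count of non-overlapping `CG` dinucleotides
divided by sequence length.

## Methylation-variability screen

**Input.** Six-column per-CpG coverage files (chrom, position,
position, % methylation, methylated count, unmethylated count). Counts
are primary; the percentage column is only validated, never used.
Records at consecutive positions p and p+1 are the two strands of one
CpG dyad (true CpGs are ≥ 2 bp apart) and merge by summing counts onto
p — CpG methylation is palindromic, so pooling the strands is the
standard treatment. Standard and oxidative bisulphite samples are
deliberately not distinguished.

**Edge windows.** Each element contributes windows at its
outward-facing LTR edges only: both edges for fully-structured
elements (internal-facing LTR edges are never windowed), the edge with
an LTR for one-sided fragments, none for internal-only fragments, and
a single window at the 5′ edge for solo LTRs (the solo's two ends
bound the same short sequence, so a second window would largely
re-count the same CpGs). A window holds the `n_edge_cpgs` (default 8)
CpGs *inside* the element nearest the edge — inside because the
measured object is LTR methylation; a symmetric mode is available via
configuration. The non-ERV screen variant additionally caps windows at
200 bp from the edge (`edge_max_dist`) and repairs its annotation only
by joining same-class, same-strand fragments within 100 bp.

**Per-sample summary.** The edge methylation of one sample is the
pooled-count mean Σmeth/Σtotal over the window's covered CpGs, which
weights CpGs by their coverage and is stabler than averaging per-CpG
fractions under uneven depth (the unweighted mode is available via
`mean_mode`). A sample is informative with ≥ `min_calls` (20) total
calls and ≥ `min_covered_cpgs` (4) covered CpGs; edges keep only
samples passing both, and an edge needs ≥ `min_informative_samples`
(5) informative samples in *every* group to survive.

**Ranking and candidacy.** Per group, the inter-individual methylation
range is max − min over informative samples, with no trimming of
extremes. The screen statistic combines groups as the minimum of the
group ranges — requiring variability in both cell types is the
conservative choice, and the maximum is available via configuration.
An edge is a candidate when it passed the sample filter and its
statistic reaches `range_threshold` (default 0.10); an element is a
candidate when any of its edges is. The screen itself is fully
deterministic; the output table retains every intermediate filter
outcome for audit.

## k-mer enrichment

Presence counting is per sequence (a k-mer occurring three times in one
LTR counts once), skips k-mers containing non-ACGT symbols, and is
strand-specific: LTR regulatory sequences are orientation-specific and
all inputs are oriented 5′→3′ in element orientation. A `canonical`
switch collapses reverse complements for other use cases.

Fold enrichment of a sequence is (fg presence / N_fg) divided by
(bg presence / N_bg). A zero background presence is replaced by a
pseudocount (default 0.5) — without it, unbounded folds make trimming
comparisons meaningless; foreground-absent sequences get fold 0. The
fold is invariant under duplication of the background set.

Filtered k-mers (defaults: presence ≥ 5 foreground LTRs, fold ≥ 20)
are grouped into connected components of the overlap graph (edge
between two k-mers iff one's (k−1)-suffix equals the other's
(k−1)-prefix in either direction). Each component is merged by laying
k-mers along a simple path of the directed overlap graph, chosen
greedily to maximise total foreground presence (ties: longer path,
then lexicographic); on branching graphs, members off the chosen path
are regrouped and merged recursively, so every filtered k-mer ends up
in exactly one extended sequence. For the linear chains that planted
or real shared motifs produce, this reduces to the unique
shortest-superstring layout.

Each extended sequence is trimmed to the substring (length ≥
`trim_min_len`, default 10 — a floor against trivially short,
promiscuous substrings) maximising fold enrichment, computed by
exhaustive substring enumeration with the same pseudocount rule; ties
prefer the longer substring, then the 5′-most. Final motifs are
flagged against a background cap (present in ≤ 2 % of all LTRs) and
reported with foreground/secondary/genome-wide presence fractions,
ordered by fold descending.

The background set for the pipeline is all structured (fully-structured
or solo) elements' 5′ LTRs excluding the candidate set; the foreground
is the candidates' 5′ LTRs, with a solo LTR counting as a 5′ LTR.

## Synthetic data generator

The generator emulates the study design at desk scale, with every draw
taken from a named substream of one global seed (stream keys are fixed
per operation, so adding operations never shifts existing draws; two
runs with the same parameters are byte-identical).

- **Genome and elements.** Background sequence is i.i.d. uniform over
  ACGT. Elements are mutated copies (default 3 % substitution) of one
  LTR consensus and one internal consensus, laid down left to right
  with ≥ `min_spacing` (3000 bp, deliberately above `max_gap`) between
  envelopes so mending can never bridge two true elements. Flanking
  LTRs within one element are identical. CG dinucleotides are planted
  every 25 bp of the LTR consensus and protected from mutation, so
  every LTR carries ≥ 8 CpGs (12 at the default 300 bp length) and
  edge windows are always fully populated.
- **Structure mix.** A configurable fraction (default 25 %) of elements
  are solo LTRs, the rest fully structured.
- **Fragmentation.** With probability `fragmentation_rate` a
  fully-structured element's rows are split into 2–3 element IDs at
  subelement boundaries (the pieces stay contiguous: gap 0, which the
  mender treats as adjacent). Elements straddling a 500 kb multiple are
  split exactly at the boundary, reproducing the binning artefact. The
  row→true-element mapping is retained as mend-truth.
- **Methylation regimes.** One individual contributes one sample per
  group (8 individuals × B/T by default). Hypermethylated loci draw
  per-sample levels from Beta(475, 25) — mean 0.95, SD ≈ 0.01,
  reflecting the minimal inter-individual spread observed at non-variable
  elements; background (non-element) CpGs use the same regime.
  Constitutively variable loci draw one level per individual from
  Uniform(0.05, 0.95) — the full observed spread from near-0 to
  near-1 — shared across groups. Tissue-specific loci draw the uniform
  levels in the first group only and stay hypermethylated in the
  others, matching the dominant observed class (variable in B cells
  only).
- **Coverage noise.** Per CpG and sample, total calls ~
  Poisson(`coverage_mean`, default 10) and methylated calls ~
  Binomial(total, level). Poisson depth is the simplest model with the
  right informativeness failure modes: zero-coverage CpGs arise
  naturally. Zero-coverage CpGs are omitted from the written files, as
  in real coverage output.
- **Motifs.** An optional 15-mer is substituted in place at a recorded
  uniform offset into the 5′ LTRs of a chosen number of constitutively
  variable elements.

What the generator does **not** emulate: read-level data (no FASTQ, no
bisulphite-conversion errors, no mapping bias), repeat phylogenies and
age structure, CpG-density variation between LTR types, correlated
coverage along the genome, and biological coupling between methylation
level and sequence. Passing tests therefore demonstrate the
correctness of the pipeline's arithmetic, filters and assembly logic
and its behaviour under the stated noise model — not performance on
real WGBS libraries, where coverage is overdispersed and methylation
levels are spatially correlated.

## Problem sizes used in tests and the acceptance script

The repair round-trip uses 200 elements at fragmentation rate 0.4 on a
1.1 Mb genome; idempotence/conservation run over 1,000 small randomised
catalogues; oracle-equivalence comparisons use catalogues of ≤ 20
elements against a naive reimplementation of the stated heuristic
semantics. The screen-recovery experiment plants 10 constitutively
variable loci among 200 hypermethylated ones (16 samples, 10×
coverage) and requires ≥ 95 % sensitivity and specificity at the 10 %
threshold. Motif recovery plants one 15-mer in 5 of 51 foreground LTRs
against 1,000 background LTRs. These sizes exercise every code path
while keeping the whole suite within seconds.

## Known limitations

- The mending heuristic is greedy; pathological fragment clusters with
  several equally ranked partners are resolved by the documented
  tie-breaks rather than by global optimisation.
- The screen assumes groups are exchangeable labels; designs beyond
  two groups work, but no tissue-specific classifier is provided
  (calling a locus "tissue-specific" remains a downstream judgement).
- Merged-motif layout on branching overlap graphs is a greedy maximal
  path, not an optimal superstring; for the sparse component structure
  produced by ≥ 20-fold-enriched k-mers this is almost always the
  unique path.
- Headline counts from genome-scale annotations depend on upstream
  annotation versions and on the exact background-set composition;
  the package reports whatever its inputs imply rather than targeting
  published totals.
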