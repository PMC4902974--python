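# Methods

This note documents the models and procedures implemented in `homeokit`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic data can and cannot show about real haplotypes.

## Pairwise alignment (`pairalign`)

Haplotype pairs in the regime this package targets are > 90 % identical over
collinear backbones, interrupted by unevenly distributed multi-kb insertions.
The aligner therefore works anchor-first:

1. **Seeding.** All maximal exact matches of length ≥ k (default k = 15),
   both strands, after discarding k-mers occurring more than 4 times in
   either sequence. Co-diagonal k-mer hits are merged into maximal runs.
2. **Chaining.** Weighted longest-increasing-subsequence over anchors with a
   per-link gap-open penalty (10) and a diagonal-drift penalty
   (0.05 × |Δdiagonal|). The open penalty is deliberately small: a large flat
   penalty makes the chain skip legitimate short anchors immediately after a
   multi-kb insertion, which blurs insertion boundaries by hundreds of bp.
   Ties break toward the leftmost coordinate on sequence A, so chaining is
   deterministic. Leftover opposite-strand anchors are re-chained and
   reported as candidate inversions when their chained extent reaches 500 bp;
   inversion blocks are kept separate from the collinear block list.
3. **Polishing.** Inter-anchor gaps up to 5 kb on both sides are aligned at
   base level with edlib's optimal unit-cost global alignment. Unit cost
   (rather than an affine gap model) is a deliberate choice: with the
   mismatch/gap trade-offs appropriate for 1–3 % divergent sequence the two
   produce the same statistics, edlib is orders of magnitude faster at this
   scale, and its output is deterministic. Fills whose match columns account
   for < 75 % of *all* fill columns are treated as two unrelated insertions
   sharing one gap: the high-identity head and tail are kept, the core is
   re-emitted as unaligned insA/insB runs. Without this filter, a global
   aligner forced across two coincident unrelated insertions fabricates
   scattered matches that corrupt species-marker coverage. Gaps larger than
   5 kb are recorded as unaligned InDel runs without base-level alignment —
   they contribute to the gap fraction, matching how large unalignable
   InDels are treated in locus comparisons of this kind.

The alignment container is a run-length list of column operations (match,
mismatch, insertion-in-A, insertion-in-B). Conservation (gapless + InDel
columns = total columns) and A/B-swap symmetry are enforced by tests.

## Divergence statistics (`divstats`)

Published locus comparisons report SNP % and MNP % without formal
definitions; the package fixes: **SNP** = isolated mismatch column (both
neighbours in its gapless region are matches, or region edge), **MNP** =
maximal mismatch run of length ≥ 2 counted once (its columns enter MNP %).
Consequently SNP % + MNP-column % equals the total mismatch fraction, and
pooled SNP densities sit slightly below raw divergence whenever adjacent
mismatches occur. The gap fraction is InDel columns / all columns inside the
aligned span; unaligned flanks are excluded. Fragment-window statistics tile
the *concatenated gapless columns* (not genomic coordinates) at 100/250/500/
1000 nt, discard the trailing partial window, and report the sample SD of
per-window SNP counts plus the percentage of zero-SNP windows. InDel events
are classified large at ≥ 100 bp and segmental at ≥ 1 kb.

## Neutrality scans (`popgen`)

Multiple alignment is by reference projection: the reference (longest
haplotype of the group) is aligned pairwise to every member, and only
reference positions carrying a residue in *every* member are kept
(complete-deletion handling of gaps; insertions relative to the reference are
invisible — a documented bias of the projection approach). Windows of
1 kb at 100 bp step slide over reference coordinates; windows with fewer than
100 projected sites are flagged low-coverage, and windows without segregating
sites are excluded from scan averages.

Tajima's D uses the standard 1989 constants; its p-value uses the
beta-distribution approximation. Fu & Li's D* is the no-outgroup statistic
driven by the singleton count, with the corrected n-dependent coefficients.
Correctness is pinned three ways: an exact-rational transcription of the
constants on a worked n = 4 micro-case (D ≈ −0.710), exhaustive n = 4
micro-cases, and calibration against msprime coalescent simulations (mean D
and D* within sampling error of zero). A star-shaped genealogy — e.g.
haplotypes radiating independently from a founder — produces genuinely
negative D by singleton excess; that is a property of the history, not an
estimator bias.

π is reported strictly per site. Group comparisons of windowed π use a
two-sided Mann–Whitney U: exact enumeration when both groups have n ≤ 8,
normal approximation with tie correction otherwise; all-tied input returns
p = 1.

## Molecular evolution (`molevol`)

* **K2P**: k = −½ ln(1−2P−Q) − ¼ ln(1−2Q) over unambiguous columns;
  saturation (non-positive log argument) yields an undefined, flagged
  distance.
* **Divergence time**: T = k/(2r), default r = 1.3×10⁻⁸
  substitutions·site⁻¹·yr⁻¹ (the grass neutral rate conventionally used for
  LTR dating); T scales exactly as 1/r.
* **Ka/Ks**: Nei–Gojobori (1986). Site counts weight each codon position by
  the fraction of its three changes that are synonymous; changes into stop
  codons count as nonsynonymous so N + S = 3 × codons exactly. Differences
  average over substitution pathways, excluding pathways through stop codons
  whenever a stop-free pathway exists. Proportions are Jukes–Cantor
  corrected. NG86 was chosen over approximate-ML estimators because it is
  fully specifiable and verifiable against codon-table enumeration; at the
  1–5 % coding divergences this package targets the difference is
  immaterial. The method name is recorded in every output row.
* **Fisher exact selection test**: two-sided test of the neutral null
  Sd/S = Nd/N on the 2×2 table of rounded (half-up) substitution and
  non-substituted site counts; zero-margin tables give p = 1.
* **Allele grouping**: pairwise divergence times per locus from the
  synonymous clock (T = Ks/(2r), configurable to total coding K2P); T_max and
  the most divergent allele are reported; groups are maximal cliques of ≥ 3
  alleles with all pairwise times < T_max/3, found exactly (allele counts at
  one locus are small). With T_max = 0 all alleles are identical and form a
  single group. Clique semantics (rather than tree-branch membership, which
  the source material leaves ambiguous) were chosen because they are exactly
  testable against subset enumeration.

## Origin classification (`origin`)

Three evidence channels, in decreasing precedence:

1. **Per-locus votes.** For each gene in reference order, allele grouping is
   run over both panels plus the query. The vote is the species whose panel
   alleles co-occur with the query in a group; mixed groups vote "shared".
   Two safeguards keep the channel conservative: the query's nearest panel
   allele (smallest pairwise time) must itself sit in the query's group, and
   loci carried by the panels of exactly one species vote by
   presence/absence — the species-specific-gene analogue of a diagnostic
   InDel. This channel defaults to total coding-region K2P for the time
   matrix: it has ~4× the informative sites of Ks alone, which halves the
   per-locus time noise, and under near-neutral coding divergence the two
   clocks agree in expectation.
2. **Diagnostic markers.** Maximal reference intervals ≥ 500 bp aligned
   (≥ 80 % coverage) in every member of one panel and essentially unaligned
   (< 20 %) in every member of the other. The 500 bp floor keeps sensitivity
   on compact synthetic loci while real diagnostic insertions are multi-kb.
   Queries vote by their coverage of each marker interval, and each marker
   vote is slotted into the ordered vote sequence after the marker's left
   flanking gene — a diagnostic InDel is itself a locus, and treating it
   positionally lets a carried marker plus downstream other-species votes
   resolve a recombinant even when clique votes are uninformative.
3. **Panel identity.** Mean gapless identity to each panel — always
   reported, used only as a tiebreak. Raw identity can genuinely mislead: a
   haplotype may be globally closer to the wrong panel (e.g. through shared
   repeat content) while every informative locus groups it with the right
   species, which is why the channel ranks last.

A single species across the ordered effective votes ⇒ that species; exactly
one switch ⇒ *recombinant*, with the breakpoint interval bracketed by the
nearest query-annotated loci on each side of the switch; two or more
switches ⇒ *unresolved* (the target system's recombinants have single
breakpoints; multi-switch patterns indicate either noise or histories the
model does not cover).

## LTR dating (`tedate`)

Elements arrive annotated (GFF3 or simulator truth); de novo structure
discovery is out of scope. Validation checks LTR-pair global-alignment
identity ≥ 60 % and target-site-duplication equality with ≤ 1 mismatch
tolerated. Dating aligns the two LTRs globally (affine scores +1/−1/−4/−0.3),
computes K2P over ungapped columns only, and converts with T = k/(2r).
Dating is strand-invariant and unbiased on simulated elements (mean relative
error < 5 % at 1 kb LTRs, 1 My).

## The simulator (`simlocus`) and what it does and does not emulate

The generator's defaults encode the study conditions of a gene-dense
polyploid grass locus: 13 genes over ~85 kb of template (haplotypes grow to
~100–115 kb after insertions), GC 45 %, two species panels (4 + 2 members),
seven hybrid queries (4 + 2 + one recombinant), within-species pairwise SNP
densities of ~1.78 % (species A) and ~1.30 % (species B), between-species
~2.06 %, a 3 kb species-A diagnostic insertion, two species-A-specific genes
deleted from species B, two segmental insertions of 2–8 kb per haplotype and
nine LTR elements (1 kb LTRs, 5 bp TSDs, 3 kb internal) at ages 0–1.28 My —
together producing gap fractions of roughly 20–50 % of aligned columns.

Design choices worth spelling out:

* **Mutation process**: independent-site substitutions with a two-rate
  transition/transversion scheme (κ = 2), i.e. the generating process of the
  K2P estimator used downstream; no across-site rate heterogeneity.
  Substitutions that would create a premature stop codon are rejected
  (nonsense mutations are purged by selection); pseudogenization enters only
  through insertions, and insertions into exons mark the gene pseudo.
* **InDels**: a geometric small-indel channel (mean 4 bp, 2×10⁻⁴ events per
  site, exon-protected) plus an explicit segmental channel for multi-kb
  events — large InDels in real loci are TE insertions and segmental
  duplications, not the tail of a smooth length law.
* **Panel structure**: member branch lengths are heterogeneous (depth
  factors 0.35/0.35/1.0/2.4 × the species base for panel A; 1.0/1.0 for B),
  solved so the *mean* pairwise densities equal the conditions above while
  individual pairs span a realistic range (~0.6–4 %). Homeologous copies in
  an autopolyploid are exactly such a mixture of shallow and deep
  coalescences, and the deep member supplies the T_max that makes the
  grouping threshold meaningful. With homogeneous panels at these densities
  the T_max/3 clique rule cannot separate species at all — within- and
  between-species divergences differ by only ~0.3 percentage points.
* **Query descent**: hybrid queries evolve from *specific panel lineages* at
  0.1 % divergence, reflecting that hybrid cultivar haplotypes are sampled
  from the same allele pools as the progenitor panels within the last
  century, not drawn independently from species ancestors. This recent
  descent is what makes per-locus grouping informative for origin
  assignment, in the simulator as in reality.
* **Recombination** is a single uniform crossover between two shared genes,
  placed by default just upstream of the species-specific region so the
  suffix carries the diagnostic absence. Coalescent genealogies,
  multi-breakpoint recombination and TE nesting are out of scope.
* **Coordinates**: 0-based half-open throughout; GFF3 written 1-based
  inclusive; truth coordinates are lifted through every later insertion so
  the emitted truth JSON always refers to final coordinates.
* **TSD length** defaults to 5 bp, the typical LTR-retrotransposon target
  site duplication.

What passing tests show: the pipeline recovers planted divergences within
binomial error, marker boundaries within ±50 bp, LTR ages within 15 %
(1 kb LTRs, ≥ 0.5 My), the recombinant breakpoint in ≥ 90 % of seeded
replicates, and species partitions when within ≪ between divergence. What
they do not show: robustness to assembly error, to nested/fragmented TEs, to
rate heterogeneity along the sequence, to gene conversion between LTRs
(which biases ages young), or to panels that undersample the allele pool —
real haplotype panels of 2–4 members per species are close to that limit.

## Numerical and procedural details

* All randomness flows from explicit integer seeds (numpy `SeedSequence`
  spawning); fixed seed ⇒ byte-identical bundles and reports.
* Saturated distances (K2P log-domain violations, Jukes–Cantor p ≥ 3/4)
  propagate as flagged undefined values; they are excluded from grouping with
  a warning rather than clipped.
* Window averages of D and D* exclude undefined (S = 0) windows.
* Alignment statistics are computed on collinear blocks only; candidate
  inversions are reported separately and count toward the gap fraction of
  the collinear view.
* The pipeline aborts on the first failing stage, naming it, and preserves
  the outputs of completed stages; the JSON manifest records package
  version, parameters and seed.

## Problem sizes

Defaults throughout the tests and the acceptance script were chosen to keep
a full run on one CPU in a few minutes: the full-scale study uses the 13-gene
~110 kb haplotypes exactly as the default conditions specify, while
replicate-heavy checks (breakpoint recovery, grouping round-trips) use
6-gene ~15–20 kb loci with the same divergence structure — the statistics
under test are per-site quantities, so locus length only sets the sampling
error, which the tests account for explicitly.
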