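# Methods

## Genotyping model

Each single-spore isolate (SSI) of a basidiomycete dikaryon is a haploid
meiotic product: at every locus it carries exactly one of the two parental
haplotypes, A (the reference assembly) or B. Genotyping is reference-based:
reads are mapped to the A assembly and compared with a catalog of biallelic
SNP positions that distinguish the parents.

Per read (`readclass`):

* unmapped records are set aside; records with mapping quality below
  `min_mapq` (default 1) or reported multi-mapping are **repetitive**;
  supplementary records, and primaries whose split (SA) alignment lands on
  another scaffold or more than `chimera_min_distance` (default 1 kbp) away,
  are **chimeric** — all three classes cast no vote;
* catalog sites under the aligned span are tallied: a base equal to the B
  allele with Phred ≥ `min_base_quality` (default 20) counts toward B, a base
  equal to the A allele toward A. The read votes **B** on a strict B majority;
  otherwise it votes **A** — ties included, and reads covering *no* SNP site
  are A votes. This reproduces the reference-based convention faithfully,
  including its asymmetry (a vanished B signal degrades to A, never the
  reverse); `informative_only` restricts voting to SNP-covering reads for
  users who want the symmetric estimator;
* a would-be A vote showing more than `max_nonsnp_mismatches` (default 10)
  off-catalog mismatches (from the NM tag, SNP-site mismatches subtracted)
  is demoted to **ambiguous** and does not vote. The default tolerates the
  ~2 expected mismatches of a 378 bp read at 0.5% error with a wide margin.

Per scaffold and isolate (`genotyper`), the genotype is the simple majority
of its read votes: A/B on a strict majority, X on a tie with at least one
vote, "–" with no votes. X and "–" are both treated as missing downstream —
neither carries a usable parental call.

### Turning points

A crossover inside a scaffold makes the whole-scaffold majority misleading
for loci on the minority side. `scan_turning_point` runs an exhaustive
change-point search over the position-ordered voting reads: every split
between consecutive reads is scored by the total majority-vote
misclassifications of the two segments, and the best split is reported when
both segments hold ≥ `min_segment_reads` (default 5) voting reads, their
majority codes differ, and the split removes ≥ `min_score` (default 3)
misclassifications relative to the unsplit call. The original workflow
handled such cases by manual curation, so the scan emits metadata only;
`split_at_turning_points` optionally replaces flagged scaffolds by locus-
restricted left/right sub-markers split at the median detected breakpoint.
The two defaults are this package's choice (no published thresholds exist):
5 reads give a segment its own defensible majority, and a gain of 3
misclassified reads separates real switches from vote noise at the ~20-40
reads per scaffold typical of 1-1.5× coverage.

## Linkage mapping

* **Segregation screen.** Haploid progeny segregate 1:1; each marker's A:B
  counts are tested with a 1-df χ² and the marker is retained when P ≥ α
  (default 0.05). Markers with fewer than two informative calls are dropped.
  (The screen retains markers *consistent* with 1:1 — the standard practice;
  distorted markers are excluded.)
* **Two-point statistics.** For markers i, j: N = isolates with parental
  calls at both, R = discordant pairs, r̂ = R/N. The LOD is the backcross
  log-likelihood ratio at r̂ versus r = 0.5, computed exactly with the
  0·log 0 = 0 convention so that LOD = N·log₁₀2 at R = 0; no boundary
  regularisation is needed. Pairs with N < `n_min` (default 5) get LOD 0.
* **Mapping functions.** Kosambi d = 25·ln((1+2r)/(1−2r)) (default; allows
  partial interference) or Haldane d = −50·ln(1−2r); r ≥ 0.5 is reported as
  infinite distance and never grouped.
* **Grouping.** Single-linkage transitive closure over edges satisfying
  *both* LOD ≥ `lod_min` (default 3) and distance ≤ `max_gap_cm` (default
  25 cM). The partition is invariant to marker input order and A/B label
  swaps.
* **Ordering.** The objective is the sum of adjacent distances (SARF).
  Groups of ≤ 12 markers are solved exactly by Held–Karp subset dynamic
  programming; larger groups use nearest-neighbour construction from every
  start followed by 2-opt refinement. Orders are defined up to reversal; the
  orientation with the lexicographically smaller terminal marker first is
  reported. Pairs whose r̂ is inestimable (N < n_min) or ≥ 0.5 enter the
  ordering matrix with a large finite penalty; since groups are connected
  through short valid edges, penalties do not become adjacent in practice,
  and a group whose valid-edge graph disconnects raises an error naming the
  break.
* **Positions.** Cumulative adjacent two-point distances from 0 — the
  two-point convention; no multipoint likelihood is computed.
* Groups are named LG1, LG2, … by decreasing genetic span. Groups spanning
  ≤ `min_group_span_cm` (default 20 cM) are kept but reported separately
  from the headline groups, mirroring the convention of counting only
  groups longer than 20 cM.

## Summary statistics (`report`)

Per group: length = position of the last marker; average spacing =
length/(n_markers − 1) gaps; physical size = Σ member scaffold lengths;
ratio = kbp per cM. Map-wide: the overall average spacing pools gaps
(total length / (total markers − n groups)); the average ratio is the
*unweighted* mean of per-group ratios; genome coverage = total anchored
kbp / genome size. Both conventions were chosen because they are the ones
that reproduce the published table's arithmetic. Values are carried at full
precision and rounded half-to-even to one decimal only at the report
boundary. Concordance against experimental genotype tables (mating tests,
PCR-SSCP) compares whole-scaffold calls, or locus-restricted recounts when
an interval is supplied, and annotates discordances with any turning-point
record on the same cell.

## Synthetic data (`simdata`)

The generator emulates the study design end to end:

* **Parents.** Parent A is a random reference partitioned into scaffolds
  laid contiguously onto chromosomes; parent B differs at Poisson-placed
  biallelic SNPs at `snp_rate` (default 4.6×10⁻³/bp, the catalog density
  implied by 186,079 SNPs over a 40.2 Mb assembly). SNP placement is
  uniform; real SNP clustering is not modelled.
* **Meiosis.** Crossovers per chromosome are Poisson with mean (genetic
  length)/100 Morgans, positions uniform, starting haplotype a fair coin —
  Haldane's no-interference model, so loci d cM apart are recombinant with
  probability (1−e^(−2d/100))/2. Each isolate is an independent meiotic
  product (no tetrad structure). The generative model is deliberately
  Haldane while the estimator defaults to Kosambi: the simplest correct
  process versus the field's standard estimator; at the short distances that
  dominate a dense map the mismatch is ~3% and it is visible in the
  parameter-recovery tests' tolerance.
* **Reads.** Read count per isolate is Poisson(coverage·G/ℓ̄); lengths are
  Normal(378, 60) bp truncated at 50 bp (the per-read spread is this
  package's choice — only per-isolate mean lengths of 367–392 bp are
  documented); starts are uniform over the isolate's mosaic genome;
  substitution errors at `error_rate` (homopolymer indels of the 454
  chemistry are not modelled — genotyping rests on SNP-site substitutions).
  A `chimera_fraction` (default 14.3%) of reads join two random loci and a
  `repeat_fraction` (default 5.3%) emulate multi-mapping. Truth SAMs mark
  repeats with MAPQ 0 and chimeras as split primary+supplementary records
  with SA tags — explicit, reproducible proxies for classifications the
  original vendor mapper made internally. All reads are written on the
  forward strand; strand is irrelevant to vote tallies.
* **Truth.** Every (isolate, scaffold) cell records the haplotype occupying
  the larger share of the scaffold plus any within-scaffold breakpoints
  (cM mapped linearly to bp), so genotyping accuracy and turning-point
  localisation can be scored exactly.

What passing tests show — and what they do not: the simulator reproduces the
sampling noise, missingness, artifact load and crossover structure of the
design, but not reference mis-assembly, mapping bias, coverage unevenness or
SNP clustering of real data. Accuracy numbers on synthetic data are
therefore an upper bound on real-data performance at the same design
parameters.

## Problem sizes and numerical choices

Validation suites run at desk scale by design: the recovery experiments use
a 2-chromosome, 60-scaffold, 480 kb genome (12–20 isolates, 0.25–2×
coverage) and a full-information 8-chromosome, 200-marker, 100-isolate
population for group recovery — the latter matching the default generator
configuration, whose 8 × 80 cM chromosomes echo the organism's karyotype
and genome-wide map length. Accuracy fixtures give scaffolds a ~2 cM
genetic span, on the order of the study's marker density; at much sparser
scaffold tilings the within-scaffold-crossover failure mode (documented
above) dominates the error budget, which is a property of the method, not
of this implementation. Determinism: all stages draw from per-stage
generators spawned from a single seed; identical configurations yield
byte-identical FASTA/VCF/FASTQ/SAM outputs and identical pipeline manifest
digests. Tie-breaks: read-vote ties go to A (the reference state);
turning-point ties go to the leftmost split; ordering reversal ties are
resolved lexicographically. Degenerate inputs (empty SAMs, zero-read
isolates, SNP-free scaffolds, singleton groups) warn or raise as described
in each docstring rather than propagating silently.

## Known limitations

* Whole-scaffold majority voting miscalls loci on the minority side of a
  within-scaffold crossover; the turning-point scan flags but does not
  automatically fix these (opt-in splitting only).
* Two-point distances underestimate map length when many adjacent pairs
  show zero recombinants in small populations, and small populations
  fragment groups — both visible in the 20-isolate worked example.
* The LOD model assumes error-free genotype calls; genotyping noise at very
  low coverage inflates r̂ slightly.
* No imputation, no multipoint likelihood, no interference estimation, no
  diploid/dikaryotic mixtures.
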