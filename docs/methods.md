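# Methods

`cretrace` implements a phylogenetic screen for conserved cis-regulatory
elements (CREs): given template regulatory sequences that direct gene
expression to a homologous brain boundary region in flies and vertebrates
(the deutocerebral–tritocerebral boundary, DTB, and the midbrain–hindbrain
boundary, MHB), it searches the gene loci of other species for "CRE-like"
sequences, scores them against a random-sequence null, and asks which
evolutionary scenario — one origin with losses, or many independent gains —
most parsimoniously explains the resulting presence/absence pattern on a
species tree.

## Screening model

A locus is screened by local alignment of its regions against a template:

* the full gene span, introns included, for the *sv/PAX2* and *dac/DACH1*
  classes (detected elements sit in introns);
* additionally up to 5 kb of upstream and downstream intergenic flank for
  the *inv/EN2* class (`flank_bp`, default 5000, truncated at contig ends).

Both strands are screened; the source screen is silent on strand, and
orthologous elements can invert, so screening the reverse strand is the
conservative choice (forward-strand hits win residual ties).

A hit is called CRE-like when its single best alignment satisfies:

1. linkage to the same homologous gene — guaranteed structurally, since
   loci are supplied per gene class;
2. **identity ≥ 60% over ≥ 55 alignment columns** (both bounds inclusive;
   gap columns count against identity). An optional Karlin–Altschul
   expect-value cut (`max_evalue` = 0.1) exists but is off by default: the
   original procedure quotes a "BLAST e-value" for output of a tool that
   does not emit one, so the identity/length bounds are treated as the
   primary filter and the E-value as advisory;
3. noncoding: the hit interval overlaps no annotated CDS interval
   (introns, UTRs and flanks all qualify);
4. non-repetitive: implemented as a dinucleotide-entropy filter (Shannon
   entropy of 2-mer frequencies < 1.5 bits flags low complexity). The
   original check was a manual BLAST inspection; an entropy proxy is the
   closest automatable equivalent and is configurable.

Per species and class the call vocabulary is `no_gene_homolog`,
`gene_present_cre_absent`, `cre_present`, or `not_accessible`, mirroring
the four matrix symbols of the source screen. The best hit is selected by
score, then alignment length, then leftmost contig start — a deterministic
total order.

## Alignment

Alignments are computed by an in-package Waterman–Eggert algorithm:
Smith–Waterman with affine gaps for the optimum, then successive
re-computation with previously aligned residue pairs forbidden, yielding
the top-k non-intersecting local alignments. Scoring is the EDNAFULL
(NUC.4.4) table — match +5, mismatch −4, with the standard ambiguity-code
values; `N` never counts as identical. Gap penalties follow the EMBOSS
Matcher DNA defaults, open 16 and extend 4, with a length-L gap costing
`16 + (L−1)·4`; the penalties are unstated in the source and are exposed
as configuration. k defaults to 1 (the single reported alignment).

The DP kernels are numba-compiled. Ties in the DP cell maximum resolve
substitution > gap-in-query > gap-in-template, and the best cell is the
first maximum in row-major order, making output deterministic. Correctness
is checked two independent ways: against exhaustive enumeration of all
gapped local alignments for short strings, and against Biopython's
`PairwiseAligner` (an independent C implementation) on longer pairs.

The expect value `E = K·m·n·exp(−λ·score)` uses λ solved exactly from the
ungapped score composition at the background GC (Brent root of
`Σ pᵢpⱼ e^{λ sᵢⱼ} = 1`) and a configurable order-of-magnitude constant
K = 0.1; gapped λ and K are not estimated. It is documented, and should be
read, as an approximation.

## Homology index

For an alignment of `L` columns at identity `pid` against a template of
length `T`,

    HI = (L / T × pid) / 100,

so a full-length perfect self-match has HI 1. Reported HI values are
**truncated**, not rounded, to three decimals: the floor value at the
screening criteria, `HI_min = (55 / T × 60) / 100`, is 0.09269… for
T = 356 and is conventionally reported as 0.092, which fixes the
truncation rule (rounding would give 0.093). `HI_min` is 0.092 / 0.133 /
0.088 for the 356 / 247 / 373 nt templates. "Sequence length" in the
formula is taken as alignment columns — the quantity the length threshold
constrains.

Because HI is monotone in both alignment length and identity, any
alignment passing the criteria has HI ≥ HI_min by construction; the
discriminating observation is *how far above* the floor a hit sits.
Random-sequence passers barely clear it (HI ≈ 0.10–0.17), while planted
or genuine CRE-like hits spanning most of the template at ≥ 70% identity
sit near 0.7–1.0. An add-one empirical p-value
`(1 + #{null HI ≥ observed}) / (1 + n_null)` formalizes the comparison,
counting non-passing nulls as HI 0.

## Random-sequence null

The null model draws 50 i.i.d. sequences per template at the template's
length with P(G) = P(C) = 0.20 and P(A) = P(T) = 0.30 (GC fraction 0.40,
approximating average genomic composition), aligns each to the template
(forward strand, best alignment only, matching the published procedure),
and counts passers. Two quirks of the published generator snippet are
documented but not reproduced: its weight vector normalizes to GC = 1/3
rather than the stated 40:60, and its length list begins 365 where the
text (and the template itself) says 356. This package follows the stated
distribution (GC 0.40) and length (356); only the distribution, not the
PRNG stream, is reproduced (NumPy PCG64, fully seeded).

At these conditions the measured pass rate is ~8–15% per 50 (means ≈ 7.2,
5.2 and 7.2 at lengths 356, 247, 373 over 20 seeds), consistent with the
published counts of 4, 5 and 7 within binomial sampling error
(sd ≈ 2.2 per count of 50).

## Parsimony on the species tree

Characters are binary presence/absence per species; `?` marks inaccessible
genomes or absent gene homologs and constrains nothing in event counting.
The aggregate **network** character is present when ≥ 2 of the 3 CRE
classes are present (`min_present`, configurable 1–3); `?` counts as
not-present there, since a network call needs positive evidence. The
2-of-3 default is the only aggregation consistent with the published
reading in which species missing exactly one class still count as
network-bearing while species with zero classes do not.

* **Dollo losses**: with a single gain fixed on the branch to a named
  ancestor (default PDA, the protostome–deuterostome ancestor), the
  minimal loss count equals the number of maximal subtrees below the gain
  containing an absent tip and no present tip. Presences outside the gain
  clade make the scenario infeasible (raised as an error; the pipeline
  then falls back to the most recent common ancestor of present tips).
* **Gains-only** (Camin–Sokal, no reversals): the number of maximal
  subtrees containing a present tip and no absent tip.
* **Fitch changes**: unordered binary parsimony, counted bottom-up; on
  multifurcations the increment is the minority vote among resolved child
  state sets, which is exact for binary characters.
* **Lineage gains**: under the convergence reading, one gain per named
  lineage containing at least one presence; the default partition is the
  six brain-bearing lineages (chordates, brachiopods, annelids, molluscs,
  panarthropods, nematodes).

All three counting routines are validated against brute-force enumeration
(all internal labelings / all event placements) on trees of up to eight
tips. On the packaged tree and matrix, the single-origin scenario at PDA
implies 2 losses (hemichordate, priapulid) versus 6 independent lineage
gains under convergence.

The packaged tree is a rooted topology over the 18 screened species with
the PDA and LCBA ancestors labelled; branch lengths are not used.

## Synthetic data

The generator emulates the screening design, not genomes. Defaults, fixed
once as the study conditions:

* templates: random sequences of 356 / 247 / 373 nt at GC 0.40 (stand-ins
  for the real template CREs, which are not redistributable);
* locus architecture: three 200 nt exons (CDS), two 800 nt introns, 1 kb
  flanks — contig 4.2 kb, large enough to host any template mid-intron or
  mid-flank with realistic noncoding context, small enough for fast
  alignment;
* divergence: per-column substitutions plus geometric indels
  (rate 0.02/column, mean length 2). The substitution rate is set to
  `1 − (target/100)/(1 − 2·indel_rate)` — slightly below the naive
  `(100−target)/100` — to compensate for gap columns, and the draw is
  repeated until the realized re-alignment identity is within 5 points of
  target, so the per-element contract holds exactly rather than in
  expectation;
* scenario: gain at PDA, losses on the hemichordate and priapulid tips,
  mirroring the published pattern; species outside the gain clade receive
  negative loci of identical architecture.

What passing tests show: the screen recovers every planted element at
target identity ≥ 70% (sensitivity 39/39 per dataset across replicates),
maps strand and interval correctly, and the recovered event counts match
the planted scenario when no false positive intervenes. What they do not
show: behaviour on real genomes — repeat content, base composition
heterogeneity, paralogous copies and assembly gaps are all absent from the
generator.

## Known limitation: false positives scale with search space

The threshold criteria themselves admit random matches at a measurable
rate: ~8–15% of random 356-nt sequences pass against a 356-nt template,
and because the expected best-alignment score grows with log(m·n), the
per-locus false-positive rate rises with noncoding search space — measured
at ~33% per kb-scale negative locus and ~50–60% at 2–4 kb (both strands).
Consequently, exact recovery of a full presence/absence matrix containing
multi-kilobase negative loci is statistically impossible at these
thresholds: in 20 replicate datasets, sensitivity was 20/20 but exact
matrix recovery 0/20, with every failure a false positive on a negative
locus. This is a property of the 60%/55 bp criteria, not of the
implementation; the separation diagnostics (HI distance above HI_min,
empirical p-values) and the optional E-value cut — whose threshold scales
with search space — are the package's mitigations. Published screens of
real genomes report far cleaner negatives than i.i.d. sequence predicts,
suggesting real noncoding sequence is a harder target than the null model;
users screening real data should calibrate the null per locus size.

## Problem sizes and determinism

Test and analysis runs use 20 replicate seeds for null calibrations and
recovery experiments, 50 null sequences per calibration, and 18-species
datasets (54 loci) — sizes at which every distributional claim checked is
within a fraction of a binomial standard error of its asymptote. Every
random draw flows from an explicit seed (NumPy PCG64; per-purpose streams
derived via CRC-tagged seed sequences), and reports embed the seed and a
config hash, so any reported number is reproducible bit-for-bit.
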