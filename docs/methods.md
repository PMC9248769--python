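# Methods

## Clonotype definition and junction conventions

A VH clonotype is the tuple (IGHV gene, IGHJ gene, V 3′ deletion, J 5′
deletion, N-IGHD-N length, junction amino-acid sequence). The junction is
codon-based and inclusive: IMGT positions 104 (conserved Cys) through 118
(conserved Trp); CDRH3 is the junction with those two residues stripped, so
CDRH3 length = junction length − 2. Two consequences worth stating
explicitly:

- reads differing only by synonymous junction-nucleotide changes with the
  same segmentation collapse to one clonotype;
- reads with identical junction amino acids but different N-region lengths
  are *different* clonotypes — the segmentation is part of the clone's
  identity, because it records an independent recombination event.

D-gene identity is deliberately not part of the key; only the N-IGHD-N
length is. Junction amino-acid length is constrained to 5–32 residues.

Frequencies are percentages of reads with an identified rearrangement.
Non-productive rearrangements (junction out of frame, internal stop, or
missing C104/W118 anchors) are excluded from both the clonotype counts and
the denominator by default; `build_repertoire(..., productive_only=False)`
keeps them in the denominator.

## Diversity statistics

All diversity quantities use natural-log Shannon entropy
H = −Σ pᵢ ln pᵢ over clonotype frequencies:

- **Diversity** D = exp(H), the Hill number of order 1 ("effective number
  of clonotypes"): the only base/exponent combination for which "directly
  calculable from Shannon entropy" and "number of equally abundant
  clonotypes giving the observed average proportional abundance" are the
  same statement. For a uniform sample of S clonotypes D = S exactly.
- **Evenness** E = H / ln S (Pielou). For S = 1 this is 0/0 and is reported
  as NA rather than 0 or 1.
- **Dominance** = 100 · max count / total reads. Reported on the full
  sample by default (with the subsampled value alongside), since the
  most-frequent-clone share does not need depth normalization the way
  entropy does.

Because H and S are depth-dependent, statistics are computed on a fixed-size
random subsample (default 50,000 reads) drawn **without replacement**
(multivariate hypergeometric) — sequences are selected from a finite read
set, not resampled. Samples at or below the target depth are used unchanged.
The total/unique CDRH3 ratio ("1 of N") rounds half away from zero.

The CDRH3 spectratype is read-weighted, not clonotype-weighted: percent of
*reads* at each CDRH3 amino-acid length.

## Enrichment tracking

Fold enrichment = frequency(last round) / frequency(first round), computed
on full-sample frequencies (the smallest tracked frequencies, ~10⁻⁵ %, are
unresolvable at 50,000-read depth). No pseudocounts by default: a clonotype
unobserved in the first round gets status `not_evaluable` rather than a
fabricated fold; an optional floor of one read / denominator gives a
lower-bound fold when requested. Display rounding is nearest integer for
folds ≥ 10 and one decimal below — this convention reproduces every printed
per-antibody enrichment factor from its frequency pair. Final-round
frequencies are tiered <0.1 % / 0.1–1 % / >1 %; the classification band for
enriched/depleted/flat defaults to fold > 2 / < 0.5 / between.

## VH/VL clustering

Pairwise global protein alignment (BLOSUM62, affine gaps: open 10, extend 1
in score units) gives percent identity = 100 · matches / alignment columns,
with terminal-gap columns excluded from the denominator so unequal-length
pairs get a symmetric full-overlap denominator. Distances d = 1 −
identity/100 feed classic Saitou–Nei neighbor joining (via scikit-bio);
negative branch lengths are clamped to zero with the deficit moved to the
sibling branch, and n < 3 inputs return a trivial tree. NJ output is
unrooted; the dendrogram rendering roots at the midpoint. The grouping
report counts entries whose sequence occurs exactly once as "unique" — the
fraction used to judge how exhaustively a Sanger screen sampled the enriched
repertoire.

Alignment parameters are exposed because published dendrograms of this kind
rarely state their exact scoring; the identity-based distance is a
documented, reproducible stand-in for guide-tree distances of progressive
aligners.

## The panning simulator

The simulator emulates an immunized-mouse scFv library and its selection:

- **Germline genes** are synthetic: V genes end in a conserved Cys codon
  plus a 6-nt trimmable tail, J genes carry a 6-nt trimmable head before the
  conserved Trp codon and an 11-codon FR4 stub. V genes are apportioned over
  IGHV subgroups by largest remainder (census within ±1 of the weights);
  default weights put IGHV1/IGHV5/IGHV14 at 37 %/33 %/11 % — the dominant
  subgroups of such libraries — with the remainder uniform.
- **Clonotypes**: V per subgroup weights, J uniform, junction amino-acid
  length 5 + Binomial(14, 0.5) + 2 anchors (bell-shaped CDRH3 law, mean 12
  residues). N-region nucleotides are uniform over {A,C,G,T}, redrawn until
  the junction is stop-free (displayed clones are productive by
  construction); junction amino-acid composition therefore follows codon
  multiplicities rather than being exactly uniform per residue, while the
  length law is exact.
- **Segmentation canonicalization**: nominal V/J trims are drawn, the read
  is assembled, then the stored truth segmentation is recomputed by maximal
  exact germline extension into the junction interior (V side first, then
  J). Random N nucleotides that happen to match trimmed germline are
  indistinguishable from germline in any alignment, so the canonical form is
  the only segmentation an annotator can recover; defining truth this way
  makes the error-free round trip exact by construction.
- **Abundances** are log-normal with σ = 1.45 over 5,000 clonotypes by
  default; this spread was fixed once so that simulated library evenness at
  a 50,000-read sample is ≈ 0.89, the moderately uneven value characteristic
  of an immune (affinity-matured) library, as opposed to ≈ 1 for a synthetic
  randomized library.
- **Selection** is single-locus multiplicative per round: target fitness
  t ~ lognormal(0, 1.5) and off-target fitness u ~ lognormal(0, 0.5) give an
  effective weight w = t/u per clonotype (depletion folded into the ratio —
  no separate depletion counts exist to calibrate against), and
  p′ᵢ = pᵢwᵢ / Σ pⱼwⱼ. Reads are drawn multinomially at the configured depth
  (default 50,000). No phage-growth bias, display-valency effects or
  cooperativity are modeled.
- **Sequencing error** is substitution-only (indels would break the
  codon-based junction frame), default 0, allowed up to 10 % per nt.

One seed in `PanningConfig` fixes every draw; identical config + seed gives
byte-identical emitted files.

### What the simulator does and does not show

Passing tests on simulated campaigns demonstrate that the statistics and
the tracking logic are correct and that selection signal of the modeled kind
is recovered (estimated per-round relative fitness from two-round fold
changes correlates with truth at Spearman ρ ≥ 0.95 at 10⁶ reads). They do
not validate annotation quality on real reads (real V genes are far more
similar to each other than the synthetic ones), nor amplification bias,
somatic-mutation lineages, or VH–VL pairing effects, all outside the model.

## Gene assignment (convenience path)

`assign_genes` matches each germline V core (start through the Cys codon)
against the read prefix and each J core (Trp codon through FR4) against the
read suffix by edit distance (edlib, prefix-mode), calls the best gene with
ties broken by name, rejects calls with distance above 20 % of the core
length, and infers trims by maximal germline extension as above. It is built
for simulator output and clean amplicons; production repertoire annotation
should come in as pre-annotated AIRR TSV (the primary input path).

## Problem sizes and numerics

Default analyses run at 5,000 clonotypes × 50,000 reads (diversity,
trajectories) and 2,000 clonotypes × 10⁶ reads (fitness recovery) — sizes at
which every reported check completes in seconds on one CPU while keeping
≥ 100 reads for the clonotypes whose fold changes matter. Frequency vectors
are validated to sum to 1 within 1e-6 before selection and 1e-9 in entropy;
entropy uses direct summation (no bias correction — the subsample fixes the
depth instead). Deterministic tie-breaks: gene calls by lexicographic name,
clonotype orderings by key fields, NJ joins by scikit-bio's smallest-index
convention.

## Known limitations

- Real IGHV alleles differ by a handful of nucleotides; the synthetic
  germline's genes are nearly orthogonal, so the ≥ 95 % V-call accuracy at
  1 % error overstates what the convenience annotator would achieve on real
  data.
- Light chains are handled only at the level of protein clustering and
  subgroup labels; there is no VL clonotyping.
- Diversity confidence intervals, rarefaction curves and richness
  estimators (Chao1 etc.) are out of scope.
- The most-frequent-clone statistic (dominance) is not forced monotone
  across rounds — after one round of mixed depletion/selection the library's
  top clone can fall before a selected clone overtakes it, which is also the
  observed pattern in real campaigns; only diversity and evenness are
  expected to fall monotonically under dispersed selection.
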