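# Methods

This note documents the models and procedures behind `taxotyper`, the
parameter defaults that matter, the numerical choices made where the design
was open, and the limits of what the synthetic-data tests demonstrate.

## Sequence handling

Records are uppercase DNA strings over `{A,C,G,T,N,-}`. On ingest, `U` is
mapped to `T` (16S data circulate in both DNA and RNA conventions) and
IUPAC ambiguity codes other than `N` are mapped to `N` with a warning: the
entropy, identity and selection machinery treats only `{A,C,G,T}` as
informative, so finer ambiguity distinctions would never be used. All
user-facing coordinates are 1-based and inclusive; internal indexing is
0-based. FASTA writing is line-wrapped at 70 columns, so read → write →
read round-trips are byte-stable.

Multiple alignment itself is out of scope: the pipeline ingests pre-aligned
input. Only pairwise global alignment is provided, as a Gotoh affine-gap
dynamic program (default match +2, mismatch −1, gap open −4, gap extend −1;
a gap of length L scores open + (L−1)·extend). Traceback tie-breaking is
fixed — substitution preferred over gap, then gap in the second sequence —
so aligned output is a pure function of the inputs.

## Masking and site classification

Columns whose gap fraction (counting `N` as a gap) *strictly exceeds* the
threshold (default 0.5) are removed; a column at exactly 50 % gaps is kept.
The strict inequality is deliberate: "more than half gaps" is the rule,
and the boundary case is retained. Manual curation of ambiguous characters
is replaced by the deterministic N-as-missing rule, which is reproducible
where hand-editing is not.

Site classification assesses columns over their non-gap, non-N residues:
one state → conserved; ≥ 2 states → variable; variable with at least two
states each carried by at least two sequences → parsimony-informative.
Columns with fewer than two informative residues are not assessed.

## Oligotyping

Per-column Shannon entropy is computed in bits over the `{A,C,G,T}`
frequencies among informative residues (gaps/N excluded, frequencies
renormalized); columns with fewer than two informative residues get
entropy 0. The choice of base only rescales the profile — the ranking that
drives position selection is base-invariant.

The scheme takes the k highest-entropy columns (default k = 12, the
convention for subtyping the *Acidithiobacillus* complex), ties broken
toward the lower column index, returned in ascending order. The canonical
12-position scheme spans variable regions V2–V6 at E. coli 16S coordinates
46, 47, 62, 257, 263, 264, 266, 417, 418, 588, 725, 765; because mapping
alignment columns to E. coli numbering depends on the particular alignment,
that mapping is accepted as optional user input and never computed.

Catalog classification is exact string matching: a packaged CSV carries the
18 named species-complex oligotypes (7 type-strain OTs for the recognized
species, 11 phylotype OTs labelled *Acidithiobacillus* sp. with their
subclade). Unmatched strings are "novel OT"; strings with more than
`max_missing` (default 0) gap/N positions are "unclassifiable". Frequency
tables partition OTs into major/minor at `min_major` with ≥ semantics
(default 3): a three-member oligotype counts as major, which keeps the
named three-member OTs on the major side of the split; the alternative
(> 3) would silently drop them, and the boundary case had to be decided one
way.

## Identity, divergence and trees

Divergence is uncorrected p-distance × 100. The species and genus
thresholds this package applies (1.3 % / 3 % divergence, 97 / 98.7 / 94 %
identity) are conventionally defined on uncorrected values, so correction
is off by default; a Jukes–Cantor-corrected mode is available behind a
flag. Comparable columns are counted with pairwise deletion (both residues
unambiguous), keeping pairs comparable across different gap patterns;
complete deletion is available for consistency with Tajima's D.

Group summaries report mean ± SD over the fixed set of within-group
(unordered distinct) or between-group (all cross) pairs; the SD uses the
population divisor n because the pair set is exhaustive, not a sample.
Within-group values are undefined for singletons and reported as such.

Neighbor joining is delegated to scikit-bio's Saitou–Nei implementation
with labels presented in sorted order (deterministic tie-breaking) and
negative branch lengths clamped to zero with the excess moved to the
sibling edge. It is plumbing for clade-recovery checks, not a substitute
for model-based phylogenetics. `is_monophyletic` tests whether any edge
bipartition of the (unrooted) tree separates exactly the query set,
including tip edges and complements.

## MLSA

Allele calling follows MLST convention: within a locus, every distinct
sequence (exact equality after uppercasing; length variants are distinct —
no trimming heuristics, which would introduce unreproducible choices) gets
a dense 1-based number in first-seen order. Identical allele-number vectors
across the 8-locus scheme share a sequence type; incomplete profiles never
receive an ST. Locus-name spelling variants seen in the literature
(`trx?`, `hsIV`, `ihfb`) are normalized to standard gene nomenclature
(`trx`, `hslV`, `ihfB`). Concatenation is column-wise in scheme order with
per-column provenance (locus, local column) retained; strains absent from
any locus are excluded with a warning.

## Selection statistics

**Tajima's D** uses the standard 1989 constants
(a₁ = Σ1/i, a₂ = Σ1/i², b₁, b₂, c₁, c₂, e₁, e₂) with
D = (π − S/a₁)/√(e₁S + e₂S(S−1)), where π is the mean pairwise difference
count and S the number of segregating sites. Complete deletion (columns
with any gap/N removed alignment-wide) is applied first, matching the most
common implementation default. D is NaN (not an exception) when S = 0.
A worked check: n = 4 with one singleton segregating site gives π = 0.5,
S = 1, D = −0.612.

**dN/dS** is unweighted Nei–Gojobori (1986) with Jukes–Cantor correction —
chosen because it is fully specifiable and is the default Nei–Gojobori
variant in the major phylogenetics packages. Potential synonymous sites per
codon are the per-position fractions of the three single-nucleotide changes
that are synonymous (changes to stops count as nonsynonymous), averaged
between the two codons of a pair; observed Sd/Nd for 2- and 3-difference
codons average all substitution orderings equally, dropping pathways that
pass through a stop and renormalizing (if every pathway is blocked, the
differences are counted as nonsynonymous). pN and pS are corrected with
d = −(3/4)·ln(1 − 4p/3); proportions ≥ 3/4 make the statistic NaN. The
ratio is mean dN over mean dS across pairs; dS = 0 gives NaN. The genetic
code is the bacterial table (11), identical to the standard code at every
codon. Per-group ratios restrict the pair set to within-group pairs;
whether to pool all pairs or stratify by clade is exposed as the caller's
choice (`nei_gojobori` vs `branch_group_dnds`), with pooled as default.

## Delineation

Pairwise verdicts act on *mean* between-group values. With MLSA evidence,
divergence strictly above the 3 % species threshold → `distinct_species`,
otherwise `not_distinct` — strictly, so a pair at exactly 3.0 % is not
split. With 16S only, identity below 100 − 1.3 % decides. When both tiers
are present and disagree the verdict is `conflicting`. A `candidate_genus`
flag (never an automatic rename — genus assignment needs criteria beyond
sequence identity) trips when 16S identity falls below 94 % or MLSA
divergence exceeds a configurable multiple (default 4×) of the species
threshold.

The audit is defined record-wise: *novel* (OT absent from the catalog or
unclassifiable), else *unassigned* (no declared taxon; the OT-derived taxon
is attached as a proposal), else *correct*/*mis-assigned* by comparing
declared and OT-derived taxa. These four categories partition any input.
Mis-assignment rates are reported overall and per record kind
(isolate/clone) when a kind mapping is supplied, since the two kinds of
records have different error processes (experimental misdiagnosis vs
database annotation).

## Synthetic species complex

The generator emulates the statistical structure the analysis assumes: a
star phylogeny of c clades radiating from a root sequence drawn at the
target G+C (default 0.55, matching typical values for these genomes), with
strains radiating from each clade ancestor. Evolution is Jukes–Cantor;
branch lengths are set so the *expected* pairwise p-distance equals the
target, via p = (3/4)(1 − e^(−4d/3)) for a path of d expected
substitutions per site. Defaults: 16S length 1054 (the masked-alignment
width typical for this marker set), 2 rRNA copies per genome at 0 copy
divergence (operon copies in these taxa are identical or nearly so),
inter-clade divergence 0.10, within-clade divergence 0.005, 8 coding loci
sized like the MLSA scheme's fragments (296, 98, 161, 282, 96, 75, 144,
93 codons), ω = 0.1 (housekeeping genes under strong purifying selection),
mislabel rate 0.2 (between the mis-assignment levels observed for isolates
and sequence clones in public records of this complex).

Coding loci evolve codon-wise: each proposed substitution is rejected if it
creates a stop, accepted with probability ω if nonsynonymous, and always
accepted if synonymous. Mislabeled records draw their declared taxon
uniformly from the other clades, which makes the audit's measured
mis-assignment rate a binomial estimator of the configured rate.
`plant_oligotype_signal` overwrites the scheme positions with per-clade
strings, guaranteeing OT separability for classifier tests.

What the generator does **not** emulate: indels and alignment uncertainty
(alignments are gap-free; gap handling is tested on hand-built fixtures),
rate variation across sites and lineages, base-composition drift,
recombination/HGT, chimeras, and sequencing error. Tests passing on this
synthetic data therefore demonstrate the correctness of the computations
and decision rules under the stated model — not robustness to alignment
error or non-neutral evolutionary complications in real 16S surveys.

## Problem sizes and numerics

The test suite and the acceptance script run simulations at modest sizes
chosen to make Monte-Carlo checks sharp without waste: oracle comparisons
use 100 randomized small instances per statistic; divergence recovery uses
length-1054 sequences judged against 3 binomial standard errors; the
ω = 0.1 vs ω = 1 separation uses 20 replicates of 8 sequences × 900 bp;
mislabel recovery uses 120 strains against a 3σ binomial interval.
Stochastic assertions are derandomized with fixed seeds. Statistics that
are mathematically undefined on an input (D with S = 0, dN/dS with dS = 0
or p ≥ 3/4) return NaN sentinels rather than raising, so tabulation over
many loci never aborts; genuinely invalid input (internal stop codons,
ragged alignments, out-of-range thresholds) raises.

## Known limitations

- Catalog classification is exact matching only; no nearest-OT assignment
  is attempted (a one-off string is reported novel, not fuzzily matched),
  because the discriminative positions are single nucleotides apart between
  sister taxa and fuzzy matching would erase exactly the distinctions the
  method exists to draw.
- The 3 %/1.3 %/94 % cutoffs are conventions, not laws; the package
  reports verdicts against configurable thresholds and echoes the
  thresholds used into every report rather than claiming taxonomic acts.
- The automatic gap-fraction mask is a deterministic stand-in for manual
  alignment curation; on real data the two can retain different column
  sets, so masked-alignment widths are approximate, not exact.
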