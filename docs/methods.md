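# Methods

## The eight-cysteine motif and its scanner

Plant nsLTPs carry eight cysteines in the backbone
`C-Xn-C-Xn-CC-CXC-Xn-C-Xn-C`. A match is an assignment of eight
cysteine positions c1 < … < c8 of the mature peptide with c4 = c3+1
(the CC dipeptide), c6 = c5+2 (the CXC tripeptide), and a
non-cysteine at the X of CXC — allowing a cysteine there would make
assignments ambiguous, and the observed CXC centres are drawn from
twelve non-cysteine residues. The scanner backtracks over cysteine
positions anchored on CC and CXC occurrences and returns every
assignment whose seven spacer lengths (head, g12, g23, g45, g67, g78,
tail) fall within configurable bounds; the test suite proves it
equivalent to brute-force enumeration of all 8-subsets of cysteines.

Default bounds are an envelope of the gap lengths observed across the
eight cotton subfamilies, padded by about two residues (head 0–16,
g12 4–16, g23 7–19, g45 6–22, g67 10–29, g78 4–17, tail 0–40).
Unbounded spacers would make the backbone matchable in nearly any
cysteine-rich protein, so the envelope — not an open-ended pattern —
is the scanner's definition of the motif. Scanning is done on the
mature peptide when the signal-peptide cleavage site is known (the
head lengths describe the mature protein), else on the full sequence.

Sequences with extra cysteines can yield several assignments;
`best_match` prefers matches that classify to a subfamily (highest
score first) and breaks ties toward the earliest, most compact match.
This resolution rule is the package's own choice and is flagged in
output, since manual curation in family surveys is not reproducible.

## Subfamily classification

Each subfamily (Types I, II, III, IV, V, VI, VIII, IX — no Type VII
occurs in *Gossypium*) is a finite set of permitted lengths per
spacer, shipped as versioned YAML (`data/spacing_rules.yaml`) and
frozen byte-for-byte by a test fixture. A spacing vector scores one
point per core gap (g12, g23, g45, g67, g78) inside a type's set; a
label is assigned only when a unique best type reaches ≥ 4 of 5.
Head and tail, which vary far more, only break exact-score ties.
Near-misses keep their best label but stay UNCLASSIFIED — in real
surveys typing is corroborated by phylogeny, which is out of scope
here, so silent mis-typing is worse than abstention. An exhaustive
test verifies the eight rule rows are pairwise separable: every fully
rule-conformant core spacing classifies uniquely to its own type.

The CXC central residue is classed hydrophilic ({R,G,E,D,Q,S,K}) or
hydrophobic ({Y,F,L,V,M}); residues outside both observed sets are
"other" rather than being projected onto a hydropathy scale. Family
composition percentages take the total family size as an explicit
denominator, since classified counts may undercount the family.

## Screening cascade

Candidates pass, in order: valid 8 CM (with a separate MISSING_CYS
code when fewer than eight cysteines exist at all), proline content,
signal peptide, GPI anchor, storage-protein similarity, mature length
≤ 120 aa. All failing reasons are recorded, not just the first, so
filter order affects only reason ordering. Parameters:

* `max_mature_len` = 120 aa (the family's defining size cut-off);
  mature length = full length − cleavage position.
* `proline_fraction_max` = 0.15. "Proline-rich" has no standard
  numeric definition; hybrid proline-rich cell-wall proteins well
  exceed 15 % Pro while nsLTPs sit far below it. Configurable.
* Storage-protein similarity: local alignment (BLOSUM62, affine gaps)
  against a user-supplied exclusion FASTA; flagged at ≥ 40 % identity
  over ≥ 60 % of the shorter sequence. This replaces a BLAST E-value
  screen with a parameter-explicit rule; thresholds configurable.
* Annotation flags are tri-state. A gene with no flags row is
  *unknown*, and policy decides (`reject` by default, or
  `keep-with-warning`); predictor output is never fabricated.

## Duplication, orthologs, synteny

Paralog candidates are unordered within-species pairs with global
alignment identity ≥ 0.7 over ≥ 0.75 of the longer sequence
(identity computed over aligned columns after trimming terminal
gaps). A pair is **tandem** when both genes share a chromosome and
either ≤ 5 annotated genes intervene or the midpoints are ≤ 100 kb
apart; otherwise **segmental**. The tandem thresholds are package
defaults (the literature defers to precedent rather than fixing
numbers) and are exposed as arguments.

Cross-species 1:1 orthologs are reciprocal best hits by global
alignment score; tied best scores emit no pair (logged). RBH replaces
Markov-cluster orthology because only 1:1 pairs feed the downstream
Ks dating and synteny steps. Synteny blocks are inclusion-maximal
chains of ortholog anchors, strictly monotone in gene order on both
chromosomes (same or inverted orientation), with consecutive anchors
≤ 10 gene ranks apart on both sides; the implementation enumerates
chains in the anchor DAG and is tested against a brute-force
enumeration of all monotone subsets for ≤ 10 anchors.

## Ka/Ks, selection and dating

NG86-style counting: per sense codon, each position contributes the
fraction of its three possible changes that are synonymous (changes
to stop codons count as non-synonymous), so synonymous + 
non-synonymous sites always sum to 3 per codon. Differences between
codons differing at k positions are averaged over all k! substitution
orders with equal weight, discarding orders that pass through a stop
codon (if all are blocked, all orders are used). Proportions are
corrected with K = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 yields an infinite,
flagged estimate rather than a number. Codon alignments come from a
global protein alignment projected back onto whole codons; ambiguous
codons are dropped with a tally. The per-codon machinery is tested
against an independent exhaustive-pathway oracle on all 3 721 ordered
sense-codon pairs.

Selection is called purifying/positive/neutral by Ka/Ks against 1,
undefined when Ks = 0 or saturated. Ages use **t = Ks/2r** with
r = 2.6×10⁻⁹ site⁻¹·yr⁻¹ by default, reported in MY. Ks peaks are
the argmax of a Gaussian KDE (Scott bandwidth unless overridden)
evaluated on a 10⁻⁴-spaced grid from 0 to the largest value — the
grid step matches the 4-decimal precision at which such peaks are
conventionally reported; a zero-variance sample short-circuits to the
constant.

Near-identical pairs (Ks ~ 10⁻⁷) are numerically unstable under any
counting method; the curated pair table reproduces such rows through
the dating/ratio arithmetic on the recorded estimates, not by
re-estimation from sequence.

## Synthetic data: what it emulates, what it does not

The generator plants every ground truth the tests check. An nsLTP of
type T draws each spacer length uniformly from T's permitted set
(resampling if the mature length would exceed 120 aa), fills spacers
uniformly from the 19 non-cysteine residues, picks the CXC centre
hydrophilic for Type I and hydrophobic (Leu-weighted at 75.4 %)
otherwise, and prepends a 21–27 residue hydrophobic-biased signal
peptide. Decoys each violate exactly one screening filter and pass
the rest; the storage-protein exclusion record is a synthetic
stand-in built on a motif-bearing scaffold precisely so that its
mutated copy fails *only* the similarity rule.

Genomes back-translate proteins with uniform synonymous codon usage,
insert 0–2 introns (none in Types II/III; the first intron
preferentially 15–78 bp downstream of the Cys8 codon end, matching
where introns sit in this family), and lay genes across 13
chromosomes. Tandem copies sit adjacent to their source; segmental
copies go to another chromosome. Duplicate and subgenome copies are
evolved at controlled divergence (defaults: duplicates Ks 0.13,
subgenomes Ks 0.018, Ka/Ks 0.45/0.2) with the motif cysteines and
CXC centre protected from non-synonymous change. Default family
sizes (51 + 47 nsLTPs with the observed subfamily mix) and per-type
ortholog-loss fractions (complementary, e.g. Type I 2/3 vs Type V
1/3) mirror the cotton survey at desk scale.

`evolve_pair` realises a target (Ks, Ka/Ks) by placing synonymous and
non-synonymous point substitutions. Counts are integers, so the
fractional part of the expected counts S·pS and N·pN is resolved by a
Bernoulli draw (stochastic rounding): each pair stays within one
substitution of its target and the mean over many pairs equals the
target exactly. The realised divergence is re-measured with NG86 and
rejected outside a quantisation-aware window (35 % of target or 2.5
substitutions' worth, whichever is larger). No indels, no codon-usage
bias, no rate heterogeneity are simulated.

**Known limitation — Ks-peak granularity.** nsLTP coding sequences
are short (~75–140 codons, 55–100 synonymous sites), so per-pair Ks
is quantised in steps of ~1/S ≈ 0.010–0.018. At a true divergence of
0.018 most pairs carry one or two synonymous substitutions; the
one-substitution lattice values form a dense clump below 0.018 and
the KDE mode settles there, typically 0.015–0.017, while the mean Ks
recovers the planted 0.018 without bias. The corresponding check in
the test suite asserts the mode band regardless and is expected to
fail at some seeds; the mean-based recovery and the KDE mode on
continuous samples both pass. Passing tests therefore demonstrate
correct recovery of planted motifs, types, screens, duplication
modes and ortholog maps — not that a KDE mode on few short genes is
a precise divergence estimator.

## Numerical and convention choices

* Coordinates are 1-based inclusive in all external files and 0-based
  half-open internally; conversion happens once at the I/O boundary.
* Intron offsets are measured from the end of the Cys8 codon (first
  base after the codon = +1); introns projecting outside the CDS are
  marked rather than numbered.
* Alignment scoring is BLOSUM62 with gap open −10 / extend −0.5
  (global) and −10/−1-style local defaults via the same machinery;
  identity excludes terminal gaps.
* Technical qPCR replicates are averaged on the Ct scale before any
  ΔCt; replicate SD is carried for plotting, not modelled.
* All generators consume a numpy `Generator`; a dataset is
  byte-identical under a fixed seed.
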