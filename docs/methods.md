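# Methods

This note documents the models, defaults and numerical choices behind
`famevol`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and I/O

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted exactly once, inside the reader and writer. Gene
*rank* is the position-sorted index of a gene on its chromosome (ties at
identical start broken by gene id), the coordinate system used for tandem /
proximal distances and synteny chaining. Chromosome-versus-scaffold
placement is decided by a configurable name regex (default `/scaffold/i`),
since annotation naming schemes vary. Every randomized operation takes an
explicit seed, and each CLI run writes a JSON manifest with parameters and
SHA-256 input digests.

## Family identification

Membership is defined by literal motifs: the zinc-finger-like pattern
`C x2 C x6 C x3 C` (15 residues) and the leucine-zipper-like pattern
`L x6 L x3 L x6 L` (19 residues). A protein is class I when a complete zinc
finger is followed, anywhere downstream, by a zipper; class II with a zinc
finger only; otherwise rejected. This is a deliberate substitution for
profile-HMM searching: the class definitions are literal patterns, so a
deterministic scanner reproduces them exactly and needs no score thresholds.
Two knobs support sensitivity analyses: the zipper anchor set can be relaxed
from {L} to {L, I, V, M}, and each spacer can be widened by ±1.

Protein properties are computed from fixed tables so results are
reproducible bit-for-bit: average residue masses follow the ExPASy standard
table (MW = Σ residue masses + one water, 18.01524 Da), and pI uses the
EMBOSS pKa set (N-terminus 8.6, C-terminus 3.6, C 8.5, D 3.9, E 4.1, H 6.5,
K 10.8, R 12.5, Y 10.1) with Henderson–Hasselbalch charges. Net charge is
monotone decreasing in pH, so the pI is found by bisection, narrowing the
interval to 1e-7 pH units (final |charge| < 1e-4 for every sequence).

## Phylogeny

Distances are p-distances over pairwise-deleted columns (a Poisson
correction −ln(1−p) is available); the distance family used by common GUI
tools is rarely reported, and the p-distance is the assumption-free default.
Trees come from Saitou–Nei neighbor joining with the Studier–Keppler Q
criterion; joins tie-break by index order for determinism. Negative
branch-length estimates are clamped to zero with the deficit moved to the
sibling edge (standard practice). The result is unrooted, represented with a
trifurcating root surrogate; on additive matrices the reconstruction is
exact, which the tests verify on random 4–8-taxon trees.

Bootstrap support resamples alignment columns with replacement, rebuilds the
tree per replicate, and scores each internal bipartition of the
point-estimate tree by the percentage of replicates containing it (1000
replicates by default in the CLI). Subgroups are assigned by walking from
each query tip toward the root: the first ancestor containing reference tips
assigns its label if all its references agree, otherwise the tip is
`unplaced`.

The module consumes pre-aligned FASTA. Progressive multiple alignment is
out of scope; the synthetic generator emits equal-length, directly
comparable families, and users of real data should align with any standard
aligner first.

## Synteny and duplication modes

Homolog pairs (anchors) are chained per chromosome pair and orientation by
dynamic programming over rank coordinates: a chain extends when both rank
gaps are between 1 and `max_gap` (default 25), scoring
`match_score − gap_penalty·(gap units)` (defaults 50 and 1). Candidate
chains from both orientations are resolved greedily by score (ties: leftmost
start, plus before minus) so no two reported blocks on a chromosome pair
share an anchor; only chains of ≥ `min_block_size` (default 5) anchors are
reported. This additive scoring replaces E-value-based block scoring: block
*membership* is what downstream classification consumes, and the chain score
is only a tie-breaker.

Family pairs are classified with a first-match-wins priority:

1. **WGD** — the pair itself is an anchor inside a block;
2. **TD** — same chromosome, rank distance ≤ 1;
3. **PD** — same chromosome, rank distance 2–10 (the conventional
   proximal cutoff);
4. **TRD** — exactly one member is a block anchor (the parental locus) and
   the pair is not syntenic; the evidence string records which member was
   treated as parental. This is a deliberate single-genome simplification
   of outgroup-based transposed-duplicate detection, and is the one mode
   with permitted recovery slack in the acceptance tests;
5. **DD** — everything else.

Mode summaries count pairs per mode and genes per mode (each gene once, in
its highest-priority mode). Flank windows report all genes intersecting the
focal span widened by 100 kb per side, clipped at chromosome ends.

## Molecular evolution

**Codon alignment.** The two CDS are translated (terminal stop codons are
stripped; internal stops are errors naming the codon), globally aligned at
the protein level with affine gaps (BLOSUM62, gap open 10, extend 0.5; a gap
of length k costs open + (k−1)·extend), and back-translated to codon space.
Traceback ties prefer match over delete over insert, making the alignment
deterministic. Tests verify the alignment achieves the optimum of an
independent affine aligner.

**NG86 Ka/Ks.** Synonymous sites per codon are counted fractionally: each
position contributes one site split by the proportion of single-base
changes preserving the amino acid, with changes that create a stop codon
excluded from the proportion. Sites are averaged over the two sequences.
Observed differences in codons differing at several positions are averaged
over all mutational orderings that avoid stop codons (over all orderings if
none avoids them). Both proportions receive the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3), flagged saturated at p ≥ 3/4 (with a 1e-9 guard so
a floating-point tie at exactly 3/4 on tiny alignments is classified
consistently). ω = Ka/Ks is undefined when Ks = 0. A κ-weighted variant of
the site counts (transitions weighted κ) approximates the behavior of
codon estimators that model transition bias; κ itself is estimated as
2·(transitions)/(transversions) at fourfold-degenerate third positions.
The ML codon-model estimator the original analyses often use is not
re-implemented; the package validates its counting estimator against
simulation truth instead, defining true Ks as realized substitution events
divided by the ancestor's NG86 synonymous sites so estimator and truth share
a site-count denominator.

**4DTv.** Eligible sites are gap-free codon columns where both codons come
from the same fourfold-degenerate family (identical first two bases); the
statistic is the fraction of eligible third positions differing by a
transversion. It is uncorrected by default (the multiple-hit treatment of
in-house scripts is typically undocumented); a K80 transversion-distance
correction −(1/2)·ln(1−2Q) is available behind a flag. Under equal base
frequencies the raw value saturates at 1/2.

**Selection and dating.** ω below/within/above 1 ± 0.05 classifies
purifying / neutral / positive selection. Ks bands default to recent
0.15–0.30 and ancient 1.5–1.8 (closed intervals, configurable,
non-overlap enforced). Ages use T = Ks/(2r) with the default clock rate
r = 2.5×10⁻⁹ synonymous substitutions/site/year, chosen to reproduce the
Ks 0.15 ↔ 30 MYA edge of the recent-WGD window; no single rate reproduces
both ends of a 0.15–0.3 ↔ 30–45 MYA window (0.3 at this rate dates to
60 MYA), so the rate is config-exposed rather than hard-coded. Mean Ks for
multi-fragment pairs is the arithmetic mean over fragments.

## Promoters

The promoter is the 2000 bp upstream of the gene-feature start (no
UTR-aware TSS adjustment), strand-aware and clipped at chromosome bounds;
minus-strand promoters are reverse-complemented so the sequence reads
toward the gene. Matching is exact IUPAC set membership — no mismatch
tolerance, since web-tool matching tolerances are undocumented — on both
strands, reporting every offset including overlaps. The shipped catalog
holds one representative consensus per element category (ABRE for ABA,
MBS for MYB drought, CGTCA-motif for MeJA, GARE-motif for GA, …) and
exists for testing; real analyses should supply their own catalog, which
also owns the mapping from element names to categories.

## Expression

RPKM = count·10⁹/(library size · gene length in bp); presence is strictly
RPKM > 0 with no minimal-expression floor; tissue percentages are
expressed-gene fractions of the family, rounded to two decimals for
reports. The differential test defaults to the equal-variance Student
t-test (the plain "t-test" of most methods sections) with Welch behind a
flag; zero-variance degenerate groups resolve by the limit (identical
constants: t = 0, p = 1; distinct constants: p = 0). Stars follow
0.05/0.01/0.001. qPCR quantification is 2^−ΔΔCt with replicate Ct values
averaged per sample before differencing and a user-chosen calibrator
sample.

## Synthetic data

The generator emulates the inputs of a real family study at desk scale.
Defaults: 6 chromosomes × 30 genes on a 6-kb slot grid (one gene per slot,
so rank equals slot index and every gene has ≥ 2 kb of flank on both
strands); 3 planted WGD runs of 6 collinear anchor pairs (one run reversed
to exercise minus-orientation chaining) carrying 2 family pairs each;
2 tandem, 2 proximal, 1 transposed and 2 dispersed family pairs; 5
singletons; 5 class II members; 2 scaffold-anchored members exercising the
location filter. The codon model uses κ = 2, ω = 0.2 and per-mode target
Ks {WGD 0.2, TD 0.05, PD 0.05, TRD 0.3, DD 0.8} — a young tandem/proximal
cohort, a recent-WGD cohort and an older dispersed cohort, matching the
divergence structure such studies report. Divergence is a Gillespie
simulation over sense codons (transition factor κ, nonsynonymous factor ω,
stops forbidden), with branch time calibrated so expected synonymous
events per NG86 synonymous site equal the target.

Three design choices make recovery tests exact rather than probabilistic:
background proteins are cysteine-free and class II proteins leucine-free
outside their motifs (a chance motif in random background would otherwise
create family members the truth table does not know about); motif anchor
residues are frozen against nonsynonymous change (hard purifying selection
at anchors), so class labels survive divergence; and planted-present
expression counts are truncated at one read, so a sampling zero cannot
contradict planted presence — structural zeros alone encode absence.
Transposed copies descend from a family gene that is also a WGD anchor,
which realizes the "one member at a parental syntenic locus" definition
within a single genome.

For 4DTv calibration a separate exact simulator builds pairs entirely from
fourfold-degenerate codon families and evolves only third positions under
closed-form K80 transition probabilities, so any divergence — including
saturation at 10 substitutions per site — is realized faithfully and
instantly. Expression counts are negative binomial (dispersion 0.1;
Poisson at 0) with mean = planted RPKM level × length × depth; Ct tables
plant integer log2 fold changes in −2…2 against a calibrator tissue with
Gaussian Ct noise (σ = 0.1 by default, 0 for exact-recovery tests).

What the generator does **not** emulate: indel evolution within duplicate
pairs (substitution-only, so codon alignments of planted pairs are
gapless), codon-usage and GC bias (codon frequencies are uniform over
sense codons), gene-structure features (no introns/UTRs), read-level
sequencing artifacts, and background genes with genuine paralogy beyond
the planted anchors. Passing recovery tests therefore demonstrates
correctness of the algorithms under their stated models, not robustness to
alignment error, annotation noise, or compositional bias in real genomes.

## Problem sizes

The test suite and the acceptance script run entirely at desk scale, chosen
to exercise every code path with comfortable statistical margins: 22
paralog pairs of 300 codons for the selection check, 100 pairs of 500
fourfold codons for each 4DTv point, 100 replicates per Ks target for
estimator recovery, 500 random short alignments against the NG86
enumeration oracle, and the default synthetic genome (180 genes) for
end-to-end truth recovery.

## Known limitations

* NG86 with JC correction under-corrects at high divergence and ignores
  transition bias in its default site counts; pairs near saturation are
  flagged rather than estimated.
* TRD detection without outgroups cannot distinguish a transposed copy
  from a dispersed duplicate whose partner merely happens to sit in a
  block; it is the one mode allowed recovery slack.
* Bootstrap supports inherit the limitations of p-distance NJ on real,
  gappy alignments (pairwise deletion can make replicate distances
  non-additive).
* The shipped cis-element catalog is illustrative, not a curated database.
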