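# Methods

This note documents the models and procedures `alnbench` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic test bed does and does not show.

## Conservation model

**Column similarity.** A column's conservation is `1 − MD`, the mean over
all unordered pairs of rows of a normalised substitution distance

    d(a, b) = 1 − S(a, b) / sqrt(S(a, a) · S(b, b)),  clipped to [0, 1]

with BLOSUM62 as the default score matrix (any NCBI-format matrix can be
loaded). `d` is symmetric, zero on the diagonal and bounded in [0, 1];
pairs whose self-scores are not both positive (only `X` in BLOSUM62) get
maximal distance. Every pair involving a gap — including gap–gap —
contributes a fixed distance of 1.0: a gap is treated as maximally
distant from everything. Keeping the pair denominator fixed at C(n, 2)
under this convention makes the alignment-level bound below provable
rather than merely empirical. Columns with fewer than two rows have no
defined similarity (NaN).

**normd.** The alignment objective function sums the column similarities
over the full alignment length and divides by the maximum attainable sum
given the unaligned sequence lengths under the all-identical assumption.
For identical sequences of length L that maximum is L, so the natural
normaliser for mixed lengths is the **mean ungapped length**. With the
gap convention above, each pair's summed column contribution is bounded
by the shorter of its two ungapped lengths, hence
`normd ≤ 1` always, with equality exactly for identical ungapped
sequences. Inserting near-empty columns adds (at most) zero to the
numerator while lengthening some sequence, so the score strictly
decreases — the two properties that make `normd` a usable alignment
quality measure. Whether the historical implementations normalised by
alignment length or total residues is not recoverable; this variant is
documented rather than asserted identical, and its name is carried in
outputs.

**Profiles.** Block profiles are Gribskov average-score profiles: per
column, the sequence-weighted mean of the substitution-matrix rows of the
observed residues, gaps contributing nothing (occupancy is bookkept
separately). Sequence weights are Henikoff & Henikoff position-based
weights — standard, deterministic, parameter-free. A segment scores the
sum of its residues' profile weights divided by the profile length, so an
all-gap segment scores 0 and truncated segments are penalised.

**Profile–profile similarity** slides one profile along the other
(ungapped, minimum overlap 3) and scores each offset as the mean cosine
of the overlapping column weight vectors *after subtracting the
background* (the mean matrix row). The background component is shared by
every profile and would otherwise push the similarity of completely
unrelated profiles to ≈ 0.55; centred, unrelated profiles score ≈ 0,
identical ones 1, and profiles of the same block in two subfamilies at
realistic divergence ≈ 0.9. The merge threshold defaults to 0.5 on this
scale (configurable).

## Block identification

Sequences are first partitioned into subfamilies: UPGMA (average
linkage) on `1 − percent identity` distances (identity counted over
columns where both rows have residues), cut at the largest relative gap
between consecutive merge heights — ratio `(h_{i+1}+ε)/(h_i+ε)` with
ε = 0.05; if no ratio reaches 2.0 the family is kept whole. The smoothing
constant keeps tiny height differences near zero from looking like
structure; the 2.0 floor means a split requires between-cluster distances
roughly twice the within-cluster ones. Identical sequences always form
one subfamily; singletons are permitted. This is a deliberately simple,
deterministic substitute for dissimilarity-plateau partitioners with the
same contract.

Per subfamily, blocks are maximal runs of columns whose sliding-window
mean similarity (window 5, truncated at the ends rather than padded)
exceeds 0.2, at least 3 columns long. **Run edges are trimmed back to
columns whose raw (window 1) similarity also exceeds the threshold**: the
window otherwise bleeds conservation into flanking unconserved columns,
padding short conserved runs up to block length and shifting boundaries
~2–3 columns into linkers. With trimming, planted 10-column blocks are
recovered with exact or near-exact boundaries. A single-sequence
subfamily treats its residue columns as trivially conserved. Block
members are the subfamily sequences with at least one residue in the run.

Blocks found independently in several subfamilies merge when their column
intervals overlap on the shared reference axis and their profiles agree
(similarity > 0.5): members are unioned and the interval is the
intersection of the sources, re-extended while the merged membership's
windowed score stays above threshold (then edge-trimmed as above). A
merge that would fall below 3 columns is abandoned and the sources pass
through unchanged. Merging is what lets final blocks span arbitrary
subsets of sequences, including rare blocks.

**Attributes.** Per block: similarity (mean `1 − MD` over block columns,
members only; 1.0 for a single member), mean residues per member,
frequency (members / all sequences) and the fraction of member residues
inside annotated disordered intervals. Per alignment: sequence count,
mean ungapped length, `normd`, and block coverage — the fraction of
(sequence, residue) cells inside blocks, each cell counted once even
under overlapping blocks.

## Discrepancy rules

All rules operate per subfamily and need at least 4 members (quartile
statistics are meaningless below that; smaller subfamilies log a warning
and produce no flags). Quartiles use linear interpolation.

1. **Terminal errors.** For each terminus separately, a member whose
   terminal residue column falls outside the *open* window
   `(Q1 − 10, Q3 + 10)` of the subfamily's terminal-position distribution
   is flagged (a value exactly on the edge is outside). The 10-column
   margin tolerates honest start/stop wobble.
2. **Outlier segments.** Core blocks are the subfamily blocks carried by
   a strict majority of members. For each core block, every member's
   segment is scored against the weighted profile of the *other* block
   members (leave-one-out: with position-based weights an anomalous
   segment otherwise receives a dominant weight and drags a self-inclusive
   profile toward itself, masking the very outlier being sought). A
   member is flagged when its score is below the Tukey fence
   `Q1 − 1.5·IQR` **and** below half the median member score. The fence
   alone misfires at realistic subfamily sizes: on ~8 samples the
   empirical fence is noisy enough to flag a healthy extreme every few
   dozen draws, which several core blocks per family multiply into an
   unacceptable false-positive rate; genuine errors (shuffled or foreign
   segments) score far below half the median, so the conjunction costs no
   sensitivity. Both knobs are configurable. Flagged intervals extend
   outward to the nearest flanking core blocks where the sequence scores
   normally, or to the sequence terminus.
3. **Inserted segments.** Columns `i < j` both fully occupied (over
   members not flagged as terminal fragments), every strictly intervening
   column occupied by exactly one residue, all of them from the same
   single sequence, and `j − i ≥ 10`: that sequence is flagged over the
   intervening columns. Because no intervening column is fully occupied,
   scanning consecutive fully-occupied columns is exactly equivalent to
   the all-pairs definition (property-tested against a literal all-pairs
   scan).
4. **Deleted segments.** Same geometry with every intervening column at
   occupancy N − 1 and the same single sequence gapped throughout.

`scan` applies the rules in order terminal → outlier → inserted →
deleted; terminal-flagged sequences are excluded from the occupancy
counts of rules 3–4 (fragments would otherwise break the "fully
occupied" boundaries). An inserted or deleted segment also depresses the
same sequence's profile scores, so an outlier flag whose interval
overlaps a more specific flag on the same sequence is dropped — one
planted error yields one flag. `filter_reliable` keeps the unflagged
sequences, drops columns left empty, and re-projects block annotations
onto the new column axis.

The rules cannot distinguish genuine biology (splice variants, naturally
absent domains) from prediction errors; a block carried by all but one
sequence is flagged by rule 4 by design.

## Scoring

Correctness is judged on block members only. A member gapped at the
reference column contributes nothing; a column whose members place all
their residues in one test column scores 1. `CS` weights each block's
mean by its member count; regions outside blocks never contribute.
Combining takes the per-block maximum BCS across programs (ties go to
the lexicographically first program label) and averages the maxima
unweighted. Pearson correlations pairwise-delete missing values and
return NaN below 3 pairs or at zero variance. Attribute binning places a
value equal to the last edge in the last bin and drops blocks outside the
edge range; empty cells are NaN with a zero count.

## Synthetic families

The generator emulates the structure of curated references: subfamilies,
blocks carried by chosen subfamily subsets (frequency spectrum is set by
construction), disordered blocks, per-sequence linkers, planted errors.
Mutations are per-site substitutions with BLOSUM-conditioned replacement
probabilities (`P(b|a) ∝ exp(S(a,b)/2)`, no self-replacement); there are
no indels inside blocks, so every planted coordinate is exact. Subfamily
structure is two-level: a subfamily consensus mutated from the block
ancestor at `divergence_ratio` (default 3) times the member rate, then
members mutated from the consensus. The member rate is bisected until the
realized mean column similarity is within ±0.1 of the block's target
(error after 100 attempts — e.g. a low-complexity block cannot reach
similarity 0.02 because chance similarity of the 8-letter disorder
alphabet stays near 0.15). Disordered blocks draw from a low-complexity
alphabet (`AEGKPQST`) with uniform replacements and emit exact
annotations; no physical model of disorder is claimed. Linker lengths
default to 15 ± 3 per sequence, left-justified and gap-padded, making
linkers unalignable by construction while keeping terminal positions
tight enough that clean families trip no terminal flags.

`corrupt_alignment` selects `round(f · m_b)` columns per block (so the
member-count-weighted corrupted fraction is f) among columns holding at
least two member residues, and moves one randomly chosen member residue
into a fresh gap column. Exactly the selected columns become incorrect,
giving the analytic expectation `CS = 1 − f` whenever `f · m_b` is
integral for every block.

**What passing tests show — and don't.** The planted suite uses families
of 8 sequences, four 24-column blocks at similarity 0.9 and 12 ± 2
linkers; the block-recovery suite uses 10-column blocks at similarity
0.9 between 15-column linkers; stochastic measurements run 20–50 seeded
replicates. These sizes keep the whole suite fast while leaving each rule
a realistic signal-to-noise regime. Real families are messier: indels
inside conserved regions, rate heterogeneity, phylogenetic correlation
between sequences and genuinely ambiguous block boundaries are all absent
from the generator, so perfect recovery here bounds, rather than
predicts, performance on real references. The analytic CS checks, by
contrast, are exact statements about the scorer itself.

## Other numerical choices

* Internal coordinates 0-based half-open; every file format and report
  1-based inclusive, stated in each TSV header.
* Residues upper-cased on input; `.` → `-`; anything outside the
  20-letter alphabet → `X`.
* The block annotation type permits blocks of any positive width (the
  scorer accepts single-column blocks); the ≥ 3-column rule belongs to
  the block *finder*.
* Window truncation at alignment ends (no fabricated columns).
* Determinism everywhere: identical inputs and seeds give byte-identical
  alignments, blocks, reports and scores.
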