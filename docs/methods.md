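# Methods

## The analysis model

Each input is a coding-strand nucleotide sequence. Its genomic signature is
the 256-vector of overlapping tetranucleotide frequencies: windows
`seq[i:i+4]` for `i = 0 … L−4` (so `L−3` windows), counted on the given
strand only — no reverse-complement folding, because the coding strand of a
gene carries codon-level composition signal that folding would erase.
Windows containing an ambiguous base are skipped. Counts are divided by the
number of counted windows (`--norm windows`, the default), which makes every
profile a proper frequency distribution summing to 1; dividing by sequence
length instead (`--norm length`) differs only by the constant `(L−3)/L` and
is kept as an option because "normalised to length" is genuinely ambiguous in
the field's usage. All cosine distances are invariant between the two
choices, since they differ by a positive scalar per profile.

Pairwise dissimilarity is cosine distance `1 − cos∠(u, v)`, which for
nonnegative frequency vectors lies in `[0, 1]` and is 0 exactly for parallel
profiles. It is insensitive to the overall scale of a profile, which is the
property wanted when sequences differ in length.

The subgroup count is selected by the pseudo-F (Calinski–Harabasz) statistic
`[BGSS/(k−1)] / [WGSS/(n−k)]`, computed on the full 256-dimensional profiles
(not on PCA scores — PCA here is a visualisation, and reducing before model
selection would discard exactly the high-order signal the signature was built
to capture; `select_k` accepts any matrix, so scores can be passed explicitly
if wanted). For each candidate k (default range 2–10), the partition is the
best of `restarts` (default 100) k-means runs with k-means++ seeding and
derived seeds; the labelling with maximal pseudo-F per k is kept and the k
with the global maximum wins, ties toward smaller k. k-means is the base
partitioner because pseudo-F and k-means optimise the same within-cluster
sum-of-squares geometry; a labelling with zero within-cluster scatter is
reported as perfect separation and outranks any finite score. A run that
leaves a candidate cluster empty is discarded rather than scored.

The similarity matrix `S = 1 − D` is hierarchically clustered by comparing
*rows of S* with Pearson-correlation distance (`1 − r`) under average
linkage — the "profile of profiles" convention of matrix-heatmap viewers.
Leaf order is SciPy's deterministic order (smaller original index first at
ties). A constant row (which only arises when all profiles are identical)
makes the correlation undefined and is reported as an error naming the row.

%G+C is `(G+C)/(A+C+G+T)` with ambiguous bases excluded from numerator and
denominator. The high/low class threshold defaults to 0.45, the midpoint of
the two composition modes (~0.40 and ~0.50) this analysis is designed to
separate; `high` is assigned at exactly the threshold. The per-station report
gives n, high-GC count and percentage (one decimal) per station plus a pooled
overall row — a pooled ratio, deliberately not the mean of station
percentages.

Positional Shannon entropy is `H = −Σ p·log p` over the residue frequencies
of one alignment column, summed over columns into a per-alignment total.
Natural log is the default (`--bits` switches to log2; the choice scales all
totals by `ln 2` and never changes rankings). Gaps are excluded from column
frequencies by default; `gaps=symbol` counts them as a residue state. The
alphabet is whatever the alignment contains, so nucleotide and protein
alignments both work.

## Primer algebra and the in-silico screen

A degenerate primer is an IUPAC string; its degeneracy is the product over
positions of each code's base count, which equals the number of concrete
expansions (enumeration is refused above a 65,536 cap — match instead).
Back-translation of a protein motif emits, per codon position, the minimal
IUPAC code covering all codons of the residue; this is full coverage with no
codon-usage weighting, which is why textbook degeneracies arise exactly.
Matching uses IUPAC semantics (a code matches a base iff the base is in the
code's set) with an exact-match default (`max_mismatches = 0`): the screen
being modelled relies on primer specificity, and no mismatch tolerance is
part of its design.

The in-silico PCR calls a product only for a forward-strand forward-primer
site strictly upstream of a reverse-strand reverse-primer site with the
primer-inclusive span inside the size window. Templates with both sites in
the wrong mutual orientation, on the same strand, or at the wrong spacing
yield nothing — that is the arrangement-specificity contract, and it is
property-tested directly. Amplicons include both primer sequences;
restricting to the gene portion is the separate `trim_translate` step
(0-based anchor, frame 0|1|2, standard genetic code, trailing partial codon
dropped, internal stops as `*`).

## The synthetic generator

The generator exists because the real amplicon collection this analysis was
designed around was never deposited; it plants the statistical structure the
method assumes so that the pipeline can be exercised and validated end to
end.

Each group is a 3rd-order Markov chain over `{A,C,G,T}`. Baseline weights
put `(1−gc)/2` on each of A/T and `gc/2` on each of C/G in every 3-mer
context. The group's bias multiplies each weight by `exp(bias · ε)` with
`ε ~ N(0,1)` drawn once from the group seed, then renormalises the {A,T}
pair to `1−gc` and the {C,G} pair to `gc` *within every context*. Two
consequences: (1) per-step G+C probability equals `target_gc` exactly at any
bias strength, so group GC stays on target while tetranucleotide structure
diverges; (2) expected between-group cosine distance grows monotonically
with `bias_strength` (verified as a property test). The first 3-mer is
uniform over the 64 contexts; its effect on GC is O(1/L). Sequences have no
reading-frame structure by default; an `orf_mode` flag prepends ATG and
removes in-frame stops for translation tests only.

Randomness: one integer master seed per scenario; each group's drawing
stream is derived by SHA-256 of `(master_seed, group_id)`, and the bias draw
comes from the group's own seed. Identical scenarios therefore reproduce
byte-identical FASTA output.

The default scenario (`six_group_scenario`) plants six subgroups: one at
target GC 0.50 (17 sequences) and five at 0.40 (25, 25, 24, 24, 24), total
n = 139, lengths uniform on 450–530 nt (the inner-primer product window),
`bias_strength = 2.0`. At that bias the groups are cleanly separable in
signature space while per-sequence profiles remain visibly noisy (~500
windows spread over 256 bins); it is the "high-bias" regime of the planted
model, fixed at design time from the separability dial. Sequences are
assigned to four stations by explicit counts chosen to mirror a four-island
survey design: station sizes 20/61/51/7 with planted high-GC fractions
25.0 %, 18.0 %, 2.0 % and 0.0 % (counts 5/11/1/0 of 17 high-GC sequences).

What the generator does *not* emulate: real codon structure, phylogenetic
correlation within groups (sequences are i.i.d. draws from the group chain),
sequencing error, chimeras, or length variation beyond the uniform window.
Passing tests therefore demonstrate that the pipeline recovers planted
compositional structure of realistic dimension and noise level, not that six
subgroups would be found in any particular environmental sample.
`simulate_alignment` is a separate, deliberately minimal star-tree model
(random ancestor, i.i.d. per-site substitutions) used only to validate the
entropy statistics' monotone response.

## Numerical choices and degenerate inputs

- Profile counting is vectorised (stride-tricks sliding windows) and checked
  against a brute-force window enumerator on random sequences.
- Cosine distances come from SciPy's `pdist`; values are clipped at 0 and
  the diagonal forced to exactly 0 to absorb floating-point dust; entries
  are checked against element-wise recomputation at 1e-12.
- pseudo-F is implemented with explicit centroid/sum-of-squares arithmetic
  and cross-checked against both a brute-force loop and scikit-learn's
  independent implementation at 1e-9 relative.
- All stochastic steps take explicit seeds; derived seeds are spawned via
  `SeedSequence` and kept below 2³¹.
- Degenerate inputs rejected with named errors: sequences shorter than one
  window, all-ambiguous sequences, zero profile vectors, empty clusters,
  k outside `[2, n−1]`, ragged alignments, all-gap columns, invalid IUPAC
  characters (with position), size windows with min > max.

## Pipeline and reproducibility

`tetrasig run` executes simulate (or load) → optional in-silico PCR →
profiles/%G+C → distance/model selection/PCA/dendrogram → entropy → station
report. The entropy stage consumes an aligned FASTA when one is supplied;
otherwise each group's sequences are truncated to the group's minimum length
as a gap-free stand-in, since alignment construction is outside this
package's scope. Every parameter, seed, and output SHA-256 is recorded in
`manifest.json`; reruns under an identical config are byte-identical, which
the test suite asserts.

## Known limitations

- The planted-group emulation fixes group sizes and station counts by
  design choice; only station totals and the overall high-GC share have
  external anchors, so per-group sizes are a modelling convention.
- GC classification of individual ~500 nt sequences is noisy (sd ≈ 0.023),
  so a few low-GC sequences can cross the 0.45 threshold in any one
  realisation; class means are stable, individual class calls are not.
- The actual degenerate primer pairs of the motivating screen are not
  public; the primer module is validated against its algebraic contracts
  (enumeration, coverage, arrangement specificity), not against those
  oligonucleotides.
- Hierarchical clustering of the similarity matrix is a presentation-order
  device; subgroup counts come only from the pseudo-F selection.
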