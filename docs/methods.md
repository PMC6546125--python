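# Methods

## The statistic

A *match factor* starting at position `i` of a record is the longest prefix
of the suffix at `i` that also occurs at some other position of the match
space; if no character matches anywhere else, the factor is the single base.
Factors are reported greedily left to right, so they tile the record. The
count of factors per base is high in sequence without long self-matches and
collapses where long duplications exist. The match complexity of a window of
length `W` containing `N_W` factor ends is

    Cm = (N_W/W − 2/W) / (Ca − 2/W)

where `Ca = 1/μ` is the factor rate expected in random sequence (below) and
`2/W` is the minimum possible rate. Cm is 0 for minimally complex sequence
and has expectation 1 in random sequence.

All factor lookups come from one enhanced suffix array per sequence set:
the longest match at position `i` is `max(lcp[isa[i]], lcp[isa[i]+1])` with
the guard `lcp[M+1] = 0`. Windows never re-factorise: the factor ends form a
counting process `N_i` (number of ends ≤ i), and a window's count is
`N_end − N_{start−1}`. A factor therefore belongs to the window containing
its **end**; a boundary-spanning factor is counted once, in the later
window. This follows directly from the definition of `N_i` and makes a scan
O(1) per window after the single decomposition.

## The null model

For i.i.d. random sequence with base probabilities `(q, p, p, q)`,
`q = ½ − p` (GC content `2p`), the longest-match length `Y*` at a position
has the approximate CDF

    P(Y* < x) = Σ_k multinomial(x; k) π_k (1 − π_k)^L ,

summed over nucleotide-count vectors `k` summing to `x`, with `π_k` the
word probability. Because `π_k` depends only on the GC count `g` of the
word, the production code uses the exact collapse

    P(Y* < x) = Σ_{g=0..x} C(x,g) (2q)^(x−g) (2p)^g (1 − q^(x−g) p^g)^L

(O(x) per evaluation; the explicit composition sum is retained as a test
reference). `L` here is the **total match-space length** — the whole indexed
sequence set (twice that when the reverse complement is included) — because
matches are sought genome-wide; the window length enters only later through
`W`. From the CDF:

    μ  = Σ x (F(x+1) − F(x))            (mean E[Y*])
    σ² = Σ x² (F(x) − F(x−1)) − (μ+1)²  (= E[(Y*+1)²] − (E[Y*]+1)² = V[Y*])

The shifted-index variance form is algebraically `Var(Y*)`; the test suite
verifies this numerically against the pmf. Sums truncate when the residual
tail mass drops below 1e−12 (hard cap x = 1000; the nominal limit `L` is
astronomically beyond where the pmf vanishes), `(1 − π)^L` is evaluated in
log space so genome-scale `L` cannot underflow, and the far tail is clipped
at 1 where rounding would exceed it by a few ulp.

Treating factor ends as a renewal process (i.i.d. inter-event distances
distributed like `Y*`), the central limit theorem for renewal processes
gives `N_W ≈ W/μ + N(0, σ²W/μ³)` for `L ≫ W ≫ 1`, hence

    Cm ≈ Normal(1, σ²/(μW)) ,
    F⁻¹(prob) = 1 + sqrt(2σ²/(μW)) · erfinv(2·prob − 1).

Windows with Cm **at or above** the lower 5% quantile (ties qualify) are
indistinguishable from random; overlapping or book-ended qualifying windows
merge into maximal high-complexity intervals.

## Index construction details

- Suffixes are ordered with a conceptual terminator that sorts below the
  alphabet, so a suffix that is a prefix of another ranks first; the
  reported arrays contain only the true sequence positions (a 10-mer yields
  10 rows). Construction is vectorised prefix doubling (numpy `lexsort`);
  the LCP array is Kasai's algorithm, JIT-compiled. Correctness is pinned to
  brute-force suffix-sort oracles in the tests, not to the algorithm.
- Multi-record sets are concatenated with per-gap unique separator symbols,
  and every non-ACGT base is likewise a unique symbol sorting above the
  alphabet in order of appearance: no match ever crosses a record boundary
  or an ambiguous base. When rows are projected out of the full match-space
  arrays (separators, reverse-complement positions), the public LCP entry is
  the range minimum over the skipped ranks.
- Strand: the match space is forward-only by default, which reproduces the
  worked example exactly; `both_strands` appends the reverse complement so
  matches may come from either strand (match lengths can only grow — a
  tested invariant). Which convention a genome-scale analysis should use is
  a genuinely open choice; both are provided.
- Coordinates are 1-based inclusive throughout the library; BED/bedGraph
  writers convert to 0-based half-open on output.
- The persisted index stores a magic number, a format version, the record
  table, GC, ambiguity positions and the full-space sa/lcp as fixed-width
  little-endian integers; everything else is re-derived on load, and any
  truncation or version mismatch raises an error naming the file.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `W` | 10 000 bases | window length; the null variance scales as 1/W |
| `step` | 1 000 bases | window grid advance; grid starts at position 1, trailing partial window dropped |
| quantile | 0.05 | lower null quantile delimiting high-complexity windows |
| GC | global GC of the index | drives `p` in the null; override flag for chromosome-local analyses |
| `max_ambig_frac` | 0.05 | windows with a larger ambiguous-base fraction are undefined (NA), so N-runs cannot masquerade as low Cm |
| promoter | [TSS−2000, TSS+1999] | exactly 4 000 bases centred on the TSS (the asymmetric split is forced by evenness); genomic, not strand-flipped; clipped at record ends |
| `min_members` | 10 | GO categories smaller than this genome-wide are not tested |
| `iterations` | 10 000 | Monte-Carlo iterations; the p-value floor is 1/iterations, reported as "< 1/i" |

Monte-Carlo design: random window sets are drawn uniformly **without
replacement within an iteration** from the defined (non-ambiguous) window
positions of the scanned profile; gene sets are resampled from the universe
of genes carrying ≥ 1 biological-process annotation. Each iteration `i` of a
run seeded `s` uses a generator seeded from `(s, i)`, so iterations are
independent and order-insensitive — serial, chunked or reordered execution
is bitwise identical (tested). Bonferroni correction is over the categories
actually tested. RefGene transcripts deduplicate to one gene per symbol;
gene-level counting means a symbol counts once however many windows or
transcripts intersect.

## The synthetic generator

`synth` produces i.i.d. genomes of chosen GC, plants exact repeat copies
(overwriting target intervals; overlapping targets are an error), and
places gene/GO annotations in which chosen categories have a stated
fraction of their promoters inside given intervals. It emulates exactly
what the statistic measures — exact self-matches — and deliberately nothing
else: no mutated repeat copies (the statistic is exact-match-based), no
transposon families, no CpG-island composition, no isochore GC structure.
Passing tests therefore demonstrate correct behaviour of the machinery and
calibration of the null under its own assumptions, not robustness to the
compositional heterogeneity of real genomes.

Problem sizes used by the checks are desk-scale by design: 10 Mb genomes
for null calibration (the published analyses used 100 Mb simulations and
multi-gigabase genomes), 1 Mb for the 20-replicate end-to-end enrichment
recovery, 10⁴ Monte-Carlo iterations. Genome-scale figures (whole-genome
Cm ≈ 0.8 in human, thousands of called intervals, the developmental-gene
enrichments) require external multi-gigabase genomes and ~100 GB-class
index construction; they are a documented capability of the same code
paths, not part of the test suite.

## Numerical and degenerate-input choices

- `cm_value` requires `Ca > Ci`; a window too short for the null (possible
  for tiny W or extreme GC) raises rather than returning a sign-flipped Cm.
- Records shorter than `W` are skipped with a warning; unknown records
  raise.
- Factor attribution, interval merging and intersection all treat ≥ 1
  shared base as overlap; merging is done in half-open arithmetic
  internally and emitted 1-based inclusive.
- `p` (half the GC) must lie strictly inside (0, 0.5): an all-AT or all-GC
  null has no match-length distribution in this model.
- Enrichment folds with zero expected count are reported as infinite rather
  than masked; sorting is by fold descending with p-value and category id as
  deterministic tie-breaks.

## Known limitations

- **The null is approximate, and measurably so.** The match-length CDF
  assumes word occurrences are independent; at small search spaces
  (L ≈ 10³) its mean is ~0.1% above the simulated truth, and near sequence
  ends the model ignores censoring (the last positions cannot host long
  matches). At L ≥ 10⁷ the mean is accurate to ~2×10⁻⁵ in Cm units.
- **The renewal CLT underestimates the window variance by ~5–10%** because
  successive factor lengths are positively correlated. Consequently the
  analytic lower 5% quantile captures ≈ 7% of windows in a 10 Mb random
  genome rather than 5% — the thresholds are slightly permissive, i.e. they
  call slightly fewer high-complexity windows than a perfectly calibrated
  null would. Window Cm is also discrete (N_W is an integer; the lattice
  spacing is ≈ 0.4 sd at W = 10 kb), which makes tail fractions granular.
- Quantiles assume `L ≫ W ≫ 1`; for whole-record Cm of short records the
  normal window approximation is not meaningful and only the point value is
  reported.
- GO assignments are used flat, without ancestor propagation along the
  ontology graph; whole-gene (rather than promoter) intersection is
  available behind the same machinery but promoter counting is the tested
  surface.
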