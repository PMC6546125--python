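# matchcomp

Match complexity (Cm) along genomes: find the regions of a genome that look
like random sequence — no recent duplications, no repeats — and ask what
genes live there.

Unique (repeat-free) sequence is associated with function in vertebrate
genomes: promoters, CpG islands and developmental gene clusters such as the
*Hox* loci are conspicuously depleted of transposon insertions. `matchcomp`
measures uniqueness with the **match complexity**: decompose a sequence into
*match factors*, where each factor is the longest prefix of the remaining
sequence that also occurs somewhere else in the genome (on either side, not
just to the left as in classical Lempel–Ziv), and compare the observed
factor rate to what random sequence would give:

```
Cm = (Co − Ci) / (Ca − Ci)
```

with `Co = N_W / W` the observed factors per base in a window of length `W`,
`Ci = 2/W` the theoretical minimum, and `Ca = 1/μ` the expected rate in
random sequence of the same GC content, where `μ = E[Y*]` is the mean
longest-match length computed from the analytic match-length distribution

```
P(Y* < x) = Σ_g C(x,g) (2q)^(x−g) (2p)^g (1 − q^(x−g) p^g)^L ,   q = ½ − p
```

(GC content `2p`, match-space length `L`). Cm is ≈ 1 in random sequence and
→ 0 in heavily repetitive sequence. Because factor ends form a
renewal-like process, windowed Cm is approximately `Normal(1, σ²/(μW))`,
which yields analytic quantiles: windows at or above the lower 5% quantile
are *statistically indistinguishable from random* and merge into
high-complexity regions. A Monte-Carlo layer then tests whether those
regions are enriched for gene promoters (4 kb centred on the TSS) and for
GO biological-process categories.

The toolkit is aimed at genome analysts: index once (enhanced suffix array:
`sa` + `lcp` + `isa`), query many times — scans, thresholds, interval calls,
annotation and enrichment are all downstream of the persisted index.

## Worked example

The 10-mer `CGGGCGGGCT` decomposes into the factors `CGGGC.GGGC.T`:

```python
>>> from matchcomp import SequenceSet, build_esa, factorize
>>> esa = build_esa(SequenceSet([("S", "CGGGCGGGCT")]))
>>> list(esa.sa)
[1, 5, 9, 4, 8, 3, 7, 2, 6, 10]
>>> list(esa.lcp)
[-1, 5, 1, 0, 2, 1, 3, 2, 4, 0]
>>> f = factorize(esa, "S")
>>> list(f.ends), f.n_factors
([5, 9, 10], 3)
```

The first factor has length `max(lcp[isa[1]], lcp[2], 1) = max(−1, 5, 1) = 5`
(`CGGGC` reoccurs at position 5); the second starts at 6 with
`lcp[isa[6]] = lcp[9] = 4` (`GGGC`); the final `T` is unique, length 1.

A shell session on a 300 kb synthetic genome whose last third is a planted
high-copy repeat:

```
$ matchcomp synth --spec spec.json --seed 5 --out-prefix toy
planted 9 repeat copies
wrote toy.fasta (300000 bases)
$ matchcomp index toy.fasta toy.idx
indexed 300000 bases (GC 0.4996) -> toy.idx
$ matchcomp scan toy.idx -w 10000 -s 1000 -q 0.05 --bed hc.bed --genome-wide
L=300000 GC=0.4996 mu=9.0128 threshold=0.9947 windows=291 high=191 intervals=1
synth1  Cm=0.6860
```

The whole-record Cm of 0.686 reflects the one-third repetitive content; the
191 windows at or above the 5% null quantile (0.9947) merge into a single
high-complexity interval covering the 200 kb of unique sequence, written as
BED. `matchcomp annotate` and `matchcomp enrich` then count genes whose
promoters intersect those windows against random-window draws, and test GO
categories by gene-set resampling, e.g.:

```
#  process   id        C   O   E      O/E  p      p_bonferroni
1  GO:PLANT  GO:PLANT  15  15  10.53  1.4  0.003  0.018
```

`matchcomp quantile` prints thresholds for any GC/L/W without touching
sequence data — the null is fully analytic, so mammalian-genome parameters
(L ≈ 3.1 Gb) are instant.

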