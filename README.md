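# jackprod

Linear-time **jackknife (leave-one-out) products** in commutative
semigroups, and the exact conditional enrichment test built on them.

## The problem

Circular RNAs (circRNAs) can sponge microRNAs; given a miRNA target-site
motif, is it unusually enriched on any one circRNA? Statistically: for
independent nonnegative integer counts `X_0 … X_{n−1}` with observed
values `k(i)` and fixed total `K = Σ k(i)`, compute every conditional
p-value

    p_i = P{X_i ≥ k(i) | S = K}
        = Σ_{k=k(i)}^{K} g_i[k] · ḡ_i[K−k]  /  ḡ[K],

where `g_i` is the weight array of `X_i` truncated at `K` (here: the
number of ways `k` non-overlapping width-`w` motifs fit on a circular
sequence of length `I_i`), `ḡ` the truncated convolution of all arrays,
and `ḡ_i` the convolution of all but the `i`-th. At `n = 2` this is the
one-sided Fisher exact test.

The bottleneck is computing all `n` leave-one-out convolutions `ḡ_i`.
Truncated convolution has **no inverses**, so `ḡ ∘ g_i⁻¹` is unavailable;
the naive approach costs `n(n−2)` products and a plain segment tree about
`n log₂ n`. The algorithm here does it with about `3n` products (exactly
`3n − 6` at binary powers `n = 2^m`) in three phases — a rootless segment
tree built upward, a complementary tree built downward via each node's
"aunt", and a final pair transposition — in any commutative semigroup
with identity. Weights spanning thousands of orders of magnitude
(placement counts reach ~10^2608) are handled by an internal log
representation.

## Worked example

The six-integer example under addition (identity 0, padded internally to
the binary power 8):

```bash
$ jackprod demo --semigroup add --input "5 8 6 3 4 7"
jackknife: [28, 25, 27, 30, 29, 26]
products:  12 (n=6)
```

Each output is the total 33 minus the omitted element — the closed form
addition admits — but the algorithm never subtracts; it only adds. The
bit-string OR semigroup makes the tree structure visible (`--trace`
prints every row, the classic debugging workflow):

```bash
$ jackprod demo --semigroup or --input "1000 0100 0010 0001" --trace
L_0:    ['1000', '0100', '0010', '0001']
L_1:    ['1100', '0011']
L̄_1:    ['1100', '0011']
L̄_0:    ['1011', '0111', '1110', '1101']
jackknife: ['0111', '1011', '1101', '1110']
products:  6 (n=4)
```

Each leave-one-out OR is the complement of the omitted unit bit string.

## Enrichment analysis

From a FASTA of circRNA sequences (treated as circular, T→U normalized):

```bash
jackprod fixture --seed 1 --n 6 --min-len 150 --max-len 600 \
    --target-index 2 --fasta-out cohort.fa
jackprod enrich --fasta cohort.fa --motif UUACAGG
```

```text
# motif=UUACAGG	n=6	K=12	family_size=6
# overlap=allowed	degenerate=False	circular=true
# multiple-testing: Bonferroni only (fixed-sum conditioning breaks the
# positive-dependence requirement of Benjamini-Hochberg FDR control)
id	length_nt	count	p_raw	log10_p_raw	p_bonferroni
circ0000	218	0	1	-0.000000	1
circ0001	170	0	1	0.000000	1
circ0002_enriched	374	11	2.83319e-07	-6.547724	1.69992e-06
circ0003	226	0	1	-0.000000	1
circ0004	405	0	1	-0.000000	1
circ0005	172	1	0.769752	-0.113649	1
```

The planted sequence (11 of the 12 occurrences on 374 nt) gets
`p ≈ 2.8 × 10⁻⁷`, Bonferroni-adjusted `1.7 × 10⁻⁶`; the others are near
1. `log10_p_raw` stays meaningful when `p_raw` underflows doubles.
`jackprod enrich-counts --table counts.tsv --motif-width 7` runs the same
test from a precomputed `id / length_nt / count` table, for settings
without sequence data (e.g. mutation counts per alignment column).

The Python API mirrors the CLI: `jackknife_products`,
`conditional_pvalues`, `placement_distribution`, `run_enrich`, plus the
two slower oracle algorithms (`naive_jackknife`,
`segment_tree_jackknife`) used throughout the tests. See
`docs/methods.md` for the model, numerical choices and limitations.

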