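# Methods

## The problem

Given `n` elements `g_0 … g_{n−1}` of a commutative semigroup `(G, ∘)`
with identity `e` but **no inverses**, compute all `n` jackknife
(leave-one-out) products

    ḡ_j = g_0 ∘ … ∘ g_{j−1} ∘ g_{j+1} ∘ … ∘ g_{n−1}.

With inverses this is trivial (`ḡ ∘ g_j⁻¹`); without them the naive
algorithm costs `n(n−2)` products and a plain segment tree costs about
`n log₂ n`. The three-phase algorithm implemented here costs about `3n`
products (`3n − 6` exactly when `n` is a binary power) and storage for
about `2n` elements.

The driving application is an exact conditional test: for independent
nonnegative integer counts `X_i` (motif occurrences on circRNAs) with
observed values `k(i)` and fixed total `K = Σ k(i)`,

    p_i = P{X_i ≥ k(i) | S = K}
        = Σ_{k=k(i)}^{K} g_i[k] · ḡ_i[K−k]  /  ḡ[K],

where `g_i` is the weight array of `X_i` truncated at `K`, `ḡ` the
truncated convolution of all arrays and `ḡ_i` the leave-one-out
convolutions — exactly the jackknife products over the
truncated-convolution semigroup. At `n = 2` with binomial weights this is
the one-sided Fisher exact test.

## The algorithm

Row bookkeeping: `m = ⌈log₂ n⌉` rows, row `k` of length `n_k = ⌈n·2^−k⌉`.

* **Upward phase** (rootless segment tree): `L_0[j] = g_j`;
  `L_k[j] = L_{k−1}[2j] ∘ L_{k−1}[2j+1]`, with the unpaired last node of
  an odd row copied up without a product. `Σ_{k≥1} ρ(n_{k−1})` products
  (`n − 2` at binary powers).
* **Downward phase** (complementary tree): `L̄_{m−1} = L_{m−1}`; then
  descending, `L̄_{k−1}[j] = L_{k−1}[j] ∘ L̄_k[α_k(j)]` where
  `α_k(j) = min{τ(ρ(j)), n_k − 1}` is the *aunt* (sibling of the parent),
  `ρ(j) = ⌊j/2⌋`, `τ(j) = j + (−1)^j`. The unpaired last node of an odd
  row copies its aunt's complement without a product (its own block was
  itself a copy, so the complements coincide). `2n − 4` products at binary
  powers.
* **Transposition phase**: `ḡ_j = L̄_0[τ(j)]` for the paired prefix; an
  odd final element passes through. Zero products.

Degenerate sizes: `n = 0` → empty, `n = 1` → `(e)` (the empty product),
`n = 2` → swap. Padding with identity copies up to the next binary power
is supported and provably equivalent; the general-`n` path simply saves
up to a factor 2 of work. `in_place=True` overwrites the tree rows,
bounding storage by the tree itself (~`2n` elements); written and
non-written variants produce identical results and counts.

`product_count` counts only true semigroup products — identity padding and
row copies are free — which is what makes the `3n − 6` closed form exact.
The full product `ḡ` is derived by folding the two top-row nodes, outside
that accounting.

Two independent oracles pin the reconstruction: the quadratic
fold-omitting-each algorithm, and the segment-tree-only algorithm
`ḡ_j = g_[0,j) ∘ g_[j+1,n)`, whose range query keeps left and right
partial products separate and therefore stays correct in non-commutative
semigroups (tested with string concatenation). Randomized law-checking
(`validate_semigroup`, 200 seeded trials per instance) guards the
commutativity assumption the fast algorithm needs.

## Numerical representation

Placement counts reach ~10^2608, so the production mode stores every
weight as its natural log; an exact zero is a `−inf` entry (scalar
`LogWeight`s carry an explicit flag). Sums use max-shifted log-sum-exp
with a single global shift per reduction, fixing the accumulation order
for bit-reproducibility. Only (+, ×) exist — subtraction is omitted so
cancellation error cannot arise. Truncated convolution is the direct
O(K²) sum; transform methods are deliberately not offered, since
recovering terms of order 1 from sums of order 10^2608 would need
thousands of digits of working precision. Exact-integer mode exists for
oracle tests; double mode for small instances. Log and double convolution
agree to ~1e−9 relative where both are in range, and the test suite holds
the implementation to 1e−10 against enumeration oracles.

## Placement combinatorics

The null model is purely positional: `k` indistinguishable,
non-overlapping motifs of width `w` nt on a sequence of length `I` nt.
Closed forms (placements are sets of start positions; every rotation of a
circular configuration is distinct):

* linear: `C(I − k(w−1), k)`,
* circular: `(I/k) · C(I − k(w−1) − 1, k − 1)` for `k ≥ 1`, i.e.
  `I/(I − k(w−1)) · C(I − k(w−1), k)`; 1 for `k = 0`; 0 when `kw > I`.

Both are verified against an exhaustive enumeration oracle over all
`I ≤ 12, w ≤ 4, k ≤ 3`, and the circular form reproduces the
application's extreme magnitude (`I = 158565, w = 7, k = 997` →
~10^2608). Counts are exact big integers up to 64 motifs per array
(`EXACT_THRESHOLD`), log-gamma beyond; the two paths agree to ~1e−11
relative where both run. Sequence composition is ignored by design — the
model asks where motifs could sit, not what the background nucleotide
frequencies are.

## Multiple testing

Bonferroni only, family size defaulting to the number of items tested
(`n`, or `n ×` number of motifs for multi-motif runs; user-overridable).
Benjamini–Hochberg FDR is deliberately not offered: conditioning on a
fixed total makes the p-values negatively dependent — one count being
large forces the others down — violating the positive-dependence
condition FDR control needs. The TSV report header states this.

## Synthetic data generator

`generate_fixture` emulates a circRNA cohort: `n = 50` sequences of
uniform random length 200–2000 nt with i.i.d. ACGU background, a motif
(default `UUACAGG`, 7 nt — a typical miRNA target-site width) planted a
Poisson-distributed number of times with mean `length / 500`, and one
target sequence planted at 20× that rate. These defaults give observed
totals `K` of order 10², a scaled-down version of the application regime
(`n = 3086, K = 997`); the 200–2000 nt range and 1-per-500-nt rate are my
choice of a realistic mid-range cohort (real circRNAs span 69–158565 nt,
which would make small test cohorts dominated by single outliers).

What the generator does *not* emulate: realistic nucleotide composition,
length distributions with heavy tails, motif degeneracy in the planted
signal, or correlated occurrence (e.g. repeat expansions). Passing the
recovery test therefore shows the pipeline detects a strong positional
excess against its own null; it does not validate the positional null
against real circRNA biology.

## Tolerances and problem sizes

* Exact assertions wherever arithmetic is exact (integers, worked
  example, placement counts).
* 1e−10 relative for the conditional test against enumeration and the
  hypergeometric reduction; 1e−9 for log-vs-double convolution; 1e−12
  for scalar log arithmetic round trips.
* Oracle equivalence runs 200 seeded instances at `n ≤ 40` (the quadratic
  oracle dominates the cost); product-count checks go to `n = 5000`;
  recovery runs 20 replicates at `n = 50`. All sizes are chosen to keep
  the default suite in seconds while exercising every code path,
  including odd-`n` copy handling at every row parity.

## Known limitations

* The conditional test is one-sided (excess only); deficiency tests and
  joint multi-motif models are out of scope.
* The greedy non-overlap counting mode is order-dependent on a circle
  (scan starts at position 0); the default counts all matching starts.
* No dynamic updates of a built tree, no parallelism, no persistence.
* `float` mode under/overflows outside ~10^±308; use the default log mode
  for anything application-scale.
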