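"""The linear-time Jackknife Product algorithm and its two slower oracles.

Given ``n`` elements of a commutative semigroup, the jackknife (leave-one-out)
products are ``ḡ_j = g_0 ∘ … ∘ g_{j-1} ∘ g_{j+1} ∘ … ∘ g_{n-1}``.  Without
inverses the obvious shortcut ``ḡ ∘ g_j^{-1}`` is unavailable; this module
computes all ``n`` jackknife products with about ``3n`` semigroup products
(exactly ``3n − 6`` when ``n`` is a binary power) in three phases:

* **upward** — build a rootless segment tree: row ``L_k`` holds products of
  disjoint consecutive blocks of ``2^k`` inputs;
* **downward** — build the rootless *complementary* segment tree top-down:
  ``L̄_k[j]`` is the product of every input outside the block that
  ``L_k[j]`` covers, obtained by combining each node with its "aunt" (the
  sibling of its parent);
* **transposition** — swap adjacent pairs of the bottom complementary row,
  since ``L̄_0[τ(j)] = ḡ_j``.

Two independent oracle algorithms are shipped alongside: the naive
``O(n²)``-product fold-omitting-each algorithm, and the segment-tree-only
``O(n log n)`` algorithm ``ḡ_j = g_[0,j) ∘ g_[j+1,n)``, which preserves
operand order and therefore stays valid for non-commutative semigroups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

from .semigroup import InstrumentedSemigroup, SemigroupSpec, fold_product

__all__ = [
    "IndexScheme",
    "SegmentTree",
    "JackknifeResult",
    "rho",
    "tau",
    "aunt",
    "pad_to_power",
    "upward_phase",
    "downward_phase",
    "transposition_phase",
    "jackknife_products",
    "naive_jackknife",
    "segment_tree_jackknife",
    "segment_product",
]


def rho(j: int) -> int:
    """Binary right shift ρ(j) = ⌊j/2⌋ — the parent index one row up."""
    return j >> 1


def tau(j: int) -> int:
    """Transposition τ(j) = j + (−1)^j, swapping each even/odd index pair."""
    return j + 1 if j % 2 == 0 else j - 1


@dataclass(frozen=True)
class IndexScheme:
    """Index bookkeeping for an ``n``-leaf rootless tree.

    ``m = ⌈log2 n⌉`` rows; row ``k`` has ``n_k = ⌈n·2^−k⌉`` nodes.  For
    ``n = 1`` there is a single row (``m`` is forced to 1 so the leaf row
    exists).
    """

    n: int

    @property
    def m(self) -> int:
        if self.n <= 1:
            return 1
        return (self.n - 1).bit_length()

    def n_k(self, k: int) -> int:
        # ceil(n * 2^-k)
        return -(-self.n >> k) if k else self.n

    def row_lengths(self) -> list[int]:
        return [self.n_k(k) for k in range(self.m)]


def aunt(scheme: IndexScheme, k: int, j: int) -> int:
    """Aunt index α_k(j) = min{τρ(j), n_k − 1} for a row-(k−1) node.

    The aunt of node ``j`` in row ``k−1`` is the sibling of its parent in
    row ``k`` — the node whose subtree, together with everything outside
    the parent, complements ``j``'s block.  The ``min`` clamps the index
    when the top of an odd-length row has no true sibling.
    """
    if not 1 <= k < max(scheme.m, 2):
        raise ValueError(f"row index k={k} out of range for n={scheme.n}")
    if not 0 <= j < scheme.n_k(k - 1):
        raise ValueError(f"index j={j} out of range for row {k - 1} (length {scheme.n_k(k - 1)})")
    return min(tau(rho(j)), scheme.n_k(k) - 1)


@dataclass
class SegmentTree:
    """Rows ``L_0 … L_{m−1}`` of the (rootless) segment tree; ``L_0[j] = g_j``."""

    scheme: IndexScheme
    rows: list[list[Any]]

    @property
    def n(self) -> int:
        return self.scheme.n


def pad_to_power(S: SemigroupSpec | InstrumentedSemigroup, g: Sequence[Any]) -> list[Any]:
    """Pad on the right with identity copies up to the next binary power."""
    n = len(g)
    if n < 1:
        raise ValueError("pad_to_power requires at least one element")
    n_star = 1 << (n - 1).bit_length()
    return list(g) + [S.identity] * (n_star - n)


def upward_phase(S: SemigroupSpec | InstrumentedSemigroup, g: Sequence[Any]) -> SegmentTree:
    """Build the rootless segment tree bottom-up.

    Row ``k`` pairs up row ``k−1``: ``L_k[j] = L_{k−1}[2j] ∘ L_{k−1}[2j+1]``
    for ``j < ρ(n_{k−1})``, plus a product-free copy of the unpaired last
    node when ``n_{k−1}`` is odd.  Uses ``Σ_{k≥1} ρ(n_{k−1})`` products.
    """
    n = len(g)
    if n < 2:
        raise ValueError("upward_phase requires n >= 2; smaller inputs are handled upstream")
    scheme = IndexScheme(n)
    rows: list[list[Any]] = [list(g)]
    for k in range(1, scheme.m):
        prev = rows[k - 1]
        nk = scheme.n_k(k)
        row = [S.product(prev[2 * j], prev[2 * j + 1]) for j in range(rho(len(prev)))]
        if len(prev) % 2 == 1:
            row.append(prev[-1])  # unpaired top node: copy, no product
        assert len(row) == nk
        rows.append(row)
    return SegmentTree(scheme=scheme, rows=rows)


def downward_phase(
    S: SemigroupSpec | InstrumentedSemigroup,
    tree: SegmentTree,
    in_place: bool = False,
) -> list[list[Any]]:
    """Build the complementary tree ``L̄_{m−1} … L̄_0`` top-down.

    ``L̄_{m−1}`` starts as a copy of ``L_{m−1}``; then, descending,
    ``L̄_{k−1}[j] = L_{k−1}[j] ∘ L̄_k[α_k(j)]`` — each node times its aunt's
    complement — except that the unpaired last node of an odd row inherits
    its aunt's complement by a product-free copy (its own block was itself
    copied upward, so the complements coincide).

    With ``in_place=True`` the rows of ``tree`` are overwritten, bounding
    storage by the ~``2n`` elements of the tree itself; element writes are
    ordered so no value is clobbered before its last use (each ``L̄_{k−1}[j]``
    reads only ``L_{k−1}[j]`` and the already-finished row ``k``).
    """
    scheme = tree.scheme
    m = scheme.m
    if in_place:
        bar = tree.rows
        # top row: complement of a top-row node is its sibling, and
        # L̄_{m−1} = L_{m−1}, so the row is literally unchanged.
    else:
        bar = [list(row) for row in tree.rows]
    for k in range(m - 1, 0, -1):
        upper = list(bar[k]) if in_place else bar[k]
        src = tree.rows[k - 1]
        nk1 = scheme.n_k(k - 1)
        dest = bar[k - 1]
        for j in range(nk1):
            a = aunt(scheme, k, j)
            if nk1 % 2 == 1 and j == nk1 - 1:
                dest[j] = upper[a]  # unpaired node: copy, no product
            else:
                dest[j] = S.product(src[j], upper[a])
    return bar


def transposition_phase(bar_L0: Sequence[Any], n: int) -> list[Any]:
    """Unscramble the bottom complementary row into jackknife order.

    ``ḡ_j = L̄_0[τ(j)]`` for the paired prefix ``j < 2ρ(n)``; an odd final
    element passes through unchanged.  Performs zero products, and is its
    own inverse on even-length rows.
    """
    if len(bar_L0) != n:
        raise ValueError(f"expected row of length {n}, got {len(bar_L0)}")
    out = [bar_L0[tau(j)] for j in range(2 * rho(n))]
    if n % 2 == 1:
        out.append(bar_L0[n - 1])
    return out


@dataclass
class JackknifeResult:
    """All ``n`` leave-one-out products plus run accounting."""

    jackknife: list[Any]
    full_product: Any
    product_count: int
    n: int


def jackknife_products(
    S: SemigroupSpec | InstrumentedSemigroup,
    g: Sequence[Any],
    in_place: bool = False,
) -> JackknifeResult:
    """Run the three-phase algorithm; the main entry point.

    Degenerate sizes follow the only consistent reading of leave-one-out:
    ``n = 0`` gives an empty result, ``n = 1`` gives ``(e,)`` (the empty
    product), ``n = 2`` simply swaps.  ``in_place`` changes storage, never
    results.  ``product_count`` counts true semigroup products of the three
    phases (``3n − 6`` at binary powers); the full product ḡ is derived
    from the top tree row outside that accounting.
    """
    inst = S if isinstance(S, InstrumentedSemigroup) else InstrumentedSemigroup(S)
    start = inst.product_count
    n = len(g)
    if n == 0:
        return JackknifeResult([], inst.identity, 0, 0)
    if n == 1:
        return JackknifeResult([inst.identity], g[0], 0, 1)
    tree = upward_phase(inst, g)
    top = list(tree.rows[-1])
    bar = downward_phase(inst, tree, in_place=in_place)
    jack = transposition_phase(bar[0], n)
    count = inst.product_count - start
    full = fold_product(inst.inner, top) if len(top) > 1 else top[0]
    return JackknifeResult(jack, full, count, n)


def naive_jackknife(S: SemigroupSpec | InstrumentedSemigroup, g: Sequence[Any]) -> list[Any]:
    """Quadratic oracle: fold all inputs except ``g_j``, for each ``j``."""
    n = len(g)
    return [fold_product(S, [g[i] for i in range(n) if i != j]) for j in range(n)]


def segment_product(
    S: SemigroupSpec | InstrumentedSemigroup, tree: SegmentTree, i: int, j: int
) -> Any:
    """Order-preserving product of the half-open segment ``g_[i,j)``.

    The classic iterative query: walk up the rows, absorbing the at most
    two boundary nodes per level, keeping left- and right-side partial
    products separate so the result is valid without commutativity.
    ``O(log n)`` products; ``[i, i)`` is the identity.
    """
    n = tree.n
    if not (0 <= i <= j <= n):
        raise ValueError(f"invalid segment [{i}, {j}) for n={n}")
    left = None
    right = None
    l, r = i, j
    for row in tree.rows:
        if l >= r:
            break
        if l % 2 == 1:
            left = row[l] if left is None else S.product(left, row[l])
            l += 1
        if r % 2 == 1:
            r -= 1
            right = row[r] if right is None else S.product(row[r], right)
        l, r = rho(l), rho(r)
    if l < r:
        # Rootless top: only the full query [0, n) reaches the top row with
        # both nodes unabsorbed; fold them where the root would sit.
        top = tree.rows[-1]
        mid = S.product(top[0], top[1])
        left = mid if left is None else S.product(left, mid)
    parts = [p for p in (left, right) if p is not None]
    if not parts:
        return S.identity
    if len(parts) == 1:
        return parts[0]
    return S.product(parts[0], parts[1])


def segment_tree_jackknife(
    S: SemigroupSpec | InstrumentedSemigroup, g: Sequence[Any]
) -> list[Any]:
    """Segment-tree-only oracle: ``ḡ_j = g_[0,j) ∘ g_[j+1,n)``.

    ``O(n log n)`` products, but — unlike the three-phase algorithm — valid
    in any semigroup, commutative or not, because both queries preserve
    operand order.
    """
    n = len(g)
    if n == 0:
        return []
    if n == 1:
        return [S.identity]
    tree = upward_phase(S, g)
    out = []
    for j in range(n):
        pre = segment_product(S, tree, 0, j)
        post = segment_product(S, tree, j + 1, n)
        out.append(S.product(pre, post))
    return out
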