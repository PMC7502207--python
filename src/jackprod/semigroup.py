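"""Commutative semigroups with identity.

Everything downstream (the jackknife-product algorithm, truncated
convolutions, the enrichment test) runs over an abstract commutative
semigroup ``(G, ∘)`` augmented with an identity element ``e``.  A semigroup
only guarantees closure and associativity; commutativity is what the
linear-time leave-one-out algorithm additionally requires, and inverses are
deliberately never assumed (truncated convolution has none).

Instances are plain :class:`SemigroupSpec` records.  Operands are treated as
immutable values: a ``product`` must never modify its arguments, which is
what makes the in-place tree computation safe.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from functools import reduce
from typing import Any, Callable, Iterable, Sequence

__all__ = [
    "SemigroupSpec",
    "InstrumentedSemigroup",
    "ValidationReport",
    "fold_product",
    "validate_semigroup",
    "make_integer_add",
    "make_integer_max",
    "make_bitstring_or",
    "make_string_concat",
]


@dataclass(frozen=True)
class SemigroupSpec:
    """A commutative semigroup with identity.

    Parameters
    ----------
    product
        The binary operation ``(g, g') -> g ∘ g'``.  Must be closed,
        associative and commutative on the intended element set, and must
        not mutate its operands.
    identity
        The identity element ``e`` with ``e ∘ g = g ∘ e = g``.  Structures
        lacking a natural identity must adjoin a sentinel whose product
        rule returns the other operand.
    label
        Short human-readable name, used in traces and reports.
    equality
        Element equality predicate.  Exact semigroups use structural
        equality; floating-valued ones supply a tolerance-based predicate.
    """

    product: Callable[[Any, Any], Any]
    identity: Any
    label: str = "semigroup"
    equality: Callable[[Any, Any], bool] = field(default=lambda a, b: a == b)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SemigroupSpec({self.label!r})"


class InstrumentedSemigroup:
    """Wrap a :class:`SemigroupSpec`, counting true product invocations.

    Identity padding and row copies are *not* products and are never routed
    through this wrapper, so ``product_count`` matches the operation-count
    accounting of the algorithm analysis (about ``3n`` products for the
    three-phase jackknife computation).
    """

    def __init__(self, inner: SemigroupSpec):
        self.inner = inner
        self.product_count = 0

    @property
    def identity(self) -> Any:
        return self.inner.identity

    @property
    def label(self) -> str:
        return self.inner.label

    @property
    def equality(self) -> Callable[[Any, Any], bool]:
        return self.inner.equality

    def product(self, a: Any, b: Any) -> Any:
        self.product_count += 1
        return self.inner.product(a, b)

    def reset(self) -> None:
        self.product_count = 0


def fold_product(S: SemigroupSpec | InstrumentedSemigroup, g: Sequence[Any]) -> Any:
    """Fold ``g_0 ∘ g_1 ∘ … ∘ g_{n-1}``; the empty fold is the identity."""
    return reduce(S.product, g, S.identity)


@dataclass
class ValidationReport:
    """Outcome of randomized semigroup-law checking."""

    label: str
    trials: int
    violations: list[tuple[str, tuple]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_semigroup(
    S: SemigroupSpec | InstrumentedSemigroup,
    sampler: Callable[[_random.Random], Any],
    trials: int = 200,
    seed: int = 0,
) -> ValidationReport:
    """Probe the identity, commutativity and associativity laws.

    ``sampler(rng)`` draws random elements.  Each trial draws a fresh triple
    and records any law violated under ``S.equality``.  All shipped
    instances must come back clean; a deliberately broken instance (e.g.
    string concatenation) surfaces its commutativity failures here.
    """
    rng = _random.Random(seed)
    eq = S.equality
    e = S.identity
    report = ValidationReport(label=S.label, trials=trials)
    for _ in range(trials):
        a, b, c = sampler(rng), sampler(rng), sampler(rng)
        if not (eq(S.product(e, a), a) and eq(S.product(a, e), a)):
            report.violations.append(("identity", (a,)))
        ab, ba = S.product(a, b), S.product(b, a)
        if not eq(ab, ba):
            report.violations.append(("commutativity", (a, b)))
        if not eq(S.product(ab, c), S.product(a, S.product(b, c))):
            report.violations.append(("associativity", (a, b, c)))
    return report


def make_integer_add() -> SemigroupSpec:
    """Nonnegative integers under addition — the worked-example semigroup."""
    return SemigroupSpec(product=lambda a, b: a + b, identity=0, label="add")


def make_integer_max() -> SemigroupSpec:
    """Nonnegative integers under max; 0 is the identity."""
    return SemigroupSpec(product=max, identity=0, label="max")


def make_bitstring_or(width: int) -> SemigroupSpec:
    """Fixed-width bit strings under bitwise OR — the debugging semigroup.

    With unit bit strings as inputs, segment products light up contiguous
    index ranges and complementary products light up everything else, so a
    printed tree trace is self-explanatory.  Elements are ``str`` of '0'/'1'
    of exactly ``width`` characters; width mismatch is an error, never
    silent padding.
    """
    if width < 1:
        raise ValueError(f"bitstring width must be >= 1, got {width}")

    def _or(a: str, b: str) -> str:
        if len(a) != width or len(b) != width:
            raise ValueError(
                f"bitstring width mismatch: expected {width}, got {len(a)} and {len(b)}"
            )
        return "".join("1" if (x == "1" or y == "1") else "0" for x, y in zip(a, b))

    return SemigroupSpec(product=_or, identity="0" * width, label=f"or{width}")


def make_string_concat() -> SemigroupSpec:
    """String concatenation: associative but NOT commutative.

    Shipped only as a negative control for :func:`validate_semigroup` and as
    a test case for the order-preserving segment-tree oracle, which unlike
    the jackknife algorithm does not need commutativity.
    """
    return SemigroupSpec(product=lambda a, b: a + b, identity="", label="concat")
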