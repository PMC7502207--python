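"""Exact conditional test: is one of n independent counts unusually large?

For independent nonnegative integer counts ``X_0 … X_{n−1}`` with observed
values ``k(i)`` and fixed observed total ``K = Σ k(i)``, the per-item
conditional p-value is

    P{X_i ≥ k(i) | S = K}
        = Σ_{k=k(i)}^{K} g_i[k] · ḡ_i[K−k]  /  ḡ[K],

where ``g_i`` is the (truncated) weight array of ``X_i``, ``ḡ`` the
convolution of all of them, and ``ḡ_i`` the convolution of all but the
``i``-th — the jackknife products, computed here in one linear-time pass
rather than by n separate folds.  The formula is invariant to scaling any
``g_i`` by a positive constant, so configuration counts work as well as
probabilities.

At ``n = 2`` with binomial counts this reduces exactly to the one-sided
Fisher exact test (a hypergeometric tail), which doubles as a closed-form
oracle.  Multiple testing uses Bonferroni: the fixed-sum null makes the
p-values negatively dependent (one count being large forces the others
down), violating the positive-dependence condition of Benjamini–Hochberg,
so no FDR option is offered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product as _cartesian
from typing import Sequence

from scipy.stats import hypergeom

from .convolution import TruncatedArray, convolution_semigroup
from .jackknife import jackknife_products
from .logspace import LogWeight, lw_mul, lw_ratio_log10, lw_sum

__all__ = [
    "ObservedData",
    "ItemResult",
    "EnrichmentResult",
    "conditional_pvalues",
    "bonferroni",
    "hypergeometric_tail_oracle",
    "bruteforce_conditional_oracle",
]


@dataclass(frozen=True)
class ObservedData:
    """Observed counts plus each item's weight array, truncated at K = Σk(i)."""

    k_obs: tuple[int, ...]
    g_list: tuple[TruncatedArray, ...]

    def __post_init__(self):
        if len(self.k_obs) != len(self.g_list):
            raise ValueError("k_obs and g_list lengths differ")
        if any(k < 0 for k in self.k_obs):
            raise ValueError("observed counts must be nonnegative")
        K = self.K
        for i, g in enumerate(self.g_list):
            if g.K != K:
                raise ValueError(
                    f"g_list[{i}] truncated at {g.K}, but observed total K={K}: "
                    "all arrays must share the observed total as truncation order"
                )

    @property
    def n(self) -> int:
        return len(self.k_obs)

    @property
    def K(self) -> int:
        return sum(self.k_obs)


@dataclass(frozen=True)
class ItemResult:
    """Per-item test output; log10 survives where the linear p underflows."""

    p_raw: float
    log10_p_raw: float
    p_bonferroni: float
    numerator: LogWeight
    denominator: LogWeight


@dataclass
class EnrichmentResult:
    items: list[ItemResult] = field(default_factory=list)
    family_size: int = 1
    product_count: int = 0

    @property
    def p_raw(self) -> list[float]:
        return [it.p_raw for it in self.items]

    @property
    def p_bonferroni(self) -> list[float]:
        return [it.p_bonferroni for it in self.items]


def bonferroni(p: float, family_size: int) -> float:
    """Familywise correction min(1, family_size · p)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if family_size < 1:
        raise ValueError(f"family_size must be >= 1, got {family_size}")
    return min(1.0, family_size * p)


def conditional_pvalues(data: ObservedData, family_size: int | None = None) -> EnrichmentResult:
    """All n conditional p-values P{X_i ≥ k(i) | S = K} from one jackknife pass.

    Runs the three-phase jackknife over the truncated-convolution semigroup
    (~3n convolutions total), then evaluates the tail sum per item in log
    space.  ``family_size`` defaults to n; pass n × (number of motifs) when
    several motifs share one analysis.
    """
    n, K = data.n, data.K
    if n == 0:
        return EnrichmentResult(items=[], family_size=family_size or 1)
    if family_size is None:
        family_size = n
    S = convolution_semigroup(K, data.g_list[0].mode)
    res = jackknife_products(S, list(data.g_list), in_place=False)
    gbar = res.full_product
    den = gbar.weight(K)
    if den.is_zero:
        raise ValueError(
            f"the observed total K={K} has zero weight under the model: "
            "observation and null model are inconsistent"
        )
    items = []
    for i in range(n):
        g_i = data.g_list[i]
        gbar_i = res.jackknife[i]
        num = lw_sum(
            lw_mul(g_i.weight(k), gbar_i.weight(K - k)) for k in range(data.k_obs[i], K + 1)
        )
        log10p = lw_ratio_log10(num, den)
        p = min(1.0, 10.0 ** log10p) if log10p > -745 else 0.0
        items.append(
            ItemResult(
                p_raw=p,
                log10_p_raw=min(log10p, 0.0),
                p_bonferroni=bonferroni(p, family_size),
                numerator=num,
                denominator=den,
            )
        )
    return EnrichmentResult(items=items, family_size=family_size, product_count=res.product_count)


def hypergeometric_tail_oracle(N0: int, N1: int, K: int, k: int) -> float:
    """Fisher-exact (n=2) closed form: P{H ≥ k}, H ~ Hypergeom(N0+N1, N0, K).

    The binomial success probability cancels under the fixed-sum
    conditioning, so the tail depends only on the trial counts.
    """
    if K > N0 + N1:
        raise ValueError("total successes cannot exceed total trials")
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N0 + N1, N0, K))


def bruteforce_conditional_oracle(data: ObservedData, i: int) -> float:
    """Independent oracle for the conditional p-value by joint enumeration.

    Sums Π_j g_j[x_j] over every count vector with Σx = K, splitting the
    mass by whether x_i ≥ k(i).  Exponential in n — refuses instances with
    more than ~10^6 candidate vectors.
    """
    n, K = data.n, data.K
    if (K + 1) ** n > 10**6:
        raise ValueError(f"instance too large to enumerate: (K+1)^n = {(K + 1) ** n}")
    lin = [g.to_linear() for g in data.g_list]
    num = 0.0
    den = 0.0
    for x in _cartesian(range(K + 1), repeat=n):
        if sum(x) != K:
            continue
        weight = math.prod(lin[j][x[j]] for j in range(n))
        den += weight
        if x[i] >= data.k_obs[i]:
            num += weight
    if den == 0.0:
        raise ValueError("observed total has zero weight under the model")
    return num / den
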