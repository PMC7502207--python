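"""Truncated convolution: the application's commutative semigroup.

For independent nonnegative integer counts ``X`` and ``Y`` with weight
arrays ``g'`` and ``g''`` (probabilities, or configuration counts — the
conditional test is invariant to the distinction), the distribution of
``X + Y`` restricted to totals ``≤ K`` is the truncated convolution

    (g' ∘ g'')[k] = Σ_{j=0}^{k} g'[j] · g''[k−j],   k = 0 … K.

With the unit mass at 0 as identity ``e = (1, 0, …, 0)`` this is a
commutative semigroup — and pointedly *not* a group: any element with
``g[0] < 1`` has no inverse, which is why leave-one-out products cannot be
formed by division and the jackknife algorithm earns its keep.

Three weight modes share one array type: exact integers (oracle tests and
small instances), doubles, and log space (the production mode — counts in
the motif application reach ~10^2608).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .logspace import LogWeight
from .semigroup import SemigroupSpec, fold_product

__all__ = ["TruncatedArray", "convolve", "convolution_semigroup", "distribution_of_sum"]

_MODES = ("int", "float", "log")
_NEG_INF = -np.inf


@dataclass(frozen=True)
class TruncatedArray:
    """A (K+1)-vector of nonnegative weights under one of three modes.

    ``w`` is a tuple of python ints (mode "int"), floats (mode "float"),
    or natural-log floats with −inf encoding an exact zero (mode "log" —
    the per-element equivalent of a :class:`~jackprod.logspace.LogWeight`).
    """

    K: int
    w: tuple
    mode: str = "float"

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {_MODES}")
        if self.K < 0:
            raise ValueError(f"truncation order K must be >= 0, got {self.K}")
        if len(self.w) != self.K + 1:
            raise ValueError(f"expected {self.K + 1} weights, got {len(self.w)}")
        if self.mode in ("int", "float") and any(x < 0 for x in self.w):
            raise ValueError("weights must be nonnegative")

    @staticmethod
    def from_weights(weights: Sequence, mode: str = "float") -> "TruncatedArray":
        K = len(weights) - 1
        if mode == "log":
            w = tuple(_NEG_INF if x == 0 else math.log(x) for x in weights)
        elif mode == "int":
            w = tuple(int(x) for x in weights)
        else:
            w = tuple(float(x) for x in weights)
        return TruncatedArray(K=K, w=w, mode=mode)

    @staticmethod
    def from_logs(logs: Sequence[float]) -> "TruncatedArray":
        return TruncatedArray(K=len(logs) - 1, w=tuple(float(v) for v in logs), mode="log")

    @staticmethod
    def unit_mass(K: int, mode: str = "float") -> "TruncatedArray":
        """The identity e: all mass on the total 0."""
        if mode == "log":
            return TruncatedArray(K, (0.0,) + (_NEG_INF,) * K, "log")
        one = 1 if mode == "int" else 1.0
        zero = 0 if mode == "int" else 0.0
        return TruncatedArray(K, (one,) + (zero,) * K, mode)

    def to_linear(self) -> np.ndarray:
        """Weights on the linear scale (may over/underflow in log mode)."""
        if self.mode == "log":
            return np.exp(np.asarray(self.w, dtype=float))
        return np.asarray(self.w, dtype=float)

    def weight(self, k: int) -> LogWeight:
        """Entry k as a LogWeight, whatever the mode."""
        if self.mode == "log":
            return LogWeight.from_log(self.w[k])
        return LogWeight.from_linear(self.w[k])

    def total_mass(self) -> float:
        if self.mode == "log":
            return float(np.exp(logsumexp(np.asarray(self.w))))
        return float(sum(self.w))


def convolve(a: TruncatedArray, b: TruncatedArray) -> TruncatedArray:
    """Truncated convolution ``(a ∘ b)[k] = Σ_j a[j]·b[k−j]``.

    Direct ``O(K²)`` summation — transform methods are unusable at these
    magnitude ranges, where recovering a term of order 10^0 from sums of
    order 10^2608 would demand thousands of digits of precision.
    """
    if a.K != b.K:
        raise ValueError(f"truncation mismatch: K={a.K} vs K={b.K}")
    if a.mode != b.mode:
        raise ValueError(f"mode mismatch: {a.mode!r} vs {b.mode!r}")
    K = a.K
    if a.mode == "log":
        return TruncatedArray(K, tuple(_log_convolve(a.w, b.w)), "log")
    if a.mode == "int":
        w = tuple(sum(a.w[j] * b.w[k - j] for j in range(k + 1)) for k in range(K + 1))
        return TruncatedArray(K, w, "int")
    aw = np.asarray(a.w, dtype=float)
    bw = np.asarray(b.w, dtype=float)
    w = np.convolve(aw, bw)[: K + 1]
    return TruncatedArray(K, tuple(float(x) for x in w), "float")


def _log_convolve(la: Sequence[float], lb: Sequence[float]) -> np.ndarray:
    """Log-domain truncated convolution via per-total log-sum-exp.

    Builds the matrix M[j, k] = la[j] + lb[k−j] (−inf where k < j) and
    reduces each column with one max shift, so the accumulation order is
    fixed and reproducible.
    """
    K = len(la) - 1
    a = np.asarray(la, dtype=float)
    b = np.asarray(lb, dtype=float)
    j = np.arange(K + 1)
    diff = j[None, :] - j[:, None]  # k - j
    with np.errstate(invalid="ignore"):
        M = a[:, None] + np.where(diff >= 0, b[np.clip(diff, 0, K)], _NEG_INF)
    M[np.isnan(M)] = _NEG_INF  # -inf + inf guards (cannot occur: weights finite or -inf)
    return logsumexp(M, axis=0)


def convolution_semigroup(K: int, mode: str = "float") -> SemigroupSpec:
    """The truncated-convolution semigroup at a fixed truncation order K.

    K is fixed per analysis at the observed total ΣK(i); every array in one
    run shares it.  Equality is exact in integer mode and relative-tolerance
    (1e−9) otherwise.
    """
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")

    if mode == "int":
        def eq(x: TruncatedArray, y: TruncatedArray) -> bool:
            return x.w == y.w
    elif mode == "log":
        def eq(x: TruncatedArray, y: TruncatedArray) -> bool:
            return all(
                math.isclose(p, q, rel_tol=1e-9, abs_tol=1e-12)
                or (p == _NEG_INF and q == _NEG_INF)
                for p, q in zip(x.w, y.w)
            )
    else:
        def eq(x: TruncatedArray, y: TruncatedArray) -> bool:
            return all(math.isclose(p, q, rel_tol=1e-9, abs_tol=1e-300) for p, q in zip(x.w, y.w))

    return SemigroupSpec(
        product=convolve,
        identity=TruncatedArray.unit_mass(K, mode),
        label=f"conv(K={K},{mode})",
        equality=eq,
    )


def distribution_of_sum(
    g_list: Iterable[TruncatedArray], K: int | None = None, mode: str = "float"
) -> TruncatedArray:
    """Distribution of the sum of independent counts: the fold ḡ = g_0 ∘ … ∘ g_{n−1}.

    An empty list is the sum of no variates — the unit mass at 0 — and
    needs an explicit ``K`` (and mode) to know its shape.
    """
    g_list = list(g_list)
    if not g_list:
        if K is None:
            raise ValueError("empty list: pass K (and mode) to shape the identity")
        return TruncatedArray.unit_mass(K, mode)
    S = convolution_semigroup(g_list[0].K, g_list[0].mode)
    return fold_product(S, g_list)
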