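"""Analytical null distribution of the match complexity Cm.

For an i.i.d. random sequence with GC content 2p (base frequencies
q, p, p, q for A, C, G, T with q = 0.5 - p), the length Y* of the longest
match starting at a position and occurring elsewhere in a sequence of length
L has CDF

    P(Y* < x) ~= sum_k  multinomial(x; k) * prod_j p_j^{k_j}
                        * (1 - prod_j p_j^{k_j})^L

summed over nucleotide-count vectors k = (kA, kC, kG, kT) with sum x.  Since
the probability of a word depends only on its GC count g = kC + kG, the sum
collapses to a single sum over g:

    P(Y* < x) = sum_g  C(x, g) * (2q)^(x-g) * (2p)^g * (1 - q^(x-g) p^g)^L

which is the production path (O(x) per evaluation; the full composition sum
is kept as a slow reference).  From this CDF come the mean mu = E[Y*] and
variance sigma2 = V[Y*] of the match length, and Ca = 1/mu, the expected
match-factor count per base in random sequence.

The factor ends form a renewal process, so by the renewal CLT the factor
count N_W of a window of length W (with L >> W >> 1) is approximately normal,
giving

    Cm ~ Normal(1, sigma2 / (mu * W))

whose quantile function 1 + sqrt(2*sigma2/(mu*W)) * erfinv(2p - 1) supplies
the thresholds that separate high-complexity windows from the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfinv, gammaln

__all__ = [
    "NullModel",
    "CmNull",
    "match_length_cdf",
    "match_length_cdf_composition",
    "null_moments",
    "cm_value",
    "cm_quantile",
]

_TAIL_TOL = 1e-12
_X_MAX = 1000


def _check_p(p: float) -> None:
    if not (0.0 < p < 0.5):
        raise ValueError(f"p must lie strictly between 0 and 0.5, got {p}")


def match_length_cdf(x: int, p: float, L: int) -> float:
    """P(Y* < x): probability the longest match at a position is shorter than x.

    Collapsed single sum over the GC count g of the length-x word; the
    no-occurrence factor (1 - pi)^L is evaluated in log space so it is safe
    for genome-scale L.
    """
    _check_p(p)
    if x < 1 or L < 1:
        raise ValueError("x and L must be >= 1")
    q = 0.5 - p
    g = np.arange(x + 1)
    log_mult = gammaln(x + 1) - gammaln(g + 1) - gammaln(x - g + 1)
    log_word = (x - g) * math.log(q) + g * math.log(p)  # prob of one word
    log_weight = log_mult + x * math.log(2.0) + log_word
    # (1 - pi)^L with pi = q^(x-g) p^g
    log_miss = L * np.log1p(-np.exp(log_word))
    # accumulated rounding can push the far tail a few ulp past 1
    return float(min(1.0, np.exp(log_weight + log_miss).sum()))


def match_length_cdf_composition(x: int, p: float, L: int) -> float:
    """Reference evaluation as the explicit sum over 4-part compositions.

    Enumerates every nucleotide-count vector (kA, kC, kG, kT) summing to x.
    O(x^3) terms — used to validate the collapsed form, not for production.
    """
    _check_p(p)
    if x < 1 or L < 1:
        raise ValueError("x and L must be >= 1")
    q = 0.5 - p
    logs = {"A": math.log(q), "C": math.log(p), "G": math.log(p), "T": math.log(q)}
    total = 0.0
    for ka in range(x + 1):
        for kc in range(x - ka + 1):
            for kg in range(x - ka - kc + 1):
                kt = x - ka - kc - kg
                log_mult = (
                    gammaln(x + 1)
                    - gammaln(ka + 1)
                    - gammaln(kc + 1)
                    - gammaln(kg + 1)
                    - gammaln(kt + 1)
                )
                log_word = (
                    ka * logs["A"] + kc * logs["C"] + kg * logs["G"] + kt * logs["T"]
                )
                total += math.exp(log_mult + log_word + L * math.log1p(-math.exp(log_word)))
    return total


def null_moments(
    p: float, L: int, tail_tol: float = _TAIL_TOL, x_max: int = _X_MAX
) -> tuple[float, float]:
    """Mean mu = E[Y*] and variance sigma2 = V[Y*] of the match length.

    mu   = sum_x x * (F(x+1) - F(x))
    sigma2 = sum_x x^2 * (F(x) - F(x-1)) - (mu + 1)^2
           = E[(Y*+1)^2] - (E[Y*]+1)^2   (= V[Y*], the shifted-index form)

    The sums run until the residual tail mass 1 - F(x) drops below
    ``tail_tol`` (the nominal upper limit L is astronomically beyond where
    the pmf vanishes); failure to converge by ``x_max`` raises.
    """
    _check_p(p)
    if L < 2:
        raise ValueError("L must be >= 2")
    mu = 0.0
    m2 = 0.0  # E[(Y+1)^2]
    f_prev = match_length_cdf(1, p, L)
    m2 += f_prev  # mass at Y = 0 contributes (0+1)^2 * P(Y=0)
    for x in range(1, x_max + 1):
        f_next = match_length_cdf(x + 1, p, L)
        pmf = f_next - f_prev
        mu += x * pmf
        m2 += (x + 1) ** 2 * pmf
        f_prev = f_next
        if 1.0 - f_next < tail_tol:
            break
    else:
        raise RuntimeError(
            f"match-length moments did not converge by x={x_max}; "
            f"residual tail mass {1.0 - f_prev:.3e}"
        )
    sigma2 = m2 - (mu + 1.0) ** 2
    return mu, sigma2


@dataclass(frozen=True)
class NullModel:
    """Random-sequence null for match statistics at a given GC and length.

    Attributes
    ----------
    p : per-base probability of C (and of G); GC content is 2p.
    L : total match-space length in bases (the whole indexed sequence set,
        not the window — matches are sought across all of it).
    mu : expected longest-match length E[Y*].
    sigma2 : variance V[Y*].
    Ca : expected match-factor count per base, 1/mu.
    """

    p: float
    L: int
    mu: float
    sigma2: float

    @property
    def Ca(self) -> float:
        return 1.0 / self.mu

    @property
    def gc(self) -> float:
        return 2.0 * self.p

    @classmethod
    def from_gc(cls, gc: float, L: int) -> "NullModel":
        """Build the null from a GC content and match-space length."""
        p = gc / 2.0
        mu, sigma2 = null_moments(p, L)
        return cls(p=p, L=L, mu=mu, sigma2=sigma2)

    @classmethod
    def from_esa(cls, esa, gc: float | None = None) -> "NullModel":
        """Null matched to an index: its global GC (or an override) and its L.

        When the index covers both strands the match space is twice the
        sequence length.
        """
        g = esa.gc if gc is None else gc
        L = 2 * esa.L if esa.both_strands else esa.L
        return cls.from_gc(g, L)

    def window_null(self, W: int) -> "CmNull":
        return CmNull(W=W, mu=self.mu, sigma2=self.sigma2)


@dataclass(frozen=True)
class CmNull:
    """Normal approximation of window Cm: mean 1, variance sigma2/(mu*W)."""

    W: int
    mu: float
    sigma2: float

    @property
    def mean(self) -> float:
        return 1.0

    @property
    def variance(self) -> float:
        return self.sigma2 / (self.mu * self.W)


def cm_value(Co: float, Ci: float, Ca: float) -> float:
    """Match complexity Cm = (Co - Ci) / (Ca - Ci).

    Co is the observed factor rate, Ci = 2/W the theoretical minimum, and Ca
    the random-sequence expectation; the subtraction pins Cm to 0 for
    minimally complex sequence and expectation 1 for random sequence.
    """
    if Ca <= Ci:
        raise ValueError(
            f"Ca={Ca:.6g} <= Ci={Ci:.6g}: window too short for the null model"
        )
    return (Co - Ci) / (Ca - Ci)


def cm_quantile(prob: float, null: CmNull) -> float:
    """Quantile of the window-Cm null: 1 + sqrt(2*sigma2/(mu*W))*erfinv(2p-1)."""
    if not (0.0 < prob < 1.0):
        raise ValueError(f"prob must lie strictly between 0 and 1, got {prob}")
    if null.variance <= 0.0 or not np.isfinite(null.variance):
        raise ValueError(f"degenerate null variance {null.variance}")
    return 1.0 + math.sqrt(2.0 * null.sigma2 / (null.mu * null.W)) * float(
        erfinv(2.0 * prob - 1.0)
    )
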