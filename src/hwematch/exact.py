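"""Exact test of Hardy-Weinberg proportions for a single diallelic locus.

The test conditions on the observed allele counts: given ``nA`` copies of one
allele among ``2n`` total, the heterozygote count ``h`` fully determines the
genotype configuration, and under random mating each configuration has the
Levene/Haldane conditional probability

    P(h | nA, n) = n! 2^h nA! (2n - nA)! / (n_AA! n_Aa! n_aa! (2n)!)

The two-sided p-value sums the probabilities of all attainable heterozygote
counts whose conditional probability does not exceed that of the observed
configuration (probability ordering, the standard form of the exact HWE test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "GenotypeCounts",
    "hwe_exact_pvalue",
    "log_multinomial_hwe_prob",
    "het_log_probs",
]

# tie comparison tolerance for "probability <= observed" (relative);
# guarantees the observed configuration is always included, hence p > 0
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts (AA, Aa, aa) for one SNP in one group of individuals."""

    n_AA: int
    n_Aa: int
    n_aa: int

    def __post_init__(self) -> None:
        for name in ("n_AA", "n_Aa", "n_aa"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa

    @property
    def n_minor(self) -> int:
        """Count of the allele coded 'a' (2 per aa homozygote, 1 per het)."""
        return 2 * self.n_aa + self.n_Aa

    def as_array(self) -> np.ndarray:
        return np.array([self.n_AA, self.n_Aa, self.n_aa], dtype=np.int64)

    def __add__(self, other: "GenotypeCounts") -> "GenotypeCounts":
        return GenotypeCounts(
            self.n_AA + other.n_AA, self.n_Aa + other.n_Aa, self.n_aa + other.n_aa
        )


class _LogFactorialTable:
    """Cached log-factorial values, grown geometrically on demand."""

    def __init__(self) -> None:
        self._table = gammaln(np.arange(1024, dtype=np.float64) + 1.0)

    def upto(self, m: int) -> np.ndarray:
        if m >= self._table.size:
            size = max(m + 1, 2 * self._table.size)
            self._table = gammaln(np.arange(size, dtype=np.float64) + 1.0)
        return self._table


_LOGFACT = _LogFactorialTable()


def het_log_probs(nA: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional log-probabilities of every attainable heterozygote count.

    Parameters
    ----------
    nA
        Copies of one allele (either orientation) among the ``2n`` alleles.
    n
        Number of diploid individuals, ``n >= 1``.

    Returns
    -------
    (h, logp)
        Heterozygote counts sharing the parity of ``nA`` and their exact
        conditional log-probabilities; ``exp(logp)`` sums to 1.
    """
    if n < 1:
        raise ValueError("empty sample")
    if not 0 <= nA <= 2 * n:
        raise ValueError(f"allele count {nA} outside [0, {2 * n}]")
    lf = _LOGFACT.upto(2 * n)
    nA = min(nA, 2 * n - nA)  # orientation-symmetric by construction
    nB = 2 * n - nA
    h = np.arange(nA & 1, min(nA, nB) + 1, 2, dtype=np.int64)
    n_hom_a = (nA - h) // 2
    n_hom_b = (nB - h) // 2
    logp = (
        lf[n]
        + h * np.log(2.0)
        + lf[nA]
        + lf[nB]
        - lf[n_hom_a]
        - lf[h]
        - lf[n_hom_b]
        - lf[2 * n]
    )
    logp -= logsumexp(logp)  # exact normalization at large n
    return h, logp


def log_multinomial_hwe_prob(h: int, nA: int, n: int) -> float:
    """Log conditional probability of ``h`` heterozygotes given allele counts.

    ``h`` must share the parity of ``nA`` and satisfy
    ``0 <= h <= min(nA, 2n - nA)``.
    """
    if (h - nA) % 2 != 0:
        raise ValueError(f"heterozygote count {h} has wrong parity for nA={nA}")
    hs, logp = het_log_probs(nA, n)
    if h < hs[0] or h > hs[-1]:
        raise ValueError(f"heterozygote count {h} unattainable for nA={nA}, n={n}")
    return float(logp[(h - hs[0]) // 2])


def _pvalue_from_logprobs(logp: np.ndarray, idx_obs: int) -> float:
    """Probability-ordering p-value given the full conditional distribution."""
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[idx_obs]
    p = float(probs[probs <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def hwe_exact_pvalue(counts: GenotypeCounts) -> float:
    """Exact two-sided HWP p-value conditional on observed allele counts."""
    n = counts.n
    if n == 0:
        raise ValueError("empty sample")
    nA = counts.n_minor  # orientation-symmetric; either allele works
    h, logp = het_log_probs(nA, n)
    if h.size == 1:
        return 1.0
    idx = int((counts.n_Aa - h[0]) // 2)
    return _pvalue_from_logprobs(logp, idx)


def hwe_exact_pvalue_triple(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Fast path of :func:`hwe_exact_pvalue` on raw integers (no dataclass)."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty sample")
    nA = 2 * n_aa + n_Aa
    h, logp = het_log_probs(nA, n)
    if h.size == 1:
        return 1.0
    return _pvalue_from_logprobs(logp, (n_Aa - int(h[0])) // 2)
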