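"""Constrained-likelihood Hardy-Weinberg tests for case-control data.

Retrospective likelihood: conditioning on stratum membership, an individual in
stratum ``s`` with genotype ``k`` contributes ``P(X = k | s) = p_{s|k} P_k /
P(s)``, where ``p_{s|k}`` is the probability of landing in stratum ``s`` given
genotype ``k`` and ``P_k`` the population genotype frequency.  Since the
stratum probabilities are fixed known constants (disease prevalence ``f`` for
two strata, the joint probabilities ``K_ij`` of secondary trait ``T = i`` and
disease ``D = j`` for four), the kernel that matters is

    log L = sum_k G_k log P_k + sum_{s,k} N_{sk} log p_{s|k}

with ``G_k`` the pooled genotype counts.  Writing genotype relative risks
``r_{sk} = p_{s|k} / p_{s|0}`` (``r_{s0} = 1``) gives

    two strata:  p_{1|k} = f r_k / (P_0 + r_1 P_1 + r_2 P_2),  p_{0|k} = 1 - p_{1|k}
    four strata: p_{ij|k} = K_ij r_ijk / (P_0 + r_ij1 P_1 + r_ij2 P_2)

In the four-stratum model the per-genotype normalisations
``sum_ij p_{ij|k} = 1`` impose two independent constraints (the third follows
because ``sum_k P_k p_{ij|k} = K_ij`` holds identically), leaving 8 free
parameters under the alternative and 7 under the HWP null
(``P_1 = 2p(1-p)``, ``P_2 = (1-p)^2``).  The constraints are enforced in
closed form by deriving the reference block's conditional probabilities
``s_k = 1 - sum_{(i,j) != (0,0)} K_ij r_ijk / D_ij`` from the other three
blocks' free risks.  Both tests refer ``2 (log L_alt - log L_null)`` to a
one-degree-of-freedom chi-square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .exact import GenotypeCounts

__all__ = [
    "BlockCounts",
    "PopulationParams",
    "LikelihoodParams",
    "TestResult",
    "neg_log_likelihood",
    "maximize_likelihood",
    "fit_lrt",
    "fit_elrt",
]

# block order convention used throughout: (T,D) = (0,0), (1,0), (0,1), (1,1)
BLOCK_ORDER: tuple[tuple[int, int], ...] = ((0, 0), (1, 0), (0, 1), (1, 1))

_LOG_RISK_BOUND = math.log(1e6)
_NM_OPTIONS = {"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000, "maxfev": 20000}
_NEG_STAT_TOL = -1e-4
_N_RESTARTS = 5


@dataclass(frozen=True)
class PopulationParams:
    """Joint probabilities K_ij = P(T=i, D=j) in the general population."""

    k00: float
    k10: float
    k01: float
    k11: float

    def __post_init__(self) -> None:
        ks = self.as_array()
        if not np.all((ks > 0) & (ks < 1)):
            raise ValueError(f"all K_ij must lie in (0,1), got {ks}")
        if abs(ks.sum() - 1.0) > 1e-9:
            raise ValueError(f"K_ij must sum to 1, got {ks.sum()!r}")

    @property
    def f_d(self) -> float:
        """Primary disease prevalence, K_01 + K_11."""
        return self.k01 + self.k11

    @property
    def f_t(self) -> float:
        """Secondary phenotype prevalence, K_10 + K_11."""
        return self.k10 + self.k11

    def as_array(self) -> np.ndarray:
        """K_ij in block order (0,0), (1,0), (0,1), (1,1)."""
        return np.array([self.k00, self.k10, self.k01, self.k11], dtype=float)

    @classmethod
    def from_conditionals(
        cls, f_d: float, t_given_case: float, t_given_control: float
    ) -> "PopulationParams":
        """Build K_ij from f_D and the trait rates within cases/controls."""
        return cls(
            k00=(1 - t_given_control) * (1 - f_d),
            k10=t_given_control * (1 - f_d),
            k01=(1 - t_given_case) * f_d,
            k11=t_given_case * f_d,
        )


@dataclass(frozen=True)
class BlockCounts:
    """Genotype counts in the four (T, D) strata of a matched study."""

    b00: GenotypeCounts
    b10: GenotypeCounts
    b01: GenotypeCounts
    b11: GenotypeCounts

    def block(self, t: int, d: int) -> GenotypeCounts:
        return {(0, 0): self.b00, (1, 0): self.b10, (0, 1): self.b01, (1, 1): self.b11}[
            (t, d)
        ]

    def as_array(self) -> np.ndarray:
        """(4, 3) counts in block order (0,0), (1,0), (0,1), (1,1)."""
        return np.stack([b.as_array() for b in (self.b00, self.b10, self.b01, self.b11)])

    @property
    def block_sizes(self) -> np.ndarray:
        """Block totals N_ij in block order."""
        return self.as_array().sum(axis=1)

    @property
    def n_total(self) -> int:
        return int(self.block_sizes.sum())

    def pooled(self) -> GenotypeCounts:
        return self.b00 + self.b10 + self.b01 + self.b11

    def by_disease(self) -> tuple[GenotypeCounts, GenotypeCounts]:
        """(controls, cases) collapsed over the secondary trait."""
        return self.b00 + self.b10, self.b01 + self.b11

    def by_trait(self) -> tuple[GenotypeCounts, GenotypeCounts]:
        """(trait absent, trait present) collapsed over disease status."""
        return self.b00 + self.b01, self.b10 + self.b11

    @classmethod
    def from_array(cls, arr: Sequence[Sequence[int]]) -> "BlockCounts":
        a = np.asarray(arr, dtype=np.int64)
        if a.shape != (4, 3):
            raise ValueError(f"expected (4, 3) counts, got shape {a.shape}")
        gs = [GenotypeCounts(*map(int, row)) for row in a]
        return cls(*gs)


@dataclass(frozen=True)
class LikelihoodParams:
    """Explicit parameter point for :func:`neg_log_likelihood`.

    ``P`` is the genotype-frequency simplex.  For the four-stratum model
    ``risks`` has shape (3, 2): relative risks (r_ij1, r_ij2) for the blocks
    (1,0), (0,1), (1,1); the (0,0) block is implied by the normalisation
    constraints.  For the two-stratum model ``risks`` is (r_1, r_2) for the
    stratum-present group.  Under the HWP null pass ``maf`` instead of ``P``.
    """

    risks: np.ndarray
    P: np.ndarray | None = None
    maf: float | None = None

    def genotype_freqs(self) -> np.ndarray:
        if self.P is not None:
            P = np.asarray(self.P, dtype=float)
            if P.shape != (3,) or abs(P.sum() - 1.0) > 1e-9 or np.any(P < 0):
                raise ValueError("P must be a length-3 probability simplex")
            return P
        if self.maf is None:
            raise ValueError("provide either P or maf")
        p = float(self.maf)
        if not 0.0 < p < 1.0:
            raise ValueError("maf must lie in (0,1)")
        return np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])


@dataclass(frozen=True)
class TestResult:
    """Outcome of one HWP test on one SNP."""

    method: str
    pvalue: float | None
    statistic: float | None = None
    converged: bool = True
    n_iter: int = 0
    loglik_null: float | None = None
    loglik_alt: float | None = None
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# likelihood kernels (plain-float accumulation: these run inside tight
# optimisation loops, so numpy per-call overhead is deliberately avoided)
# ---------------------------------------------------------------------------


def _nll_two_eval(P: Sequence[float], r1: float, r2: float, N: list[list[float]],
                  f: float) -> float:
    """N = [[absent counts], [present counts]] per genotype."""
    P0, P1, P2 = P
    denom = P0 + r1 * P1 + r2 * P2
    total = 0.0
    for k, (Pk, rk) in enumerate(zip((P0, P1, P2), (1.0, r1, r2))):
        n0, n1 = N[0][k], N[1][k]
        gk = n0 + n1
        p1k = f * rk / denom
        p0k = 1.0 - p1k
        if gk:
            if Pk <= 0.0:
                return math.inf
            total -= gk * math.log(Pk)
        if n1:
            if p1k <= 0.0:
                return math.inf
            total -= n1 * math.log(p1k)
        if n0:
            if p0k <= 0.0:
                return math.inf
            total -= n0 * math.log(p0k)
        if p1k < 0.0 or p0k < 0.0:  # infeasible point even with zero counts
            return math.inf
    return total


def _nll_four_eval(P: Sequence[float], risks: Sequence[float],
                   N: list[list[float]], K: Sequence[float]) -> float:
    """risks = (r10_1, r10_2, r01_1, r01_2, r11_1, r11_2) in block order."""
    P0, P1, P2 = P
    G = [N[0][k] + N[1][k] + N[2][k] + N[3][k] for k in range(3)]
    total = 0.0
    for k, Pk in enumerate((P0, P1, P2)):
        if G[k]:
            if Pk <= 0.0:
                return math.inf
            total -= G[k] * math.log(Pk)
    s0 = s1 = s2 = 1.0
    for b in range(1, 4):
        r1 = risks[2 * (b - 1)]
        r2 = risks[2 * (b - 1) + 1]
        denom = P0 + r1 * P1 + r2 * P2
        if denom <= 0.0:
            return math.inf
        q0 = K[b] / denom
        q1 = q0 * r1
        q2 = q0 * r2
        s0 -= q0
        s1 -= q1
        s2 -= q2
        for k, q in enumerate((q0, q1, q2)):
            if N[b][k]:
                if q <= 0.0:
                    return math.inf
                total -= N[b][k] * math.log(q)
    # reference block (T=0, D=0): conditional probabilities implied by the
    # per-genotype normalisation constraints
    for k, sk in enumerate((s0, s1, s2)):
        if sk < 0.0:
            return math.inf
        if N[0][k]:
            if sk <= 0.0:
                return math.inf
            total -= N[0][k] * math.log(sk)
    return total


def neg_log_likelihood(
    params: LikelihoodParams,
    blocks,
    pop,
    *,
    model: str = "four_stratum",
    null_constrained: bool = False,
) -> float:
    """Negative log-likelihood at an explicit parameter point.

    ``blocks`` is a :class:`BlockCounts` (four-stratum) or a
    ``(absent, present)`` pair of :class:`GenotypeCounts` (two-stratum);
    ``pop`` is a :class:`PopulationParams` or, for the two-stratum model, the
    prevalence of the stratifying phenotype.  When ``null_constrained`` the
    genotype frequencies must come from ``params.maf``.
    """
    if null_constrained and params.maf is None:
        raise ValueError("null-constrained evaluation requires params.maf")
    P = params.genotype_freqs()
    risks = np.asarray(params.risks, dtype=float)
    if np.any(risks < 0):
        raise ValueError("relative risks must be non-negative")
    if model == "two_stratum":
        absent, present = blocks
        N = [list(map(float, absent.as_array())), list(map(float, present.as_array()))]
        return _nll_two_eval(tuple(P), float(risks[0]), float(risks[1]), N, float(pop))
    if model == "four_stratum":
        N = [list(map(float, row)) for row in blocks.as_array()]
        return _nll_four_eval(tuple(P), list(risks.ravel()), N, pop.as_array())
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# gradient kernels: negative log-likelihood and its exact gradient in the
# unconstrained coordinates, vectorised over the 4x3 (or 2x3) count table.
# Used by the quasi-Newton primary fit; the simplex path below is the fallback.
# ---------------------------------------------------------------------------


def _xlogy_sum(N: np.ndarray, p: np.ndarray) -> float:
    """sum N*log(p) with the 0*log(0)=0 convention; +inf count on p<=0 -> -inf."""
    mask = N > 0
    if np.any(p[mask] <= 0.0):
        return -math.inf
    out = np.zeros_like(p)
    out[mask] = N[mask] * np.log(p[mask])
    return float(out.sum())


def _four_value_grad(
    theta: np.ndarray, N: np.ndarray, K: np.ndarray, null: bool
) -> tuple[float, np.ndarray]:
    """(NLL, grad) for the four-stratum model; N is (4,3), K is (4,)."""
    if null:
        v = theta[0]
        p = 1.0 / (1.0 + math.exp(-v))
        P = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
        lrisks = theta[1:7]
    else:
        P = np.array(_simplex_from_logits(theta[0], theta[1]))
        lrisks = theta[2:8]
    R = np.ones((3, 3))  # blocks (1,0),(0,1),(1,1) x genotypes; r_b0 = 1
    R[:, 1:] = np.exp(lrisks.reshape(3, 2))
    D = R @ P  # (3,)
    q = (K[1:, None] / D[:, None]) * R  # p_{ij|k} for the three free blocks
    s = 1.0 - q.sum(axis=0)  # reference-block probabilities
    bad = np.inf, np.zeros_like(theta)
    if np.any(s < 0.0):
        return bad
    G = N.sum(axis=0).astype(float)
    ll = _xlogy_sum(G, P) + _xlogy_sum(N[1:].astype(float), q) + _xlogy_sum(
        N[0].astype(float), s
    )
    if not np.isfinite(ll):
        return bad
    # gradient in (P, log r) coordinates
    A = N[1:].sum(axis=1).astype(float)  # per-block totals
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(N[0] > 0, N[0] / s, 0.0)
    U = q @ W  # (3,) sum_k W_k q_bk
    V = R * P[None, :] / D[:, None]  # (3,3): r_bl P_l / D_b
    # d(-ll)/d log r_bm, m = 1,2
    grad_lr = -(N[1:, 1:] - (A - U)[:, None] * V[:, 1:] - W[None, 1:] * q[:, 1:])
    gP = -(
        np.where(G > 0, G / P, 0.0)
        - ((A - U)[:, None] * R / D[:, None]).sum(axis=0)
    )
    if null:
        dPdp = np.array([2 * p, 2 - 4 * p, -2 * (1 - p)])
        gv = float(gP @ dPdp) * p * (1 - p)
        grad = np.concatenate([[gv], grad_lr.ravel()])
    else:
        # multinomial-logit chain rule: dP_l/du_m = P_l (delta_lm - P_m)
        gu = np.array(
            [
                gP[1] * P[1] * (1 - P[1]) - (gP[0] * P[0] + gP[2] * P[2]) * P[1],
                gP[2] * P[2] * (1 - P[2]) - (gP[0] * P[0] + gP[1] * P[1]) * P[2],
            ]
        )
        grad = np.concatenate([gu, grad_lr.ravel()])
    return -ll, grad


def _two_value_grad(
    theta: np.ndarray, N: np.ndarray, f: float, null: bool
) -> tuple[float, np.ndarray]:
    """(NLL, grad) for the two-stratum model; N is (2,3) [absent; present]."""
    if null:
        v = theta[0]
        p = 1.0 / (1.0 + math.exp(-v))
        P = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
        lr = theta[1:3]
    else:
        P = np.array(_simplex_from_logits(theta[0], theta[1]))
        lr = theta[2:4]
    r = np.ones(3)
    r[1:] = np.exp(lr)
    D = float(r @ P)
    p1 = f * r / D
    p0 = 1.0 - p1
    bad = np.inf, np.zeros_like(theta)
    if np.any(p0 < 0.0):
        return bad
    G = N.sum(axis=0).astype(float)
    n0, n1 = N[0].astype(float), N[1].astype(float)
    ll = _xlogy_sum(G, P) + _xlogy_sum(n1, p1) + _xlogy_sum(n0, p0)
    if not np.isfinite(ll):
        return bad
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(n1 > 0, n1, 0.0) - np.where(n0 > 0, n0 * p1 / p0, 0.0)
    V = r * P / D
    # d(-ll)/d log r_m = -(c_m - (sum_k c_k) V_m)
    grad_lr = -(c[1:] - c.sum() * V[1:])
    gP = -(np.where(G > 0, G / P, 0.0) - c.sum() * r / D)
    if null:
        dPdp = np.array([2 * p, 2 - 4 * p, -2 * (1 - p)])
        grad = np.concatenate([[float(gP @ dPdp) * p * (1 - p)], grad_lr])
    else:
        gu = np.array(
            [
                gP[1] * P[1] * (1 - P[1]) - (gP[0] * P[0] + gP[2] * P[2]) * P[1],
                gP[2] * P[2] * (1 - P[2]) - (gP[0] * P[0] + gP[1] * P[1]) * P[2],
            ]
        )
        grad = np.concatenate([gu, grad_lr])
    return -ll, grad


# ---------------------------------------------------------------------------
# unconstrained reparametrisation used by the optimiser
# ---------------------------------------------------------------------------


def _simplex_from_logits(u1: float, u2: float) -> tuple[float, float, float]:
    e1 = math.exp(min(u1, 700.0))
    e2 = math.exp(min(u2, 700.0))
    z = 1.0 + e1 + e2
    return 1.0 / z, e1 / z, e2 / z


def _hwp_from_logit(v: float) -> tuple[float, float, float]:
    p = 1.0 / (1.0 + math.exp(-v))
    return p * p, 2.0 * p * (1.0 - p), (1.0 - p) * (1.0 - p)


def _make_objective_four(N: list[list[float]], K: np.ndarray, null: bool) -> Callable:
    Kl = list(map(float, K))

    if null:

        def nll(theta: np.ndarray) -> float:
            P = _hwp_from_logit(theta[0])
            risks = [math.exp(t) for t in theta[1:7]]
            return _nll_four_eval(P, risks, N, Kl)

    else:

        def nll(theta: np.ndarray) -> float:
            P = _simplex_from_logits(theta[0], theta[1])
            risks = [math.exp(t) for t in theta[2:8]]
            return _nll_four_eval(P, risks, N, Kl)

    return nll


def _make_objective_two(N: list[list[float]], f: float, null: bool) -> Callable:
    if null:

        def nll(theta: np.ndarray) -> float:
            P = _hwp_from_logit(theta[0])
            return _nll_two_eval(P, math.exp(theta[1]), math.exp(theta[2]), N, f)

    else:

        def nll(theta: np.ndarray) -> float:
            P = _simplex_from_logits(theta[0], theta[1])
            return _nll_two_eval(P, math.exp(theta[2]), math.exp(theta[3]), N, f)

    return nll


@dataclass
class OptimumResult:
    theta: np.ndarray
    fun: float
    converged: bool
    n_iter: int


def maximize_likelihood(
    objective: Callable[[np.ndarray], float],
    start: np.ndarray,
    bounds: Sequence[tuple[float, float]] | None = None,
) -> OptimumResult:
    """Minimise a negative log-likelihood with the Nelder-Mead simplex.

    The parameter space is unconstrained by construction (logit / log
    coordinates), so box bounds only serve as numerical guard rails.
    Returns the best point found with a convergence flag; callers restart
    from perturbed points when the flag is down.
    """
    res = optimize.minimize(
        objective,
        np.asarray(start, dtype=float),
        method="Nelder-Mead",
        bounds=bounds,
        options=_NM_OPTIONS,
    )
    return OptimumResult(
        theta=res.x, fun=float(res.fun), converged=bool(res.success), n_iter=int(res.nit)
    )


def _multi_fit(
    objective: Callable,
    start: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    rng: np.random.Generator,
    force_restarts: bool = False,
) -> OptimumResult:
    best = maximize_likelihood(objective, start, bounds)
    if best.converged and not force_restarts:
        return best
    for _ in range(_N_RESTARTS):
        theta0 = np.asarray(start, dtype=float) + rng.normal(scale=0.3, size=len(start))
        cand = maximize_likelihood(objective, theta0, bounds)
        if cand.fun < best.fun:
            best = cand
    return best


def _fit(
    value_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    nm_objective: Callable[[np.ndarray], float],
    start: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    rng: np.random.Generator,
) -> OptimumResult:
    """Quasi-Newton fit with exact gradients; simplex multi-start fallback.

    L-BFGS-B on the analytic (value, gradient) pair is the fast primary
    route; whenever it reports failure the derivative-free simplex path
    (:func:`maximize_likelihood` with perturbed restarts) takes over and the
    better optimum wins.
    """
    # no box bounds here: the logit/log coordinates are unconstrained and
    # infeasible points already evaluate to +inf (bounds also trip a scipy
    # L-BFGS-B stall at interior starts); the simplex fallback keeps them
    res = optimize.minimize(
        value_grad,
        np.asarray(start, dtype=float),
        jac=True,
        method="L-BFGS-B",
        options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 2000},
    )
    best = OptimumResult(
        theta=res.x, fun=float(res.fun), converged=bool(res.success),
        n_iter=int(res.nit),
    )
    if not best.converged or not np.isfinite(best.fun):
        nm = _multi_fit(nm_objective, start, bounds, rng)
        if nm.fun < best.fun or not np.isfinite(best.fun):
            nm.converged = nm.converged or best.converged
            best = nm
        else:
            best.converged = best.converged or nm.converged
    return best


def _pooled_allele_freq(G: np.ndarray) -> float:
    """Frequency of the allele coded A from pooled genotype counts."""
    n = G.sum()
    p = (2 * G[0] + G[1]) / (2 * n)
    return float(np.clip(p, 1e-3, 1 - 1e-3))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _chi2_result(
    method: str,
    nll_null: OptimumResult,
    nll_alt: OptimumResult,
    flags: tuple[str, ...] = (),
) -> TestResult:
    stat = 2.0 * (nll_null.fun - nll_alt.fun)
    clipped = max(stat, 0.0)
    pval = float(chi2.sf(clipped, df=1))
    converged = nll_null.converged and nll_alt.converged and stat > _NEG_STAT_TOL
    return TestResult(
        method=method,
        pvalue=pval if converged else None,
        statistic=clipped,
        converged=converged,
        n_iter=nll_null.n_iter + nll_alt.n_iter,
        loglik_null=-nll_null.fun,
        loglik_alt=-nll_alt.fun,
        flags=flags + (() if stat > _NEG_STAT_TOL else ("negative_statistic",)),
    )


def fit_lrt(
    absent: GenotypeCounts,
    present: GenotypeCounts,
    prevalence: float,
    *,
    method: str = "lrt",
    rng: np.random.Generator | None = None,
) -> TestResult:
    """Two-stratum prevalence-constrained LRT of HWP.

    ``absent`` / ``present`` are the genotype counts of the individuals
    without / with the stratifying phenotype (disease or secondary trait);
    ``prevalence`` is that phenotype's general-population prevalence.  Under
    the alternative 4 parameters are free (two genotype-frequency dof and the
    two relative risks); the HWP null ties the genotype frequencies to a
    single allele frequency, leaving 3.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0,1)")
    if absent.n == 0 or present.n == 0:
        raise ValueError("both strata must contain individuals")
    rng = rng if rng is not None else np.random.default_rng(12345)
    G = absent.as_array() + present.as_array()
    if int((G > 0).sum()) < 2:
        return TestResult(method=method, pvalue=1.0, statistic=0.0,
                          flags=("degenerate",))
    N = [list(map(float, absent.as_array())), list(map(float, present.as_array()))]
    Narr = np.stack([absent.as_array(), present.as_array()]).astype(float)
    phat = _pooled_allele_freq(G)
    rb = (-_LOG_RISK_BOUND, _LOG_RISK_BOUND)
    ub = (-30.0, 30.0)

    null_obj = _make_objective_two(N, prevalence, null=True)
    null_vg = lambda th: _two_value_grad(th, Narr, prevalence, null=True)
    theta0_null = np.array([_logit(phat), 0.0, 0.0])
    opt_null = _fit(null_vg, null_obj, theta0_null, [ub, rb, rb], rng)

    alt_obj = _make_objective_two(N, prevalence, null=False)
    alt_vg = lambda th: _two_value_grad(th, Narr, prevalence, null=False)
    p_null = 1.0 / (1.0 + math.exp(-opt_null.theta[0]))
    P1 = 2 * p_null * (1 - p_null)
    P2 = (1 - p_null) ** 2
    P0 = p_null**2
    theta0_alt = np.array(
        [math.log(P1 / P0), math.log(P2 / P0), opt_null.theta[1], opt_null.theta[2]]
    )
    opt_alt = _fit(alt_vg, alt_obj, theta0_alt, [ub, ub, rb, rb], rng)

    stat = 2.0 * (opt_null.fun - opt_alt.fun)
    if stat < _NEG_STAT_TOL:
        opt_alt = _multi_fit(alt_obj, theta0_alt, [ub, ub, rb, rb], rng,
                             force_restarts=True)
    return _chi2_result(method, opt_null, opt_alt)


def fit_elrt(
    blocks: BlockCounts,
    pop: PopulationParams,
    *,
    rng: np.random.Generator | None = None,
) -> TestResult:
    """Four-stratum extended LRT of HWP for a frequency-matched study.

    Maximises the block-multinomial likelihood over 8 free parameters under
    the alternative and 7 under the HWP null; the difference is referred to a
    one-degree-of-freedom chi-square.
    """
    rng = rng if rng is not None else np.random.default_rng(12345)
    arr = blocks.as_array()
    sizes = arr.sum(axis=1)
    K = pop.as_array()
    if np.any((sizes > 0) & (K <= 0)):
        raise ValueError("population parameters assign zero probability to an "
                         "occupied block")
    G = arr.sum(axis=0)
    if int((G > 0).sum()) < 2:
        return TestResult(method="elrt", pvalue=1.0, statistic=0.0,
                          flags=("degenerate",))
    N = [list(map(float, row)) for row in arr]
    Narr = arr.astype(float)
    phat = _pooled_allele_freq(G)
    rb = (-_LOG_RISK_BOUND, _LOG_RISK_BOUND)
    ub = (-30.0, 30.0)

    null_obj = _make_objective_four(N, K, null=True)
    null_vg = lambda th: _four_value_grad(th, Narr, K, null=True)
    theta0_null = np.concatenate([[_logit(phat)], np.zeros(6)])
    opt_null = _fit(null_vg, null_obj, theta0_null, [ub] + [rb] * 6, rng)

    alt_obj = _make_objective_four(N, K, null=False)
    alt_vg = lambda th: _four_value_grad(th, Narr, K, null=False)
    p_null = 1.0 / (1.0 + math.exp(-opt_null.theta[0]))
    P0, P1, P2 = p_null**2, 2 * p_null * (1 - p_null), (1 - p_null) ** 2
    theta0_alt = np.concatenate(
        [[math.log(P1 / P0), math.log(P2 / P0)], opt_null.theta[1:7]]
    )
    opt_alt = _fit(alt_vg, alt_obj, theta0_alt, [ub, ub] + [rb] * 6, rng)

    stat = 2.0 * (opt_null.fun - opt_alt.fun)
    if stat < _NEG_STAT_TOL:
        opt_alt = _multi_fit(alt_obj, theta0_alt, [ub, ub] + [rb] * 6, rng,
                             force_restarts=True)
    return _chi2_result("elrt", opt_null, opt_alt)
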