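"""Synthetic frequency-matched case-control studies with a secondary trait.

The generative process is a pair of logistic models on four independent SNPs
(dominant coding) and three environmental covariates: the first model produces
the secondary phenotype T, the second produces the primary disease D given T.
Intercepts are calibrated so that the population prevalences of T and D hit
requested targets; study samples are then drawn case-control style with
controls frequency-matched to the cases on T.

Default coefficients give four association patterns at log-odds 0.4055
(OR 1.5): SNP 1 affects both T and D, SNP 2 only D, SNP 3 only T, and SNP 4
neither, with T itself a strong disease risk factor (log-odds 1.0983, OR 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .likelihood import BlockCounts, PopulationParams

__all__ = [
    "SimulationScenario",
    "simulate_population",
    "calibrate_intercepts",
    "build_population",
    "estimate_joint_probs",
    "sample_frequency_matched",
    "sample_unmatched",
    "perturb_population_params",
    "phenotype_genotype_cells",
    "draw_matched_blocks",
    "draw_unmatched_blocks",
]

_INTERCEPT_BOUNDS = (-20.0, 20.0)

COHORT_COLUMNS = ["snp1", "snp2", "snp3", "snp4", "sex", "ethn", "age", "T", "D"]


@dataclass(frozen=True)
class SimulationScenario:
    """All knobs of one simulated study condition.

    ``maf`` are per-SNP minor-allele frequencies (genotypes drawn from HWP);
    ``alpha_*`` are log-odds in the secondary-trait model, ``beta_*`` in the
    disease model (which additionally includes the trait term).  Age is a
    3-band covariate (frequencies ``age_freqs``) entering both models
    additively, one log-odds step per band.
    """

    maf: tuple[float, ...] = (0.4, 0.4, 0.4, 0.4)
    alpha_snp: tuple[float, ...] = (0.4055, 0.0, 0.4055, 0.0)
    beta_snp: tuple[float, ...] = (0.4055, 0.4055, 0.0, 0.0)
    alpha_sex: float = 0.6931
    alpha_ethn: float = 0.4055
    alpha_age: float = 0.0
    beta_sex: float = 0.0
    beta_ethn: float = 0.4055
    beta_age: float = 0.4055
    beta_trait: float = 1.0983
    sex_prev: float = 0.5
    ethn_prev: float = 0.75
    age_freqs: tuple[float, ...] = (0.36, 0.39, 0.25)
    f_t: float = 0.3
    f_d: float = 0.3
    n_cases: int = 2000
    n_controls: int = 2000
    c: float = 0.02
    pool_size: int = 1_000_000
    alpha0: float | None = None
    beta0: float | None = None

    def __post_init__(self) -> None:
        if len(self.maf) != len(self.alpha_snp) or len(self.maf) != len(self.beta_snp):
            raise ValueError("maf, alpha_snp and beta_snp must align")
        if not all(0 < m < 1 for m in self.maf):
            raise ValueError("MAFs must lie in (0,1)")
        for name in ("f_t", "f_d", "sex_prev", "ethn_prev"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0,1)")
        if self.c < 0:
            raise ValueError("matching tolerance c must be non-negative")
        if abs(sum(self.age_freqs) - 1.0) > 1e-9:
            raise ValueError("age band frequencies must sum to 1")


def _draw_covariates(
    scn: SimulationScenario, size: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for i, m in enumerate(scn.maf):
        out[f"snp{i + 1}"] = rng.binomial(2, m, size=size).astype(np.int8)
    out["sex"] = (rng.random(size) < scn.sex_prev).astype(np.int8)
    out["ethn"] = (rng.random(size) < scn.ethn_prev).astype(np.int8)
    out["age"] = rng.choice(
        np.arange(len(scn.age_freqs), dtype=np.int8), size=size, p=scn.age_freqs
    )
    return out


def _linear_predictors(
    scn: SimulationScenario, cov: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """(eta_T, eta_D-without-trait-term), both excluding intercepts."""
    eta_t = np.zeros(cov["sex"].size)
    eta_d = np.zeros(cov["sex"].size)
    for i, (a, b) in enumerate(zip(scn.alpha_snp, scn.beta_snp)):
        dom = (cov[f"snp{i + 1}"] >= 1).astype(float)  # dominant genetic model
        eta_t += a * dom
        eta_d += b * dom
    eta_t += scn.alpha_sex * cov["sex"] + scn.alpha_ethn * cov["ethn"]
    eta_t += scn.alpha_age * cov["age"].astype(float)
    eta_d += scn.beta_sex * cov["sex"] + scn.beta_ethn * cov["ethn"]
    eta_d += scn.beta_age * cov["age"].astype(float)
    return eta_t, eta_d


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    lo, hi = _INTERCEPT_BOUNDS

    def gap(c: float) -> float:
        return float(expit(c + eta).mean() - target)

    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"target prevalence {target} unreachable within intercept bounds"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10))


def calibrate_intercepts(
    scn: SimulationScenario,
    f_t: float | None = None,
    f_d: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Intercepts (alpha0, beta0) hitting target prevalences of T and D.

    Each intercept is solved by root finding on the Monte-Carlo expectation
    over a pool of ``scn.pool_size`` individuals drawn from ``rng`` (the trait
    intercept first; the trait is then realised before the disease intercept
    is solved, since D depends on T).
    """
    f_t = scn.f_t if f_t is None else f_t
    f_d = scn.f_d if f_d is None else f_d
    rng = rng if rng is not None else np.random.default_rng(0)
    cov = _draw_covariates(scn, scn.pool_size, rng)
    eta_t, eta_d = _linear_predictors(scn, cov)
    alpha0 = _solve_intercept(eta_t, f_t)
    t = rng.random(scn.pool_size) < expit(alpha0 + eta_t)
    beta0 = _solve_intercept(eta_d + scn.beta_trait * t, f_d)
    return alpha0, beta0


def simulate_population(
    scn: SimulationScenario, size: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Cohort of ``size`` individuals with genotypes, covariates, T and D.

    Requires ``scn.alpha0`` and ``scn.beta0`` (see
    :func:`calibrate_intercepts` / :func:`build_population`).
    """
    if size < 1:
        raise ValueError("population size must be at least 1")
    if scn.alpha0 is None or scn.beta0 is None:
        raise ValueError("scenario intercepts not set; calibrate first")
    cov = _draw_covariates(scn, size, rng)
    eta_t, eta_d = _linear_predictors(scn, cov)
    t = (rng.random(size) < expit(scn.alpha0 + eta_t)).astype(np.int8)
    d = (rng.random(size) < expit(scn.beta0 + eta_d + scn.beta_trait * t)).astype(
        np.int8
    )
    cov["T"] = t
    cov["D"] = d
    return pd.DataFrame(cov, columns=COHORT_COLUMNS)


def build_population(
    scn: SimulationScenario, rng: np.random.Generator
) -> tuple[pd.DataFrame, PopulationParams, SimulationScenario]:
    """Calibrate intercepts and simulate the population pool in one pass.

    The intercepts are solved on the very pool that is returned, so the
    realised prevalences track the targets up to Bernoulli noise.  Returns
    the pool, the joint (T, D) probabilities estimated from it, and the
    scenario with intercepts filled in.
    """
    cov = _draw_covariates(scn, scn.pool_size, rng)
    eta_t, eta_d = _linear_predictors(scn, cov)
    alpha0 = _solve_intercept(eta_t, scn.f_t)
    t = (rng.random(scn.pool_size) < expit(alpha0 + eta_t)).astype(np.int8)
    beta0 = _solve_intercept(eta_d + scn.beta_trait * t, scn.f_d)
    d = (rng.random(scn.pool_size) < expit(beta0 + eta_d + scn.beta_trait * t)).astype(
        np.int8
    )
    cov["T"] = t
    cov["D"] = d
    pool = pd.DataFrame(cov, columns=COHORT_COLUMNS)
    calibrated = replace(scn, alpha0=alpha0, beta0=beta0)
    return pool, estimate_joint_probs(pool), calibrated


def estimate_joint_probs(pop: pd.DataFrame) -> PopulationParams:
    """K_ij estimated as (T, D) cell fractions of a simulated population."""
    n = len(pop)
    t = pop["T"].to_numpy()
    d = pop["D"].to_numpy()
    cells = {}
    for i in (0, 1):
        for j in (0, 1):
            c = int(np.sum((t == i) & (d == j)))
            if c == 0:
                raise ValueError(f"empty (T={i}, D={j}) cell in population")
            cells[(i, j)] = c / n
    return PopulationParams(
        k00=cells[(0, 0)], k10=cells[(1, 0)], k01=cells[(0, 1)], k11=cells[(1, 1)]
    )


def sample_frequency_matched(
    pop: pd.DataFrame,
    n_cases: int,
    n_controls: int,
    c: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw a case-control study frequency-matched on the secondary trait.

    Cases are drawn uniformly from the pool's D=1 individuals; their trait
    fraction q1 sets the control target q0 ~ Uniform(q1-c, q1+c) (truncated
    to [0,1]), and ``round(q0 n_controls)`` controls come from the T=1
    stratum, the rest from T=0.
    """
    d = pop["D"].to_numpy()
    t = pop["T"].to_numpy()
    case_idx = np.flatnonzero(d == 1)
    if case_idx.size < n_cases:
        raise ValueError(f"pool has {case_idx.size} cases, need {n_cases}")
    sel_cases = rng.choice(case_idx, size=n_cases, replace=False)
    q1 = float(t[sel_cases].mean())
    q0 = float(np.clip(rng.uniform(q1 - c, q1 + c), 0.0, 1.0))
    n_t1 = int(round(q0 * n_controls))
    n_t0 = n_controls - n_t1
    sel_controls = []
    for ti, need in ((1, n_t1), (0, n_t0)):
        stratum = np.flatnonzero((d == 0) & (t == ti))
        if stratum.size < need:
            raise ValueError(
                f"control stratum T={ti} has {stratum.size} individuals, need {need}"
            )
        if need:
            sel_controls.append(rng.choice(stratum, size=need, replace=False))
    idx = np.concatenate([sel_cases] + sel_controls)
    return pop.iloc[idx].reset_index(drop=True)


def sample_unmatched(
    pop: pd.DataFrame, n_cases: int, n_controls: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw cases and controls uniformly within D strata, ignoring the trait."""
    d = pop["D"].to_numpy()
    picks = []
    for dj, need in ((1, n_cases), (0, n_controls)):
        stratum = np.flatnonzero(d == dj)
        if stratum.size < need:
            raise ValueError(f"D={dj} stratum has {stratum.size} individuals, need {need}")
        picks.append(rng.choice(stratum, size=need, replace=False))
    return pop.iloc[np.concatenate(picks)].reset_index(drop=True)


def perturb_population_params(
    pop: PopulationParams, fraction: float, rng: np.random.Generator
) -> PopulationParams:
    """Misspecify the population parameters by up to +/- ``fraction``.

    The disease prevalence and the two conditional trait probabilities
    Pr(T=1 | D=j) are each drawn uniformly within +/- ``fraction`` of truth
    (truncated into (0,1) with a warning), then a consistent K_ij table is
    reconstituted.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    if fraction == 0.0:
        return pop

    def jitter(v: float) -> float:
        lo, hi = v * (1 - fraction), v * (1 + fraction)
        x = float(rng.uniform(lo, hi))
        if x <= 0.0 or x >= 1.0:
            warnings.warn("perturbed probability truncated into (0,1)", stacklevel=2)
            x = float(np.clip(x, 1e-6, 1 - 1e-6))
        return x

    f_d = jitter(pop.f_d)
    t_case = jitter(pop.k11 / (pop.k01 + pop.k11))
    t_control = jitter(pop.k10 / (pop.k00 + pop.k10))
    return PopulationParams.from_conditionals(f_d, t_case, t_control)


# ---------------------------------------------------------------------------
# count-level replicate sampling (used by the study runner): sampling rows
# uniformly without replacement induces multivariate hypergeometric draws on
# the (T, genotype) contingency cells, so replicates need only the cell counts
# ---------------------------------------------------------------------------


def phenotype_genotype_cells(
    pop: pd.DataFrame, snp: str
) -> tuple[np.ndarray, np.ndarray]:
    """(case_cells, control_cells), each (T x genotype) = (2, 3) counts."""
    g = pop[snp].to_numpy()
    t = pop["T"].to_numpy()
    d = pop["D"].to_numpy()
    out = []
    for dj in (1, 0):
        cells = np.zeros((2, 3), dtype=np.int64)
        for ti in (0, 1):
            mask = (d == dj) & (t == ti)
            cells[ti] = np.bincount(g[mask], minlength=3)
        out.append(cells)
    return out[0], out[1]


def draw_matched_blocks(
    case_cells: np.ndarray,
    control_cells: np.ndarray,
    n_cases: int,
    n_controls: int,
    c: float,
    rng: np.random.Generator,
) -> BlockCounts:
    """One frequency-matched replicate as four-stratum genotype counts.

    Distributionally identical to :func:`sample_frequency_matched` followed by
    tabulation, but O(1) in the pool size.
    """
    case_draw = rng.multivariate_hypergeometric(case_cells.ravel(), n_cases).reshape(
        2, 3
    )
    q1 = case_draw[1].sum() / n_cases
    q0 = float(np.clip(rng.uniform(q1 - c, q1 + c), 0.0, 1.0))
    n_t1 = int(round(q0 * n_controls))
    n_t0 = n_controls - n_t1
    for ti, need in ((1, n_t1), (0, n_t0)):
        if control_cells[ti].sum() < need:
            raise ValueError(
                f"control stratum T={ti} has {control_cells[ti].sum()} "
                f"individuals, need {need}"
            )
    ctrl_t1 = rng.multivariate_hypergeometric(control_cells[1], n_t1)
    ctrl_t0 = rng.multivariate_hypergeometric(control_cells[0], n_t0)
    return BlockCounts.from_array(
        np.stack([ctrl_t0, ctrl_t1, case_draw[0], case_draw[1]])
    )


def draw_unmatched_blocks(
    case_cells: np.ndarray,
    control_cells: np.ndarray,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
) -> BlockCounts:
    """One unmatched replicate: controls drawn ignoring the trait."""
    case_draw = rng.multivariate_hypergeometric(case_cells.ravel(), n_cases).reshape(
        2, 3
    )
    ctrl_draw = rng.multivariate_hypergeometric(
        control_cells.ravel(), n_controls
    ).reshape(2, 3)
    return BlockCounts.from_array(
        np.stack([ctrl_draw[0], ctrl_draw[1], case_draw[0], case_draw[1]])
    )
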