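"""Monte-Carlo driver: type-I-error studies and batch QC threshold sweeps.

For each scenario the runner calibrates the generative model once, builds a
population pool, estimates the joint (T, D) probabilities from it, then draws
study replicates and applies every requested HWP test to each.  Results are
rejection proportions with binomial Monte-Carlo standard errors, in a flat
table whose schema is shared across methods.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exact import GenotypeCounts, hwe_exact_pvalue
from .likelihood import BlockCounts, PopulationParams, TestResult, fit_elrt, fit_lrt
from .mixture import MixtureConfig, emhwp_pvalue, mhwp_pvalue
from .simulate import (
    SimulationScenario,
    build_population,
    draw_matched_blocks,
    draw_unmatched_blocks,
    phenotype_genotype_cells,
)

__all__ = [
    "StudyScenario",
    "StudyGrid",
    "RejectionTable",
    "apply_method",
    "replicate_pvalues",
    "run_type_i_study",
    "run_threshold_sweep",
]

logger = logging.getLogger(__name__)

METHODS = ("elrt", "emhwp", "lrt_d", "lrt_t", "mhwp_d", "mhwp_t", "exact_controls")

# replicate failure fraction above which a scenario is aborted rather than
# silently dropped from the denominator
_MAX_FAILURE_FRACTION = 1e-3


@dataclass(frozen=True)
class StudyScenario:
    """One cell of the simulation grid: a generative model plus a tested SNP."""

    label: str
    scenario: SimulationScenario
    snp: str = "snp1"
    design: str = "matched"  # or "unmatched"


@dataclass(frozen=True)
class StudyGrid:
    scenarios: tuple[StudyScenario, ...]
    methods: tuple[str, ...] = ("elrt", "emhwp", "lrt_d", "lrt_t", "mhwp_d", "mhwp_t")
    alphas: tuple[float, ...] = (0.05, 0.0001)
    replicates: int = 5000
    mixture_replicates: int | None = 2000  # mixture tests cost ~M exact tests each
    mixture: MixtureConfig = field(default_factory=MixtureConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 100:
            raise ValueError("need at least 100 replicates")
        for a in self.alphas:
            if not 0 < a < 1:
                raise ValueError("alpha levels must lie in (0,1)")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


RejectionTable = pd.DataFrame  # scenario, method, alpha, rejection, se, replicates


def apply_method(
    method: str,
    blocks: BlockCounts,
    pop: PopulationParams,
    mixture: MixtureConfig,
    rng: np.random.Generator,
) -> TestResult:
    """Run one HWP test on a four-stratum replicate."""
    if method == "elrt":
        return fit_elrt(blocks, pop, rng=rng)
    if method == "lrt_d":
        controls, cases = blocks.by_disease()
        return fit_lrt(controls, cases, pop.f_d, method="lrt_d", rng=rng)
    if method == "lrt_t":
        t0, t1 = blocks.by_trait()
        return fit_lrt(t0, t1, pop.f_t, method="lrt_t", rng=rng)
    if method == "emhwp":
        return emhwp_pvalue(blocks, pop, mixture, rng)
    if method == "mhwp_d":
        controls, cases = blocks.by_disease()
        return mhwp_pvalue(controls, cases, pop.f_d, mixture, rng)
    if method == "mhwp_t":
        t0, t1 = blocks.by_trait()
        return mhwp_pvalue(t0, t1, pop.f_t, mixture, rng)
    if method == "exact_controls":
        controls, _ = blocks.by_disease()
        return TestResult(method=method, pvalue=hwe_exact_pvalue(controls))
    raise ValueError(f"unknown method {method!r}")


def replicate_pvalues(
    study: StudyScenario,
    methods: Sequence[str],
    replicates: int,
    seed: int | np.random.SeedSequence,
    mixture: MixtureConfig | None = None,
    mixture_replicates: int | None = None,
) -> tuple[dict[str, np.ndarray], PopulationParams]:
    """Per-replicate p-values for each method under one scenario.

    A master seed sequence spawns independent child streams for the
    population pool and for every replicate, so any replicate is reproducible
    in isolation.  Mixture methods may run on a prefix of the replicates
    (``mixture_replicates``); their arrays are NaN beyond that point.
    """
    mixture = mixture or MixtureConfig()
    mixture_replicates = (
        replicates if mixture_replicates is None else min(mixture_replicates, replicates)
    )
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    pool_seed, rep_root = ss.spawn(2)
    scn = study.scenario
    pool, pop, _ = build_population(scn, np.random.default_rng(pool_seed))
    case_cells, control_cells = phenotype_genotype_cells(pool, study.snp)
    del pool

    pvals = {m: np.full(replicates, np.nan) for m in methods}
    failures = {m: 0 for m in methods}
    mixture_methods = {"emhwp", "mhwp_d", "mhwp_t"}
    rep_seeds = rep_root.spawn(replicates)
    for r in range(replicates):
        rng = np.random.default_rng(rep_seeds[r])
        if study.design == "matched":
            blocks = draw_matched_blocks(
                case_cells, control_cells, scn.n_cases, scn.n_controls, scn.c, rng
            )
        elif study.design == "unmatched":
            blocks = draw_unmatched_blocks(
                case_cells, control_cells, scn.n_cases, scn.n_controls, rng
            )
        else:
            raise ValueError(f"unknown design {study.design!r}")
        for m in methods:
            if m in mixture_methods and r >= mixture_replicates:
                continue
            res = apply_method(m, blocks, pop, mixture, rng)
            if res.pvalue is None:
                failures[m] += 1
            else:
                pvals[m][r] = res.pvalue
    for m in methods:
        denom = mixture_replicates if m in mixture_methods else replicates
        if failures[m] > _MAX_FAILURE_FRACTION * denom:
            raise RuntimeError(
                f"method {m} failed on {failures[m]}/{denom} replicates "
                f"in scenario {study.label}"
            )
        if failures[m]:
            logger.warning(
                "scenario %s: %d replicate(s) failed for %s (excluded)",
                study.label,
                failures[m],
                m,
            )
    return pvals, pop


def _rejection_rows(
    label: str, pvals: dict[str, np.ndarray], alphas: Sequence[float]
) -> list[dict]:
    rows = []
    for m, p in pvals.items():
        valid = p[~np.isnan(p)]
        nrep = valid.size
        for a in alphas:
            rate = float(np.mean(valid <= a)) if nrep else float("nan")
            se = float(np.sqrt(rate * (1 - rate) / nrep)) if nrep else float("nan")
            rows.append(
                {
                    "scenario": label,
                    "method": m,
                    "alpha": a,
                    "rejection": rate,
                    "se": se,
                    "replicates": nrep,
                }
            )
    return rows


def run_type_i_study(
    grid: StudyGrid, checkpoint: str | Path | None = None
) -> RejectionTable:
    """Rejection proportions for every (scenario, method, alpha) cell.

    With ``checkpoint`` set, completed scenarios are cached to a JSON file and
    skipped when the run is re-invoked.
    """
    done: dict[str, list[dict]] = {}
    ckpt = Path(checkpoint) if checkpoint else None
    if ckpt and ckpt.exists():
        done = json.loads(ckpt.read_text())
    root = np.random.SeedSequence(grid.seed)
    scenario_seeds = root.spawn(len(grid.scenarios))
    rows: list[dict] = []
    for study, sseed in zip(grid.scenarios, scenario_seeds):
        if study.label in done:
            rows.extend(done[study.label])
            continue
        logger.info("running scenario %s", study.label)
        pvals, _ = replicate_pvalues(
            study,
            grid.methods,
            grid.replicates,
            sseed,
            grid.mixture,
            grid.mixture_replicates,
        )
        srows = _rejection_rows(study.label, pvals, grid.alphas)
        rows.extend(srows)
        done[study.label] = srows
        if ckpt:
            ckpt.write_text(json.dumps(done))
    return pd.DataFrame(rows)


def run_threshold_sweep(
    panel: Sequence[tuple[str, BlockCounts]],
    pop: PopulationParams,
    methods: Sequence[str],
    thresholds: Sequence[float],
    mixture: MixtureConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Batch-QC workflow: SNPs rejected per method at each p-value threshold.

    Each SNP is tested once per method; counts at decreasing thresholds are
    therefore non-increasing by construction.
    """
    if not panel:
        raise ValueError("empty SNP panel")
    mixture = mixture or MixtureConfig()
    ss = np.random.SeedSequence(seed)
    snp_seeds = ss.spawn(len(panel))
    pvals: dict[str, list[float]] = {m: [] for m in methods}
    for (snp_id, blocks), sseed in zip(panel, snp_seeds):
        rng = np.random.default_rng(sseed)
        for m in methods:
            res = apply_method(m, blocks, pop, mixture, rng)
            pvals[m].append(res.pvalue if res.pvalue is not None else np.nan)
    thr = sorted(thresholds, reverse=True)
    rows = []
    for m in methods:
        arr = np.asarray(pvals[m])
        for t in thr:
            rows.append(
                {"method": m, "threshold": t, "rejected": int(np.nansum(arr <= t))}
            )
    return pd.DataFrame(rows)
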