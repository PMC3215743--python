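"""Mixture resampling tests: allocation arithmetic, draws, KDE mode."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hwematch.exact import GenotypeCounts, hwe_exact_pvalue
from hwematch.likelihood import BlockCounts, PopulationParams
from hwematch.mixture import (
    MixtureConfig,
    draw_mixture_counts,
    emhwp_pvalue,
    kde_mode,
    mhwp_pvalue,
    mixture_allocation,
)

POP_4225 = PopulationParams(k00=0.40, k10=0.20, k01=0.25, k11=0.15)


@pytest.mark.parametrize(
    "sizes,pop,n_m,draws",
    [
        # sample already at population proportions: everything is used
        ((400, 200, 250, 150), POP_4225, 1000, (400, 200, 250, 150)),
        # equal blocks: largest-remainder split with caps
        ((500, 500, 500, 500), POP_4225, 1250, (500, 250, 313, 187)),
        # one tiny block binds the whole allocation
        (
            (10, 1000, 1000, 1000),
            PopulationParams(k00=0.25, k10=0.25, k01=0.25, k11=0.25),
            40,
            (10, 10, 10, 10),
        ),
    ],
)
def test_allocation_known_values(sizes, pop, n_m, draws):
    alloc = mixture_allocation(sizes, pop)
    assert alloc.n_mixture == n_m
    assert tuple(alloc.draws) == draws


@given(st.lists(st.integers(min_value=0, max_value=5000), min_size=4, max_size=4),
       st.lists(st.floats(min_value=0.02, max_value=1.0), min_size=4, max_size=4))
@settings(max_examples=200, deadline=None)
def test_allocation_conservation_and_caps(sizes, kraw):
    """Sum of draws equals the mixture size; no block is over-drawn."""
    k = np.array(kraw) / sum(kraw)
    if np.any(k <= 0.01):
        return
    pop = PopulationParams(*k)
    if min(s / kk for s, kk in zip(sizes, k)) < 1:
        with pytest.raises(ValueError):
            mixture_allocation(sizes, pop)
        return
    alloc = mixture_allocation(sizes, pop)
    assert int(alloc.draws.sum()) == alloc.n_mixture
    assert np.all(alloc.draws <= np.asarray(sizes))
    assert alloc.n_mixture == int(np.floor(min(s / kk for s, kk in zip(sizes, k))))


def test_allocation_rejects_empty_required_block():
    with pytest.raises(ValueError, match="cannot represent"):
        mixture_allocation((0, 100, 100, 100), POP_4225)


def test_exhaustive_draw_returns_pooled_counts():
    # block sizes (40, 20, 25, 15) exactly at the population proportions,
    # so the allocation uses every individual
    blocks = BlockCounts.from_array([[20, 15, 5], [10, 8, 2],
                                     [12, 9, 4], [7, 6, 2]])
    alloc = mixture_allocation(blocks.block_sizes, POP_4225)
    assert np.array_equal(alloc.draws, blocks.block_sizes)
    g = draw_mixture_counts(blocks, alloc, np.random.default_rng(0))
    assert g.as_array().tolist() == blocks.pooled().as_array().tolist()


def test_draw_expectation_tracks_block_fractions():
    """Mean genotype counts over draws match sum_ij draw_ij * block fraction."""
    blocks = BlockCounts.from_array([[400, 300, 300], [100, 300, 100],
                                     [250, 100, 150], [50, 100, 50]])
    alloc = mixture_allocation(blocks.block_sizes, POP_4225)
    rng = np.random.default_rng(31)
    total = np.zeros(3)
    n_draws = 4000
    for _ in range(n_draws):
        total += draw_mixture_counts(blocks, alloc, rng).as_array()
    mean = total / n_draws
    arr = blocks.as_array().astype(float)
    frac = arr / arr.sum(axis=1, keepdims=True)
    expected = (alloc.draws[:, None] * frac).sum(axis=0)
    # hypergeometric variance bound: 3 SE with binomial upper bound per block
    se = np.sqrt((alloc.draws[:, None] * frac * (1 - frac)).sum(axis=0) / n_draws)
    assert np.all(np.abs(mean - expected) <= 3 * se + 1e-9)


def test_single_genotype_block_contributes_only_that_genotype():
    blocks = BlockCounts.from_array([[0, 0, 500], [100, 100, 100],
                                     [100, 100, 100], [100, 100, 100]])
    pop = PopulationParams(k00=0.25, k10=0.25, k01=0.25, k11=0.25)
    alloc = mixture_allocation(blocks.block_sizes, pop)
    rng = np.random.default_rng(1)
    g = draw_mixture_counts(blocks, alloc, rng)
    assert g.n_aa >= alloc.draws[0]  # the aa-only block lands entirely in aa


def test_kde_mode_degenerate_and_bimodal():
    assert kde_mode(np.full(50, 0.5)) == 0.5
    mode = kde_mode(np.concatenate([np.full(450, 0.01), np.full(50, 0.9)]))
    assert mode < 0.05  # mode, not the mean (~0.10)


def test_kde_mode_matches_histogram_argmax_oracle():
    """On a smooth unimodal sample the KDE mode agrees with a fine-binned
    histogram argmax to within a few grid cells."""
    rng = np.random.default_rng(11)
    x = rng.beta(20, 20, size=500)
    mode = kde_mode(x)
    hist, edges = np.histogram(x, bins=40, range=(0, 1))
    oracle = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    assert abs(mode - oracle) <= 0.03
    assert abs(mode - 0.5) <= 0.03


def test_kde_mode_input_validation():
    with pytest.raises(ValueError):
        kde_mode([0.5])
    with pytest.raises(ValueError):
        kde_mode([0.5, 1.5])


def test_emhwp_deterministic_given_seed(pop_mid):
    rng = np.random.default_rng(3)
    blocks = BlockCounts.from_array(rng.multinomial(800, [0.36, 0.48, 0.16], size=4))
    cfg = MixtureConfig(m=100)
    r1 = emhwp_pvalue(blocks, pop_mid, cfg, np.random.default_rng(42))
    r2 = emhwp_pvalue(blocks, pop_mid, cfg, np.random.default_rng(42))
    assert r1.pvalue == r2.pvalue
    assert r1.statistic is None


def test_mhwp_deterministic_and_near_full_sample_use():
    g0 = GenotypeCounts(360, 480, 160)
    g1 = GenotypeCounts(355, 490, 155)
    # prevalence equal to the sample case fraction: nearly the whole sample
    f = g1.n / (g0.n + g1.n)
    cfg = MixtureConfig(m=100)
    r1 = mhwp_pvalue(g0, g1, f, cfg, np.random.default_rng(9))
    r2 = mhwp_pvalue(g0, g1, f, cfg, np.random.default_rng(9))
    assert r1.pvalue == r2.pvalue
    n_m = int(r1.flags[0].split("=")[1])
    assert n_m >= g0.n + g1.n - 2


def test_mixture_of_population_proportions_matches_pooled_exact_test(pop_mid):
    """Blocks at population proportions and HWP: the mixture p-value should
    sit near the single exact test on the pooled sample."""
    arr = np.outer(pop_mid.as_array(), [0.36, 0.48, 0.16]) * 2000
    blocks = BlockCounts.from_array(np.round(arr).astype(int))
    pooled_p = hwe_exact_pvalue(blocks.pooled())
    res = emhwp_pvalue(blocks, pop_mid, MixtureConfig(m=200),
                       np.random.default_rng(5))
    assert abs(res.pvalue - pooled_p) < 0.35  # same order, both far from 0
    assert res.pvalue > 0.3
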