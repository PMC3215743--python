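# Methods

## Setting and notation

A diallelic marker has genotypes X ∈ {0, 1, 2} (AA, Aa, aa) with population
frequencies P₀, P₁, P₂; under Hardy–Weinberg proportions (HWP)
P₀ = p², P₁ = 2p(1−p), P₂ = (1−p)² for allele frequency p. A case–control
study of a primary disease D records a binary secondary phenotype T at
collection and draws controls frequency-matched to the cases on T:
|Pr(T=1|D=0) − Pr(T=1|D=1)| ≤ c, with c small (default 0.02). The
general-population joint probabilities K_ij = Pr(T=i, D=j) are assumed known
(from registries or prior studies); marginals f_D = K₀₁+K₁₁ and
f_T = K₁₀+K₁₁. The inferential target is HWP *in the general population*,
not in any study stratum.

## Exact HWP test (computational kernel)

Conditional on the observed allele counts (nA copies of one allele among 2n),
the heterozygote count h determines the genotype table and has probability
P(h | nA, n) = n! 2^h nA! (2n−nA)! / (n_AA! n_Aa! n_aa! (2n)!). The
two-sided p-value sums P(h') over all attainable h' with
P(h') ≤ P(h_obs) (probability ordering). Numerical choices: log-factorials
are cached in a geometrically grown table; the log-probabilities are
re-normalised with a log-sum-exp so they sum to one to machine precision
even at n = 5000; the tie comparison uses a relative tolerance of 1e-12 so
the observed configuration is always included, guaranteeing p > 0; the
allele count is folded to min(nA, 2n−nA) so the test is exactly symmetric
under allele relabelling. A monomorphic sample has a single attainable
configuration and returns p = 1.

## Extended likelihood-ratio test (eLRT)

Conditioning on stratum membership, an individual in stratum (i,j) with
genotype k contributes P(X=k | T=i, D=j) = p_ij|k P_k / K_ij, where
p_ij|k = Pr(T=i, D=j | X=k). With genotype relative risks
r_ijk = p_ij|k / p_ij|0 (r_ij0 = 1), the known K_ij pin down

    p_ij|k = K_ij r_ijk / (P₀ + r_ij1 P₁ + r_ij2 P₂),

which automatically satisfies Σ_k P_k p_ij|k = K_ij for every block. The
remaining per-genotype normalisations Σ_ij p_ij|k = 1 (k = 0, 1, 2) carry
one linear dependency — weighting them by P_k yields Σ K_ij = 1 identically —
so only two are independent. Counting: 2 genotype-frequency degrees of
freedom + 8 raw risks − 2 constraints = 8 free parameters under the
alternative; the HWP null replaces (P₁, P₂) by one allele frequency, giving
7. The statistic 2(log L̂_alt − log L̂_null) is referred to χ²(1).

Rather than passing the constraints to a constrained optimiser, the
reference block's conditionals are eliminated in closed form:
s_k = 1 − Σ_{(i,j)≠(0,0)} K_ij r_ijk / D_ij plays the role of p₀₀|k, and the
consistency condition Σ_k P_k s_k = K₀₀ holds identically, so the (0,0)
block needs no parameters of its own. The two-stratum baseline (LRT_d /
LRT_t, depending on the stratifying phenotype) is the same construction with
two strata and prevalence f: p_1|k = f r_k / (P₀ + r₁P₁ + r₂P₂),
p_0|k = 1 − p_1|k; 4 free parameters under the alternative, 3 under the null.

**Optimisation.** The likelihood is maximised in unconstrained coordinates:
multinomial-logit for (P₀,P₁,P₂) (alternative), logit allele frequency
(null), log relative risks. The primary fit is L-BFGS-B with exact analytic
gradients (chain-ruled through the eliminated block; verified against finite
differences); a Nelder–Mead simplex with five seeded perturbed restarts is
the fallback whenever the quasi-Newton path reports failure, and the better
optimum wins. The alternative fit warm-starts from the null solution, which
also makes a negative statistic a reliable failure signal: pre-clip values
below −1e−4 trigger the multi-start path rather than silent clipping; the
final statistic is clipped at 0. Infeasible parameter points (any implied
probability negative, or zero where its count is positive) evaluate to +∞ so
line searches retreat; cells with zero counts contribute nothing regardless
of their probability (0·log 0 = 0). SNPs with fewer than two observed
genotype classes return p = 1 with a `degenerate` flag. Simplex tolerances:
function 1e-10, parameter 1e-8, 5000 iterations per start; quasi-Newton:
ftol 1e-13, gtol 1e-9.

## Extended mixture exact test (emHWP)

The mixture approach physically reconstructs a population sample. The
largest subsample whose strata can sit at population proportions has size
N_m = ⌊min_ij N_ij / K_ij⌋; the block draws apportion N_m by K_ij with the
largest-remainder rule, capped at the available N_ij (capped excess moves to
the next-largest remainder; ties break toward the earlier block in the fixed
(0,0),(1,0),(0,1),(1,1) order). Within each block, individuals are sampled
without replacement — implemented at the genotype-count level as a
multivariate hypergeometric draw on the block's triple, which is
distributionally identical to per-individual sampling and much faster. The
exact HWP p-value of the pooled draw is computed; the procedure repeats
M = 500 times; the reported p-value is the mode of a Gaussian kernel density
over the M values (Silverman bandwidth 0.9·min(sd, IQR/1.34)·M^(−1/5),
argmax on a 512-point grid over [0, 1]). Per-test caching: within one test
the mixture size is fixed, so p-values are tabulated once per observed
allele count and re-used across draws.

**Why the KDE is not boundary-corrected.** Reflecting mass at 0 doubles the
estimated density at the boundary. Mixture p-value distributions under the
null are typically right-skewed with an interior peak, and the doubled
boundary density routinely overtakes that peak, manufacturing a spurious
mode at p ≈ 0: on 300 null replicates of the matched design the reflected
estimator rejected at 0.103 instead of ≈ 0.05, while the plain estimator
sat at 0.050. The plain KDE argmax is therefore used. The two-stratum
baseline (mHWP_d / mHWP_t) uses N_m = ⌊min(m/(1−f), n/f)⌋ with
round(N_m·f) individuals drawn from the phenotype-present stratum.

## Synthetic study generator

Two logistic models generate the phenotypes over four independent SNPs
(genotypes drawn from HWP at each SNP's MAF) and three covariates:

    logit Pr(T=1) = α₀ + Σᵢ αᵢ·dom(Xᵢ) + α₅·sex + α₆·ethn + α₇·age
    logit Pr(D=1) = β₀ + Σᵢ βᵢ·dom(Xᵢ) + β₅·sex + β₆·ethn + β₇·age + β₈·T

with dominant coding dom(X) = 1{X ≥ 1}. Default log-odds 0.4055 (OR 1.5)
give the four association patterns — SNP 1 affects both phenotypes, SNP 2
only D, SNP 3 only T, SNP 4 neither — with sex (prevalence 50%) at OR 2 on
T only, ethnicity (75%) at OR 1.5 on both, and β₈ = 1.0983 (OR 3) linking T
to D. Age is a three-band covariate entering both models additively (one
log-odds step per band); the band frequencies are 36% / 39% with the top
band the 25% remainder — the remainder convention and per-step coding are
this package's choice where only two band frequencies are standard.

Intercepts are calibrated to target prevalences (defaults f_T = f_D = 0.3)
by Brent root-finding on the Monte-Carlo expectation over the pool itself
(α₀ first; T is then realised before β₀ is solved, since D depends on T),
bounded to [−20, 20]. The population pool defaults to 10⁶ individuals per
scenario; K_ij is estimated once from the pool and reused across replicates.
Matched studies draw n_cases cases uniformly, compute their trait fraction
q₁, draw the control target q₀ ~ Uniform(q₁−c, q₁+c) truncated to [0,1], and
fill round(q₀·n_controls) controls from the T=1 stratum and the rest from
T=0. A ±20% misspecification perturbation jitters f_D and the two
conditional trait probabilities uniformly and reconstitutes a consistent
K_ij table.

The replicate loop uses a count-level equivalent of the row-level sampler:
uniform sampling without replacement induces multivariate hypergeometric
draws on the (T, genotype) contingency cells, so replicates cost O(1) in the
pool size. Both samplers are exercised by the matching-inequality tests.

**What the generator does not emulate:** linkage disequilibrium between
markers (SNPs are independent), genotyping error itself (the simulations
measure false-positive rates on clean markers), continuous secondary
phenotypes, gene–trait interactions in the disease model, and individual
(rather than frequency) matching. Passing tests therefore demonstrate
calibration of the tests under the stated generative design, not robustness
to those features of real data.

## Monte-Carlo study runner and problem sizes

For each scenario the runner calibrates once, builds the pool, estimates
K_ij, then per replicate draws a matched study and applies every requested
method; results are rejection proportions with binomial SEs
(√(p̂(1−p̂)/R)), and a master seed sequence spawns independent child
streams per scenario and per replicate, so any replicate is reproducible in
isolation and results are order-independent. Method failures on a replicate
are counted and excluded only if below 0.1% of replicates; otherwise the
scenario aborts. Reference values in the tests come from million-replicate
published tables; this package's checks run at desk scale — 1200–5000
replicates in the test suite, 6000 (likelihood tests) / 2000 (mixture tests)
in `scripts/acceptance.py` — with agreement asserted within 3 Monte-Carlo
SEs of the reduced-scale estimate. The threshold-sweep workflow tests each
SNP of a panel once per method and counts rejections at a decreasing ladder
of thresholds, so counts are monotone by construction.

## Known limitations

- K_ij (or f for the two-stratum tests) must be supplied; the ±20%
  perturbation utility supports sensitivity analyses but the tests do not
  propagate uncertainty in these inputs.
- The χ²(1) reference for the eLRT is asymptotic; at low MAF and very small
  nominal levels it can run slightly anti-conservative (visible in the
  published tables as well), while the emHWP test stays conservative.
- The emHWP p-value is a mode estimate on a 512-point grid; its resolution
  is ~0.002, which matters only for thresholds far below those used in QC.
- Autosomal diallelic markers only; no X-chromosome or multi-allelic tests.
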