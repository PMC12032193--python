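# Methods

## Model

`psem` implements piecewise structural equation modeling for multi-species
count data. A community model is a directed acyclic graph (DAG) whose
vertices are either *endogenous* (species occurrence counts, each the
response of one structured equation) or *exogenous* (landscape covariates,
never a response). Every structured equation is a Poisson log-link GLM:

    y_v ~ Poisson(mu_v),   log mu_v = b0 + sum_{u in parents(v)} b_{uv} * x_u

Landscape covariates are centred and scaled (sample sd, n−1 denominator)
before fitting; species predictors enter as raw counts. That asymmetry is
deliberate: occurrence counts carry their natural scale (an extra wild
boar detection, not an extra standard deviation), which is why raw
species-on-species estimates are small while their standardized effects
are comparable to covariate effects.

Rather than a joint covariance likelihood, global fit is judged through
the DAG's testable implications (local estimation):

- **Basis set.** One independence claim per unordered non-adjacent vertex
  pair with at least one endogenous member, excluding exogenous–exogenous
  pairs (the model places no constraint on covariate covariances) and
  pairs under a correlated error. The conditioning set is the union of
  both vertices' parents.
- **Claim testing.** The claim's response is regressed on its
  conditioning set plus the other vertex; the claim's p-value is the
  two-sided Wald p of that extra coefficient. Direction: the single
  endogenous member responds if only one is endogenous; the descendant
  responds if the pair is ancestrally ordered; otherwise, under the
  default *conserve* rule, both directions are fitted and the smaller p
  kept. With count responses the test is not direction-symmetric, and
  taking the minimum guards against accepting a wrong model at the price
  of a conservative (slightly inflated) per-claim rejection rate. The
  rule is switchable (`conserve=False` fixes the lexicographically first
  vertex as response).
- **Fisher's C.** C = −2 Σ ln p_i over the k claim p-values, referred to
  a chi-square with 2k df. A *non*-significant result (p > 0.05) means
  the claimed absences of paths are consistent with the data.
- **Chi-square GOF.** χ² = −2 (Σ loglik(model equations) − Σ
  loglik(saturated equations)), where the saturated counterpart of each
  equation regresses its response on every topologically permissible
  predecessor: all exogenous vertices plus all endogenous vertices
  earlier in the deterministic causal order (exogenous first, ties broken
  lexicographically). df is the difference in total parameter count.
  This pins one concrete saturation scheme; df bookkeeping is emitted so
  any divergence from other implementations' printed dfs is diagnosable.

Per-equation fit is summarised by the Nagelkerke pseudo-R²,
R² = [1 − exp(2(ll₀ − ll)/n)] / [1 − exp(2 ll₀/n)], clamped to [0, 1].

## Standardized coefficients

Effect sizes are reported as std_b = b · sd(x) / sd_latent(y). The
default `latent_linear` method takes sd_latent(y) = sd(η̂), the spread of
the fitted linear predictor, with no added error-variance term — the log
link has no canonical latent error variance. An alternative
`observation_empirical` method uses sd(log(y + 1)). Consequence stated
openly: standardized estimates from other software that adds a
distribution-specific error variance to the denominator will differ
(typically ours are larger, since the denominator omits residual
variation); raw estimates, SEs and p-values are unaffected. The method
used is recorded on every fit.

## Stepwise optimization

Starting from an a-priori model, each pass:

1. tests every basis-set claim;
2. walks significant claims (p < α = 0.05) in ascending-p order
   (lexicographic pair-name ties, for reproducibility): a claim matching
   a *whitelist* entry — the model file's explicit list of biologically
   defensible addable paths; the software never judges biology — is
   tentatively added and kept only if Fisher's C decreases; a significant
   species–species claim with no whitelist match becomes a correlated
   error, removing the pair from the basis set; anything else is
   rejected and recorded;
3. prunes hypothesized paths that are simultaneously non-significant
   (p ≥ α) and fitted with a sign contradicting their expected sign.
   Non-significant paths with the expected sign are retained; paths added
   during the run are never pruned; pruned paths never re-enter.

Passes repeat until a full pass changes nothing. Termination is
guaranteed: the whitelist is finite, every addition strictly lowers C,
and every removal strictly shrinks the path set. The full trace (every
addition, rejection, correlated error and removal, with p-values and C
before/after) is serialisable and exactly replayable.

**Combining models.** The combined model is the union of the retained
paths and correlated errors of the two optimized models. Two edge cases
need policy: a shared path with conflicting expected signs is an error;
and the two models may retain *opposite directions* over the same pair
(predator→prey from the top-down model, prey→predator from the
bottom-up), whose union would be cyclic. Given the data table, the
direction with the smaller Wald p-value in its source model's equation
is kept; without data the conflict is an error. This situation does not
arise when one model's optimization removes its direction, but on
simulated data it is common and needs a deterministic rule.

## Synthetic data

The generator emulates a two-season camera-trap survey of ~140 stations
(64 winter, 76 autumn):

- Covariates: elevation ~ U(663, 1617) m; terrain ruggedness index ~
  U(84, 494); forest proportion ~ Beta scaled to [0.1, 1.0] with mean
  0.77 (concentration 5 — ranges and means are known, the exact field
  distribution is not and is irrelevant to the machinery under test);
  local road density ~ U(0.21, 0.34) km/km².
- Counts are simulated forward in topological order:
  y ~ Poisson(exp(b0 + Σ b·parent)), covariate parents scaled, species
  parents raw — exactly the structure the fitted model assumes. A linear
  predictor above 30 aborts with the offending station and species.
- Default truth: the final combined DAG with its published path
  coefficients. Intercepts are not published; they are calibrated by
  bisection (relative tolerance 2%, evaluation table of 10,000 stations,
  fixed internal seed), working through species in causal order, so that
  simulated mean counts match the observed per-station detection rates
  (fox 7.04 down to hare 0.51, i.e. the observed shares of a 3599-record
  survey over 140 stations). This conflates season and station effects,
  which the observed shares do not decompose.

Deliberately absent, because the fitted model assumes none of them:
spatial autocorrelation, detection/effort processes, zero-inflation,
overdispersion. Passing tests therefore demonstrate correctness of the
machinery under the model's own assumptions — not robustness of the
scientific conclusions to violations of those assumptions in field data.

## Calibration experiments

Type-I calibration of the global Fisher's C test (rejection rate 0.05 ±
0.03 under the true DAG, 500 replicates, n = 300) and the power check
for a single omitted path (coefficient 0.5 on a unit-sd predictor,
detected in ≥ 90% of replicates) use a compact trophic-chain generating
model — two covariates, two species in a chain — whose basis-set claims
are all uniquely directed (one endogenous member or ancestrally ordered).
This is intentional: under the conserve rule an unordered
dual-endogenous claim takes the minimum of two correlated p-values and
is conservative by construction, so a calibration experiment including
such claims would measure the (documented) conservatism of that rule
rather than the correctness of the machinery.

## Numerical choices

- IRLS: deviance-based convergence, relative tolerance 1e-8, max 100
  iterations, step-halving on deviance increase; SEs from the inverse
  Fisher information at the optimum. Matches reference GLM
  implementations to 1e-6 on random problems.
- Wald (not likelihood-ratio) per-coefficient p-values, two-sided,
  normal reference.
- Probabilities are floored at 1e-300 before any logarithm, so Fisher's
  C stays finite and orderings stable under extreme claims.
- Linear predictors are clipped at ±30 inside likelihood evaluation;
  the simulator refuses to generate means above e^30 outright.
- All orderings (topological ties, basis-set claims, candidate
  processing) are lexicographic, so every output is byte-stable.

## Degrees-of-freedom bookkeeping

Residual df is reported as n − (predictors + 1) per equation, and
Fisher's C df as exactly 2k. Published tables for this system show two
quirks the package surfaces rather than forces agreement with: the text
reports the combined model's C at 28 df while its comparison table lists
26 (27.973 at 26 df reproduces the printed p = 0.36; at 28 df it would
be 0.46 — the table is taken as authoritative), and printed per-equation
residual dfs imply one more estimated parameter than predictors + 1 for
some equations. The package reports its own arithmetic.

## Known limitations

- Plain Poisson only: no negative-binomial or zero-inflated equations,
  no random effects, no effort offsets.
- No latent or composite variables; no cyclic (non-recursive) models.
- The hypothesized-model fixtures encode a narrative description of the
  a-priori path diagrams; where a published figure is the only source of
  an edge list, the encoding is a reconstruction and df-level agreement
  with published model-comparison rows is not expected.
- Whitelists operationalise "biologically relevant"; an empty whitelist
  means the optimizer can only prune and add correlated errors.
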