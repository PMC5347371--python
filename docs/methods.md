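# Methods

## Model

`ggpa` jointly analyzes GWAS summary statistics (per-SNP association
p-values) for n phenotypes.  Each p-value is probit-transformed,
y_it = Φ⁻¹(1 − p_it), so that null SNPs have standard-normal scores.  A
latent binary indicator e_it marks SNP t as associated with phenotype i,
and the score is emitted from a two-group mixture

    y_it | e_it ~ (1 − e_it) · N(0, 1) + e_it · LN(μ_i, σ_i²),

where LN(μ, σ²) is the log-normal density with mean exp(μ + σ²/2).  The
log-normal support (0, ∞) encodes the one-sided alternative: a score
y ≤ 0 (p ≥ 0.5) has zero probability of being associated.

Pleiotropy enters through a pairwise Markov random field over phenotypes.
Given an undirected graph G on the n phenotypes, the indicator vector of
each SNP follows the auto-logistic law

    p(e_t | α, β, G) ∝ exp( Σ_i α_i e_it + Σ_{i~j} β_ij e_it e_jt ),

with node terms α_i (baseline log-odds of association) and positive edge
couplings β_ij.  SNPs are independent given the parameters (users should
supply LD-pruned summary statistics; the model has no LD machinery).  The
normalizing constant is computed exactly by enumerating all 2^n joint
states; this is cheap through n ≈ 12–15 (4,096 states at n = 12) and the
implementation refuses n above a configurable cap (default 20).

Priors: μ_i ~ N(θ_μ, τ_μ²), σ_i² ~ IG(a_σ, b_σ), α_i ~ N(θ_α, τ_α²),
and β_ij ~ Γ(a_β, b_β) on edges with a point mass at zero off edges.
Defaults θ_μ = θ_α = 0, τ_μ² = τ_α² = 10⁴, a_σ = b_σ = 0.5 (substantial
mass on modest variances), a_β = 4, b_β = 2 (coupling prior mean 2,
variance 1, keeping edge couplings away from zero a priori).  The graph
prior p(G) ∝ 1/max(|E|, 1) favors sparse graphs; the original 1/|E| form
is undefined at the empty graph, and the max(·, 1) convention keeps the
empty graph reachable with the same weight as any one-edge graph.

## Posterior computation

A Metropolis-Hastings-within-Gibbs sampler; one sweep is:

1. **Latent field.**  Systematic scan over phenotypes, each column
   redrawn for all SNPs at once from the single-site conditional
   logistic(α_i + Σ_{j~i} β_ij e_jt + log-likelihood ratio), exactly zero
   where y ≤ 0.  (Componentwise updating was validated against 2^n-block
   enumeration of p(e_t | y_t) on small instances.)
2. **Signal parameters.**  Conjugate draws of μ_i (normal) and σ_i²
   (inverse-gamma) from the log-scores of currently associated SNPs; with
   an empty component both come from their priors.
3. **Node terms.**  Gaussian random walk on each α_i (default proposal SD
   0.1); the acceptance ratio needs only the sufficient statistic
   S_i = Σ_t e_it and the change in the exact log-normalizer.
4. **Couplings.**  Log-scale random walk on each β_ij over current edges
   (default SD 0.2), with the Jacobian correction; uses S_ij = Σ_t e_it e_jt.
5. **Graph.**  Reversible-jump birth/death toggles on pairs chosen
   uniformly; a birth draws β* from its Γ prior so prior and proposal
   densities cancel and the acceptance ratio reduces to
   β*·S_ij − T·Δ(log normalizer) + the graph-prior ratio.  Ten toggles
   are performed per sweep (configurable).  With chains of ~10⁴ sweeps a
   single toggle per sweep gives each of the n(n−1)/2 pairs only a few
   hundred proposals, which we found leaves edge-inclusion traces with
   single-digit switch counts; ten toggles restores per-pair proposal
   budgets comparable to chains five times longer, at the negligible cost
   of one 2^n logsumexp per toggle.

The exact normalizer is maintained incrementally: the vector of 2^n state
energies is cached and a single-parameter proposal only adds a rank-one
term before a logsumexp.

**Initialization** is data-driven: e_it ← 1{y_it > 1}, (μ_i, σ_i²) from
moments of log y over the seeded set, α_i ← logit of the seeded fraction
(clamped to [−10, −1]), empty graph.  The seed is deliberately dense.
GWAS signals can be weak enough that essentially no SNP is individually
significant, and a sparse seed (e.g. genome-wide-significant SNPs only)
can start signal components empty; the full conditional of (μ_i, σ_i²)
given an empty component is the diffuse prior, whose draws (|μ| ~ 100,
σ² ~ 10⁵) make the signal density vanish everywhere and the empty state
effectively absorbing.  Burn-in prunes an over-seeded component in tens
of sweeps; it cannot rescue a dead one.

**Seeding.**  A single integer seed expands into three named substreams
(field, parameters, graph), so kernels can be reordered without
perturbing each other's randomness; runs are bitwise reproducible.

**Storage.**  The full T×n field is not stored by default; the running
posterior means of e_it and e_it·e_jt over all main iterations — exactly
what association inference needs — are accumulated instead, together
with thinned draws of (α, μ, σ², β, G) and the log-posterior trace.

Optional Robbins–Monro proposal-scale adaptation is available during
burn-in only (off by default); scales are frozen afterwards to preserve
detailed balance.

## Inference outputs

**Phenotype graph.**  Each pair gets the posterior edge probability
p(E(i,j)|Y) and the exceedance probability p(β_ij > 0|Y); an edge is
declared when p(E(i,j)|Y) > 0.5 and p(β_ij > 0|Y) > 0.95.  Because β_ij
is positive exactly when the edge is present, the exceedance probability
numerically equals the edge probability, making the effective rule
p(E|Y) > 0.95; an alternative rule (95% credible interval of the
marginal β draws, zeros included, excluding zero) is available by flag.
Coupling summaries are reported both marginally (absent-edge draws count
as zero) and conditionally on edge presence.

**Association mapping.**  Local false discovery rates f_it = 1 −
p(e_it=1|Y) (pairwise: f_ijt = 1 − p(e_it=1, e_jt=1|Y)) are thresholded
by the direct posterior probability approach: sort ascending (stable,
ties by input order), call the largest prefix whose running mean stays
below the nominal global FDR bound τ.  The realized FDR estimate over
the called set is ≤ τ by construction, and call sets are nested in τ.

## Synthetic data generator

The generator reproduces the benchmark simulation design: a 7-phenotype
graph with a tight triangle P1–P2–P3 (β = 4.0, 1.8, 2.3), a weaker chain
P3–P4 (2.5) and P4–P5 (5.0), and isolated negative controls P6, P7;
α = (−4.7, −3.0, −5.5, −4.8, −3.6, −2.5, −3.5); 20,000 SNPs.  Indicator
vectors are drawn by 1,000 Gibbs sweeps from the all-zero state (scan
order and initialization are the generator's own choices; the burn length
dominates any initialization effect at these parameters).  Scores are
emitted as y_it ~ N(μ_i, σ_i²) for associated SNPs — μ = (1.1, 1.0, 1.2,
1.2, 1.3, 1.1, 1.3), σ = (0.4, 0.3, 0.35, 0.3, 0.45, 0.4, 0.3) — versus
N(0, 1) otherwise, then p = 1 − Φ(y).

Two deliberate properties of this design matter for interpretation:

- **Mild misspecification.**  The generator's signal is normal while the
  fitted signal component is log-normal.  The fitted (μ_i, σ_i²) are
  log-scale parameters and are *not* comparable to the generating
  (μ_i, σ_i); recovery is assessed on the signal-score scale via the
  fitted component's mean exp(μ + σ²/2) and standard deviation
  exp(μ + σ²/2)·√(exp(σ²) − 1).  An option `lognormal_signal` draws
  signal scores from the moment-matched log-normal instead, for exact
  model-match experiments.
- **Weak signals.**  With signal-score means near 1.1 against a N(0, 1)
  null, single-phenotype evidence is bounded: even under the *true*
  generating parameters the exact (2^7-state enumeration) posterior
  p(e_it = 1 | y_t) never exceeds ≈ 0.89, and the direct posterior
  probability call set at τ = 0.1 is empty for every phenotype.  An
  empty call set on this scenario is therefore the correct answer, and
  FDR control holds trivially; power comparisons use the full ranking
  (AUC), which the pleiotropy coupling improves substantially for linked
  phenotypes and leaves unchanged for isolated ones.

The generator models no LD (SNPs independent), no overlapping-subject
correlation between studies, and no allele-frequency structure; passing
tests demonstrate correctness of the model and sampler under the model's
own independence assumptions, not robustness to those real-data features.

## Problem sizes used by the test suite

The end-to-end checks fit the benchmark scenario at its native size
(20,000 SNPs, 7 phenotypes) with 2,000 burn-in + 8,000 main iterations —
enough for every edge-inclusion trace to switch hundreds of times —
and replicate graph recovery across four additional seeds at 800 + 3,200
iterations.  Distributional kernel tests (prior reproduction at T = 0,
enumeration comparisons) use chains of 10³–10⁴ draws on 2–3 phenotypes.

## Numerical choices and edge cases

- p-values are clamped into [ε, 1−ε], ε = 10⁻¹² (Φ⁻¹ diverges at 0/1;
  the clamp preserves ordering of genome-wide-significant SNPs without
  overflow).  Rows with missing values are dropped, not imputed.
- σ² fallback at initialization when a component is empty: 1.0 (the null
  variance); the IG(0.5, 0.5) prior has no finite mean.
- fdr ties are broken by SNP input order (stable sort): deterministic
  outputs.
- The Geweke convergence score on the log-posterior trace uses
  batch-means standard errors (first 10% vs last 50%).
- Degenerate inputs: a data set whose scores are all ≤ 0 yields a
  permanently empty field and fdr ≡ 1; n > 20 raises a capability error
  rather than attempting a 2^n enumeration.

## Known limitations

- The log-normal signal component has a light right tail on the score
  scale when σ² is small, so extreme outlier scores (far above the
  fitted signal mean) can be assigned to the null; with weak fitted
  signals this caps per-SNP posteriors (see above).
- Weak edges near the detectability limit can leave the graph posterior
  genuinely bimodal.  On the benchmark scenario, phenotypes linked only
  through an intermediate node (P3 and P5, via P4) are marginally
  correlated, and with couplings around 2 the posterior can split its
  mass between the true chain P3–P4–P5 and a direct P3–P5 edge (long
  reference chains put ≈ 0.58 on each on some data realizations).  The
  strict declaration rule (effectively p(E|Y) > 0.95) then declares
  neither; exact recovery of every weak edge on a given realization is
  not guaranteed at 20,000 SNPs.  Users should read mid-range edge
  probabilities as genuine structural uncertainty, not noise.
- Couplings are restricted positive (Γ prior): antagonistic pleiotropy
  is representable only as edge absence.
- Exact enumeration limits the method to moderate phenotype counts
  (n ≤ 20; practically n ≤ 15 for speed).
- The sampler is single-chain and sequential; per-SNP conditional
  independence is exploited by vectorization, not parallelism.
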