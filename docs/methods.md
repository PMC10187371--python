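# Methods

## The model

`clclsa` classifies subjects from M omics layers (e.g. mRNA expression, DNA
methylation, miRNA expression) when an arbitrary subset of layers may be
missing per subject.  Subject j's view-i feature vector x_i^(j) ∈ R^{V_i}
passes through four stages:

1. **Feature-level attention.**  A linear network f_i scores every feature
   through a sigmoid, `fatt = σ(f_i(x))`, and the features are gated
   elementwise: `x ⊙ fatt`.  The gate output lies strictly in (0,1); it is
   a soft feature-selection mechanism, not a transformer-style attention.
2. **Omics embedding.**  An MLP emb_i (linear → ReLU → dropout 0.5) maps the
   gated features to a latent block `x̂ ∈ R^D`.  D is shared by all omics so
   latents are mutually comparable.
3. **Omics-level attention.**  A linear network g_i produces one sigmoid
   scalar per subject, `matt = σ(g_i(x̂))`, which rescales the whole block:
   `ẑ = x̂ ⊙ matt` (scalar broadcast over D — g_i maps D→1, so a per-subject
   scalar is the only shape consistent with its architecture).
4. **Fusion and classification.**  The M gated blocks are concatenated in
   view order and a softmax head c maps R^{M·D} to class probabilities.
   Per-omics auxiliary softmax heads c_i operate on each block alone.

**Cross-omics completion.**  For every ordered pair (i,k) a bridge network
h_ik = dec_i∘enc_k (linear–BN–ReLU bottleneck, D→…→D) predicts omics i's
latent from omics k's.  Bridges are fitted by the summed squared error
Σ_j ‖h_ik(ẑ_k) − ẑ_i‖², restricted to subjects where both omics are
observed, with the target ẑ_i detached — otherwise minimizing the
reconstruction loss can collapse all omics latents onto one point.  A
missing latent is imputed as the unweighted mean of the bridge predictions
from all observed source omics; with a single source this degenerates to
that one prediction.  The mean was chosen because it is symmetric in the
sources and no principled weighting is available without extra assumptions.

**Contrastive alignment.**  Latent rows of two omics are softmax-normalized
into probability vectors, and their batch-averaged outer product (then
symmetrized and renormalized) is read as a D×D joint probability table P.
The pair loss

    L(P) = − Σ_{d,d'} P_{dd'} ln( P_{dd'} / (P_d^{α+1} P_{d'}^{α+1}) )

equals −MI(P) at α = 0; α > 0 adds a marginal-entropy reward that resists
collapse.  The total sums over all ordered pairs, using only jointly
observed subjects, so imputed latents can never reward bridge
self-consistency.  The softmax row normalization is our choice — something
must turn unconstrained latents into probabilities, and row-softmax is the
convention of the contrastive objective this loss descends from; α defaults
to 9 for the same reason and is prominently exposed in the config.

**Objective.**  L = L_clf + λ_al·L_al + λ_co·L_co + λ_cl·L_cl, with summed
(not averaged) cross-entropies.  L_al adds, per omics, the auxiliary
cross-entropy plus a squared penalty pulling the omics gate `matt` toward
the auxiliary head's confidence.  Confidence is the true-class probability
(TCP) of c_i, detached in the squared term; the maximum softmax probability
is available as a config alternative.  The literal printed form of the
auxiliary term would *reward* misclassification (`+ y log ŷ`); we read it
as standard cross-entropy, which is the only reading consistent with its
stated purpose of boosting training.

**Training.**  Each epoch runs two full-batch phases: (1) complete subjects
update everything, including all M(M−1) bridges and the contrastive loss;
(2) incomplete subjects have missing latents imputed (bridges in eval mode,
batch-norm running statistics) and contribute to the classification and
auxiliary losses only.  λ_co is forced to 0 on complete data.  Gradients
from phase-2 classification may flow into the imputed latents end-to-end
(`detach_imputed` turns this off).  Optimization is Adam, initial learning
rate 1e-4, ×0.2 step decay every 500 epochs, 2500-epoch cap, no early
stopping.  Inputs are standardized per feature using observed training rows.

## Desk-scale regime

The reference schedule (1e-4 × 2500 epochs) is expensive on a laptop-class
budget, and its effect on parameter movement is roughly the product of
learning rate and step count.  `TrainConfig.desk_scale()` therefore runs
300 epochs at 1e-3 (total displacement ≈ 0.3 vs the reference 0.25); the
whole synthetic benchmark — recovery, imputation comparison, ablations —
uses this schedule (the missing-rate sweep uses 150 epochs per point since
it trains 27 models).  This is a package choice: the bridges in particular
need the full displacement budget to converge from their random
initialization to calibrated regressors, so shortening epochs without
raising the rate leaves them mid-flight.

## Synthetic data: what it emulates and what it does not

Each subject has a latent u ~ N(μ_y, I_q) (q = 8); class means are placed
at minimum pairwise distance Δ = 8 (units of the within-class sd).  View i
observes x_i = u·A_i + ε with fixed random loadings A_i (scale 0.05/√q per
entry) and i.i.d. noise ε ~ N(0, 0.5²).  Defaults: N = 400 subjects, M = 3
views of 100/100/60 features, C = 3 balanced classes.

* Δ = 8 guarantees the generator's separability contract: with zero feature
  noise the training sample is linearly separable from any single view
  (unit-sd Gaussian clouds need means ≳6 sd apart for N = 400 points to
  separate with high probability).
* The loading scale 0.05 was calibrated against an independent reference
  classifier (ℓ2 logistic regression), not against this package's model:
  it places fused complete-data held-out accuracy near 0.92 and single-view
  accuracy near 0.70 — the regime of real multi-omics benchmarks, where
  integration helps and missing layers cost accuracy.  With order-1
  loadings the 100-feature views are essentially noiseless copies of the
  latent and every comparison saturates at ACC 1.0.
* Because all views observe the *same* latent through linear maps with
  independent noise, a model retrained from scratch with zero-filled
  latents is close to Bayes-optimal: imputation can add no information.
  The completion comparison therefore contrasts one trained model's two
  inference paths (bridge-imputed vs zero-filled latents); it measures
  whether the completion mechanism matters to a model that expects
  completed inputs, which is the method's actual claim.
* Not emulated: count-valued expression, beta-valued methylation, feature
  correlation structure, batch effects, informative missingness (masks are
  missing-completely-at-random), or heterogeneous per-feature relevance.
  Passing tests validate the mechanism, not biological realism.

## Numerical choices

* All arithmetic is float64 on a small reverse-mode autodiff engine
  (`clclsa.nn`) written for this package; layer initialization is fan-in
  uniform, seeded, and every random draw descends from the run seed, so
  identical configs reproduce bitwise.
* Logs are floored at 1e-12 (cross-entropy) and 1e-8 (contrastive tables);
  the floors enter through a clip whose gradient vanishes on the clipped
  side.
* Batch norm uses biased variance in the batch-statistics path, unbiased
  in the running estimate (momentum 0.1), running statistics in eval mode.
* Grid search ties are broken by F1, then by the smaller λ-sum (preferring
  the simpler objective).
* Binary F1 takes class 1 as positive; AUC is the Mann–Whitney statistic
  with half credit for ties.  Test subjects are masked at the training
  missing rate by default (`mask_test=False` evaluates on complete data).

## What the synthetic benchmark can and cannot show

The benchmark demonstrates recovery of class structure, graceful
degradation with the missing rate, and the value of latent completion at
inference.  It does **not** demonstrate a benefit from the attention gates
and auxiliary confidence loss: on this generator the stripped-down variant
(gates fixed at 1, λ_al = λ_cl = 0) matches or slightly exceeds the full
model (≈0.89 vs ≈0.87 mean ACC at η = 0.3 over 5 seeds).  That is a
property of the data, not a bug in the components: with homogeneous
linear-Gaussian views a linear classification head is already close to
optimal and re-weights features on its own, so sigmoid gates are redundant
degrees of freedom and the auxiliary objective only constrains capacity.
The gains these components deliver on real multi-omics cohorts rely on
heterogeneous, redundant, noisy-in-structured-ways features that this
generator deliberately does not emulate (an `informative_fraction < 1`
option adds pure-noise features, which in our measurements was still not
sufficient to make the gates pay off).  Conclusions about the attention
components should come from real data, not from this benchmark.

## Known limitations

* Full-batch training only by default; the engine is not tuned for
  mini-batch throughput or GPUs.
* The contrastive table is D×D, so very large latent dims make the loss
  quadratic in D.
* With M = 1 the completion and contrastive components are inert by
  construction.
* Missingness is assumed MCAR by the mask generator; informative
  missingness would need a different mask model.
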