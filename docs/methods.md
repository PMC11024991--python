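# Methods and design notes

## Scope and model of the problem

The package classifies drugs into three torsades-de-pointes (TdP) risk
classes from simulated cellular electrophysiology.  A drug is characterised
by dose–response measurements on four cardiac currents (INaL, INa, ICaL,
IKr), a free therapeutic plasma concentration Cmax (nM), and — for
training/benchmarking — a known risk label.  The pipeline propagates
measurement uncertainty (Hill posterior samples) through a paced
ventricular-cell simulation into nine biomarkers, classifies each biomarker
vector, and evaluates the classifier with a drug-level resampling protocol.

## Hill pharmacology and MCMC

Fractional block is `b(D) = 1/(1 + (IC50/D)^h)`; the zero-dose limit is
defined as exactly 0.  Concentrations are nanomolar throughout, and the
dose–response reader rejects percent-scale block values.

The Bayesian fit uses a Gaussian observation model on fractional block with

* log-uniform prior on IC50 over [1e-3, 1e9] nM,
* log-normal prior on h centred at 1 (sd of log = 0.5),
* half-normal prior (scale 0.1) on the noise sd,

sampled by adaptive random-walk Metropolis in (log IC50, log h, log sd):
four parallel chains, Robbins–Monro step adaptation toward 30% acceptance
during an adaptation phase equal in length to the sampling phase, then a
frozen step size.  Chains are pooled and thinned to exactly `n_samples`
draws (2,000 by default).  Acceptance outside [0.05, 0.95] attaches a
diagnostic warning to the fit rather than failing it.  The fitting code the
reference protocol delegates to is not redistributable, so these priors and
the sampler are this package's own documented choices; they recover IC50
within a few percent and give nominal interval coverage on synthetic data
at noise sd 0.02 (checked by the acceptance suite at 100 replicates).

Desk-scale fits in the test suite use shorter chains (1,500–2,000
iterations); the two-parameter posterior is effectively converged well
below the default chain length.

## Surrogate ventricular cell

Detailed human-ventricular models are deliberately out of scope; the
package defines a model contract (state names including Vm and [Ca]i, a
pure derivative function, a per-channel current reporter, per-channel
conductances) and ships a compact surrogate:

* Hodgkin–Huxley-style INa (m³h), INaL, ICaL (d·f), IKr with an
  instantaneous inward-rectification factor, IKs (xs²), instantaneous IK1,
  and Ito (r·s); reversal potentials ENa = ECa = +60 mV, EK = −88 mV.
* A single-pool calcium transient `d[Ca]/dt = −k·ICaL − ([Ca]−Ca0)/τ`
  (k = 6·10⁻⁶ mM·µF/µA, τ = 200 ms, Ca0 = 10⁻⁴ mM), so Ca-transient
  amplitude is monotone in ICaL conductance by construction.
* Conductances tuned once so that control behaviour at BCL 2,000 ms is
  physiological: resting Vm ≈ −88 mV, APD90 ≈ 254 ms, dVm/dt_max ≈
  110 mV/ms, Ca amplitude ≈ 10⁻³ mM; APD90 prolongs strictly with IKr
  block and Ca amplitude falls strictly with ICaL block.

What the surrogate does *not* reproduce: detailed AP morphology, rate
adaptation, intracellular ion homeostasis, spontaneous EAD generation, or
quantitative qNet values of community models.  Pipeline-level tests
therefore establish that the machinery is correct and directionally
faithful, not that its biomarker values match any particular published
cell model.  External models plug in through a JSON exchange schema
(states, parameters, rate and current expressions) via
`load_external_model`.

### Numerics

LSODA with rtol 1e-6 / atol 1e-8, integrated beat by beat with the final
state of beat k seeding beat k+1; the rectangular stimulus (−80 µA/µF,
0.5 ms, protocol-level so the model derivative stays pure) starts each
beat.  Output is sampled at `output_dt = 0.25 ms`: at this resolution
APD90 of the surrogate is grid-converged (halving the step changes it by
~0.1 ms, and the dominant residual error — undersampling of the narrow AP
peak — only appears at 0.5 ms and coarser).  Simulations are bitwise
deterministic for fixed inputs.

## Biomarkers

Durations are measured from the instant of maximal upstroke slope (earliest
sample attaining the maximum, which makes the convention exact on
piecewise-linear fixtures) to the first linear-interpolated crossing of
`peak − fraction·(peak − rest)`, with rest taken at the first (pre-stimulus)
sample.  A beat that never recrosses the threshold yields a
`NO_REPOL` sentinel; flagged components propagate through concentration
averaging, and flagged (drug, sample) rows are excluded from the assembled
dataset with a logged count rather than imputed — imputation would have to
invent a duration for a failed repolarisation, which is exactly the signal
the flag carries.

qNet integrates the six-current sum (IKr, ICaL, INaL, Ito, IKs, IK1) by the
trapezoid rule on the output grid; with currents in µA/µF and time in ms
its unit is µC/µF.  qInward is the mean of the drug/control integral ratios
of INaL and ICaL; the control run uses the same model/protocol with zero
block and is computed once per feature-extraction pass.  Zero control
integrals raise a degenerate-control error.

Each (drug, Hill-sample) is simulated at 4 multiples of Cmax (1–4×) and the
nine biomarkers are averaged arithmetically across the four concentrations
to give one feature row.

## Classifier

`RiskANNClassifier` is a numpy implementation of a small
softmax network: 9 → h1 → h2 → 3 with leaky-ReLU activations, categorical
cross-entropy, and an elastic penalty (L1 = L2 = 0.01 by default) applied
to the first hidden layer's weight matrix only.  Minibatch Adam or RMSprop,
seeded Glorot-uniform initialisation, per-feature z-scoring fitted on the
training rows inside `fit` (required for the larger grid learning rates to
be meaningful).  Training is deterministic given the seed.

Grid search enumerates the full Cartesian product of the tuned sets
(batch 32/64; RMSprop/Adam; 5–7 neurons per hidden layer, searched
independently per layer since the reference architecture has 6 and 5;
learning rate 0.1/0.01/0.001; leaky-ReLU slope 0.1/0.01/0.001/0.2/0.02/
0.002) under stratified, seeded 10-fold cross-validation.  The selection
metric — never named by the reference protocol — is mean validation
accuracy; ties break by enumeration order.  Class order is fixed to
(high, intermediate, low) everywhere, including probability columns.
Models serialise to a single JSON artifact (format-versioned; newer
versions are refused on load).

The ordinal baseline is a single-feature proportional-odds model
`P(Y ≤ k | x) = σ(c_k − βx)` with two ordered thresholds, fitted by
bounded L-BFGS-B maximum likelihood on the standardized covariate
(|β| capped at 20; hitting the cap flags probable perfect separation).
An independent statsmodels `OrderedModel` fit cross-checks slope and
log-likelihood in the test suite.

## Evaluation protocol

Each bootstrap iteration draws exactly one biomarker sample per test drug
(uniformly over that drug's rows).  This one-per-drug reading is an
inference from the granularity of reported AUC values (on a 16-drug panel
split 4/7/5, one-vs-rest AUCs live on lattices of 1/48, 1/63 and 1/55
half-steps — a property the test suite asserts).  Per class: AUC from the
class-probability ranking (rank-based concordance, ties counted half,
verified against an exhaustive pairwise oracle and scikit-learn), and
sensitivity/specificity from argmax predictions, giving
LR⁺ = sens/(1−spec) and LR⁻ = (1−sens)/spec with zero denominators clipped
at ε = 10⁻⁶ and flagged.  Summaries are the median and empirical 2.5/97.5
percentiles (linear interpolation) over iterations; the mean classification
error gets mean ± 1.96·SD/√N with N = total test rows.

## Shapley explanations

The value function is the interventional expectation over a background
sample: features in S come from the explained row, the rest from the
background row, averaged over the background.  With p = 9 all 512 subsets
are enumerated exactly; the explanation target is the per-class softmax
probability (matching the risk-probability framing), and the default
background is 100 seeded training rows.  A permutation sampler with
reported Monte-Carlo standard error covers larger feature sets.  Global
importance is mean |φ| per class and aggregated; ties break alphabetically.
Feature-reduction experiments retrain on nested top-k prefixes of a
ranking and re-run the bootstrap protocol.  `REPORTED_RANKING` preserves
the published reduction-group ordering (qInward, qNet, CaD50, CaD90,
APD50, then APD90, Ca_rest, Vm_rest, dVm/dt_max) for reproducing the
grouping logic with a fixed ranking.

## Synthetic data

`gen_dose_response` places 8 log-spaced doses over [IC50/30, 30·IC50] and
adds clipped Gaussian noise (sd 0.02 by default — tight, automated
patch-clamp-like replicates).  `gen_trace_fixture` builds piecewise-linear
AP/Ca beats whose biomarkers are exact arithmetic consequences of the
requested parameters, plus constant/sine/pulse current waveforms with
closed-form integrals for the charge-metric oracles.  `gen_feature_table`
draws drug-level means per class (separation `effect_size` population sd,
default 2; drug scatter 0.5 sd; per-sample scatter 1 sd) with the
class-conditional directions of the expected pharmacology — high-risk
drugs carry prolonged APD/CaD, reduced qNet and a shifted qInward
signature — so explanation sanity checks have a known answer.  It does not
emulate the IC50–h posterior correlation of real fits, assay-specific
noise structure, or multichannel pharmacological realism; passing tests on
these tables demonstrates correct pipeline mechanics and statistical
behaviour, not clinical performance.

The null-discrimination check uses 12 test drugs per class: with one sample
per drug per iteration, the chance AUC of a small fixed drug panel has
large variance (sd ≈ 0.15 at 3 + 6 drugs), and only a larger panel makes
the chance distribution concentrate near 0.5.

## Execution profiles and problem sizes

The `desk` profile (default) runs 20 Hill samples, 50-beat pacing with the
representative beat chosen among the last 25, 500 bootstrap iterations and
a reduced training schedule; the `paper` profile sets the full-scale
parameters (2,000 samples, 1,000 beats, selection among the last 250,
10,000 iterations, 200 epochs), which is cluster-scale work.  The test
suite and the acceptance script use desk-scale sizes throughout (50-beat
electrophysiology checks, 100 × MCMC replicates at 400 retained draws,
2,000-iteration bootstrap summaries); these sizes are stated in the
relevant docstrings.

## Known limitations

* The surrogate cell is directionally faithful but not quantitatively
  comparable to detailed human-ventricular models; qNet/qInward magnitudes
  are model-specific.
* The MCMC stand-in is not guaranteed to match the posterior spread of the
  reference fitting code (priors/likelihood unpublished).
* Extreme likelihood ratios depend on the clipping constant; only their
  order of magnitude is meaningful.
* No dynamic (state-dependent) hERG binding, no tissue-level simulation,
  no calibration to in-vivo outcomes.
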