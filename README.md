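# cagc — Granger causality for single-cell calcium imaging

`cagc` infers **directed functional connectivity** from population calcium
imaging recorded at single-cell resolution.  Plain correlation tells you
which neurons are co-active; Granger causality (GC) asks the directional
question: does the *past* of neuron Y improve the prediction of neuron X
beyond what X's own past (and, in the conditioned variant, everyone else's
past) already provides?

Applying GC naively to DF/F traces goes wrong in well-understood ways —
slow calcium decay, correlated measurement noise, motion artifacts,
non-Gaussian bursting — and this package implements the corrections that
make it work in practice, together with synthetic network simulators so
every stage can be validated against ground truth.  It is aimed at
experimentalists and analysts working with recordings of tens of neurons
(zebrafish spinal cord and hindbrain being the motivating systems).

## The statistic

For a target trace $x_t$ and candidate driver $y_t$, two nested OLS
autoregressions are fitted over lags $1..L$:

$$
\text{reduced: } x_t = \tilde a_0 + \sum_{q=1}^{L} \tilde a_q x_{t-q} + \tilde\varepsilon_t,
\qquad
\text{full: } x_t = a_0 + \sum_{q=1}^{L} a_q x_{t-q} + \sum_{q=1}^{L} b_q y_{t-q} + \varepsilon_t .
$$

Their residual comparison gives the F-statistic
$F_{Y\to X} = \frac{(\mathrm{RSS}_r-\mathrm{RSS}_f)/(M_f-M_r)}{\mathrm{RSS}_f/(T_{\mathrm{regr}}-M_f)}$
and the GC value
$GC_{Y\to X} = \max\!\big(\ln \frac{\mathrm{RSS}_r/(T_{\mathrm{regr}}-M_r)}{\mathrm{RSS}_f/(T_{\mathrm{regr}}-M_f)},\,0\big)$,
a monotone transform of $F$.  The multivariate variant (MVGC) adds every
other recorded neuron (and any stimulus series) to both models, separating
direct from indirect influence.

What makes the pipeline calcium-specific:

* **Preprocessing** — global single-timepoint motion artifacts are
  detected and interpolated away; neurons with tens-of-seconds decays or
  no oscillating activity are removed; traces are denoised by
  total-variation regularization of the derivative (an L1 penalty on the
  trace's second difference), which removes correlated white noise while
  keeping the fast calcium onsets sharp.
* **Lag selection** — the maximum lag $L$ is chosen at the knee of the
  mean-GC-versus-lag curve.
* **Adaptive significance** — the analytic F-test is exact only for
  Gaussian i.i.d. residuals.  The true null is built by cyclically
  rotating (or, for stimulus-locked data, epoch-permuting) the driver
  trace, refitting $F$ over hundreds of shuffles, and ML-fitting a
  two-parameter F-distribution to the ensemble; a link is significant if
  its observed $F$ exceeds the fitted $(1-p)$ quantile.  Dividing $F$ by
  the ensemble mean ("normalized GC") additionally removes the
  signal-to-noise bias of the naive statistic.
* **Metrics** — ipsilateral weight ratio WIC, rostrocaudal ratio WRC,
  per-neuron drive, link-recovery error rates, and a position-normalized
  polar histogram of link directions.
* **Simulators** — a 10-neuron benchmark network run under VAR, Poisson-
  GLM and GLM-calcium dynamics, plus a two-chain bursting "motoneuron"
  generator with stimulus gating, calcium convolution and imaging-rate
  downsampling.

## Worked example

Simulate two chains of five motoneurons gated by alternating left/right
stimuli, then fit conditioned GC with the shuffle-based threshold:

```python
from cagc import (ChainStimulusParams, GrangerCausality,
                  simulate_motoneuron_chains, directional_metrics)

sim = simulate_motoneuron_chains(ChainStimulusParams(duration=600.0, seed=0))
model = GrangerCausality(sim.recording, lag=1, mode="mvgc")
result = model.fit(significance="adaptive", n_shuffles=100, seed=0)
print(result.summary())

dm = directional_metrics(result, sim.recording)
print(f"WIC = {dm.wic:.3f}")
print(f"WRC = {dm.wrc:.3f}")
```

```
Granger causality results
=========================================
mode:                 mvgc
neurons:              10
maximum lag L:        1
regression samples:   2399
params (full/red.):   11/10
significance rule:    adaptive cyclic-shuffle threshold, p=0.05
significant links:    39/90
mean GC value:        0.0268144
mean significant GC:  0.0261395
=========================================
WIC = 0.980
WRC = 0.560
```

Of the 90 ordered neuron pairs, 39 carry a significant directed link.
WIC = 0.98 says essentially all recovered information flow is ipsilateral
(0.5 would mean no side bias; the residual 0.02 reflects the genuine
left-to-right stimulus timing in the generative model), and WRC = 0.56 a
rostral-to-caudal bias beyond the 0.5 null — with a 2.5 s calcium decay
sampled at 4 Hz, directionality within a chain is partly washed out,
exactly the regime the simulator probes.

The same pipeline is available from the shell:

```bash
cagc simulate chains --out rec.h5 --seed 0
cagc pipeline rec.h5 --out results/ --mode mvgc --significance adaptive
```

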