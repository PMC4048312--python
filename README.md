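# gtenet

Reconstruction of directed excitatory **and inhibitory** synaptic
connectivity in (simulated) neuronal cultures from calcium-imaging
fluorescence, using **Generalized Transfer Entropy** (GTE), plus the
complete in-silico laboratory needed to validate it: a bursting
integrate-and-fire culture simulator with short-term synaptic
depression, a calcium-fluorescence forward model with camera noise and
light scattering, and ROC/labeling evaluation against the known ground
truth.

It is written for computational neuroscientists who want to (a) test
connectivity-inference methods on realistic surrogate calcium data with
a known connectome, or (b) apply state-conditioned transfer entropy to
their own per-neuron fluorescence traces.

## The method in brief

For every ordered neuron pair (i → j) the pipeline computes a
transfer-entropy score on binarized fluorescence increments,

    GTE(i→j) = Σ p(y_{t+1}, y_t^(k), x_t^(k+s)) ·
               log₂ [ p(y_{t+1} | y_t^(k), x_t^(k+s)) / p(y_{t+1} | y_t^(k)) ],

with two extensions to plain transfer entropy: the sum runs only over
frames where the **population-average fluorescence lies below a
conditioning level** (the inter-burst regime, where pairwise causal
influences track direct synaptic links instead of network-wide burst
recruitment), and an optional shift s = 1 (the *instantaneous feedback
term*, IFT) includes the source's same-frame value, compensating for
frame intervals much longer than synaptic delays. Traces are high-pass
filtered with a discrete difference and symbolized by the optimal
two-Gaussian threshold ΔF/2 + (σ²/ΔF)·ln((1−p)/p). Scores are
thresholded into a reconstructed network and scored by ROC analysis
(true-positive vs false-positive link ratios) against the ground truth.

To resolve link *types*, the same network is analyzed in two
pharmacological conditions — inhibition active ("E+I") and blocked
("E-only", bicuculline in vitro, zeroed inhibitory weights in silico).
Excitatory links appear in both reconstructions, so the score **sum**
ranks them; inhibitory links exist only with inhibition active, so the
score **difference** (E+I minus E-only) ranks those. Neurons are then
labeled by the difference of their putative excitatory and inhibitory
out-degrees in high-purity (≤5 % false positive) subnetworks, and the
labeling accuracy is tested against an exact binomial chance model.

See `docs/methods.md` for the full model equations, parameter tables
and design decisions.

## Worked example

```python
from gtenet import (DynamicsParams, FluorescenceParams, GTEParams,
                    generate_er_network, rewire_to_target_clustering,
                    simulate, synthesize_recording, detect_bursts,
                    select_conditioning_level, gte_matrix,
                    roc_curve, tpr_at_fpr, clustering_coefficient)

net = generate_er_network(n_neurons=100, p_connect=0.12,
                          frac_excitatory=0.8, seed=1)
net = rewire_to_target_clustering(net, target_cc=0.5, seed=1)
print(f"CC = {clustering_coefficient(net.adjacency):.4f}")

params = DynamicsParams(dt=0.2)          # E+I condition, calibrated coupling
raster = simulate(net, params, duration=1500.0, seed=3)
stats = detect_bursts(raster)
print(f"burst rate = {stats.burst_rate:.3f} Hz, "
      f"interburst firing = {stats.interburst_firing_rate:.2f} Hz")

rec = synthesize_recording(raster, net, FluorescenceParams(), seed=4)
gte = GTEParams(conditioning_level=select_conditioning_level(rec),
                spike_amplitude=0.143, noise_sd=0.045,
                firing_prob_per_frame=stats.interburst_firing_rate * 0.02)
scores = gte_matrix(rec, gte)
curve = roc_curve(scores.scores, net.adjacency)
print(f"AUC = {curve.auc:.3f}, TPR@10%FPR = {tpr_at_fpr(curve, 0.10):.3f}")
```

Output (exact numbers vary with the seed and network):

```
CC = 0.4996
burst rate = 0.058 Hz, interburst firing = 0.25 Hz
AUC = 0.860, TPR@10%FPR = 0.613
```

Read: the rewiring hit the target clustering within 0.1 %; the culture
bursts irregularly (here about every 17 s — use
`calibrate_synaptic_strength` to pin the burst rate of a specific
network to a target) with sparse ~0.25 Hz firing in between, like a
real preparation; and from fluorescence alone — noise, saturation and
scattering included — GTE separates true from spurious synapses with
an ROC area of 0.86, recovering ~60 % of the true links at a 10 %
false-positive budget. `docs/methods.md` discusses what limits this
rate (spike-detection loss at realistic imaging noise and the
directionality ambiguity of same-frame interactions).

The same pipeline is scriptable from the shell:

```bash
gtenet netgen --n 100 --p-connect 0.12 --target-cc 0.5 --seed 1 --out net.txt
gtenet simulate --network net.txt --duration 1500 --seed 3 --out raster.txt
gtenet fluoresce --raster raster.txt --network net.txt --seed 4 --out fluo.txt
gtenet gte --fluorescence fluo.txt --out scores.txt
gtenet evaluate --scores scores.txt --truth net.txt
```

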