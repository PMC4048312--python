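# Methods

`gtenet` reproduces, end to end and purely in silico, a study design for
reconstructing the directed synaptic connectivity of a bursting neuronal
culture from calcium-imaging data, and for labeling neurons and links as
excitatory or inhibitory by combining recordings made with inhibition
active ("E+I") and pharmacologically blocked ("E-only"). This note
documents the models, the estimator, every tunable that matters, and the
design choices made where the original description leaves the design
open.

## 1. Ground-truth networks

Networks are directed Erdős–Rényi graphs: `n = 100` neurons placed
uniformly at random in a 1 mm² square, each ordered pair connected
independently with `p = 0.12`, each neuron excitatory with probability
0.8 (inhibitory otherwise). The average full directed clustering
coefficient (Fagiolo's definition: per-node directed-triangle count
normalized by `d(d-1) - 2d_bi`, averaged over nodes, zero-denominator
nodes contributing 0) is then raised from its ER value (~0.12) to a
target of 0.5 by degree-preserving double-edge swaps: two random links
i→j and k→l are replaced by i→l and k→j, and a proposal is accepted only
if it creates no self-loop or duplicate, strictly increases the
clustering coefficient, and does not overshoot the upper edge of the
0.1 % relative tolerance band. Link count, in/out degrees, neuron types
and positions are conserved exactly. The swap-acceptance rule is our
choice (the construction is only named, not specified, in the original account); it is
seed-deterministic and converges for the study sizes in a few seconds.

## 2. Culture dynamics

Leaky integrate-and-fire neurons with conduction delays, alpha-shaped
synaptic currents, and Tsodyks–Markram short-term depression at the
presynaptic terminals. Membrane equation (voltages mV, times ms):

    tau_m dV/dt = -(V - V_rest) + (I_E - I_I + I_ext + eta) / g_leak

with `tau_m = 30`, `V_rest = -60`, threshold `-45`, reset `-58`,
refractory 3 ms. A spike of presynaptic neuron i injects, after a
per-link conduction delay (2 ± 1 ms, uniform), an alpha current
`g · Y_i · (t/tau_a) e^(1 - t/tau_a)`, where `Y_i = beta · R_i` is the
fraction of synaptic resources released by that spike. The rise time is
receptor-specific: `tau_a = 2 ms` for excitatory (AMPA-like) currents
and 8 ms for inhibitory (GABA_A-like) ones, whose kinetics are several
times slower than AMPA's; the slower inhibitory kernel also means an
inhibitory influence spans an appreciable part of one 20 ms imaging
frame. Resource kinetics per presynaptic neuron: on a spike an
amount `beta R` moves from the recovered pool R to the active pool A;
A decays to the inactive pool with `tau_inact = 3 ms`; the inactive pool
recovers with `tau_rec` (excitatory and inhibitory terminals have their
own recovery constants). Inhibitory links inject the sign-reversed
current; "blocking inhibition" zeroes their postsynaptic weight while
inhibitory neurons keep firing, and is bit-identical to scaling
inhibitory weights to zero under the same seed.

Spontaneous activity has two sources, mirroring the η noise term and the
external-drive protocol of the study design:

* **Poisson kicks** — an independent per-neuron Poisson train of
  excitatory alpha-kicks at `background_rate = 0.16 Hz`. External
  stimulation is modeled exactly as stated in the original protocol: the
  Poisson rate is increased by `external_drive_rate`, with no spatial
  structure. The kick peak current is set so that a single kick
  produces a just-subthreshold EPSP (the tau_a = 2 ms alpha current is
  attenuated ~×0.14 by the membrane filter), so a kick fires the neuron
  with probability well below 1 and the firing-rate response to the
  drive stays sublinear and below 3 Hz over the protocol range.
* **Ornstein–Uhlenbeck membrane noise** with stationary standard
  deviation 4 mV (exact discretization, dt-robust). This is our
  realization of the membrane-noise term: without it, subthreshold EPSPs
  would be deterministically invisible, single-spike transmission would
  have probability ~0 between bursts, and no algorithm could recover
  connectivity from inter-burst data. With it, a single EPSP of a few mV
  raises the postsynaptic firing probability by a few percent per event,
  which is the causal signal the estimator detects.

Numerical scheme: fixed-step exponential-Euler for the membrane and the
(linear) synaptic filter states — each alpha synapse is two exactly
integrated first-order states, so superposed kernels are exact at step
boundaries — with a ring buffer for delayed deliveries. Spikes are
detected at step boundaries, so the single-neuron inter-spike-interval
oracle holds to within 2·dt. Default dt = 0.1 ms; the pipeline-scale
runs use 0.2 ms (a tenth of the smallest time constant), and a
convergence test checks that halving dt changes spike counts of a
deterministic probe by <2 %. Non-finite membrane state raises an
integration error naming the step.

**Depression constants.** `tau_rec` (excitatory) = 800 ms, `tau_rec`
(inhibitory) = 100 ms, `beta = 0.5`. These sit in the classical
depressing-synapse range and were chosen — once — to satisfy three
observables of the study conditions simultaneously: (i) spontaneous
network bursts at ~0.1 Hz whose termination is caused by resource
depletion within the 100–200 ms burst; (ii) inter-burst firing that
keeps most synaptic resources recovered, so pairwise transmission is
detectable between bursts; (iii) under a weak external drive raising
firing to 1–3 Hz, only partial depression (steady-state R ≈ 0.5–0.8),
so the network remains coupled and reconstruction *improves* with the
larger event count instead of collapsing. Strongly depleting synapses
(e.g. beta 0.8 with multi-second recovery) satisfy (i) but fail (iii):
at 3 Hz they drive steady-state R below 0.1 and functionally decouple
the network.

**Coupling calibration.** The single free coupling g (shared by all
synapses; inhibitory weights use the same magnitude) is calibrated by
bisection on probe simulations against the target network burst rate:
0.10 Hz with inhibition blocked, 0.12 Hz with inhibition active, each
condition calibrated separately, exactly as the original study
prescribes. Burst detection (needed to operationalize the burst rate):
a burst is a maximal run of 50 ms windows in which at least 40 % of all
neurons fire; both constants are configurable since no operational
definition is given in the original study. The inter-burst firing rate is the
mean per-neuron rate outside burst windows.

## 3. Calcium fluorescence forward model

Each spike adds 50 µM to the dye-bound calcium concentration, which
unbinds with `tau_ca = 1 s`; the sampled concentration at the camera
frame boundary (frame interval 20 ms, i.e. 50 fps) is computed exactly
(no intra-frame discretization error). The emitted fluorescence is a
saturating Hill readout, `F = c^h / (c^h + K_d^h)` with `K_d = 300 µM`
and `h = 1` (saturation level normalized to 1), plus i.i.d. Gaussian
camera noise of standard deviation 0.03 per frame: a single spike from
rest produces ΔF ≈ 0.14, a per-frame signal-to-noise ratio of ~5 on the
raw trace. Light scattering adds to each trace a fraction
`A_sc = 0.15` of every other cell's fluorescence weighted by an
*unnormalized* Gaussian kernel of the mutual distance with width
50 µm. Noise is added at the cell and then mixed by the scattering
operator (the equation order of the model); a flag provides the other
order. The kernel width matters: at 150 µm in this 100-neuron/1 mm²
culture, scattered crosstalk becomes comparable to a cell's own
single-spike signal and produces spatially correlated false detections
that cap reconstruction quality; 50 µm — a realistic point-spread scale
for soma-resolved imaging — keeps scattering a perturbation. Inverse
(correction) filtering of scattering is deliberately out of scope.

## 4. Generalized Transfer Entropy

The estimator sees only the fluorescence matrix. Stages:

1. **Difference filter**: `out[t] = F[t+1] - F[t]` (high-pass).
2. **Symbolization** into binary spike indicators by a sharp threshold.
   The optimal threshold for a two-Gaussian mixture of the differenced
   trace — no-spike frames N(0, σ²) with weight 1-p, spike frames
   N(ΔF, σ²) with weight p — is `ΔF/2 + (σ²/ΔF) ln((1-p)/p)`,
   verified in the tests against a grid-search maximizer of the
   correct-mapping probability. σ here is the noise scale of the
   *differenced* trace; the pipeline estimates it robustly from the data
   (median absolute deviation), which also absorbs the scattering
   contribution, and estimates p from the measured inter-burst rate.
   Ties at the threshold map to 0 (threshold-level samples are
   noise-dominated). Reconstruction is insensitive to threshold
   inflation up to ~30 % above the optimum.
3. **Conditioning (state selection)**: only frames whose population-
   average raw fluorescence lies below the conditioning level enter the
   estimate — the inter-burst regime, where pairwise interactions
   reflect direct links rather than network-wide burst recruitment. The
   level is placed at the transition between the Gaussian-like noise
   core of the population-average histogram and its bursting right
   tail: robustly, median + 3 × (median − 15.87th percentile). A sample
   at differenced index t is used only if *all* frames it touches
   (t-k+1 … t+1) are below the level.
4. **Plug-in TE at Markov order k = 2** (configurable), in bits. For
   the pair x→y, joint states (y_next, y_past^k, x_past^k) are counted
   by integer-packing the (2k+1)-bit word into a histogram; the tests
   verify exact count-level agreement with a naive dictionary-counting
   implementation. With the **instantaneous feedback term** (IFT)
   enabled, the source window is shifted one frame forward to include
   the same bin as y_next — necessary when synaptic delays (ms) are far
   below the frame interval (20 ms), at the price of inflating
   bidirectional calls. IFT is on by default for spontaneous recordings
   and off for stimulated ones, following the observed regime
   dependence. No delay embedding and no estimator bias correction are
   applied.

Scores are ≥ 0 up to plug-in fluctuation; the diagonal is undefined
(NaN). With the conditioning level at +∞ and IFT off the estimator
reduces exactly to conventional transfer entropy.

## 5. Evaluation and E/I labeling

Reconstructed networks keep the top fraction of off-diagonal scores
(deterministic tie-break: score desc, source id, target id). ROC curves
sweep all distinct thresholds; TPR = recovered true links / true links,
FPR = included non-links / non-links, diagonal excluded; AUC by
trapezoid; TPR at a target FPR by linear interpolation. The
implementation is cross-checked against scikit-learn's ROC and against
brute-force enumeration on small instances.

Link-type separation without a-priori knowledge combines the two
conditions: `sum = EI + Eonly` ranks putative excitatory links (present
in both), `diff = EI - Eonly` ranks putative inhibitory links (present
only with inhibition active); only rank order is used. For neuron
labeling, both matrices are thresholded at a high-purity level — the
largest score-ranked link set whose false-positive ratio stays ≤ 5 %
(computable in simulation where the truth is known; a plain link-count
fraction is exposed for blind use) — links appearing in both subnetworks
(impossible under Dale's principle) are removed and counted, each neuron
is ranked by `d_i = outdeg_E(i) - outdeg_I(i)`, and the top prior
fraction (0.8) is labeled excitatory, ties broken by id. Labeling
significance per class uses the binomial chance model: under random
assignment respecting known class fractions, a class-q neuron is
correctly labeled with probability q, so the number of correct calls is
Binomial(N_class, q); we report the upper-tail probability and call the
labeling significant below α = 0.05. A pooled-chance variant
(q = f_E² + f_I²) is available behind a flag. The expected number of
chance spike coincidences between two unconnected neurons,
`N · (f · window)²`, is provided as a utility and verified against
Poisson simulation.

## 6. What the synthetic data does and does not emulate

The generator reproduces the dynamical signatures the study design
states: irregular network bursts (~0.1 Hz blocked / 0.12 Hz intact,
~10 s inter-burst intervals, 100–200 ms width), low inter-burst firing,
a right-skewed population-fluorescence histogram whose burst tail
shortens when inhibition is active, saturating calcium responses,
camera noise and scattering crosstalk. It does not emulate: dye
bleaching, motion artifacts, ROI segmentation errors,
distance-dependent connectivity, conductance-based membrane dynamics,
long-term plasticity, or spatially patterned stimulation. Passing tests
on this data therefore demonstrates the estimator's behavior under the
stated model class, not performance on arbitrary real recordings — in
particular, real cultures may have lower inter-burst rates and unknown
single-spike fluorescence amplitudes, the two quantities this pipeline
estimates from the data.

## 7. Problem sizes and numerical choices

Defaults reproduce the study conditions (100 neurons, 1 h recordings,
5 network realizations). The test suite and the acceptance script run
the same pipeline at reduced scale — 20–25 simulated minutes per
condition, 3 realizations, dt = 0.2 ms, calibration on the first
realization's network with 4–6 bisection probes of 240–300 s — sizes
chosen so the full recomputation stays at desk scale; reconstruction
quality at these durations is within a few points of the 1 h runs
(estimator statistics saturate once conditioned samples reach ~10⁵).
Degenerate inputs are handled explicitly: empty rasters yield zero
fluorescence and zero burst statistics; constant population signals
raise an error in level selection; all-ones/all-zeros ground truth
raises a degenerate-ROC error; insufficient conditioned samples warn
and flag the estimate rather than failing.

## 8. Reproduction fidelity

With all constants frozen as above, the pipeline reproduces the
*qualitative* structure of the study faithfully — bursting regimes and
their calibration, the right-skewed fluorescence histogram with a
shorter E+I tail, the benefit of conditioning, the failure of
spontaneous-regime neuron labeling, and the large improvement of
labeling under weak stimulation — while the *quantitative*
reconstruction rates at 10 % false positives run some 15–25 percentage
points below the printed reference values. Three measured mechanisms
account for this, all documented by the diagnostic scripts used during
development: (i) at the chosen signal-to-noise ratio the optimal sharp
threshold detects only ~50–60 % of inter-burst spikes in the
differenced trace; on perfectly detected spike frames the same
estimator reaches a true-positive rate near 0.9, so roughly half the
gap is detection loss in the imaging model; (ii) the instantaneous
feedback term — indispensable here, since without it inhibitory-link
detection collapses to chance — makes roughly a third of the
top-scoring false positives reverse duplicates of true links, a
directionality ambiguity the source method acknowledges; (iii) the
performance is insensitive to recording length beyond ~25 simulated
minutes, confirming the ceiling is systematic rather than statistical.
Since several of the original pipeline's numeric constants (camera
noise, per-spike fluorescence jump, scattering scale, conditioning
level placement) could not be recovered and had to be chosen
independently, the per-cent-level agreement of those headline rates is
not expected; the property-level checks (estimator exactness, oracle
agreement, calibration, monotonicities) are the meaningful gate.

## 9. Known limitations

* The inhibitory-link reconstruction from the difference of conditions
  is the weakest stage, as in the original study; its quality depends
  sensitively on the two recordings having comparable event statistics,
  and degrades when the two conditions' firing regimes differ.
* The external-drive axis is calibrated in units of the added Poisson
  rate; its mapping to the resulting firing rate is model-specific, so
  drive values should be compared through the firing-rate response
  curve rather than nominally.
* Plug-in TE is biased upward by finite samples; scores are comparable
  within a recording (rank order is what the pipeline uses), not across
  recordings of very different lengths.
* The high-purity labeling threshold uses the true FPR in simulation;
  blind use on real data requires choosing a link-count fraction.
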