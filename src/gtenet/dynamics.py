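"""Leaky integrate-and-fire simulation of a bursting neuronal culture.

Neurons are leaky integrate-and-fire units coupled by alpha-shaped
excitatory (AMPA-like) and inhibitory (GABA-like) currents with axonal
conduction delays.  Presynaptic terminals undergo Tsodyks–Markram
short-term depression, which terminates network bursts and sets the slow
inter-burst time scale.  Spontaneous activity is driven by independent
per-neuron Poisson trains of excitatory kicks; an external stimulation
protocol is modeled purely as an increase of that Poisson rate.  Blocking
inhibition (the in-silico analogue of bicuculline) zeroes the postsynaptic
effect of inhibitory links while inhibitory neurons keep firing.

Membrane equation (voltages in mV, times in ms):

    tau_m dV/dt = -(V - V_rest) + (I_E(t) - I_I(t) + I_const + eta) / g_leak

where I_E and I_I are sums of alpha kernels ``w (t/tau_a) exp(1 - t/tau_a)``
over delayed presynaptic spike arrivals, each weighted by the coupling g
and by the fraction of synaptic resources released by that spike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .errors import CalibrationError, IntegrationError, ParameterError, ValidationError
from .topology import EXCITATORY, GroundTruthNetwork

__all__ = [
    "DynamicsParams",
    "SpikeRaster",
    "BurstStatistics",
    "alpha_current",
    "depression_step",
    "simulate",
    "detect_bursts",
    "calibrate_synaptic_strength",
    "mean_firing_rate",
]


@dataclass
class DynamicsParams:
    """Parameters of the culture model.

    Default constants follow the Tsodyks–Uziel–Markram class of bursting
    culture models: a 15 mV threshold gap and depressing synapses whose
    depletion terminates network bursts, while noise-assisted ignition
    keeps bursts rare (~0.1 Hz).  The coupling ``synaptic_strength_g`` is
    the free parameter calibrated against the target network burst rate.
    """

    v_rest: float = -60.0          # mV
    v_threshold: float = -45.0     # mV
    v_reset: float = -58.0         # mV
    tau_membrane: float = 30.0     # ms
    g_leak: float = 1.0            # dimensionless (currents expressed in mV)
    refractory_time: float = 3.0   # ms
    synaptic_strength_g: float = 74.0  # mV peak current per fully-recovered spike
    delay_mean: float = 2.0        # ms, axonal conduction
    delay_jitter: float = 1.0      # ms, uniform half-width per link
    alpha_rise_tau: float = 2.0    # ms, synaptic rise time (AMPA-like)
    alpha_rise_tau_inh: float = 8.0  # ms, inhibitory rise time (GABA_A-like,
    # slower than AMPA; its influence spans a 20 ms imaging frame)
    tau_recovery_exc: float = 800.0    # ms, resource recovery, E terminals
    tau_recovery_inh: float = 100.0    # ms, resource recovery, I terminals
    tau_inactivation: float = 3.0      # ms, active -> inactive pool
    release_fraction_beta: float = 0.5  # fraction of R released per spike
    background_rate: float = 0.16  # Hz, spontaneous Poisson kicks per neuron
    external_drive_rate: float = 0.0   # Hz, added stimulation
    background_amplitude: float = 75.0  # mV, peak current of one background kick
    # (the membrane filter attenuates a tau_a=2 ms alpha current by ~x0.14,
    # so one kick gives a ~10.7 mV EPSP: subthreshold, fires with the help
    # of membrane noise -> sublinear drive response capped below ~3 Hz)
    noise_amplitude: float = 4.0   # mV, stationary std of membrane (OU) noise
    constant_current: float = 0.0  # mV, tonic input (testing/oracles)
    dt: float = 0.1                # ms integration step
    inhibition_blocked: bool = False
    inhibitory_weight_scale: float = 1.0  # multiplies inhibitory weights

    def __post_init__(self):
        if self.v_reset >= self.v_threshold:
            raise ParameterError("v_reset must be below v_threshold")
        for name in ("tau_membrane", "alpha_rise_tau", "alpha_rise_tau_inh",
                     "tau_recovery_exc",
                     "tau_recovery_inh", "tau_inactivation", "dt"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 < self.release_fraction_beta <= 1:
            raise ParameterError("release_fraction_beta must be in (0, 1]")
        if self.background_rate < 0 or self.external_drive_rate < 0:
            raise ParameterError("Poisson rates must be non-negative")
        smallest = min(self.tau_membrane, self.alpha_rise_tau,
                       self.alpha_rise_tau_inh, self.tau_recovery_exc,
                       self.tau_recovery_inh, self.tau_inactivation)
        if self.dt > smallest / 10:
            warnings.warn(
                f"dt={self.dt} ms exceeds a tenth of the smallest time "
                f"constant ({smallest} ms); integration may be inaccurate",
                stacklevel=2,
            )


@dataclass
class SpikeRaster:
    """Spike events of a simulation, ordered by time."""

    times: np.ndarray      # s
    ids: np.ndarray        # neuron indices
    duration: float        # s
    n_neurons: int

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.times.shape != self.ids.shape:
            raise ValidationError("times and ids must have equal length")
        if self.times.size and (self.times.min() < 0 or self.times.max() > self.duration):
            raise ValidationError("spike times must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class BurstStatistics:
    burst_times: np.ndarray   # s, burst onset times
    burst_rate: float         # Hz
    interburst_firing_rate: float  # Hz per neuron, outside burst windows
    duration: float


def alpha_current(t_since_arrival, alpha_rise_tau: float):
    """Alpha synaptic kernel, unit peak at ``t = alpha_rise_tau``.

    ``a(t) = (t/tau) exp(1 - t/tau)`` for t >= 0 and 0 before arrival.
    """
    if alpha_rise_tau <= 0:
        raise ParameterError("alpha_rise_tau must be positive")
    t = np.asarray(t_since_arrival, dtype=float)
    out = np.where(t >= 0, (t / alpha_rise_tau) * np.exp(1.0 - t / alpha_rise_tau), 0.0)
    if np.ndim(t_since_arrival) == 0:
        return float(out)
    return out


def depression_step(state, spike: bool, params: DynamicsParams,
                    dt: float | None = None, is_excitatory: bool = True):
    """Advance the (recovered R, active A) resource pools by one step.

    On a spike an amount ``beta * R`` moves from the recovered to the
    active pool (and is the transmitted amplitude fraction); the active
    pool decays to the inactive pool with ``tau_inactivation`` and the
    inactive pool recovers with the type-specific recovery constant.
    Returns ``(R, A, released)``.
    """
    r, a = state
    if not (0 <= r <= 1 and 0 <= a <= 1 and r + a <= 1 + 1e-12):
        raise ValidationError("resource fractions must satisfy R, A, R+A in [0, 1]")
    dt = params.dt if dt is None else dt
    tau_rec = params.tau_recovery_exc if is_excitatory else params.tau_recovery_inh
    released = 0.0
    if spike:
        released = params.release_fraction_beta * r
        r -= released
        a += released
    a_new = a * np.exp(-dt / params.tau_inactivation)
    r_new = r + dt * (1.0 - r - a) / tau_rec
    return min(max(r_new, 0.0), 1.0), min(max(a_new, 0.0), 1.0), released


@njit(cache=True, fastmath=True)
def _run_network(
    n_steps, dt, n,
    indptr, indices, delays_steps, link_weight,
    v_rest, v_threshold, v_reset, tau_m, g_leak, ref_steps,
    tau_alpha, tau_alpha_inh, tau_rec, tau_inact, beta,
    kick_steps, kick_ids, kick_amp,
    noise_amp, const_current, noise_seed,
    max_spikes,
):
    """Fixed-step exponential-Euler integration with a delay ring buffer."""
    em = np.exp(-dt / tau_m)
    ea = np.exp(-dt / tau_alpha)
    gain = np.e / tau_alpha * dt
    ea_i = np.exp(-dt / tau_alpha_inh)
    gain_i = np.e / tau_alpha_inh * dt
    ein = np.exp(-dt / tau_inact)
    inv_g_leak = 1.0 / g_leak
    inv_tau_rec = dt / tau_rec

    v = np.full(n, v_rest)
    ref = np.zeros(n, dtype=np.int64)
    z_e = np.zeros(n)
    y_e = np.zeros(n)
    z_i = np.zeros(n)
    y_i = np.zeros(n)
    res_r = np.ones(n)
    res_a = np.zeros(n)

    buf_len = 1
    for m in range(len(delays_steps)):
        if delays_steps[m] + 1 > buf_len:
            buf_len = delays_steps[m] + 1
    buf_e = np.zeros((buf_len, n))
    buf_i = np.zeros((buf_len, n))

    spike_steps = np.empty(max_spikes, dtype=np.int64)
    spike_ids = np.empty(max_spikes, dtype=np.int64)
    n_sp = 0
    kick_ptr = 0
    n_kicks = len(kick_steps)
    use_noise = noise_amp > 0.0
    if use_noise:
        np.random.seed(noise_seed)
    noise_scale = noise_amp * np.sqrt(1.0 - em * em)

    for step in range(n_steps):
        row = step % buf_len
        while kick_ptr < n_kicks and kick_steps[kick_ptr] == step:
            buf_e[row, kick_ids[kick_ptr]] += kick_amp
            kick_ptr += 1

        for i in range(n):
            ze = z_e[i] + buf_e[row, i]
            buf_e[row, i] = 0.0
            zi = z_i[i] + buf_i[row, i]
            buf_i[row, i] = 0.0
            ye = y_e[i]
            yi = y_i[i]
            current = (ye - yi + const_current) * inv_g_leak
            if ref[i] > 0:
                ref[i] -= 1
                v[i] = v_reset
            else:
                vi = v_rest + current + (v[i] - v_rest - current) * em
                if use_noise:
                    vi += noise_scale * np.random.normal()
                if vi >= v_threshold:
                    if n_sp >= max_spikes:
                        return spike_steps[:n_sp], spike_ids[:n_sp], -1
                    spike_steps[n_sp] = step
                    spike_ids[n_sp] = i
                    n_sp += 1
                    vi = v_reset
                    ref[i] = ref_steps
                    released = beta * res_r[i]
                    res_r[i] -= released
                    res_a[i] += released
                    for m in range(indptr[i], indptr[i + 1]):
                        w = link_weight[m] * released
                        if w == 0.0:
                            continue
                        j = indices[m]
                        target_row = (step + delays_steps[m]) % buf_len
                        if w > 0.0:
                            buf_e[target_row, j] += w
                        else:
                            buf_i[target_row, j] -= w
                v[i] = vi
            # flush decayed synaptic states to zero: exponential decay
            # otherwise drives them into denormal range and stalls the FPU
            ye = (ye + ze * gain) * ea
            y_e[i] = ye if ye > 1e-12 else 0.0
            ze = ze * ea
            z_e[i] = ze if ze > 1e-12 else 0.0
            yi = (yi + zi * gain_i) * ea_i
            y_i[i] = yi if yi > 1e-12 else 0.0
            zi = zi * ea_i
            z_i[i] = zi if zi > 1e-12 else 0.0
            aa = res_a[i] * ein
            res_a[i] = aa if aa > 1e-12 else 0.0
            res_r[i] += (1.0 - res_r[i] - res_a[i]) * inv_tau_rec[i]

        if step % 50000 == 0:
            for i in range(n):
                if not np.isfinite(v[i]):
                    return spike_steps[:n_sp], spike_ids[:n_sp], step + 1
    return spike_steps[:n_sp], spike_ids[:n_sp], 0


def simulate(
    net: GroundTruthNetwork,
    params: DynamicsParams,
    duration: float,
    seed: int = 0,
) -> SpikeRaster:
    """Simulate the culture for ``duration`` seconds.

    Deterministic given ``seed``: conduction delays, Poisson background
    kicks and (optional) membrane noise are all drawn from streams derived
    from it.  With ``params.inhibition_blocked`` the postsynaptic weight of
    inhibitory links is zero but the random streams are unchanged, so the
    run is bit-identical to one where inhibitory weights are zeroed by
    hand.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    n = net.n_neurons
    dt = params.dt
    n_steps = int(round(duration * 1000.0 / dt))

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    # CSR adjacency, per-link delays and signed weights
    adj = net.adjacency
    out_counts = adj.sum(axis=1)
    indptr = np.zeros(n + 1, dtype=np.int64)
    indptr[1:] = np.cumsum(out_counts)
    indices = np.concatenate([np.flatnonzero(adj[i]) for i in range(n)]) \
        if indptr[-1] else np.zeros(0, dtype=np.int64)
    indices = indices.astype(np.int64)
    delays_ms = params.delay_mean + params.delay_jitter * (2 * rng.random(len(indices)) - 1)
    delays_ms = np.clip(delays_ms, dt, None)
    delays_steps = np.maximum(np.round(delays_ms / dt).astype(np.int64), 1)
    is_exc_pre = np.repeat(net.neuron_type == EXCITATORY, out_counts)
    weight = np.where(is_exc_pre, params.synaptic_strength_g,
                      -params.synaptic_strength_g * params.inhibitory_weight_scale)
    if params.inhibition_blocked:
        weight = np.where(is_exc_pre, weight, 0.0)

    # Poisson background + external drive, pre-drawn per neuron
    rate_hz = params.background_rate + params.external_drive_rate
    kick_steps_list = []
    kick_ids_list = []
    if rate_hz > 0:
        kick_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
        expected = rate_hz * duration
        for i in range(n):
            n_k = kick_rng.poisson(expected)
            if n_k:
                steps_i = np.sort(
                    (kick_rng.random(n_k) * n_steps).astype(np.int64))
                kick_steps_list.append(steps_i)
                kick_ids_list.append(np.full(n_k, i, dtype=np.int64))
    if kick_steps_list:
        kick_steps = np.concatenate(kick_steps_list)
        kick_ids = np.concatenate(kick_ids_list)
        order = np.argsort(kick_steps, kind="stable")
        kick_steps = kick_steps[order]
        kick_ids = kick_ids[order]
    else:
        kick_steps = np.zeros(0, dtype=np.int64)
        kick_ids = np.zeros(0, dtype=np.int64)

    tau_rec = np.where(net.neuron_type == EXCITATORY,
                       params.tau_recovery_exc, params.tau_recovery_inh)
    ref_steps = max(int(round(params.refractory_time / dt)), 1)
    max_spikes = int(duration * n * 40) + 1000
    noise_seed = int(np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(2,))).integers(2**31 - 1))

    spike_steps, spike_ids, status = _run_network(
        n_steps, dt, n,
        indptr, indices, delays_steps, weight,
        params.v_rest, params.v_threshold, params.v_reset,
        params.tau_membrane, params.g_leak, ref_steps,
        params.alpha_rise_tau, params.alpha_rise_tau_inh,
        tau_rec, params.tau_inactivation,
        params.release_fraction_beta,
        kick_steps, kick_ids, params.background_amplitude,
        params.noise_amplitude, params.constant_current, noise_seed,
        max_spikes,
    )
    if status > 0:
        raise IntegrationError(f"non-finite membrane potential near step {status - 1}")
    if status < 0:
        raise IntegrationError("spike buffer overflow; dynamics likely runaway")
    times = spike_steps * (dt / 1000.0)
    return SpikeRaster(times, spike_ids, duration, n)


def detect_bursts(
    raster: SpikeRaster,
    window: float = 50.0,
    fraction_threshold: float = 0.4,
) -> BurstStatistics:
    """Detect network bursts as runs of windows of quasi-synchronous firing.

    The raster is partitioned into contiguous windows of ``window`` ms; a
    window is burst-like when at least ``fraction_threshold`` of all
    neurons fire in it, and a burst is a maximal run of burst-like
    windows.  The inter-burst firing rate is the mean per-neuron rate over
    non-burst windows.
    """
    if window <= 0:
        raise ParameterError("window must be positive")
    if not 0 < fraction_threshold <= 1:
        raise ParameterError("fraction_threshold must be in (0, 1]")
    w_s = window / 1000.0
    n_windows = max(int(np.ceil(raster.duration / w_s)), 1)
    if raster.n_spikes == 0:
        return BurstStatistics(np.zeros(0), 0.0, 0.0, raster.duration)
    idx = np.minimum((raster.times / w_s).astype(np.int64), n_windows - 1)
    # distinct neurons per window
    pair = idx * raster.n_neurons + raster.ids
    unique_pairs = np.unique(pair)
    counts = np.bincount((unique_pairs // raster.n_neurons).astype(np.int64),
                         minlength=n_windows)
    burst_like = counts >= fraction_threshold * raster.n_neurons
    # maximal runs
    padded = np.concatenate(([False], burst_like, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    burst_times = starts * w_s
    n_bursts = len(starts)
    burst_rate = n_bursts / raster.duration
    spikes_outside = np.sum(~burst_like[idx])
    time_outside = raster.duration - burst_like.sum() * w_s
    if time_outside > 0:
        ib_rate = spikes_outside / (raster.n_neurons * time_outside)
    else:
        ib_rate = 0.0
    return BurstStatistics(burst_times, float(burst_rate), float(ib_rate),
                           raster.duration)


def mean_firing_rate(raster: SpikeRaster) -> float:
    """Mean per-neuron firing rate in Hz over the whole recording."""
    return raster.n_spikes / (raster.n_neurons * raster.duration)


def calibrate_synaptic_strength(
    net: GroundTruthNetwork,
    params: DynamicsParams,
    target_burst_rate: float,
    tolerance: float = 0.03,
    seed: int = 0,
    bracket: tuple[float, float] = (20.0, 250.0),
    probe_duration: float = 300.0,
    max_iter: int = 12,
    burst_window: float = 50.0,
    burst_fraction: float = 0.4,
) -> tuple[float, float]:
    """Bisect the coupling g to reach a target network burst rate.

    Runs fixed-duration probe simulations at candidate couplings and
    bisects on the measured burst rate, which grows with g over the
    useful bracket.  Returns ``(g, achieved_rate)``.

    Raises
    ------
    CalibrationError
        If the bracket endpoints do not straddle the target rate.
    """

    def rate_at(g: float) -> float:
        p = replace(params, synaptic_strength_g=g)
        raster = simulate(net, p, probe_duration, seed=seed)
        return detect_bursts(raster, burst_window, burst_fraction).burst_rate

    lo, hi = bracket
    r_lo, r_hi = rate_at(lo), rate_at(hi)
    if not (r_lo <= target_burst_rate <= r_hi):
        raise CalibrationError(
            f"target {target_burst_rate} Hz outside bracket rates "
            f"[{r_lo:.4f}, {r_hi:.4f}] for g in [{lo}, {hi}]"
        )
    g_best, r_best = (lo, r_lo) if abs(r_lo - target_burst_rate) < abs(
        r_hi - target_burst_rate) else (hi, r_hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = rate_at(mid)
        if abs(r_mid - target_burst_rate) < abs(r_best - target_burst_rate):
            g_best, r_best = mid, r_mid
        if abs(r_mid - target_burst_rate) <= tolerance:
            return mid, r_mid
        if r_mid < target_burst_rate:
            lo = mid
        else:
            hi = mid
    return g_best, r_best
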