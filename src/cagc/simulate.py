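"""Ground-truth network simulators.

Three dynamics on a small directed network with known signed adjacency:

* VAR    — linear vector autoregression, the model class GC itself assumes;
* GLM    — Poisson spiking with log-linear history coupling (nonlinear,
           non-Gaussian);
* GLM-calcium — GLM spikes convolved with an exponential calcium-indicator
           kernel, the realistic benchmark for calcium imaging.

plus a statistical two-chain "motoneuron" simulator: two ipsilateral chains
of neurons driven by alternating left/right binary stimuli with a
propagation delay along each chain, Poisson spiking, calcium convolution
and downsampling to the imaging frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sp_signal

from .recording import FluorescenceRecording, NeuronMeta

__all__ = [
    "NetworkModel",
    "SimulationOutput",
    "ChainStimulusParams",
    "benchmark_network",
    "simulate_var",
    "simulate_glm",
    "simulate_glm_calcium",
    "calcium_convolve",
    "add_global_noise",
    "simulate_motoneuron_chains",
]


@dataclass(frozen=True)
class NetworkModel:
    """Signed network with a boxcar interaction kernel.

    ``A[i, j] = 1`` when neuron j is directly presynaptic to neuron i; the
    sign of the interaction is carried by the source neuron's type
    ``s[j]`` (+1 excitatory, -1 inhibitory).  The memory kernel is
    ``Gamma[q, i, j] = A[i, j] * s[j] * c`` for lags q = 1..Ltrue and zero
    beyond.
    """

    A: np.ndarray
    s: np.ndarray
    c: float
    Ltrue: int

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=int)
        s = np.asarray(self.s, dtype=int)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("A must be square")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("A entries must be 0/1")
        if s.shape != (A.shape[0],) or not np.isin(s, (-1, 1)).all():
            raise ValueError("s must be a vector of +/-1, one per neuron")
        if self.c <= 0:
            raise ValueError("connection strength c must be positive")
        if self.Ltrue < 1:
            raise ValueError("Ltrue must be >= 1")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "s", s)

    @property
    def n_neurons(self) -> int:
        return self.A.shape[0]

    @property
    def kernel(self) -> np.ndarray:
        """(Ltrue, N, N) signed interaction kernel Gamma."""
        g = self.A * self.s[np.newaxis, :] * self.c
        return np.repeat(g[np.newaxis, :, :].astype(float), self.Ltrue, axis=0)

    def companion_spectral_radius(self) -> float:
        """Spectral radius of the VAR companion matrix (< 1 <=> stationary)."""
        n, L = self.n_neurons, self.Ltrue
        comp = np.zeros((n * L, n * L))
        comp[:n, :] = np.concatenate(list(self.kernel), axis=1)
        if L > 1:
            comp[n:, : n * (L - 1)] = np.eye(n * (L - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    @property
    def true_links(self) -> list[tuple[int, int]]:
        """Ordered (driver j, target i) pairs with a direct connection."""
        return [(j, i) for i, j in zip(*np.nonzero(self.A))]


@dataclass(frozen=True)
class SimulationOutput:
    """Bundle of a simulated recording and its ground truth."""

    recording: FluorescenceRecording
    truth: object  # NetworkModel, or list of (driver, target) links for chains
    spikes: Optional[np.ndarray] = None
    stimuli: Optional[dict] = None
    sim_dt: Optional[float] = None


# --------------------------------------------------------------------------
# Benchmark network fixture
# --------------------------------------------------------------------------

# 10-neuron benchmark topology: 5 excitatory (0-4) and 5 inhibitory (5-9)
# neurons, 16 directed links, no self-loops, containing feed-forward chains
# (so pairwise GC sees indirect paths) and a long mixed-sign feedback loop.
# The fixture is version-pinned and is the single source of truth for all
# link-recovery benchmarks here.
_BENCHMARK_EDGES: tuple[tuple[int, int], ...] = (
    # (driver j, target i): an E->I->E->... loop through all ten neurons,
    (0, 5),
    (5, 1),
    (1, 6),
    (6, 2),
    (2, 7),
    (7, 3),
    (3, 8),
    (8, 4),
    (4, 9),
    (9, 0),
    # plus cross-links creating parallel indirect paths (e.g. I5 reaches I6
    # through both E1 and E2), the motif that makes pairwise GC report
    # spurious links while conditioned GC does not.
    (5, 2),
    (2, 6),
    (6, 3),
    (3, 7),
    (0, 7),
    (1, 8),
)


def benchmark_network(c: float = 0.1265, Ltrue: int = 2) -> NetworkModel:
    """The packaged 10-neuron benchmark network (5 excitatory, 5 inhibitory).

    Defaults give the canonical VAR benchmark (connection strength
    c=0.1265, kernel extent Ltrue=2), which is comfortably stationary.
    """
    A = np.zeros((10, 10), dtype=int)
    for j, i in _BENCHMARK_EDGES:
        A[i, j] = 1
    s = np.array([1] * 5 + [-1] * 5)
    return NetworkModel(A=A, s=s, c=c, Ltrue=Ltrue)


# --------------------------------------------------------------------------
# Dynamics
# --------------------------------------------------------------------------


def simulate_var(
    model: NetworkModel,
    T: int,
    sigma: float = 1.0,
    seed: Optional[int] = None,
    dt: float = 1.0,
) -> SimulationOutput:
    """Linear VAR trajectory f_{i,t} = sum_q sum_j Gamma_{ij,q} f_{j,t-q} + xi.

    The noise xi is i.i.d. Gaussian with standard deviation ``sigma``.  A
    burn-in of 10*Ltrue samples is discarded.  Raises if the model is
    non-stationary or the trajectory diverges.
    """
    rho = model.companion_spectral_radius()
    if rho >= 1:
        raise ValueError(f"non-stationary model: companion spectral radius {rho:.3f} >= 1")
    rng = np.random.default_rng(seed)
    n, L = model.n_neurons, model.Ltrue
    burn = 10 * L
    total = T + burn + L
    kern = model.kernel
    f = np.zeros((total, n))
    f[:L] = rng.normal(0.0, sigma, size=(L, n))
    noise = rng.normal(0.0, sigma, size=(total, n))
    for t in range(L, total):
        acc = noise[t].copy()
        for q in range(1, L + 1):
            acc += kern[q - 1] @ f[t - q]
        f[t] = acc
        if np.max(np.abs(acc)) > 1e6:
            raise FloatingPointError(
                "VAR trajectory diverged (|f| > 1e6); model is effectively non-stationary"
            )
    sig = f[L + burn :].T
    rec = FluorescenceRecording(signal=sig, dt=dt)
    return SimulationOutput(recording=rec, truth=model, sim_dt=dt)


def simulate_glm(
    model: NetworkModel,
    T: int,
    mu: float = float(np.log(0.25)),
    seed: Optional[int] = None,
    dt: float = 1.0,
    max_rate: float = 100.0,
    rate_cap: float = 1e4,
) -> SimulationOutput:
    """Poisson-GLM spiking: sigma_{i,t} ~ Poisson(lambda_{i,t}) with
    log lambda_{i,t} = mu + sum_q sum_j Gamma_{ij,q} sigma_{j,t-q}.

    ``mu`` is the base log-rate (default exp(mu) = 0.25 expected spikes per
    step, the sparse-firing regime typical of imaging-rate binning); the
    base rate must stay below ``max_rate``.  Realized rates
    above ``rate_cap`` abort the simulation (runaway excitation).  The
    spike-count matrix itself is the analysis signal.
    """
    if np.exp(mu) >= max_rate:
        raise ValueError(f"base rate exp(mu)={np.exp(mu):.3g} exceeds {max_rate}/step")
    rng = np.random.default_rng(seed)
    n, L = model.n_neurons, model.Ltrue
    burn = 10 * L
    total = T + burn + L
    kern = model.kernel
    spikes = np.zeros((total, n), dtype=np.int64)
    for t in range(L, total):
        log_rate = np.full(n, mu)
        for q in range(1, L + 1):
            log_rate += kern[q - 1] @ spikes[t - q]
        rate = np.exp(log_rate)
        if np.max(rate) > rate_cap:
            raise FloatingPointError(
                f"spike rate overflow ({np.max(rate):.1f}/step); reduce c or mu"
            )
        spikes[t] = rng.poisson(rate)
    out = spikes[L + burn :]
    rec = FluorescenceRecording(signal=out.T.astype(float), dt=dt)
    return SimulationOutput(recording=rec, truth=model, spikes=out.T, sim_dt=dt)


def calcium_convolve(spikes: np.ndarray, tau_ca: float, delta_sim: float) -> np.ndarray:
    """Causal convolution of spike trains with the calcium-indicator kernel
    exp(-q * delta_sim / tau_ca), q >= 0.

    Implemented as the exact recursion f_t = spikes_t + a f_{t-1} with
    a = exp(-delta_sim/tau_ca).
    """
    if tau_ca <= 0:
        raise ValueError("tau_ca must be positive")
    spikes = np.atleast_2d(np.asarray(spikes, dtype=float))
    a = np.exp(-delta_sim / tau_ca)
    out = sp_signal.lfilter([1.0], [1.0, -a], spikes, axis=-1)
    return out


def simulate_glm_calcium(
    model: NetworkModel,
    T: int,
    mu: float = float(np.log(0.25)),
    tau_ca: float = 2.5,
    seed: Optional[int] = None,
    dt: float = 1.0,
) -> SimulationOutput:
    """GLM spiking convolved with an exponential calcium kernel.

    ``tau_ca`` is in the same units as ``dt`` (one simulation step by
    default).
    """
    glm = simulate_glm(model, T, mu=mu, seed=seed, dt=dt)
    traces = calcium_convolve(glm.spikes, tau_ca=tau_ca, delta_sim=dt)
    rec = FluorescenceRecording(signal=traces, dt=dt)
    return SimulationOutput(recording=rec, truth=model, spikes=glm.spikes, sim_dt=dt)


def add_global_noise(
    rec: FluorescenceRecording, sigma_zeta: float, seed: Optional[int] = None
) -> FluorescenceRecording:
    """Add one shared Gaussian white-noise series zeta(t) to every neuron.

    This models system-wide measurement noise (e.g. laser fluctuations or
    motion), which is perfectly correlated across neurons and is the main
    source of spurious GC links in imaging data.
    """
    if sigma_zeta < 0:
        raise ValueError("sigma_zeta must be >= 0")
    if sigma_zeta == 0:
        return rec
    rng = np.random.default_rng(seed)
    zeta = rng.normal(0.0, sigma_zeta, size=rec.n_timepoints)
    return rec.with_signal(rec.signal + zeta[np.newaxis, :])


# --------------------------------------------------------------------------
# Two-chain bursting "motoneuron" simulator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainStimulusParams:
    """Parameters of the two-chain stimulus-gated Poisson simulator.

    Two chains of ``n_per_chain`` neurons (left and right body side) are
    gated by binary block stimuli I_L(t), I_R(t).  On/off block durations
    are drawn uniformly from ``tau_on_range``/``tau_off_range`` (seconds);
    each right-side on-block starts ``tau_delay`` after the corresponding
    left-side block ends, with the delay drawn from ``tau_delay_range``.
    Within a chain, neuron of rank k sees the stimulus delayed by
    k * ``tau_info``.  Spiking is Poisson at base rate ``lambda0`` while
    the (delayed) stimulus is on; spikes are convolved with an exponential
    calcium kernel of timescale ``tau_ca`` and downsampled from the
    simulation step ``delta_sim`` to the imaging interval ``tau_sampling``.
    """

    n_per_chain: int = 5
    tau_on_range: tuple[float, float] = (1.0, 10.0)
    tau_off_range: tuple[float, float] = (1.0, 10.0)
    tau_delay_range: tuple[float, float] = (0.25, 1.0)
    lambda0: float = 32.0
    tau_info: float = 0.25
    tau_ca: float = 2.5
    tau_sampling: float = 0.25
    delta_sim: float = 0.0125
    duration: float = 1000.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("tau_on_range", "tau_off_range", "tau_delay_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if self.delta_sim > self.tau_sampling:
            raise ValueError("delta_sim must not exceed tau_sampling")
        if self.lambda0 * self.delta_sim >= 1:
            raise ValueError(
                "lambda0 * delta_sim must be < 1 to retain per-step stochasticity"
            )
        if self.n_per_chain < 1 or self.duration <= 0:
            raise ValueError("invalid chain geometry or duration")


def _block_stimulus(
    rng: np.random.Generator, params: ChainStimulusParams, n_steps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Binary left/right stimuli at simulation resolution, starting off."""
    dt = params.delta_sim
    i_l = np.zeros(n_steps)
    i_r = np.zeros(n_steps)
    t = rng.uniform(*params.tau_off_range)  # start in the off-state
    while t < params.duration:
        on = rng.uniform(*params.tau_on_range)
        a, b = int(round(t / dt)), int(round((t + on) / dt))
        i_l[a : min(b, n_steps)] = 1.0
        # right-side block trails the left block's offset by tau_delay
        delay = rng.uniform(*params.tau_delay_range)
        on_r = rng.uniform(*params.tau_on_range)
        ar = int(round((t + on + delay) / dt))
        br = int(round((t + on + delay + on_r) / dt))
        i_r[min(ar, n_steps) : min(br, n_steps)] = 1.0
        t = t + on + delay + on_r + rng.uniform(*params.tau_off_range)
    return i_l, i_r


def simulate_motoneuron_chains(params: ChainStimulusParams) -> SimulationOutput:
    """Simulate two stimulus-gated chains of bursting neurons.

    Returns a recording of 2 * ``n_per_chain`` neurons with side and
    rostrocaudal metadata (left chain first), the spike trains and stimuli
    at simulation resolution, and the ground-truth within-chain
    rostral-to-caudal link set (adjacent links k -> k+1 on each side).
    """
    rng = np.random.default_rng(params.seed)
    n_steps = int(round(params.duration / params.delta_sim))
    i_l, i_r = _block_stimulus(rng, params, n_steps)

    k_shift = params.tau_info / params.delta_sim
    n = params.n_per_chain
    rates = np.zeros((2 * n, n_steps))
    for k in range(n):
        shift = int(round(k * k_shift))
        rates[k, shift:] = i_l[: n_steps - shift] if shift else i_l
        rates[n + k, shift:] = i_r[: n_steps - shift] if shift else i_r
    rates *= params.lambda0

    spikes = rng.poisson(rates * params.delta_sim)
    traces = calcium_convolve(spikes, tau_ca=params.tau_ca, delta_sim=params.delta_sim)

    step = int(round(params.tau_sampling / params.delta_sim))
    sampled = traces[:, ::step]

    meta = []
    for side, x in (("L", -10.0), ("R", 10.0)):
        for k in range(n):
            meta.append(
                NeuronMeta(
                    label=f"{side}{k}",
                    side=side,
                    rostrocaudal_rank=k,
                    position=(x, -10.0 * k),
                )
            )
    rec = FluorescenceRecording(
        signal=sampled, dt=params.tau_sampling, neuron_meta=tuple(meta)
    )
    truth = [(k, k + 1) for k in range(n - 1)] + [
        (n + k, n + k + 1) for k in range(n - 1)
    ]
    return SimulationOutput(
        recording=rec,
        truth=truth,
        spikes=spikes,
        stimuli={"I_L": i_l, "I_R": i_r},
        sim_dt=params.delta_sim,
    )
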