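"""Ground-truth linear systems and surrogate multi-phase LFP recordings.

The pipeline identifies discrete-time linear state-space systems

    x_{k+1} = A x_k + B u_k,      y_k = C x_k

from their impulse responses (Markov parameters ``C A^{k-1} B``).  This
module generates (i) random stable systems with known order — the ground
truth for exact-recovery tests, (ii) their impulse responses, (iii)
piecewise-linear fixtures for the change-point stage, and (iv) surrogate
multi-channel LFP recordings organised into experimental phases whose
complexity (underlying system order) and amplitude follow per-phase
schedules, emulating the decay observed during euthanasia.

All randomness flows from one integer seed through ``numpy.random.Generator``
instances; no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .recording import MultiChannelRecording, samples_per_phase

__all__ = [
    "StateSpaceSystem",
    "SyntheticConfig",
    "generate_state_space_system",
    "generate_modal_lfp_system",
    "impulse_response",
    "generate_piecewise_linear",
    "generate_synthetic_lfp",
]


@dataclass
class StateSpaceSystem:
    """Discrete-time linear system (A, B, C).

    ``A`` is n x n, ``B`` is n x p, ``C`` is q x n. Stability (spectral
    radius of A below 1) is guaranteed by the generator but not enforced
    here, so explicitly constructed unstable systems can be used to test
    instability guards downstream.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError(f"A must be square, got {self.A.shape}")
        if self.B.shape[0] != n:
            raise ValueError(
                f"B has {self.B.shape[0]} rows, expected {n} (state dimension)"
            )
        if self.C.shape[1] != n:
            raise ValueError(
                f"C has {self.C.shape[1]} columns, expected {n} (state dimension)"
            )

    @property
    def order(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.C.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A))))


def generate_state_space_system(
    order: int,
    n_inputs: int = 1,
    n_outputs: int = 1,
    spectral_radius: float = 0.9,
    seed: int | np.random.Generator | None = None,
    eigenvalues: np.ndarray | None = None,
) -> StateSpaceSystem:
    """Random stable system of a prescribed order.

    A random (Ginibre) state matrix is rescaled so its spectral radius equals
    ``spectral_radius`` exactly; all eigenvalue magnitudes are therefore
    bounded by it. When ``eigenvalues`` is given (real values, magnitudes
    < 1), ``A`` is their diagonal matrix instead and ``spectral_radius``
    is ignored.

    Identical seeds produce identical systems.
    """
    if order < 1:
        raise ValueError(f"order must be a positive integer, got {order}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if eigenvalues is not None:
        lam = np.asarray(eigenvalues, dtype=float)
        if lam.size != order:
            raise ValueError("number of prescribed eigenvalues must equal order")
        if np.any(np.abs(lam) >= 1):
            raise ValueError("prescribed eigenvalues must have magnitude < 1")
        A = np.diag(lam)
    else:
        if not 0 < spectral_radius < 1:
            raise ValueError(
                f"spectral_radius must lie in (0, 1), got {spectral_radius}"
            )
        if order == 1:
            A = np.array([[spectral_radius]])
        else:
            G = rng.standard_normal((order, order))
            rho = np.max(np.abs(np.linalg.eigvals(G)))
            A = G * (spectral_radius / rho)
    B = rng.standard_normal((order, n_inputs))
    C = rng.standard_normal((n_outputs, order))
    return StateSpaceSystem(A=A, B=B, C=C)


def generate_modal_lfp_system(
    order: int,
    n_outputs: int,
    rate: float,
    f_lo: float = 0.4,
    f_hi: float = 10.0,
    osc_coherence_s: tuple[float, float] = (2.0, 8.0),
    wander_coherence_s: tuple[float, float] = (4.0, 8.0),
    seed: int | np.random.Generator | None = None,
) -> StateSpaceSystem:
    """LFP-like system: slow aperiodic wander plus narrowband rhythms.

    The state matrix is block diagonal: up to two real poles with coherence
    times drawn from ``wander_coherence_s`` model the aperiodic (1/f-like)
    drift every recording shows, and the remaining order is filled with 2x2
    rotation blocks — damped oscillators whose frequencies are spread over
    ``[f_lo, f_hi]`` Hz and whose coherence times come from
    ``osc_coherence_s``. Coherence times are in seconds, so the construction
    is invariant to the sampling rate. Pole radii are ``exp(-1/(tau*rate))``,
    strictly inside the unit circle. ``B`` and ``C`` are dense random
    matrices (every channel sees every mode).

    Driven by white noise, such a system produces slowly wandering,
    near-coherent oscillations — the qualitative texture of a local field
    potential — with the number of distinct rhythms set by ``order``.
    """
    if order < 1:
        raise ValueError(f"order must be a positive integer, got {order}")
    if not 0 < f_lo < f_hi < rate / 2:
        raise ValueError("need 0 < f_lo < f_hi < rate/2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def radius(tau_bounds):
        tau = rng.uniform(*tau_bounds)
        return float(np.exp(-1.0 / (tau * rate)))

    blocks: list[np.ndarray] = []
    n_wander = min(2, order)
    for _ in range(n_wander):
        blocks.append(np.array([[radius(wander_coherence_s)]]))
    remaining = order - n_wander
    n_pairs = remaining // 2
    for i in range(n_pairs):
        # stratified frequencies so higher order occupies a wider band
        f = f_lo + (f_hi - f_lo) * (i + rng.uniform(0.2, 0.8)) / n_pairs
        theta = 2 * np.pi * f / rate
        rho = radius(osc_coherence_s)
        blocks.append(rho * np.array([[np.cos(theta), -np.sin(theta)],
                                      [np.sin(theta), np.cos(theta)]]))
    if remaining % 2:
        blocks.append(np.array([[radius(wander_coherence_s)]]))
    A = np.zeros((order, order))
    at = 0
    for b in blocks:
        k = b.shape[0]
        A[at:at + k, at:at + k] = b
        at += k
    B = rng.standard_normal((order, order))
    C = rng.standard_normal((n_outputs, order))
    return StateSpaceSystem(A=A, B=B, C=C)


def impulse_response(system: StateSpaceSystem, m: int) -> MultiChannelRecording:
    """Impulse response y_0..y_{m-1} of a system, as a q-channel recording.

    Convention: a unit impulse is applied on every input channel at k = 0
    (u_0 sums the columns of B) with x_0 = 0, so y_0 = 0 and
    y_k = C A^{k-1} (B 1_p) for k >= 1. Computed by state propagation.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    q = system.n_outputs
    y = np.zeros((q, m))
    x = system.B @ np.ones(system.n_inputs)
    for k in range(1, m):
        y[:, k] = system.C @ x
        x = system.A @ x
    return MultiChannelRecording(samples=y, rate=1.0, group="synthetic")


def generate_piecewise_linear(
    knot_times: np.ndarray,
    knot_values: np.ndarray,
    rate: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> MultiChannelRecording:
    """Single-channel piecewise-linear signal sampled at ``rate``.

    The noise-free output interpolates the knots exactly at every sample that
    coincides with a knot time; Gaussian noise of standard deviation
    ``noise_sd`` is added when requested.
    """
    t = np.asarray(knot_times, dtype=float)
    v = np.asarray(knot_values, dtype=float)
    if t.size < 2 or t.size != v.size:
        raise ValueError("need >= 2 knots with matching times and values")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knot_times must be strictly increasing")
    if rate <= 0:
        raise ValueError("rate must be positive")
    m = int(np.floor((t[-1] - t[0]) * rate + 0.5)) + 1
    times = t[0] + np.arange(m) / rate
    y = np.interp(times, t, v)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=m)
    return MultiChannelRecording(samples=y[np.newaxis, :], rate=rate, group="synthetic")


@dataclass
class SyntheticConfig:
    """Conditions for a surrogate euthanasia-style recording.

    Defaults mirror the experimental setting the pipeline targets: 4 LFP
    channels at 3000 Hz, seven 5-minute phases (a pre-CO2 baseline followed
    by six euthanasia phases), with per-phase underlying system order
    (complexity) and RMS amplitude both decaying across phases.
    """

    n_channels: int = 4
    rate: float = 3000.0
    phase_duration: float = 300.0
    n_phases: int = 7
    true_order_schedule: tuple[int, ...] | None = None
    amplitude_schedule: tuple[float, ...] | None = None
    f_hi_schedule: tuple[float, ...] | None = None
    f_lo: float = 0.4
    profile: str = "modal"  # modal (LFP-like) | broadband (dense random A)
    noise_sd: float = 0.02
    trend_knot_count: int = 0
    trend_scale: float = 0.2
    spectral_radius: float = 0.95  # broadband profile only
    seed: int = 0

    # canonical 7-phase euthanasia schedules: complexity (system order),
    # RMS amplitude and spectral ceiling all decay from the awake baseline
    # toward a noise-floor-dominated final phase
    _DEFAULT_ORDERS = (18, 14, 10, 8, 6, 4, 2)
    # RMS halves every phase (~6 dB/phase, tens of dB over the session)
    _DEFAULT_AMPS = (1.0, 0.5, 0.25, 0.125, 0.062, 0.031, 0.016)
    _DEFAULT_F_HI = (10.0, 7.0, 5.0, 3.5, 2.5, 1.8, 1.2)

    def __post_init__(self) -> None:
        if self.n_phases < 1 or self.n_channels < 1:
            raise ValueError("n_phases and n_channels must be >= 1")
        if self.true_order_schedule is None:
            self.true_order_schedule = tuple(
                int(v) for v in np.maximum(
                    1, np.round(np.geomspace(18, 2, self.n_phases))
                )
            ) if self.n_phases != 7 else self._DEFAULT_ORDERS
        if self.amplitude_schedule is None:
            self.amplitude_schedule = (
                tuple(np.geomspace(1.0, 0.03, self.n_phases))
                if self.n_phases != 7 else self._DEFAULT_AMPS
            )
        if self.f_hi_schedule is None:
            self.f_hi_schedule = (
                tuple(np.geomspace(10.0, 1.2, self.n_phases))
                if self.n_phases != 7 else self._DEFAULT_F_HI
            )
        for name in ("true_order_schedule", "amplitude_schedule", "f_hi_schedule"):
            if len(getattr(self, name)) != self.n_phases:
                raise ValueError(f"{name} must have length n_phases")
        if any(o < 1 for o in self.true_order_schedule):
            raise ValueError("true orders must be >= 1")
        if any(a < 0 for a in self.amplitude_schedule):
            raise ValueError("amplitudes must be >= 0")
        if self.profile not in ("modal", "broadband"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.noise_sd < 0 or self.trend_scale < 0:
            raise ValueError("noise_sd and trend_scale must be >= 0")

    @property
    def samples_per_phase(self) -> int:
        return samples_per_phase(self.rate, self.phase_duration)


def _filtered_noise(system: StateSpaceSystem, n_steps: int, rng: np.random.Generator,
                    burn_in: int = 200) -> np.ndarray:
    """Stationary state-space-filtered white noise, shape (q, n_steps).

    Simulated through the modal (eigen) decomposition of A so each state mode
    reduces to a first-order recursive filter; falls back to direct state
    propagation if the eigenvector basis is ill-conditioned.
    """
    n, p = system.order, system.n_inputs
    total = n_steps + burn_in
    w = rng.standard_normal((p, total))
    forcing = system.B @ w  # n x total
    lam, P = np.linalg.eig(system.A)
    if np.linalg.cond(P) < 1e8:
        g = np.linalg.solve(P, forcing.astype(complex))
        s = np.empty_like(g)
        for i in range(n):
            s[i] = scipy.signal.lfilter([1.0], [1.0, -lam[i]], g[i])
        x = (P @ s).real
    else:  # defective A: plain recursion
        x = np.zeros((n, total))
        xk = np.zeros(n)
        for k in range(total):
            xk = system.A @ xk + forcing[:, k]
            x[:, k] = xk
    return (system.C @ x)[:, burn_in:]


def generate_synthetic_lfp(config: SyntheticConfig) -> MultiChannelRecording:
    """Surrogate multi-phase LFP recording.

    Per phase ``i`` the stochastic component is white noise filtered through
    a random stable system of order ``true_order_schedule[i]``, normalised to
    unit RMS (jointly over channels) and scaled by ``amplitude_schedule[i]``.
    A piecewise-linear trend spanning the whole recording (zero when
    ``trend_knot_count == 0``) and i.i.d. Gaussian measurement noise of
    standard deviation ``noise_sd`` are added. Phase boundaries are recorded
    as fence-post indices. Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    q = config.n_channels
    n_per = config.samples_per_phase
    total = n_per * config.n_phases

    blocks = []
    for phase in range(config.n_phases):
        order = config.true_order_schedule[phase]
        amp = config.amplitude_schedule[phase]
        if config.profile == "modal":
            system = generate_modal_lfp_system(
                order,
                n_outputs=q,
                rate=config.rate,
                f_lo=config.f_lo,
                f_hi=config.f_hi_schedule[phase],
                seed=rng,
            )
        else:
            system = generate_state_space_system(
                order,
                n_inputs=order,
                n_outputs=q,
                spectral_radius=config.spectral_radius,
                seed=rng,
            )
        sig = _filtered_noise(system, n_per, rng, burn_in=min(2000, 4 * n_per))
        rms = np.sqrt(np.mean(sig**2))
        if rms > 0 and amp > 0:
            sig = sig * (amp / rms)
        else:
            sig = np.zeros_like(sig)
        blocks.append(sig)
    samples = np.concatenate(blocks, axis=1)

    if config.trend_knot_count > 0:
        t_total = total / config.rate
        interior = np.sort(rng.uniform(0.0, t_total, size=config.trend_knot_count))
        knot_t = np.concatenate(([0.0], interior, [t_total]))
        times = np.arange(total) / config.rate
        for c in range(q):
            knot_v = rng.normal(0.0, config.trend_scale, size=knot_t.size)
            samples[c] += np.interp(times, knot_t, knot_v)

    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, size=samples.shape)

    boundaries = np.arange(config.n_phases + 1) * n_per
    return MultiChannelRecording(
        samples=samples,
        rate=config.rate,
        channel_labels=[f"ch{i}" for i in range(q)],
        group="synthetic",
        phase_boundaries=boundaries,
    )
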