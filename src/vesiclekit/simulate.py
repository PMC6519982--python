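"""Stochastic forward simulation of the two-class RRP model and sweep synthesis.

`simulate_quantal_train` draws binomial release from each site class at each
action potential and refills vacancies between stimuli by per-vacancy
Bernoulli trials, giving integer per-stimulus quantal contents.
`render_sweep` turns a quantal train into a raw current sweep (quantal
waveforms + minis + Gaussian noise) so that the measurement stage can be
tested end-to-end against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import ReleaseModelParams
from .protocols import StimulusProtocol

__all__ = [
    "QuantalTrain",
    "SweepTrace",
    "simulate_quantal_train",
    "simulate_averaged_train",
    "render_sweep",
]


@dataclass
class QuantalTrain:
    """Per-stimulus quantal contents aligned to a stimulus protocol.

    The central exchange format between the simulation, measurement and
    estimation stages. ``quanta`` are non-negative reals (integers when
    simulated, fractional after averaging sweeps or measuring real traces).
    """

    stim_times: np.ndarray
    quanta: np.ndarray
    n_sweeps_averaged: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        self.quanta = np.asarray(self.quanta, dtype=float)
        if self.stim_times.shape != self.quanta.shape:
            raise ValueError("stim_times and quanta must have equal length")

    @property
    def n_stimuli(self) -> int:
        return int(self.stim_times.size)

    @property
    def cumulative(self) -> np.ndarray:
        """Cumulative quanta evaluated at each stimulus time."""
        return np.cumsum(self.quanta)

    def scaled(self, k: float) -> "QuantalTrain":
        return QuantalTrain(self.stim_times.copy(), self.quanta * k,
                            self.n_sweeps_averaged, dict(self.meta))


@dataclass
class SweepTrace:
    """A sampled current sweep. Inward synaptic currents are negative (nA)."""

    sample_rate: float
    current: np.ndarray
    stim_times: np.ndarray
    quantal_waveform: tuple = (1e-4, 5e-4, None)  # (rise tau s, decay tau s, peak nA or None)
    noise_sd: float = 0.0
    t0: float = 0.0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        self.current = np.asarray(self.current, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.current.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.current.size / self.sample_rate


def _fill_probability(params: ReleaseModelParams, t_prev: float, t_next: float,
                      in_train: bool) -> float:
    """Probability that one vacancy refills during (t_prev, t_next).

    Intervals shorter than ``rest_threshold`` (or flagged as within-train) use
    the constant alpha_train; longer gaps use the rest-dependent decaying rate
    integrated from the end of the previous stimulus.
    """
    dt = t_next - t_prev
    if dt <= 0:
        return 0.0
    rec = params.recruitment
    if in_train and dt < params.rest_threshold:
        integral = rec.alpha_train * dt
    else:
        integral = float(rec.rest_integral(dt))
    return 1.0 - np.exp(-integral)


def simulate_quantal_train(params: ReleaseModelParams, protocol: StimulusProtocol,
                           seed: int | None = None) -> QuantalTrain:
    """Simulate one sweep of the two-class vacancy-recruitment model.

    Both site classes start full. At each stimulus, the effective release
    probability is min(1, pv*(1+F)) with F the shared facilitation state;
    released counts are Binomial(occupancy, pv_eff). Between stimuli each
    vacancy fills independently with probability 1 - exp(-∫ alpha dt).

    Identical (params, protocol, seed) gives bit-identical output.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    times = protocol.stim_times
    n_stim = times.size
    occ = np.array([params.n_high, params.n_low], dtype=np.int64)
    cap = np.array([params.n_high, params.n_low], dtype=np.int64)
    pv = np.array([params.pv_high, params.pv_low], dtype=float)

    quanta = np.zeros(n_stim)
    fac = 0.0
    last_t = None
    released_total = 0
    recruited_total = 0
    for i, t in enumerate(times):
        if last_t is not None:
            # facilitation decays continuously; refill happens in the gap
            dt = t - last_t
            fac *= np.exp(-dt / params.facilitation_tau)
            p_fill = _fill_probability(params, last_t, t, in_train=True)
            if p_fill > 0:
                refill = rng.binomial(cap - occ, p_fill)
                occ = occ + refill
                recruited_total += int(refill.sum())
        pv_eff = np.minimum(1.0, pv * (1.0 + fac))
        k = rng.binomial(occ, pv_eff)
        occ = occ - k
        quanta[i] = k.sum()
        released_total += int(k.sum())
        if params.facilitation_increment > 0:
            fac += params.facilitation_increment
        last_t = t

    return QuantalTrain(
        times.copy(), quanta, n_sweeps_averaged=1,
        meta={
            "seed": int(seed),
            "released_total": released_total,
            "recruited_total": recruited_total,
            "final_occupancy": occ.tolist(),
            "capacity": int(params.capacity),
        },
    )


def simulate_averaged_train(params: ReleaseModelParams, protocol: StimulusProtocol,
                            n_sweeps: int, seed: int) -> QuantalTrain:
    """Average `n_sweeps` independent simulated sweeps, as done experimentally
    (multiple trials from one preparation averaged before analysis)."""
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_sweeps)]
    acc = np.zeros(protocol.n_stimuli)
    for s in seeds:
        acc += simulate_quantal_train(params, protocol, seed=s).quanta
    return QuantalTrain(protocol.stim_times.copy(), acc / n_sweeps,
                        n_sweeps_averaged=n_sweeps, meta={"seed": int(seed)})


def _quantal_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials kernel with unit time-integral (1/s units)."""
    if rise_tau <= 0 or decay_tau <= 0 or decay_tau <= rise_tau:
        raise ValueError("require 0 < rise_tau < decay_tau")
    h = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    return h / (decay_tau - rise_tau)


def render_sweep(train: QuantalTrain, waveform=(1e-4, 5e-4), noise_sd: float = 0.0,
                 mini_rate: float = 0.0, seed: int = 0, sample_rate: float = 5e4,
                 quantal_size: float = 0.1, quantal_cv: float = 0.3,
                 pre_time: float = 0.12, post_time: float = 0.05,
                 latency: float = 1e-3) -> SweepTrace:
    """Render a quantal train as a raw current sweep.

    Each stimulus contributes quanta x a unit-charge quantal waveform scaled
    by ``quantal_size`` (pC); Poisson minis at ``mini_rate`` have lognormal
    charges with coefficient of variation ``quantal_cv``; Gaussian baseline
    noise of SD ``noise_sd`` (nA) is added. Inward currents are negative.
    Evoked responses begin ``latency`` seconds after their stimulus (synaptic
    delay), so that artifact blanking at the stimulus does not clip them.

    The trace starts ``pre_time`` s before the first stimulus (baseline
    window) and extends ``post_time`` s past the last.
    """
    rng = np.random.default_rng(seed)
    rise_tau, decay_tau = waveform[0], waveform[1]
    t0 = float(train.stim_times[0] - pre_time) if train.n_stimuli else 0.0
    t_end = float(train.stim_times[-1] + post_time) if train.n_stimuli else post_time
    n = int(np.round((t_end - t0) * sample_rate)) + 1
    current = np.zeros(n)

    # kernel support: long enough that the truncated tail carries <0.1% charge
    k_len = int(np.ceil((rise_tau + 8 * decay_tau) * sample_rate))
    kt = np.arange(k_len) / sample_rate
    kernel = _quantal_kernel(kt, rise_tau, decay_tau)
    kernel *= sample_rate / kernel.sum()  # exact unit charge on the sampling grid

    def add_event(t_event: float, charge_pc: float):
        i0 = int(np.round((t_event - t0) * sample_rate))
        if i0 < 0 or i0 >= n:
            return
        seg = min(k_len, n - i0)
        # charge pC over seconds -> nA: 1 pC/s = 1e-3 nA
        current[i0:i0 + seg] -= (charge_pc * 1e-3) * kernel[:seg]

    for t_event, q in zip(train.stim_times, train.quanta):
        if q != 0:
            add_event(float(t_event) + latency, float(q) * quantal_size)

    if mini_rate > 0:
        n_minis = rng.poisson(mini_rate * (t_end - t0))
        mini_times = rng.uniform(t0, t_end, size=n_minis)
        if quantal_cv > 0:
            sigma = np.sqrt(np.log(1.0 + quantal_cv**2))
            mu = np.log(quantal_size) - 0.5 * sigma**2
            mini_charges = rng.lognormal(mu, sigma, size=n_minis)
        else:
            mini_charges = np.full(n_minis, quantal_size)
        for t_event, c in zip(np.sort(mini_times), mini_charges):
            add_event(float(t_event), float(c))

    if noise_sd > 0:
        current += rng.normal(0.0, noise_sd, size=n)

    return SweepTrace(sample_rate, current, train.stim_times.copy(),
                      (rise_tau, decay_tau, None), noise_sd, t0=t0)
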