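"""Vacancy-limited recruitment kinetics and the deterministic expectation model.

The readily releasable pool (RRP) is modelled as a fixed number of release
sites. A site holds at most one vesicle; an action potential releases each
docked vesicle independently with the site-class release probability pv, and
empty sites refill by first-order kinetics: over a time interval dt each
vacancy fills independently with probability 1 - exp(-∫ alpha dt), where
alpha is the unitary recruitment rate (fraction of vacant space refilled per
unit time).

During ongoing trains alpha is a constant ``alpha_train``; after a train ends
the rate is elevated and decays back to its resting value during the rest
interval, modelled as a decaying exponential alpha(t) = alpha_inf +
(alpha_0 - alpha_inf) * exp(-t / tau_alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RecruitmentRateFunction",
    "ReleaseModelParams",
    "expected_occupancy",
]


@dataclass(frozen=True)
class RecruitmentRateFunction:
    """Rest-dependent unitary recruitment rate.

    Parameters
    ----------
    alpha_0 : float
        Rate at rest onset (train end), 1/s. Calyx default 5.4/s.
    alpha_inf : float
        Late-rest asymptotic rate, 1/s.
    tau_alpha : float
        Decay time constant of the rest-dependent rate, s.
    alpha_train : float
        Constant rate applying during ongoing stimulation, 1/s.
    """

    alpha_0: float = 5.4
    alpha_inf: float = 1.5
    tau_alpha: float = 2.0
    alpha_train: float = 5.0

    def __post_init__(self):
        for name in ("alpha_0", "alpha_inf", "alpha_train"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau_alpha <= 0:
            raise ValueError("tau_alpha must be > 0")

    def rest_rate(self, t_rest):
        """alpha(t) during a rest, t seconds after the train ended."""
        t = np.asarray(t_rest, dtype=float)
        return self.alpha_inf + (self.alpha_0 - self.alpha_inf) * np.exp(-t / self.tau_alpha)

    def rest_integral(self, t_rest):
        """∫_0^t alpha(s) ds during a rest, in closed form."""
        t = np.asarray(t_rest, dtype=float)
        return self.alpha_inf * t + (self.alpha_0 - self.alpha_inf) * self.tau_alpha * (
            1.0 - np.exp(-t / self.tau_alpha)
        )


@dataclass(frozen=True)
class ReleaseModelParams:
    """Generative parameters of the two-class RRP model.

    The RRP holds ``n_high`` sites of release probability ``pv_high`` and
    ``n_low`` sites of ``pv_low`` (low-pv vesicles are the slowly releasing /
    "reluctant" subpool). Mean release probability when full:
    p̄v = (n_high*pv_high + n_low*pv_low) / (n_high + n_low).

    ``facilitation_increment`` adds a shared multiplicative facilitation state
    F (pv_eff = min(1, pv*(1+F))) that increments after each stimulus and
    decays with ``facilitation_tau``; default off.
    """

    n_high: int = 2880
    n_low: int = 320
    pv_high: float = 0.36
    pv_low: float = 0.12
    recruitment: RecruitmentRateFunction = field(default_factory=RecruitmentRateFunction)
    facilitation_increment: float = 0.0
    facilitation_tau: float = 0.1
    quantal_size: float = 0.1  # pC
    quantal_cv: float = 0.3
    mini_rate: float = 0.0  # events/s
    rest_threshold: float = 0.1  # s; intervals >= this use the rest-dependent rate
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.pv_low <= self.pv_high <= 1.0):
            raise ValueError("require 0 <= pv_low <= pv_high <= 1")
        if self.n_high < 0 or self.n_low < 0:
            raise ValueError("site counts must be >= 0")
        if self.quantal_size <= 0:
            raise ValueError("quantal_size must be > 0")
        if self.quantal_cv < 0 or self.mini_rate < 0:
            raise ValueError("quantal_cv and mini_rate must be >= 0")
        if self.facilitation_tau <= 0:
            raise ValueError("facilitation_tau must be > 0")

    @property
    def capacity(self) -> int:
        return self.n_high + self.n_low

    @property
    def pv_bar(self) -> float:
        """Mean per-vesicle release probability when the pool is full."""
        n = self.capacity
        if n == 0:
            return 0.0
        return (self.n_high * self.pv_high + self.n_low * self.pv_low) / n

    def scaled_pv(self, factor: float) -> "ReleaseModelParams":
        """Return a copy with both class pv values scaled by `factor`.

        Models a change in extracellular Ca2+ (or a genotype that acts
        uniformly on the release machinery); values are clipped to 1.
        """
        from dataclasses import replace

        return replace(
            self,
            pv_high=min(1.0, self.pv_high * factor),
            pv_low=min(1.0, self.pv_low * factor),
        )


def expected_occupancy(n, pv, alpha, delta, n_stimuli):
    """Deterministic expectation of the single-class depletion/refill recursion.

    Occupancy before stimulus i+1 obeys o_{i+1} = N(1-s) + o_i (1-pv) s with
    s = exp(-alpha*delta); the steady state is o* = N(1-s)/(1-(1-pv)s) and the
    steady-state release per stimulus r* = pv * o*.

    Parameters
    ----------
    n : float
        Pool capacity (number of sites).
    pv : float
        Release probability per docked vesicle per stimulus.
    alpha : float
        Constant unitary recruitment rate, 1/s.
    delta : float
        Inter-stimulus interval, s.
    n_stimuli : int
        Number of stimuli.

    Returns
    -------
    occupancy : ndarray
        Pre-stimulus occupancy o_i, i = 0..n_stimuli-1 (o_0 = n).
    o_star : float
        Steady-state pre-stimulus occupancy.
    r_star : float
        Steady-state release per stimulus, pv * o_star.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    s = np.exp(-alpha * delta)
    occ = np.empty(int(n_stimuli))
    o = float(n)
    for i in range(int(n_stimuli)):
        occ[i] = o
        o = n * (1.0 - s) + o * (1.0 - pv) * s
    denom = 1.0 - (1.0 - pv) * s
    o_star = n * (1.0 - s) / denom if denom > 0 else float(n)
    return occ, o_star, pv * o_star
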