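"""RRP capacity, p̄v, and unitary recruitment rate from quantal trains.

Two estimators are provided, named after the conventions of the field:

'S' (back-extrapolation)
    A line is fitted by least squares to the cumulative quantal content over
    a late, steady-state window of the train; the ordinate intercept at train
    onset is the RRP capacity and the slope is the recruitment rate.

'M' (vacancy-recruitment model)
    The fixed-capacity model — release sites hold at most one vesicle, each
    docked vesicle is released with probability pv per action potential, and
    each vacancy refills with probability 1 - exp(-alpha*dt) between stimuli
    — is fitted to the per-stimulus quantal contents by nonlinear least
    squares. The capacity (occupancy at train onset) is the RRP estimate;
    alpha can be fixed or fitted jointly.

`RRPTrainModel` wraps both behind a statsmodels-style Model/Results pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .simulate import QuantalTrain

__all__ = [
    "RRPEstimate",
    "PvEstimate",
    "RRPTrainModel",
    "RRPTrainResults",
    "estimate_rrp_backextrapolation",
    "estimate_rrp_model",
    "estimate_pv",
    "estimate_unitary_recruitment_rate",
    "excess_recruitment",
    "SaturationError",
    "ConvergenceError",
]


class SaturationError(ValueError):
    """Steady-state release exceeds what the vacancies could supply."""


class ConvergenceError(RuntimeError):
    """Model fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_estimate=None):
        super().__init__(message)
        self.last_estimate = last_estimate


@dataclass
class RRPEstimate:
    """Output of methods 'S' and 'M'.

    ``rrp0`` is the pool content at train onset (quanta). For method 'M',
    ``capacity`` is the fitted (or fixed) site count, equal to rrp0 for a
    rested train; ``occupancy_pre``/``occupancy_post`` are the fitted model's
    occupancy just before/after each stimulus.
    """

    method: str
    rrp0: float
    recruitment_per_stimulus: np.ndarray
    ss_window: tuple
    alpha_used: float | None = None
    fit_residual: float = 0.0
    converged: bool = True
    capacity: float | None = None
    pv_fit: float | None = None
    occupancy_pre: np.ndarray | None = None
    occupancy_post: np.ndarray | None = None
    warnings: list = field(default_factory=list)

    @property
    def recruitment_total(self) -> float:
        return float(np.sum(self.recruitment_per_stimulus))


@dataclass
class PvEstimate:
    """Mean per-vesicle release probability with its provenance."""

    pv_bar: float
    numerator: float
    denominator: float
    method: str
    context: str = "rested"


def _window_mask(t_rel, ss_window):
    lo, hi = ss_window
    return (t_rel >= lo - 1e-9) & (t_rel <= hi + 1e-9)


def estimate_rrp_backextrapolation(train: QuantalTrain, ss_window=(0.15, 0.30)) -> RRPEstimate:
    """Back-extrapolation ('S') estimate of RRP content.

    Least-squares line through cumulative quanta vs time over ``ss_window``
    (seconds relative to the first stimulus); rrp0 is the intercept at train
    onset, recruitment per stimulus is slope x inter-stimulus interval.
    """
    t_rel = train.stim_times - train.stim_times[0]
    mask = _window_mask(t_rel, ss_window)
    if mask.sum() < 3:
        raise ValueError("steady-state window must contain >= 3 stimuli")
    cum = train.cumulative
    slope, intercept = np.polyfit(t_rel[mask], cum[mask], 1)
    resid = cum[mask] - (slope * t_rel[mask] + intercept)

    warns = []
    q_win = train.quanta[mask]
    q_slope = np.polyfit(t_rel[mask], q_win, 1)[0]
    span = t_rel[mask][-1] - t_rel[mask][0]
    if q_win.mean() > 0 and abs(q_slope) * span > 0.25 * q_win.mean():
        warns.append("per-stimulus quanta still trending in window; "
                     "steady state may not be reached")
        warnings.warn(warns[-1], stacklevel=2)
    if intercept < 0:
        warns.append("negative back-extrapolated intercept")
        warnings.warn(warns[-1], stacklevel=2)

    if train.n_stimuli > 1:
        isi = np.median(np.diff(train.stim_times))
    else:
        isi = 0.0
    rec = np.full(train.n_stimuli, max(slope, 0.0) * isi)
    return RRPEstimate("S", float(intercept), rec, tuple(ss_window),
                       alpha_used=None,
                       fit_residual=float(np.sqrt(np.mean(resid**2))),
                       converged=True, warnings=warns)


def _model_trajectory(quanta_shape, intervals, n_cap, o0, pv, alpha):
    """Deterministic expectation recursion: predicted quanta, occupancy and
    per-interval recruitment for capacity n_cap starting at occupancy o0."""
    n_stim = quanta_shape
    q_hat = np.empty(n_stim)
    occ_pre = np.empty(n_stim)
    occ_post = np.empty(n_stim)
    rec = np.zeros(n_stim)
    o = float(o0)
    for i in range(n_stim):
        occ_pre[i] = o
        q_hat[i] = pv * o
        o = o * (1.0 - pv)
        occ_post[i] = o
        if i < n_stim - 1:
            fill = 1.0 - np.exp(-alpha * intervals[i])
            r = (n_cap - o) * fill
            rec[i] = r
            o += r
    return q_hat, occ_pre, occ_post, rec


def estimate_rrp_model(train: QuantalTrain, alpha: float | str = "fit",
                       ss_window=(0.15, 0.30), tol: float = 0.1,
                       max_iter: int = 100, capacity: float | None = None) -> RRPEstimate:
    """Vacancy-recruitment ('M') estimate of RRP content.

    Fits the deterministic expectation of the fixed-capacity model to the
    per-stimulus quanta by nonlinear least squares, initialized from method
    'S'. Free parameters: capacity N and pv (plus alpha when ``alpha='fit'``).
    When ``capacity`` is given, N is held fixed and the occupancy at train
    onset is fitted instead — the mode used for the second train of a paired
    (recovery) protocol, which starts partially full.

    Raises
    ------
    ConvergenceError
        If the optimizer does not converge within ``max_iter`` iterations;
        the exception carries the last iterate.
    """
    t = train.stim_times
    q = train.quanta
    n_stim = q.size
    if n_stim < 3:
        raise ValueError("need >= 3 stimuli")
    intervals = np.diff(t)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s_est = estimate_rrp_backextrapolation(train, ss_window)
    n0 = max(float(s_est.rrp0), float(q[0]) + 1e-6, 1e-3)
    pv0 = min(max(q[0] / n0, 1e-4), 0.99)

    fit_alpha = isinstance(alpha, str)
    if fit_alpha and alpha != "fit":
        raise ValueError("alpha must be a rate in 1/s or the string 'fit'")
    alpha0 = 5.0 if fit_alpha else float(alpha)

    fixed_cap = capacity is not None

    def unpack(x):
        if fixed_cap:
            o0, pv = x[0], x[1]
            n_cap = float(capacity)
        else:
            o0, pv = x[0], x[1]
            n_cap = x[0]
        a = x[2] if fit_alpha else alpha0
        return n_cap, o0, pv, a

    def residuals(x):
        n_cap, o0, pv, a = unpack(x)
        q_hat, *_ = _model_trajectory(n_stim, intervals, n_cap, o0, pv, a)
        return q_hat - q

    x0 = [n0, pv0]
    lb = [1e-6, 1e-6]
    ub = [np.inf, 1.0]
    if fixed_cap:
        x0[0] = min(n0, float(capacity))
        ub[0] = float(capacity) * 1.05
    if fit_alpha:
        x0.append(alpha0)
        lb.append(0.0)
        ub.append(np.inf)

    sol = least_squares(residuals, x0, bounds=(lb, ub), xtol=tol * 1e-6,
                        ftol=1e-12, max_nfev=max_iter * (len(x0) + 1))
    n_cap, o0, pv, a = unpack(sol.x)
    q_hat, occ_pre, occ_post, rec = _model_trajectory(n_stim, intervals, n_cap, o0, pv, a)
    est = RRPEstimate("M", float(o0), rec, tuple(ss_window), alpha_used=float(a),
                      fit_residual=float(np.sqrt(np.mean((q_hat - q) ** 2))),
                      converged=bool(sol.status > 0), capacity=float(n_cap),
                      pv_fit=float(pv), occupancy_pre=occ_pre, occupancy_post=occ_post)
    if not sol.status > 0:
        raise ConvergenceError(f"model fit did not converge: {sol.message}",
                               last_estimate=est)
    if np.min(occ_post) < -tol:
        est.warnings.append("fitted occupancy dips below zero")
        warnings.warn(est.warnings[-1], stacklevel=2)
    return est


def estimate_pv(first_response: float, rrp: RRPEstimate, context: str = "rested") -> PvEstimate:
    """p̄v = quanta released by an isolated action potential / RRP content."""
    if rrp.rrp0 <= 0:
        raise ValueError("RRP estimate must be positive")
    pv = float(first_response) / float(rrp.rrp0)
    if pv > 1:
        warnings.warn(f"pv_bar = {pv:.3f} exceeds 1", stacklevel=2)
    return PvEstimate(pv, float(first_response), float(rrp.rrp0),
                      method=rrp.method, context=context)


def estimate_unitary_recruitment_rate(train: QuantalTrain, rrp: RRPEstimate,
                                      ss_window=None) -> float:
    """First-order rate constant of vacancy refilling, from steady state.

    rate = -ln(1 - r_ss / v_ss) / delta, where r_ss is the mean per-stimulus
    release in the window and v_ss the mean post-release vacancy of the
    fitted model (the fraction of vacant space refilled per inter-stimulus
    interval, converted to a rate).
    """
    if rrp.occupancy_post is None or rrp.capacity is None:
        raise ValueError("needs a method-'M' estimate with occupancy trajectory")
    if ss_window is None:
        ss_window = rrp.ss_window
    t_rel = train.stim_times - train.stim_times[0]
    mask = _window_mask(t_rel, ss_window)
    if not mask.any():
        raise ValueError("empty steady-state window")
    r_ss = float(train.quanta[mask].mean())
    if r_ss <= 0:
        return 0.0
    v_ss = float(rrp.capacity - rrp.occupancy_post[mask].mean())
    if r_ss >= v_ss:
        raise SaturationError("steady-state release exceeds available vacancies")
    delta = float(np.median(np.diff(train.stim_times[mask])))
    return -np.log(1.0 - r_ss / v_ss) / delta


def excess_recruitment(quanta, intervals, alpha: float):
    """Recruitment driven by observed release into vacancies that start at zero.

    Bookkeeping for the frequency-jump differential analysis: the *excess*
    vacancy created by the differential release starts at zero at jump onset,
    grows by each differential release, and refills between stimuli with
    probability 1 - exp(-alpha*delta). Returns the per-interval recruited
    counts (aligned with the gap following each stimulus; last entry 0).
    """
    quanta = np.asarray(quanta, dtype=float)
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size != quanta.size - 1:
        raise ValueError("need len(intervals) == len(quanta) - 1")
    rec = np.zeros(quanta.size)
    v = 0.0
    for i in range(quanta.size):
        v += quanta[i]
        if i < intervals.size:
            r = v * (1.0 - np.exp(-alpha * intervals[i]))
            rec[i] = r
            v -= r
    return rec


# ---------------------------------------------------------------------------
# Model/Results facade
# ---------------------------------------------------------------------------

_SS_WINDOW_PRESETS = {"calyx": (0.15, 0.30)}


class RRPTrainModel:
    """Readily-releasable-pool model of one depleting stimulus train.

    Parameters
    ----------
    train : QuantalTrain
        Per-stimulus quantal contents (typically averaged over sweeps).
    ss_window : (float, float), optional
        Steady-state window, seconds relative to the first stimulus.
        Defaults: calyx 0.15-0.30 s (a 300 Hz x 300 ms train); any other
        preparation uses the final third of the train.
    preparation : str
        'calyx' or 'schaffer' (controls the default window only).

    Examples
    --------
    >>> model = RRPTrainModel(train)          # doctest: +SKIP
    >>> res = model.fit(method="M", alpha=5.0)  # doctest: +SKIP
    >>> print(res.summary())                  # doctest: +SKIP
    """

    def __init__(self, train: QuantalTrain, ss_window=None, preparation: str = "calyx"):
        self.train = train
        self.preparation = preparation
        if ss_window is None:
            if preparation in _SS_WINDOW_PRESETS:
                ss_window = _SS_WINDOW_PRESETS[preparation]
            else:
                t_end = float(train.stim_times[-1] - train.stim_times[0])
                ss_window = (2.0 * t_end / 3.0, t_end)
        self.ss_window = tuple(ss_window)

    @classmethod
    def from_dataframe(cls, df, time_col: str = "stim_time_s", quanta_col: str = "quanta",
                       **kwargs) -> "RRPTrainModel":
        """Build from a tidy DataFrame with stimulus-time and quanta columns."""
        train = QuantalTrain(df[time_col].to_numpy(float), df[quanta_col].to_numpy(float))
        return cls(train, **kwargs)

    def fit(self, method: str = "M", alpha: float | str = "fit", tol: float = 0.1,
            max_iter: int = 100, capacity: float | None = None) -> "RRPTrainResults":
        if method == "S":
            est = estimate_rrp_backextrapolation(self.train, self.ss_window)
        elif method == "M":
            est = estimate_rrp_model(self.train, alpha=alpha, ss_window=self.ss_window,
                                     tol=tol, max_iter=max_iter, capacity=capacity)
        else:
            raise ValueError("method must be 'S' or 'M'")
        return RRPTrainResults(self, est)


class RRPTrainResults:
    """Estimates and diagnostics from a fitted RRPTrainModel."""

    def __init__(self, model: RRPTrainModel, estimate: RRPEstimate):
        self.model = model
        self.estimate = estimate
        self.pv = estimate_pv(model.train.quanta[0], estimate)

    @property
    def rrp0(self) -> float:
        return self.estimate.rrp0

    @property
    def pv_bar(self) -> float:
        return self.pv.pv_bar

    @property
    def method(self) -> str:
        return self.estimate.method

    @property
    def recruitment_total(self) -> float:
        return self.estimate.recruitment_total

    def unitary_recruitment_rate(self) -> float:
        return estimate_unitary_recruitment_rate(self.model.train, self.estimate)

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "RRP train estimate".center(46),
            "=" * 46,
            f"{'method':<28}{e.method:>18}",
            f"{'n stimuli':<28}{self.model.train.n_stimuli:>18d}",
            f"{'sweeps averaged':<28}{self.model.train.n_sweeps_averaged:>18d}",
            f"{'ss window (s)':<28}{str(e.ss_window):>18}",
            f"{'RRP content at onset':<28}{e.rrp0:>18.1f}",
            f"{'pv_bar (1st resp / RRP0)':<28}{self.pv_bar:>18.4f}",
            f"{'recruitment (quanta)':<28}{e.recruitment_total:>18.1f}",
            f"{'fit residual (quanta RMS)':<28}{e.fit_residual:>18.2f}",
        ]
        if e.method == "M":
            lines.append(f"{'capacity N':<28}{e.capacity:>18.1f}")
            lines.append(f"{'pv (model fit)':<28}{e.pv_fit:>18.4f}")
            lines.append(f"{'alpha (1/s)':<28}{e.alpha_used:>18.3f}")
        lines.append("=" * 46)
        for w in e.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)
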