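"""Non-compartmental analysis of IV-bolus concentration–time profiles.

Implements the classic linear-up/log-down trapezoidal AUC/AUMC rules, a
terminal-slope (lambda-z) search that maximises adjusted R² over candidate
terminal windows, log-linear back-extrapolation of C0, and the derived
exposure metrics (AUC∞, clearance, Vz, Vss).  Observations flagged below
the limit of quantification are excluded from all computations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConcProfile",
    "NCAResult",
    "NCAError",
    "InsufficientDataError",
    "NoTerminalPhaseError",
    "fit_lambda_z",
    "auc_lin_up_log_down",
    "nca_iv_bolus",
]


class NCAError(ValueError):
    pass


class InsufficientDataError(NCAError):
    pass


class NoTerminalPhaseError(NCAError):
    pass


@dataclass(frozen=True)
class ConcProfile:
    """One individual's concentration–time profile after a single IV dose.

    ``times`` days, ``concs`` µg/mL, ``dose`` mg/kg.  ``blq`` flags points
    below the quantification limit; they are ignored everywhere.
    """

    times: np.ndarray
    concs: np.ndarray
    dose: float
    blq: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concs, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise NCAError("times and concs must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise NCAError("times must be strictly increasing")
        if np.any(c < 0):
            raise NCAError("concentrations must be non-negative")
        b = self.blq
        b = np.zeros(t.size, dtype=bool) if b is None else np.asarray(b, dtype=bool)
        if b.shape != t.shape:
            raise NCAError("blq flags must match times")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concs", c)
        object.__setattr__(self, "blq", b)

    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        m = ~self.blq & (self.concs > 0)
        return self.times[m], self.concs[m]


@dataclass(frozen=True)
class NCAResult:
    """Exposure metrics for one profile (units: µg/mL, days, L/day/kg, L/kg)."""

    cmax: float
    tmax: float
    c0: float
    auc_last: float
    auc_inf: float
    aumc_inf: float
    lambda_z: float
    t_half: float
    n_lambda_points: int
    adj_r2: float
    cl_f: float
    vz: float
    vss: float


def _loglin_fit(t: np.ndarray, logc: np.ndarray) -> tuple[float, float, float]:
    """OLS of log-conc on time: returns (slope, intercept, r2)."""
    n = t.size
    tm, lm = t.mean(), logc.mean()
    sxx = float(np.sum((t - tm) ** 2))
    sxy = float(np.sum((t - tm) * (logc - lm)))
    slope = sxy / sxx
    intercept = lm - slope * tm
    ss_res = float(np.sum((logc - intercept - slope * t) ** 2))
    ss_tot = float(np.sum((logc - lm) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def fit_lambda_z(profile: ConcProfile) -> tuple[float, int, float]:
    """Estimate the terminal elimination rate constant lambda-z.

    Log-linear regressions are fitted over candidate terminal windows (the
    last 3, 4, … points after excluding Cmax); the window with the largest
    adjusted R² wins, with ties within 1e-4 resolved toward more points.
    Returns ``(lambda_z, n_points, adj_r2)``.
    """
    t, c = profile.quantifiable()
    if t.size < 3:
        raise InsufficientDataError("need >=3 quantifiable points for lambda-z")
    i_cmax = int(np.argmax(c))
    t_term, c_term = t[i_cmax + 1 :], c[i_cmax + 1 :]
    if t_term.size == 0:
        raise NoTerminalPhaseError("concentrations still rising at the last sample")
    if t_term.size < 3:
        raise InsufficientDataError("need >=3 terminal points after excluding Cmax")
    logc = np.log(c_term)
    candidates = []  # (adj_r2, n, lambda_z)
    for n in range(3, t_term.size + 1):
        slope, _, r2 = _loglin_fit(t_term[-n:], logc[-n:])
        if slope >= 0:
            continue
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        candidates.append((adj, n, -slope))
    if not candidates:
        raise NoTerminalPhaseError("no window with a negative terminal slope")
    best_adj = max(a for a, _, _ in candidates)
    adj, n, lz = max(
        (c for c in candidates if c[0] >= best_adj - 1e-4), key=lambda c: c[1]
    )
    return lz, n, adj


def _segment_auc(t1: float, t2: float, c1: float, c2: float) -> tuple[float, float]:
    """(AUC, AUMC) of one interval: linear up / log down."""
    dt = t2 - t1
    if c2 >= c1 or c1 == 0 or c2 == 0:
        auc = 0.5 * (c1 + c2) * dt
        aumc = 0.5 * (c1 * t1 + c2 * t2) * dt
    else:
        lr = math.log(c1 / c2)
        auc = dt * (c1 - c2) / lr
        aumc = dt * (t1 * c1 - t2 * c2) / lr + dt * dt * (c1 - c2) / (lr * lr)
    return auc, aumc


def auc_lin_up_log_down(profile: ConcProfile) -> float:
    """AUC from the first to the last quantifiable point (linear up, log down)."""
    t, c = profile.quantifiable()
    if t.size < 2:
        raise InsufficientDataError("need >=2 quantifiable points for AUC")
    return sum(
        _segment_auc(t[i], t[i + 1], c[i], c[i + 1])[0] for i in range(t.size - 1)
    )


def nca_iv_bolus(profile: ConcProfile) -> NCAResult:
    """Full IV-bolus NCA of one profile.

    C0 is back-extrapolated log-linearly through the first two quantifiable
    concentrations (falling back to the first observed value when they do
    not decline); the [0, t1] segment uses C0.  AUC∞ adds Clast/λz using
    the observed last quantifiable concentration.
    """
    if not profile.dose > 0:
        raise NCAError("dose must be > 0")
    t, c = profile.quantifiable()
    if t.size < 2:
        raise InsufficientDataError("need >=2 quantifiable points")
    lambda_z, n_pts, adj_r2 = fit_lambda_z(profile)

    cmax = float(c.max())
    tmax = float(t[int(np.argmax(c))])
    # back-extrapolate C0 to time zero
    if t[0] > 0:
        slope = (math.log(c[1]) - math.log(c[0])) / (t[1] - t[0])
        c0 = float(np.exp(math.log(c[0]) - slope * t[0])) if slope < 0 else float(c[0])
        tt = np.concatenate(([0.0], t))
        cc = np.concatenate(([c0], c))
    else:
        c0 = float(c[0])
        tt, cc = t, c

    auc_last = 0.0
    aumc_last = 0.0
    for i in range(tt.size - 1):
        a, m = _segment_auc(tt[i], tt[i + 1], cc[i], cc[i + 1])
        auc_last += a
        aumc_last += m

    c_last, t_last = float(c[-1]), float(t[-1])
    auc_inf = auc_last + c_last / lambda_z
    aumc_inf = aumc_last + c_last * t_last / lambda_z + c_last / lambda_z**2

    cl_f = profile.dose / auc_inf  # (mg/kg)/(mg·day/L) = L/day/kg
    vz = cl_f / lambda_z
    vss = cl_f * aumc_inf / auc_inf
    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        c0=c0,
        auc_last=auc_last,
        auc_inf=auc_inf,
        aumc_inf=aumc_inf,
        lambda_z=lambda_z,
        t_half=math.log(2.0) / lambda_z,
        n_lambda_points=n_pts,
        adj_r2=adj_r2,
        cl_f=cl_f,
        vz=vz,
        vss=vss,
    )
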