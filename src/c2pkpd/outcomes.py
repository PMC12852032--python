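"""Transplant-outcome statistics on log-transformed longitudinal data.

Two estimators are provided for treated-vs-control comparisons of
positive-valued outcomes (serum creatinine, BUN, NGAL fold-increase):

* :func:`fit_day3` — a single-day linear model on log values with a
  separate residual variance per treatment group; the group difference is
  tested with a Wald statistic using Welch–Satterthwaite degrees of
  freedom.
* :func:`fit_longitudinal` — a longitudinal model on log values with
  group, day and their interaction as categorical fixed effects and a
  per-treatment-group heterogeneous covariance among an animal's repeated
  measures: heterogeneous compound symmetry (CSH; per-day SDs, one common
  correlation) or heterogeneous first-order autoregressive (ARH(1);
  per-day SDs, correlation decaying with positional lag).  Fitting is by
  restricted maximum likelihood with derivative-free optimisation from
  three deterministic starts; animals with partial follow-up contribute
  their available rows.

Group contrasts (:func:`wald_contrast`) are reported as percent
reductions, 100·(1 − exp(cᵀβ)), with confidence limits transformed the
same way and Satterthwaite degrees of freedom obtained from numerical
derivatives of the fitted covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import t as t_dist

__all__ = [
    "OutcomeTable",
    "MixedModelFit",
    "TreatmentEffect",
    "OutcomeError",
    "fit_day3",
    "fit_longitudinal",
    "wald_contrast",
]

GROUP_ORDER = ("control", "treated")
RHO_BOUND = 0.99
# hard floor on residual SDs: keeps the GLS system well-conditioned when the
# data are (near-)noise-free
SD_FLOOR = 1e-4


class OutcomeError(ValueError):
    pass


@dataclass
class OutcomeTable:
    """Long-format outcome data: one row per animal × day × outcome.

    Values must be strictly positive (they are modelled on the log scale)
    and follow-up must be monotone: an animal absent at one day is absent
    at all later days for that outcome.
    """

    df: pd.DataFrame

    REQUIRED = ("animal", "group", "day", "outcome", "value")

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise OutcomeError(f"missing columns: {missing}")
        if (df["value"] <= 0).any():
            raise OutcomeError("outcome values must be strictly positive")
        dup = df.duplicated(subset=["animal", "day", "outcome"])
        if dup.any():
            raise OutcomeError("duplicate animal×day×outcome rows")
        for outcome, sub in df.groupby("outcome"):
            days_all = sorted(sub["day"].unique())
            for animal, rows in sub.groupby("animal"):
                obs = sorted(rows["day"].unique())
                if obs != days_all[: len(obs)]:
                    raise OutcomeError(
                        f"non-monotone follow-up for animal {animal!r} ({outcome})"
                    )

    @classmethod
    def from_csv(cls, path) -> "OutcomeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def subset(self, outcome: str, day=None) -> pd.DataFrame:
        sub = self.df[self.df["outcome"] == outcome]
        if day is not None:
            sub = sub[sub["day"] == day]
        return sub


@dataclass
class TreatmentEffect:
    """A treated-vs-control contrast reported as a percent reduction."""

    pct_reduction: float
    ci_low: float
    ci_high: float
    p_value: float
    df: float
    contrast: str
    log_estimate: float
    se: float

    def as_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "pct_reduction": self.pct_reduction,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "df": self.df,
            "log_estimate": self.log_estimate,
            "se": self.se,
        }


def _pct_effect(est: float, se: float, df: float, contrast: str) -> TreatmentEffect:
    if se == 0.0:
        p = 1.0 if est == 0.0 else 0.0
        lo = hi = est
    else:
        dfe = df if math.isfinite(df) and df > 0 else np.inf
        tstat = est / se
        p = 2.0 * float(t_dist.sf(abs(tstat), dfe))
        tcrit = float(t_dist.ppf(0.975, dfe))
        lo, hi = est - tcrit * se, est + tcrit * se
    # lower log bound -> larger reduction
    return TreatmentEffect(
        pct_reduction=100.0 * (1.0 - math.exp(est)),
        ci_low=100.0 * (1.0 - math.exp(hi)),
        ci_high=100.0 * (1.0 - math.exp(lo)),
        p_value=p,
        df=df,
        contrast=contrast,
        log_estimate=est,
        se=se,
    )


def fit_day3(table: OutcomeTable, outcome: str, day: float = 3) -> TreatmentEffect:
    """Single-day heterogeneous-variance model on log values.

    Equivalent to Welch's unequal-variance comparison of log-group means;
    the effect is reported as a percent reduction of the treated group's
    geometric mean relative to control.
    """
    sub = table.subset(outcome, day=day)
    grp = {g: np.log(sub[sub["group"] == g]["value"].to_numpy(float)) for g in GROUP_ORDER}
    for g, v in grp.items():
        if v.size < 2:
            raise OutcomeError(f"group {g!r} needs >=2 animals at day {day}")
    yc, yt = grp["control"], grp["treated"]
    est = float(yt.mean() - yc.mean())
    v_t = yt.var(ddof=1) / yt.size
    v_c = yc.var(ddof=1) / yc.size
    se = math.sqrt(v_t + v_c)
    if se == 0.0:
        df = np.inf
    else:
        df = (v_t + v_c) ** 2 / (
            v_t**2 / (yt.size - 1) + v_c**2 / (yc.size - 1)
        )
    return _pct_effect(est, se, df, contrast=f"day-{day:g}")


# ---------------------------------------------------------------------------
# longitudinal REML with heterogeneous CSH / ARH(1) covariance
# ---------------------------------------------------------------------------


def _solve_gls(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve A beta = b with diagonal equilibration (A can be ill-scaled
    when some residual SDs sit at the floor)."""
    d = np.sqrt(np.abs(np.diag(A)))
    d[d <= 0] = 1.0
    As = A / np.outer(d, d)
    bs = b / d
    try:
        x = np.linalg.solve(As, bs)
    except np.linalg.LinAlgError:
        x = np.linalg.lstsq(As, bs, rcond=None)[0]
    return x / d


def _corr_matrix(structure: str, rho: float, idx: np.ndarray) -> np.ndarray:
    """Correlation among the observed day positions ``idx`` (0-based)."""
    if structure == "CSH":
        k = idx.size
        C = np.full((k, k), rho)
        np.fill_diagonal(C, 1.0)
        return C
    if structure == "ARH1":
        lag = np.abs(idx[:, None] - idx[None, :])
        return rho**lag
    raise OutcomeError(f"unknown covariance structure {structure!r}")


@dataclass
class MixedModelFit:
    """A fitted heterogeneous-covariance longitudinal model on log values."""

    beta: dict[str, float]
    vcov_beta: np.ndarray
    covparams: dict[str, dict]
    structure: str
    reml_loglik: float
    converged: bool
    days: list
    groups: list
    n_obs: int
    _theta: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    _reml: Callable = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def beta_vector(self) -> np.ndarray:
        return np.array(list(self.beta.values()))


def _build_design(sub: pd.DataFrame):
    days = sorted(sub["day"].unique())
    groups = [g for g in GROUP_ORDER if g in set(sub["group"])]
    if not groups:
        raise OutcomeError("no recognised treatment groups")
    labels = ["(Intercept)"]
    if len(groups) > 1:
        labels.append("treated")
    labels += [f"day{d:g}" for d in days[1:]]
    if len(groups) > 1:
        labels += [f"treated:day{d:g}" for d in days[1:]]
    p = len(labels)

    def x_row(gi: int, di: int) -> np.ndarray:
        x = np.zeros(p)
        x[0] = 1.0
        off = 1
        if len(groups) > 1:
            x[1] = float(gi == 1)
            off = 2
        if di > 0:
            x[off + di - 1] = 1.0
            if len(groups) > 1 and gi == 1:
                x[off + len(days) - 1 + di - 1] = 1.0
        return x

    return days, groups, labels, x_row


def _group_patterns(sub: pd.DataFrame, days: list, groups: list):
    """Organise animals by (group, observed-day pattern) for fast REML."""
    day_pos = {d: i for i, d in enumerate(days)}
    out: dict[tuple[int, tuple[int, ...]], list[np.ndarray]] = {}
    for (g, animal), rows in sub.groupby(["group", "animal"], sort=True):
        gi = groups.index(g)
        rows = rows.sort_values("day")
        idx = tuple(day_pos[d] for d in rows["day"])
        out.setdefault((gi, idx), []).append(np.log(rows["value"].to_numpy(float)))
    return {k: np.array(v) for k, v in out.items()}


def _reml_machinery(patterns, days, groups, x_row, structure):
    D, G = len(days), len(groups)
    p = x_row(0, 0).size
    # constants per (group, pattern): design block, per-pattern mean and
    # within-pattern scatter (kept separate so the REML quadratic form can be
    # evaluated without catastrophic cancellation on near-noise-free data)
    blocks = []
    for (gi, idx), Y in patterns.items():
        ii = np.array(idx)
        n_a = Y.shape[0]
        m = Y.mean(axis=0)
        resid = Y - m
        blocks.append(
            (
                gi,
                ii,
                np.array([x_row(gi, di) for di in idx]),  # Xp (k×p)
                n_a,
                m,
                resid.T @ resid,  # within-pattern scatter
            )
        )
    n_total = sum(Y.size for Y in patterns.values())

    def components(theta: np.ndarray):
        sds = np.exp(np.clip(theta[: G * D], math.log(SD_FLOOR), 20.0)).reshape(G, D)
        rhos = RHO_BOUND * np.tanh(theta[G * D :])
        A = np.zeros((p, p))
        b = np.zeros(p)
        pieces = []
        logdet = 0.0
        scatter_quad = 0.0
        for gi, ii, Xp, n_a, m, scat in blocks:
            s = sds[gi, ii]
            S = _corr_matrix(structure, rhos[gi], ii) * np.outer(s, s)
            sign, ld = np.linalg.slogdet(S)
            if sign <= 0:
                return None
            try:
                Si = np.linalg.inv(S)
            except np.linalg.LinAlgError:
                return None
            logdet += n_a * float(ld)
            XtSi = Xp.T @ Si
            A += n_a * (XtSi @ Xp)
            b += n_a * (XtSi @ m)
            scatter_quad += float(np.sum(Si * scat))
            pieces.append((Xp, n_a, m, Si))
        return A, b, scatter_quad, logdet, pieces

    def neg2_reml(theta: np.ndarray) -> float:
        comp = components(theta)
        if comp is None:
            return 1e12
        A, b, scatter_quad, logdet, pieces = comp
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e12
        beta = _solve_gls(A, b)
        if not np.all(np.isfinite(beta)):
            return 1e12
        ypy = scatter_quad
        for Xp, n_a, m, Si in pieces:
            d = m - Xp @ beta
            ypy += n_a * float(d @ Si @ d)
        return logdet + logdetA + ypy + (n_total - p) * math.log(2.0 * math.pi)

    return components, neg2_reml, n_total


def _moment_inits(patterns, days, groups, structure) -> list[np.ndarray]:
    D, G = len(days), len(groups)
    # per-(group, day) residual SDs around cell means
    cells: dict[tuple[int, int], list[float]] = {}
    for (gi, idx), Y in patterns.items():
        for j, di in enumerate(idx):
            cells.setdefault((gi, di), []).extend(Y[:, j])
    logsd = np.full((G, D), math.log(0.3))
    pooled = []
    for (gi, di), vals in cells.items():
        if len(vals) >= 2:
            sd = float(np.std(vals, ddof=1))
            if sd > 0:
                logsd[gi, di] = math.log(max(sd, 1e-3))
                pooled.append(math.log(max(sd, 1e-3)))
    if pooled:
        flat = float(np.mean(pooled))
    else:
        flat = math.log(0.3)

    def z(rho: float) -> float:
        return math.atanh(max(min(rho / RHO_BOUND, 0.95), -0.95))

    starts = [
        np.concatenate([logsd.ravel(), np.full(G, z(0.3))]),
        np.concatenate([np.full(G * D, flat), np.full(G, z(0.0))]),
        np.concatenate([logsd.ravel(), np.full(G, z(0.7))]),
    ]
    return starts


def fit_longitudinal(
    table: OutcomeTable,
    outcome: str,
    structure: str = "CSH",
    *,
    maxfev: int = 4000,
) -> MixedModelFit:
    """REML fit of the heterogeneous CSH or ARH(1) longitudinal model.

    ARH(1) lags are positional: days {3,5,7,14} occupy positions 1..4 and
    the correlation between positions s and t is rho^|s-t|.
    """
    if structure not in ("CSH", "ARH1"):
        raise OutcomeError(f"structure must be 'CSH' or 'ARH1', got {structure!r}")
    sub = table.subset(outcome)
    if sub.empty:
        raise OutcomeError(f"no rows for outcome {outcome!r}")
    days, groups, labels, x_row = _build_design(sub)
    if len(days) < 2:
        raise OutcomeError("need >=2 days for a longitudinal fit")
    for g in groups:
        for d in days:
            if sub[(sub["group"] == g) & (sub["day"] == d)].empty:
                raise OutcomeError(f"empty design cell: group {g!r}, day {d:g}")
    patterns = _group_patterns(sub, days, groups)
    components, neg2_reml, n_total = _reml_machinery(
        patterns, days, groups, x_row, structure
    )

    # first (moment-based) start gets the full budget; the other two act as
    # local-optimum guards and are polished only if they win
    starts = _moment_inits(patterns, days, groups, structure)
    best = None
    for s, budget in zip(starts, (maxfev, maxfev // 8, maxfev // 8)):
        res = minimize(
            neg2_reml,
            s,
            method="Nelder-Mead",
            options={"maxfev": budget, "xatol": 1e-5, "fatol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    assert best is not None
    if not best.success:  # a guard start won on a reduced budget: polish it
        best = minimize(
            neg2_reml,
            best.x,
            method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 1e-5, "fatol": 1e-8},
        )
    theta = best.x
    comp = components(theta)
    if comp is None:
        raise OutcomeError("covariance singular at the optimum")
    A, b = comp[0], comp[1]
    beta = _solve_gls(A, b)
    vcov = np.linalg.inv(A)

    G, D = len(groups), len(days)
    sds = np.exp(np.clip(theta[: G * D], math.log(SD_FLOOR), 20.0)).reshape(G, D)
    rhos = RHO_BOUND * np.tanh(theta[G * D :])
    covparams = {
        g: {"sd": {f"{d:g}": float(sds[gi, di]) for di, d in enumerate(days)},
            "rho": float(rhos[gi])}
        for gi, g in enumerate(groups)
    }
    return MixedModelFit(
        beta=dict(zip(labels, beta)),
        vcov_beta=vcov,
        covparams=covparams,
        structure=structure,
        reml_loglik=-0.5 * best.fun,
        converged=bool(best.success),
        days=days,
        groups=groups,
        n_obs=n_total,
        _theta=theta,
        _reml=(components, neg2_reml),
    )


def _contrast_vector(fit: MixedModelFit, contrast: str) -> np.ndarray:
    labels = list(fit.beta)
    if "treated" not in labels:
        raise OutcomeError("contrast requires both treatment groups in the fit")
    c = np.zeros(len(labels))
    D = len(fit.days)
    if contrast == "day-3":
        c[labels.index("treated")] = 1.0  # reference day is the first (day 3)
    elif contrast == "across-days":
        c[labels.index("treated")] = 1.0
        for d in fit.days[1:]:
            c[labels.index(f"treated:day{d:g}")] = 1.0 / D
    else:
        raise OutcomeError(f"unknown contrast {contrast!r}")
    return c


def _satterthwaite_df(fit: MixedModelFit, c: np.ndarray) -> float:
    components, neg2_reml = fit._reml
    theta = fit._theta

    def var_c(th: np.ndarray) -> float:
        comp = components(th)
        if comp is None:
            return np.nan
        A = comp[0]
        return float(c @ np.linalg.solve(A, c))

    v0 = var_c(theta)
    h = 1e-4
    grad = np.zeros(theta.size)
    for j in range(theta.size):
        e = np.zeros(theta.size)
        e[j] = h
        grad[j] = (var_c(theta + e) - var_c(theta - e)) / (2 * h)
    # observed information of the REML criterion (-2 log-lik) is H/2
    hstep = 1e-3
    n = theta.size
    H = np.zeros((n, n))
    f0 = neg2_reml(theta)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = hstep
        fpp = neg2_reml(theta + ei)
        fmm = neg2_reml(theta - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / hstep**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = hstep
            H[i, j] = H[j, i] = (
                neg2_reml(theta + ei + ej)
                - neg2_reml(theta + ei - ej)
                - neg2_reml(theta - ei + ej)
                + neg2_reml(theta - ei - ej)
            ) / (4 * hstep**2)
    try:
        var_theta = 2.0 * np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        return np.inf
    denom = float(grad @ var_theta @ grad)
    if not math.isfinite(denom) or denom <= 0:
        return np.inf
    df = 2.0 * v0**2 / denom
    return max(df, 1.0)


def wald_contrast(
    fit: MixedModelFit, contrast: str, *, satterthwaite: bool = True
) -> TreatmentEffect:
    """Wald test of a treated-vs-control contrast from a longitudinal fit.

    ``contrast='day-3'`` is the group difference at the first day;
    ``'across-days'`` averages the per-day group differences on the log
    scale.  Degrees of freedom are Satterthwaite, from numerical
    derivatives of cᵀ·Var(β)·c with respect to the covariance parameters;
    ``satterthwaite=False`` skips that computation and uses a normal
    reference (useful in Monte-Carlo loops that only need the estimate).
    """
    c = _contrast_vector(fit, contrast)
    beta = fit.beta_vector
    est = float(c @ beta)
    var = float(c @ fit.vcov_beta @ c)
    se = math.sqrt(max(var, 0.0))
    df = _satterthwaite_df(fit, c) if (satterthwaite and se > 0) else np.inf
    return _pct_effect(est, se, df, contrast=contrast)
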