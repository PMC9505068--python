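"""Noncompartmental analysis (NCA) of single-dose IV-bolus profiles.

Given a concentration–time profile C(t) sampled from time zero, the
moment integrals are computed by the linear trapezoidal rule:

    AUC_0-t  = integral of C dt        (exposure)
    AUMC_0-t = integral of t * C dt    (first moment)
    M2_0-t   = integral of t^2 * C dt  (second moment)

The terminal elimination rate constant lambda_z is the negative slope of
an ordinary least-squares fit of ln C on t over terminal points; the
default point selection maximises adjusted r^2 over terminal suffixes of
at least three quantifiable points after (and excluding) C_max. The tail
beyond the last quantifiable time t_last is extrapolated analytically from
the predicted last concentration C_pred = exp(fit at t_last):

    AUC_0-inf  = AUC_0-t  + C_pred / lz
    AUMC_0-inf = AUMC_0-t + t_last * C_pred / lz + C_pred / lz^2
    M2_0-inf   = M2_0-t + t_last^2 * C_pred / lz
                 + 2 * t_last * C_pred / lz^2 + 2 * C_pred / lz^3

Derived parameters: MRT = AUMC/AUC, VRT = M2/AUC - MRT^2 (both to t and to
infinity), t_half = ln2 / lz, CL = Dose / AUC_0-inf, V = CL / lz, and
C_max = the maximum observed concentration. The definitional identities
t_half * lz = ln2, CL * AUC_0-inf = Dose and V = CL / lz hold exactly for
every accepted fit.

Units follow the plasma study convention: time in h, concentration in
ug/L, dose in ug/kg, hence CL in L/h/kg and V in L/kg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConcentrationTimeProfile",
    "LambdaZFit",
    "NCAResult",
    "PARAM_COLUMNS",
    "trapezoid_moments",
    "fit_lambda_z",
    "nca_parameters",
    "batch_nca",
    "BatchNCAResult",
]

#: the 14 reported parameters, in conventional reporting order
PARAM_COLUMNS = [
    "auc_0_t", "auc_0_inf", "aumc_0_t", "aumc_0_inf",
    "mrt_0_t", "mrt_0_inf", "vrt_0_t", "vrt_0_inf",
    "lambda_z", "c_last_pred", "t_half", "v", "cl", "c_max",
]


@dataclass
class ConcentrationTimeProfile:
    """One subject's dose and sampled plasma concentrations.

    ``bloq`` flags samples below the lower limit of quantification; such
    points are retained in the profile but excluded from terminal-phase
    fitting.
    """

    subject_id: str
    group: str
    dose: float  # ug per kg body weight
    times: np.ndarray  # h, strictly increasing, starting at 0
    concentrations: np.ndarray  # ug/L, non-negative
    bloq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.bloq is None:
            self.bloq = np.zeros(self.times.shape, dtype=bool)
        else:
            self.bloq = np.asarray(self.bloq, dtype=bool)
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if self.bloq.shape != self.times.shape:
            raise ValueError("bloq flags must match the sampling length")
        if self.times.size and self.times[0] != 0:
            raise ValueError("sampling must start at time 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if int((~self.bloq).sum()) < 3:
            raise ValueError("at least 3 quantifiable points are required")

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression diagnostics."""

    lambda_z: float  # 1/h
    intercept: float  # ln(ug/L) at t = 0
    n_points: int
    t_first: float
    t_last: float
    r2_adjusted: float
    c_last_pred: float  # ug/L, back-predicted at the profile's last time


@dataclass(frozen=True)
class NCAResult:
    """The 14 noncompartmental parameters plus the terminal fit."""

    subject_id: str
    group: str
    auc_0_t: float
    auc_0_inf: float
    aumc_0_t: float
    aumc_0_inf: float
    mrt_0_t: float
    mrt_0_inf: float
    vrt_0_t: float
    vrt_0_inf: float
    lambda_z: float
    c_last_pred: float
    t_half: float
    v: float
    cl: float
    c_max: float
    fit: LambdaZFit = field(compare=False)

    def as_series(self) -> pd.Series:
        return pd.Series({c: getattr(self, c) for c in PARAM_COLUMNS})


def trapezoid_moments(profile: ConcentrationTimeProfile) -> tuple[float, float, float]:
    """Linear-trapezoid AUC, AUMC and second-moment integral over the
    observed interval."""
    t, c = profile.times, profile.concentrations
    if t.size < 2:
        raise ValueError("at least two points are needed for integration")
    auc = float(np.trapezoid(c, t))
    aumc = float(np.trapezoid(t * c, t))
    m2 = float(np.trapezoid(t * t * c, t))
    return auc, aumc, m2


def _ols_loglinear(t: np.ndarray, lnc: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and adjusted r^2 of ln C on t."""
    slope, intercept = np.polyfit(t, lnc, 1)
    resid = lnc - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((lnc - lnc.mean()) ** 2).sum())
    n = t.size
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return float(slope), float(intercept), r2_adj


def fit_lambda_z(
    profile: ConcentrationTimeProfile,
    selection: str | int | tuple[float, float] = "auto",
) -> LambdaZFit:
    """Estimate the terminal elimination rate constant.

    selection:
        ``"auto"``       best adjusted r^2 over terminal suffixes of >= 3
                         quantifiable points strictly after C_max;
        ``int`` k        the last k quantifiable points (still after C_max);
        ``(t0, t1)``     all quantifiable points with t0 <= t <= t1.

    Raises ``ValueError`` when fewer than three candidate points exist or
    no candidate window shows a terminal decline (positive slope).
    """
    t, c, bloq = profile.times, profile.concentrations, profile.bloq
    usable = (~bloq) & (c > 0)
    i_cmax = int(np.argmax(np.where(usable, c, -np.inf)))
    candidates = np.flatnonzero(usable & (np.arange(t.size) > i_cmax))
    t_last_q = float(t[np.flatnonzero(usable)[-1]])

    if isinstance(selection, tuple):
        lo, hi = selection
        idx = candidates[(t[candidates] >= lo) & (t[candidates] <= hi)]
        windows = [idx]
    elif isinstance(selection, int):
        if selection < 3:
            raise ValueError("last_n selection needs at least 3 points")
        windows = [candidates[-selection:]]
    elif selection == "auto":
        windows = [candidates[-k:] for k in range(3, candidates.size + 1)]
    else:
        raise ValueError(f"unknown selection {selection!r}")

    best: LambdaZFit | None = None
    for idx in windows:
        if idx.size < 3:
            continue
        slope, intercept, r2_adj = _ols_loglinear(t[idx], np.log(c[idx]))
        if slope >= 0:
            continue
        fit = LambdaZFit(
            lambda_z=-slope,
            intercept=intercept,
            n_points=int(idx.size),
            t_first=float(t[idx[0]]),
            t_last=float(t[idx[-1]]),
            r2_adjusted=r2_adj,
            c_last_pred=float(np.exp(intercept + slope * t_last_q)),
        )
        if best is None or fit.r2_adjusted > best.r2_adjusted:
            best = fit
    if best is None:
        if not any(idx.size >= 3 for idx in windows):
            raise ValueError(
                "no terminal decline: fewer than 3 quantifiable points after C_max"
            )
        raise ValueError("no terminal decline (non-positive elimination slope)")
    return best


def nca_parameters(
    profile: ConcentrationTimeProfile,
    selection: str | int | tuple[float, float] = "auto",
) -> NCAResult:
    """Full noncompartmental parameter set for one profile."""
    fit = fit_lambda_z(profile, selection)
    auc_t, aumc_t, m2_t = trapezoid_moments(profile)
    lz = fit.lambda_z
    usable = (~profile.bloq) & (profile.concentrations > 0)
    t_last = float(profile.times[np.flatnonzero(usable)[-1]])
    cp = fit.c_last_pred

    auc_inf = auc_t + cp / lz
    aumc_inf = aumc_t + t_last * cp / lz + cp / lz**2
    m2_inf = m2_t + t_last**2 * cp / lz + 2 * t_last * cp / lz**2 + 2 * cp / lz**3

    mrt_t = aumc_t / auc_t
    mrt_inf = aumc_inf / auc_inf
    vrt_t = m2_t / auc_t - mrt_t**2
    vrt_inf = m2_inf / auc_inf - mrt_inf**2

    cl = profile.dose / auc_inf
    return NCAResult(
        subject_id=profile.subject_id,
        group=profile.group,
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        aumc_0_t=aumc_t,
        aumc_0_inf=aumc_inf,
        mrt_0_t=mrt_t,
        mrt_0_inf=mrt_inf,
        vrt_0_t=vrt_t,
        vrt_0_inf=vrt_inf,
        lambda_z=lz,
        c_last_pred=cp,
        t_half=math.log(2) / lz,
        v=cl / lz,
        cl=cl,
        c_max=float(profile.concentrations.max()),
        fit=fit,
    )


@dataclass
class BatchNCAResult:
    """Subject-by-parameter table plus the subjects whose terminal fit
    failed (excluded from any downstream summary)."""

    table: pd.DataFrame  # columns: subject, group, then PARAM_COLUMNS
    failures: pd.DataFrame  # columns: subject, group, reason


def batch_nca(
    profiles: Iterable[ConcentrationTimeProfile],
    selection: str | int | tuple[float, float] = "auto",
) -> BatchNCAResult:
    """Run NCA over a study's profiles, flagging failed fits instead of
    aborting."""
    rows, failed = [], []
    for p in profiles:
        try:
            res = nca_parameters(p, selection)
        except ValueError as exc:
            logger.warning("NCA failed for subject %s: %s", p.subject_id, exc)
            failed.append({"subject": p.subject_id, "group": p.group, "reason": str(exc)})
            continue
        row = {"subject": p.subject_id, "group": p.group}
        row.update({c: getattr(res, c) for c in PARAM_COLUMNS})
        rows.append(row)
    table = pd.DataFrame(rows, columns=["subject", "group", *PARAM_COLUMNS])
    failures = pd.DataFrame(failed, columns=["subject", "group", "reason"])
    if table.empty:
        raise ValueError("every profile failed noncompartmental analysis")
    return BatchNCAResult(table=table, failures=failures)
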