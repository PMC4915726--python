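"""Stereoselectivity and kinetics analytics.

Signed enantiomeric excess from enantiomer peak areas, the odds-form
selectivity log(E) = log10[(1+ee)/(1−ee)], replicate aggregation, and
nonlinear Michaelis–Menten fitting with standard errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PeakPair",
    "EnantioStat",
    "KineticsFit",
    "EnantiopureError",
    "ConvergenceError",
    "ee_from_areas",
    "log_e_from_ee",
    "aggregate_replicates",
    "enantio_stat",
    "fit_michaelis_menten",
    "catalytic_efficiency",
]


class EnantiopureError(ValueError):
    """|ee| >= 1: the selectivity E is unbounded."""


class ConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge or a parameter is unidentifiable."""


@dataclass(frozen=True)
class PeakPair:
    """Integrated areas of the two enantiomer peaks of one run.

    ``area_ref`` belongs to the designated reference enantiomer (the sign
    convention of the assay); the assignment metadata (label, retention
    time) travels with the pair.
    """

    area_ref: float
    area_other: float
    run_id: str = ""
    ref_label: str = ""
    ref_retention_min: float | None = None

    def __post_init__(self) -> None:
        if self.area_ref < 0 or self.area_other < 0:
            raise ValueError("peak areas must be non-negative")
        if self.area_ref + self.area_other <= 0:
            raise ValueError("both peak areas are zero")


def ee_from_areas(p: PeakPair) -> float:
    """Signed enantiomeric excess (area_ref − area_other)/(area_ref + area_other).

    Positive toward the reference enantiomer.  ±1 (single-enantiomer) values
    raise a warning flag but are returned as-is.
    """
    ee = (p.area_ref - p.area_other) / (p.area_ref + p.area_other)
    if abs(ee) == 1.0:
        warnings.warn(f"run {p.run_id or '?'}: single enantiomer detected (ee = {ee:+.0f})", stacklevel=2)
    return ee


def log_e_from_ee(ee: float) -> float:
    """log10[(1+ee)/(1−ee)]: base-10 odds-form selectivity, antisymmetric in ee."""
    if abs(ee) >= 1.0:
        raise EnantiopureError(f"enantiopure: E unbounded at ee = {ee}")
    return math.log10((1.0 + ee) / (1.0 - ee))


def aggregate_replicates(values: Sequence[float]) -> tuple[float, float | None, int]:
    """Mean, sample SD (n−1; None for a single value) and n of replicate ee values."""
    if len(values) == 0:
        raise ValueError("no replicate values")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if len(arr) < 2:
        warnings.warn("single replicate: SD undefined", stacklevel=2)
        return mean, None, 1
    return mean, float(arr.std(ddof=1)), len(arr)


@dataclass(frozen=True)
class EnantioStat:
    """Replicate-aggregated ee (fraction and %), with its log(E)."""

    ee: float
    ee_pct: float
    log_E: float
    n_replicates: int
    sd_ee_pct: float | None
    unbounded: bool = False


def enantio_stat(ee_pct_values: Sequence[float]) -> EnantioStat:
    """Aggregate replicate ee values (in %) and attach log(E) of the mean.

    Enantiopure means (|ee| = 100 %) yield a flagged ±inf sentinel instead
    of raising.
    """
    mean_pct, sd_pct, n = aggregate_replicates(ee_pct_values)
    ee = mean_pct / 100.0
    try:
        log_e = log_e_from_ee(ee)
        unbounded = False
    except EnantiopureError:
        log_e = math.copysign(math.inf, ee)
        unbounded = True
    return EnantioStat(
        ee=ee, ee_pct=mean_pct, log_E=log_e, n_replicates=n, sd_ee_pct=sd_pct, unbounded=unbounded
    )


@dataclass(frozen=True)
class KineticsFit:
    """Michaelis–Menten parameters with standard errors."""

    K_M: float
    K_M_se: float
    k_cat: float
    k_cat_se: float
    efficiency: float
    efficiency_se: float
    n_points: int
    converged: bool
    covariance: np.ndarray | None = None  # 2x2, order (k_cat, K_M)

    def __post_init__(self) -> None:
        if self.K_M <= 0 or self.k_cat <= 0:
            raise ValueError("K_M and k_cat must be positive")
        if abs(self.efficiency - self.k_cat / self.K_M) > 1e-9 * max(self.efficiency, 1.0):
            raise ValueError("efficiency inconsistent with k_cat/K_M")


def michaelis_menten(S, k_cat: float, K_M: float):
    S = np.asarray(S, dtype=float)
    return k_cat * S / (K_M + S)


def fit_michaelis_menten(
    substrate: Sequence[float],
    rate: Sequence[float],
    max_iterations: int = 500,
    tol: float = 1e-8,
) -> KineticsFit:
    """Least-squares fit of v = k_cat·S/(K_M + S).

    The fit runs on log-parameters (positivity by construction), starting at
    K_M = median(S), k_cat = max(v).  Standard errors come from the local
    curvature (Gauss–Newton covariance) at the optimum; the catalytic
    efficiency carries a first-order propagated SE ignoring the k_cat–K_M
    covariance (see :func:`catalytic_efficiency` for the covariance-aware
    version).
    """
    S = np.asarray(substrate, dtype=float)
    v = np.asarray(rate, dtype=float)
    if S.shape != v.shape or S.ndim != 1:
        raise ValueError("substrate and rate must be equal-length 1-D sequences")
    n = len(S)
    if n < 4:
        raise ValueError("need at least 4 (S, v) points")
    if np.any(S <= 0) or np.any(v <= 0):
        raise ValueError("substrate concentrations and rates must be positive")

    theta0 = np.log([float(np.max(v)), float(np.median(S))])  # (log k_cat, log K_M)

    def residuals(theta):
        k_cat, K_M = np.exp(theta)
        return michaelis_menten(S, k_cat, K_M) - v

    res = least_squares(
        residuals,
        theta0,
        method="lm",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iterations,
    )
    if not res.success:
        raise ConvergenceError(f"fit did not converge: {res.message}")
    k_cat, K_M = np.exp(res.x)
    if K_M < 1e-6 * float(np.min(S)) or K_M > 1e6 * float(np.max(S)):
        raise ConvergenceError(
            f"K_M unidentifiable: fitted value {K_M:.3g} escaped the substrate range "
            f"[{np.min(S):.3g}, {np.max(S):.3g}]"
        )

    # Gauss-Newton covariance in natural parameters (k_cat, K_M)
    J = np.column_stack([S / (K_M + S), -k_cat * S / (K_M + S) ** 2])
    ssr = float(np.sum(res.fun**2))
    dof = n - 2
    try:
        cov = np.linalg.inv(J.T @ J) * (ssr / dof)
    except np.linalg.LinAlgError:
        raise ConvergenceError("singular curvature: parameters unidentifiable")
    k_cat_se = float(np.sqrt(max(cov[0, 0], 0.0)))
    K_M_se = float(np.sqrt(max(cov[1, 1], 0.0)))
    eff, eff_se = _efficiency_and_se(k_cat, k_cat_se, K_M, K_M_se, cov=None)
    return KineticsFit(
        K_M=K_M,
        K_M_se=K_M_se,
        k_cat=k_cat,
        k_cat_se=k_cat_se,
        efficiency=eff,
        efficiency_se=eff_se,
        n_points=n,
        converged=True,
        covariance=cov,
    )


def _efficiency_and_se(
    k_cat: float, k_cat_se: float, K_M: float, K_M_se: float, cov: np.ndarray | None
) -> tuple[float, float]:
    eff = k_cat / K_M
    var = (k_cat_se / K_M) ** 2 + (k_cat * K_M_se / K_M**2) ** 2
    if cov is not None:
        var -= 2.0 * k_cat / K_M**3 * float(cov[0, 1])
    return eff, float(np.sqrt(max(var, 0.0)))


def catalytic_efficiency(fit: KineticsFit, use_covariance: bool = False) -> tuple[float, float]:
    """k_cat/K_M with first-order error propagation.

    By default the k_cat–K_M covariance is ignored; ``use_covariance``
    includes the cross term from the fit's covariance matrix.
    """
    if not fit.converged:
        raise ConvergenceError("efficiency requested from a non-converged fit")
    cov = fit.covariance if use_covariance else None
    return _efficiency_and_se(fit.k_cat, fit.k_cat_se, fit.K_M, fit.K_M_se, cov)
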