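"""Nonlinear least-squares inference for flux-rejection data.

The estimation problem: given replicated observations (v_w, R_obs) for a
solution condition, find the transport parameters (sigma, k_dbl and, for
the general model, k_m) minimising the sum of squared rejection residuals

    min  sum_j ( R_obs,j - R_pred(v_w,j; sigma, k_dbl[, k_m]) )^2

with R_pred from the general rejection equation (polarization + pore
diffusion) or its advection-dominated limit.  Three strategies mirror how
such data are analysed in practice:

* per-condition fits (2 or 3 parameters) — :class:`RejectionModel`;
* a joint fit with one mass-transfer coefficient k_dbl shared across all
  conditions and a sieving coefficient per condition —
  :class:`SharedKdblModel` (k_dbl is set by hydrodynamics, not chemistry);
* one-parameter fits with k_dbl frozen, e.g. at a Sherwood-correlation
  estimate — ``RejectionModel(..., fixed_kdbl=...)``.

Nested variants are compared with an F test on residual sums of squares.
Confidence intervals are linearized (Jacobian-based) with t quantiles at
the residual degrees of freedom; rate coefficients are optimised on a log
scale so they stay positive without hard bounds, and sigma is left
unbounded by default because near-complete-rejection data can push the
estimate marginally above 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import RejectionDataset
from .transport import (
    TransportParameters,
    UnphysicalValueWarning,
    rejection_advection,
    rejection_general,
)

__all__ = [
    "RejectionModel",
    "RejectionResults",
    "SharedKdblModel",
    "SharedKdblResults",
    "ModelComparison",
    "residual_ss",
    "fit_condition",
    "fit_shared_kdbl",
    "fit_fixed_kdbl",
    "f_test",
    "adjusted_r2",
]

#: default optimizer tolerances (gradient/step) and iteration cap
DEFAULT_TOL = 1e-12
DEFAULT_MAX_ITER = 500


def _predict(v_w: np.ndarray, params: TransportParameters, model: str) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UnphysicalValueWarning)
        pe_d = v_w / params.k_dbl
        if model == "general":
            if params.k_m is None:
                raise ValueError("the general model requires k_m")
            return np.asarray(rejection_general(params.sigma, pe_d, v_w / params.k_m))
        if model == "advection":
            return np.asarray(rejection_advection(params.sigma, pe_d))
    raise ValueError(f"unknown model {model!r}; use 'general' or 'advection'")


def residual_ss(params: TransportParameters, data: RejectionDataset,
                model: str = "advection") -> float:
    """Sum of squared rejection residuals for the given parameters."""
    r = data.r_obs - _predict(data.v_w, params, model)
    return float(np.dot(r, r))


@dataclass
class ModelComparison:
    """Nested-model F test on residual sums of squares.

    The simpler model (fewer parameters) contributes ss1/df1, the richer
    one ss2/df2; F = ((ss1-ss2)/(df1-df2)) / (ss2/df2) and p is the upper
    tail of F(df1-df2, df2).  A richer model that fits worse in finite
    precision yields F <= 0, reported as computed with p = 1.
    """

    F: float
    p: float
    ss1: float
    ss2: float
    df1: int
    df2: int

    def __str__(self) -> str:
        return (
            f"F({self.df1 - self.df2}, {self.df2}) = {self.F:.4g}, "
            f"p = {self.p:.4g}"
        )


class RejectionResults:
    """Estimates, uncertainties and diagnostics from a rejection-model fit.

    Attributes
    ----------
    params : TransportParameters
        Point estimates.
    se, ci95 : dict
        Standard errors and 95% confidence half-widths per free parameter
        (linearized covariance, t quantile at ``df_resid``).
    ss_res, df_resid, adj_r2, n_obs, converged
        Fit diagnostics; ``adj_r2`` may be negative for fits worse than
        the data mean, and NaN when the data carry no variance.
    """

    def __init__(self, model: "RejectionModel", params: TransportParameters,
                 free_names: Sequence[str], free_values: np.ndarray,
                 cov: np.ndarray, ss_res: float, converged: bool,
                 message: str = "", n_iter: int = 0):
        self.model = model
        self.params = params
        self.free_names = list(free_names)
        self.cov = cov
        self.ss_res = float(ss_res)
        self.converged = bool(converged)
        self.message = message
        self.n_iter = n_iter
        self.n_obs = model.n_obs
        self.df_resid = self.n_obs - len(free_names)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        self.se = dict(zip(self.free_names, se))
        tq = stats.t.ppf(0.975, self.df_resid) if self.df_resid > 0 else np.nan
        self.ci95 = {k: tq * v for k, v in self.se.items()}
        self._free_values = np.asarray(free_values, dtype=float)
        self.adj_r2 = _adjusted_r2(self.ss_res, model.endog, len(free_names))

    @property
    def kind(self) -> str:
        return self.model.kind

    def predict(self, v_w) -> np.ndarray:
        """Predicted observed rejection at the given fluxes."""
        return _predict(np.asarray(v_w, dtype=float), self.params, self.model.kind)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.predict(self.model.exog)

    def conf_int(self) -> pd.DataFrame:
        """95% confidence intervals as a (lower, upper) frame."""
        rows = {}
        for name, val in zip(self.free_names, self._free_values):
            hw = self.ci95[name]
            rows[name] = (val - hw, val + hw)
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    def compare_f_test(self, richer: "RejectionResults") -> ModelComparison:
        """F test of this (simpler) fit against a richer nested fit."""
        return f_test(self, richer)

    def summary(self) -> str:
        lines = [
            "Rejection model fit",
            "=" * 58,
            f"condition:       {self.model.dataset.condition_id}",
            f"model:           {self.model.kind}"
            + (" (k_dbl fixed)" if self.model.fixed_kdbl is not None else ""),
            f"n_obs:           {self.n_obs}",
            f"df_resid:        {self.df_resid}",
            f"ss_res:          {self.ss_res:.6g}",
            f"adj_r2:          {self.adj_r2:.4f}",
            f"converged:       {self.converged}",
            "-" * 58,
            f"{'param':<10}{'estimate':>14}{'std err':>14}{'95% CI +/-':>14}",
        ]
        for name, val in zip(self.free_names, self._free_values):
            lines.append(
                f"{name:<10}{val:>14.6g}{self.se[name]:>14.3g}{self.ci95[name]:>14.3g}"
            )
        if self.model.fixed_kdbl is not None:
            lines.append(f"{'k_dbl':<10}{self.model.fixed_kdbl:>14.6g}"
                         f"{'(fixed)':>14}{'':>14}")
        lines.append("=" * 58)
        return "\n".join(lines)


class RejectionModel:
    """Least-squares model for observed rejection versus flux, one condition.

    Parameters
    ----------
    dataset : RejectionDataset
        The (v_w, R_obs) observations.  Duplicate concentration readings
        enter as individual observations, preserving residual degrees of
        freedom for the F test.
    kind : {'advection', 'general'}
        Advection-dominated (sigma, k_dbl) or general (sigma, k_dbl, k_m)
        rejection equation.
    fixed_kdbl : float, optional
        Freeze k_dbl at this value (m/s) and fit sigma alone
        (advection kind only).
    sigma_bounds : (float, float), optional
        Bounds on sigma; default unbounded (physically sensible fits can
        nudge past 1 on near-total-rejection data).
    """

    def __init__(self, dataset: RejectionDataset, kind: str = "advection",
                 *, fixed_kdbl: Optional[float] = None,
                 sigma_bounds: Optional[tuple] = None):
        if kind not in ("advection", "general"):
            raise ValueError(f"unknown model kind {kind!r}")
        if fixed_kdbl is not None:
            if kind != "advection":
                raise ValueError("fixed_kdbl applies to the advection model only")
            if fixed_kdbl <= 0:
                raise ValueError("fixed_kdbl must be positive")
        self.dataset = dataset
        self.kind = kind
        self.fixed_kdbl = fixed_kdbl
        self.sigma_bounds = sigma_bounds
        self.exog = dataset.v_w
        self.endog = dataset.r_obs
        self.n_obs = dataset.n_obs
        if fixed_kdbl is not None:
            self.free_names = ["sigma"]
        elif kind == "advection":
            self.free_names = ["sigma", "k_dbl"]
        else:
            self.free_names = ["sigma", "k_dbl", "k_m"]
        self.n_params = len(self.free_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, condition_id: str = "data",
                       flux_col: str = "flux_m_per_s", r_col: str = "r_obs",
                       **kwargs) -> "RejectionModel":
        ds = RejectionDataset.from_arrays(
            condition_id, df[flux_col].to_numpy(float), df[r_col].to_numpy(float)
        )
        return cls(ds, **kwargs)

    # -- internal <-> natural parameterization ---------------------------
    # theta = (sigma, log k_dbl[, log k_m]); logs keep rates positive.

    def _to_params(self, theta: np.ndarray) -> TransportParameters:
        sigma = theta[0]
        if self.fixed_kdbl is not None:
            return TransportParameters(sigma=sigma, k_dbl=self.fixed_kdbl)
        k_dbl = float(np.exp(theta[1]))
        k_m = float(np.exp(theta[2])) if self.kind == "general" else None
        return TransportParameters(sigma=sigma, k_dbl=k_dbl, k_m=k_m)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        return self.endog - _predict(self.exog, self._to_params(theta), self.kind)

    def _default_init(self) -> np.ndarray:
        # sigma: its own small-flux limit; rates: the median flux, which
        # puts the corresponding Peclet number near 1.
        sigma0 = float(np.max(self.endog))
        med = float(np.median(self.exog))
        if self.fixed_kdbl is not None:
            return np.array([sigma0])
        if self.kind == "advection":
            return np.array([sigma0, np.log(med)])
        return np.array([sigma0, np.log(med), np.log(med)])

    def _theta_from_params(self, p: TransportParameters) -> np.ndarray:
        if self.fixed_kdbl is not None:
            return np.array([p.sigma])
        if self.kind == "advection":
            return np.array([p.sigma, np.log(p.k_dbl)])
        if p.k_m is None:
            raise ValueError("general-model initialization requires k_m")
        return np.array([p.sigma, np.log(p.k_dbl), np.log(p.k_m)])

    def fit(self, init: Optional[TransportParameters] = None, *,
            tol: float = DEFAULT_TOL,
            max_iter: int = DEFAULT_MAX_ITER) -> RejectionResults:
        """Fit by trust-region-reflective least squares.

        Raises on underdetermined data (fewer observations than free
        parameters + 1); non-convergence is flagged on the results object
        rather than raised.
        """
        if self.n_obs < self.n_params + 1:
            raise ValueError(
                f"need at least {self.n_params + 1} observations to fit "
                f"{self.n_params} parameter(s); got {self.n_obs}"
            )
        theta0 = self._default_init() if init is None else self._theta_from_params(init)
        lo = np.full_like(theta0, -np.inf)
        hi = np.full_like(theta0, np.inf)
        if self.sigma_bounds is not None:
            lo[0], hi[0] = self.sigma_bounds
            theta0[0] = np.clip(theta0[0], lo[0], hi[0])
        res = optimize.least_squares(
            self._residuals, theta0, bounds=(lo, hi), method="trf",
            ftol=tol, xtol=tol, gtol=tol, max_nfev=max_iter * len(theta0),
        )
        params = self._to_params(res.x)
        cov, free_values = self._covariance(res, params)
        return RejectionResults(
            self, params, self.free_names, free_values, cov,
            ss_res=2.0 * res.cost, converged=bool(res.success),
            message=res.message, n_iter=int(res.nfev),
        )

    def _covariance(self, res, params: TransportParameters):
        """Linearized covariance in *natural* units via the log chain rule."""
        free_values = [params.sigma]
        jac = np.array(res.jac, dtype=float, copy=True)
        if self.fixed_kdbl is None:
            # d r / d k = (d r / d log k) / k
            jac[:, 1] /= params.k_dbl
            free_values.append(params.k_dbl)
            if self.kind == "general":
                jac[:, 2] /= params.k_m
                free_values.append(params.k_m)
        df = self.n_obs - self.n_params
        s2 = 2.0 * res.cost / df if df > 0 else np.nan
        jtj_inv = np.linalg.pinv(jac.T @ jac)
        return s2 * jtj_inv, np.asarray(free_values)


# ---------------------------------------------------------------------------


class SharedKdblResults:
    """Joint-fit results: one k_dbl for all conditions, sigma per condition."""

    def __init__(self, model: "SharedKdblModel", sigmas: np.ndarray,
                 k_dbl: float, cov: np.ndarray, ss_res: float,
                 converged: bool, message: str = ""):
        self.model = model
        self.sigmas = dict(zip(model.condition_ids, sigmas))
        self.k_dbl = float(k_dbl)
        self.cov = cov
        self.ss_res = float(ss_res)
        self.converged = bool(converged)
        self.message = message
        self.n_obs = model.n_obs
        self.n_params = model.n_conditions + 1
        self.df_resid = self.n_obs - self.n_params
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        tq = stats.t.ppf(0.975, self.df_resid) if self.df_resid > 0 else np.nan
        self.se_sigma = dict(zip(model.condition_ids, se[:-1]))
        self.se_kdbl = float(se[-1])
        self.ci95_sigma = {k: tq * v for k, v in self.se_sigma.items()}
        self.ci95_kdbl = tq * self.se_kdbl
        endog = np.concatenate([ds.r_obs for ds in model.datasets])
        self.adj_r2 = _adjusted_r2(self.ss_res, endog, self.n_params)

    def condition_params(self, condition_id: str) -> TransportParameters:
        return TransportParameters(sigma=self.sigmas[condition_id], k_dbl=self.k_dbl)

    def predict(self, condition_id: str, v_w) -> np.ndarray:
        return _predict(np.asarray(v_w, dtype=float),
                        self.condition_params(condition_id), "advection")

    def summary(self) -> str:
        lines = [
            "Shared-k_dbl rejection fit (advection model)",
            "=" * 62,
            f"conditions:      {self.model.n_conditions}",
            f"n_obs:           {self.n_obs}",
            f"df_resid:        {self.df_resid}",
            f"ss_res:          {self.ss_res:.6g}",
            f"adj_r2:          {self.adj_r2:.4f}",
            f"k_dbl:           {self.k_dbl:.6g} m/s "
            f"(+/- {self.ci95_kdbl:.3g}, 95% CI)",
            "-" * 62,
            f"{'condition':<22}{'sigma':>12}{'std err':>14}{'95% CI +/-':>14}",
        ]
        for cid in self.model.condition_ids:
            lines.append(
                f"{cid:<22}{self.sigmas[cid]:>12.6g}"
                f"{self.se_sigma[cid]:>14.3g}{self.ci95_sigma[cid]:>14.3g}"
            )
        lines.append("=" * 62)
        return "\n".join(lines)


class SharedKdblModel:
    """Joint advection-model fit: per-condition sigma, one shared k_dbl.

    The mass-transfer coefficient of the polarization film is set by the
    module hydrodynamics (crossflow, spacer), so when only solution
    chemistry varies across conditions it is physically one parameter.
    """

    def __init__(self, datasets: Sequence[RejectionDataset]):
        datasets = list(datasets)
        if len(datasets) == 0:
            raise ValueError("need at least one dataset")
        ids = [ds.condition_id for ds in datasets]
        if len(set(ids)) != len(ids):
            raise ValueError("condition_ids must be unique")
        self.datasets = datasets
        self.condition_ids = ids
        self.n_conditions = len(datasets)
        self.n_obs = sum(ds.n_obs for ds in datasets)
        if self.n_obs < self.n_conditions + 2:
            raise ValueError(
                "underdetermined: need total observations >= n_conditions + 2"
            )

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        k_dbl = float(np.exp(theta[-1]))
        out = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UnphysicalValueWarning)
            for sigma, ds in zip(theta[:-1], self.datasets):
                out.append(ds.r_obs - rejection_advection(sigma, ds.v_w / k_dbl))
        return np.concatenate(out)

    def fit(self, *, tol: float = DEFAULT_TOL,
            max_iter: int = DEFAULT_MAX_ITER) -> SharedKdblResults:
        sigma0 = [float(np.max(ds.r_obs)) for ds in self.datasets]
        med = float(np.median(np.concatenate([ds.v_w for ds in self.datasets])))
        theta0 = np.array(sigma0 + [np.log(med)])
        res = optimize.least_squares(
            self._residuals, theta0, method="trf",
            ftol=tol, xtol=tol, gtol=tol, max_nfev=max_iter * len(theta0),
        )
        k_dbl = float(np.exp(res.x[-1]))
        jac = np.array(res.jac, dtype=float, copy=True)
        jac[:, -1] /= k_dbl
        df = self.n_obs - len(theta0)
        s2 = 2.0 * res.cost / df if df > 0 else np.nan
        cov = s2 * np.linalg.pinv(jac.T @ jac)
        return SharedKdblResults(
            self, res.x[:-1], k_dbl, cov, ss_res=2.0 * res.cost,
            converged=bool(res.success), message=res.message,
        )


# ---------------------------------------------------------------------------
# functional layer


def fit_condition(data: RejectionDataset, model: str = "advection",
                  init: Optional[TransportParameters] = None,
                  bounds: Optional[tuple] = None) -> RejectionResults:
    """Per-condition fit; see :class:`RejectionModel`."""
    return RejectionModel(data, model, sigma_bounds=bounds).fit(init=init)


def fit_shared_kdbl(datasets: Sequence[RejectionDataset]) -> SharedKdblResults:
    """Joint fit with a single k_dbl across conditions; see :class:`SharedKdblModel`."""
    return SharedKdblModel(datasets).fit()


def fit_fixed_kdbl(data: RejectionDataset, k_dbl: float) -> RejectionResults:
    """One-parameter sigma fit with k_dbl frozen (advection model)."""
    return RejectionModel(data, "advection", fixed_kdbl=k_dbl).fit()


def f_test(fit_small, fit_large) -> ModelComparison:
    """Compare nested fits by F statistic on residual sums of squares.

    ``fit_small`` is the model with fewer parameters (larger residual df).
    Accepts any pair of objects exposing ``ss_res`` and ``df_resid``.
    F <= 0 (richer model no better in finite precision) gives p = 1; a
    perfect richer model (ss2 = 0) gives F = +inf, p = 0.
    """
    ss1, df1 = fit_small.ss_res, fit_small.df_resid
    ss2, df2 = fit_large.ss_res, fit_large.df_resid
    if df1 <= df2:
        raise ValueError(
            f"fit_small must have more residual df than fit_large "
            f"(got df1={df1}, df2={df2})"
        )
    dfn = df1 - df2
    if ss2 == 0.0:
        if ss1 == 0.0:
            return ModelComparison(0.0, 1.0, ss1, ss2, df1, df2)
        return ModelComparison(np.inf, 0.0, ss1, ss2, df1, df2)
    F = ((ss1 - ss2) / dfn) / (ss2 / df2)
    p = 1.0 if F <= 0 else float(stats.f.sf(F, dfn, df2))
    return ModelComparison(float(F), p, ss1, ss2, df1, df2)


def _adjusted_r2(ss_res: float, endog: np.ndarray, n_params: int) -> float:
    n = len(endog)
    ss_tot = float(np.sum((endog - endog.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("zero total variance: adjusted r^2 undefined",
                      UserWarning, stacklevel=2)
        return np.nan
    df_res = n - n_params
    if df_res <= 0:
        return np.nan
    return 1.0 - (ss_res / df_res) / (ss_tot / (n - 1))


def adjusted_r2(fit, data: RejectionDataset) -> float:
    """Adjusted coefficient of determination of a fit on its dataset.

    1 - (ss_res/(n-p)) / (ss_tot/(n-1)); can go negative when the model
    does worse than the data mean.
    """
    n_params = getattr(fit, "n_params", None)
    if n_params is None:
        n_params = len(fit.free_names)
    return _adjusted_r2(fit.ss_res, data.r_obs, n_params)
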