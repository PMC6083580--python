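"""Warm-season quasi-Poisson regression with a temperature x time tensor smooth.

The model for daily all-natural-cause deaths Y_i, fitted to April-September
days only, is

    log E(Y_i) = alpha + Tensor(Tmean_n, Time) + s(dos) + dow + hol + wdd

where Tmean_n is the lag 0..n moving average of daily mean temperature (the
exposure), Time the progressive day count over the study period, dos the day
of season (1..183, 6-dof spline), dow/hol categorical day-of-week and holiday
terms and wdd the previous winter's (October-March) mean daily mortality,
entered linear.  The tensor term is the row-wise product of a cubic
regression spline basis in temperature (two interior knots) with a cubic
regression spline basis in time (one degree of freedom per study year),
letting the temperature-mortality curve vary smoothly across years.

The marginal bases are cardinal ("value-interpolating") natural cubic
regression splines, so each basis is a partition of unity and the tensor
block spans both marginal main effects and the constant.  Identifiability
alongside the intercept is obtained with a single sum-to-zero constraint on
the whole block, absorbed by an orthonormal reparameterization that is
stored in the fitted model and reapplied at prediction time.  The bases are
unpenalized regression splines at the stated dimensions; no smoothing
parameter is selected.

The quasi-likelihood fit itself (IRLS, log link, Pearson chi-square
dispersion) is delegated to statsmodels GLM.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import CubicSpline
from scipy.linalg import null_space

logger = logging.getLogger("heatvar")

__all__ = [
    "BasisSpec",
    "FittedModel",
    "lagged_exposure",
    "build_frame",
    "crs_basis",
    "tensor_design",
    "sum_to_zero_transform",
    "assemble_design",
    "fit_model",
    "predict_logrr",
    "tensor_contrast",
]

DEFAULT_HOLIDAYS = ((1, 1), (5, 1), (8, 15), (12, 25))

# IRLS convergence: relative deviance change below this, or 100 iterations.
IRLS_TOL = 1e-8
IRLS_MAXITER = 100


# ---------------------------------------------------------------------------
# Exposure and model frame
# ---------------------------------------------------------------------------

def lagged_exposure(tmean: Sequence[float], n: int) -> np.ndarray:
    """Moving average of the current day and previous ``n`` days.

    Element d equals mean(tmean[d-n..d]); the first ``n`` elements are NaN
    (undefined) and are excluded downstream.  With the full-year series
    supplied, early-April exposures correctly reach back into late March.
    """
    x = np.asarray(tmean, dtype=float)
    if n < 0:
        raise ValueError("lag n must be >= 0")
    if n >= len(x):
        raise ValueError("lag n must be smaller than the series length")
    if n == 0:
        return x.copy()
    return pd.Series(x).rolling(window=n + 1).mean().to_numpy()


def build_frame(series: pd.DataFrame, n: int,
                holidays: Sequence[tuple[int, int]] = DEFAULT_HOLIDAYS,
                ) -> pd.DataFrame:
    """Restrict a full-year city series to warm-season rows ready to fit.

    Columns: date, y (deaths), tmean_n, time (1-based day count from the
    first day of the series), dos (day of season, April 1 = 1), dow (0=Mon),
    hol (0/1), wdd (previous winter October-March mean daily deaths,
    constant within a warm season), year.

    The warm-season restriction is applied AFTER lag construction so that
    early-April exposures use late-March temperatures.  A warm season whose
    preceding October-March window has no overlap with the series at all
    (e.g. a series starting April 1) is dropped with a warning; a partial
    window (a series starting January 1 has only January-March before its
    first summer) is used as observed.
    """
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values("date").reset_index(drop=True)
    dates = pd.DatetimeIndex(df["date"])
    if len(dates) > 1 and not (np.diff(dates.to_numpy()).astype("timedelta64[D]")
                               == np.timedelta64(1, "D")).all():
        raise ValueError("series dates must be contiguous daily records")

    df["tmean_n"] = lagged_exposure(df["tmean"].to_numpy(), n)
    df["time"] = np.arange(1, len(df) + 1)
    month = dates.month
    year = dates.year
    warm = (month >= 4) & (month <= 9)

    hol_set = set(holidays)
    df["hol"] = [int((m, d) in hol_set) for m, d in zip(month, dates.day)]
    df["dow"] = dates.weekday

    # dos: days since March 31 of the same year.
    mar31 = pd.to_datetime({"year": year, "month": 3, "day": 31})
    df["dos"] = (dates - pd.DatetimeIndex(mar31)).days
    df["year"] = year

    rows = []
    for yr in np.unique(year[warm]):
        season = warm & (year == yr)
        win = (((year == yr - 1) & (month >= 10)) | ((year == yr) & (month <= 3)))
        if not win.any():
            logger.warning("warm season %d dropped: no preceding winter data", yr)
            continue
        wdd = float(df.loc[win, "deaths"].mean())
        block = df.loc[season, ["date", "deaths", "tmean_n", "time",
                                "dos", "dow", "hol", "year"]].copy()
        block["wdd"] = wdd
        rows.append(block)
    if not rows:
        raise ValueError("no usable warm season in series")
    frame = pd.concat(rows, ignore_index=True)
    frame = frame.rename(columns={"deaths": "y"})
    frame = frame.dropna(subset=["tmean_n"]).reset_index(drop=True)
    return frame


# ---------------------------------------------------------------------------
# Spline bases and tensor design
# ---------------------------------------------------------------------------

def crs_basis(x: Sequence[float], knots: Sequence[float]) -> np.ndarray:
    """Cardinal natural cubic regression spline basis.

    One column per knot; column j is the natural cubic spline interpolating
    the j-th unit vector at the knots, so the row at x = knot_j is the j-th
    unit vector and coefficients are function values at the knots.  The
    basis reproduces affine functions exactly and rows sum to one.  Values
    outside the boundary knots are clamped to the boundary.
    """
    k = np.asarray(knots, dtype=float)
    if len(k) < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(k) <= 0):
        raise ValueError("knots must be strictly increasing (no duplicates)")
    xv = np.clip(np.asarray(x, dtype=float), k[0], k[-1])
    spl = CubicSpline(k, np.eye(len(k)), bc_type="natural", axis=0)
    return spl(xv)


def tensor_design(temp_basis: np.ndarray, time_basis: np.ndarray) -> np.ndarray:
    """Row-wise product of every temperature column with every time column.

    Returns the n1*n2-column tensor block (temperature index fastest).  The
    block spans both marginal main effects; the single constant redundancy
    with the intercept is removed later by :func:`sum_to_zero_transform`.
    """
    bt = np.asarray(temp_basis, dtype=float)
    bs = np.asarray(time_basis, dtype=float)
    if bt.shape[0] != bs.shape[0]:
        raise ValueError("marginal bases must have equal row counts")
    return (bt[:, :, None] * bs[:, None, :]).reshape(bt.shape[0], -1)


def sum_to_zero_transform(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Absorb the constraint mean(X beta) = 0 into the basis.

    Returns (X Z, Z) where Z is an orthonormal basis of the null space of
    the column-mean vector; the reparameterized block is identifiable
    alongside an intercept and Z maps reduced coefficients back to the
    original basis for prediction.
    """
    c = block.mean(axis=0, keepdims=True)
    z = null_space(c)
    if z.shape[1] != block.shape[1] - 1:
        raise ValueError("degenerate constraint: block has zero column means")
    return block @ z, z


@dataclass
class BasisSpec:
    """Knot layout of the three smooths.

    ``temp_knots``: boundary pair plus two equally spaced interior knots on
    the observed warm-season range of the lagged exposure.  ``time_knots``:
    one degree of freedom per study year, equally spaced over the study
    span.  ``dos_knots``: 6 dof (one per warm-season month) on [1, 183].
    """

    temp_knots: np.ndarray
    time_knots: np.ndarray
    dos_knots: np.ndarray

    def __post_init__(self) -> None:
        for name in ("temp_knots", "time_knots", "dos_knots"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_temp_interior: int = 2,
                   dos_df: int = 6) -> "BasisSpec":
        tm = frame["tmean_n"].to_numpy()
        n_years = frame["year"].nunique()
        if n_years < 3:
            raise ValueError("need at least 3 study years for the time basis")
        temp_knots = np.linspace(tm.min(), tm.max(), n_temp_interior + 2)
        time_knots = np.linspace(frame["time"].min(), frame["time"].max(), n_years)
        dos_knots = np.linspace(1.0, 183.0, dos_df)
        return cls(temp_knots, time_knots, dos_knots)


@dataclass
class FittedModel:
    """Coefficients, dispersion-scaled covariance and prediction machinery."""

    params: np.ndarray
    cov: np.ndarray
    spec: BasisSpec
    z_tensor: np.ndarray          # (n1*n2) x (n1*n2 - 1) constraint transform
    layout: dict                  # block name -> [start, stop) in params
    percentiles: dict             # min/p25/p90/p95/max of fitted tmean_n
    times: np.ndarray             # observed warm-season time indices
    exposures: np.ndarray         # observed tmean_n values (same rows)
    dispersion: float
    converged: bool
    deviance: float = float("nan")
    n_obs: int = 0

    # -- prediction -------------------------------------------------------

    def tensor_row(self, t: np.ndarray, time: np.ndarray) -> np.ndarray:
        """Reduced-basis tensor design rows at (temperature, time) pairs."""
        bt = crs_basis(np.atleast_1d(t), self.spec.temp_knots)
        bs = crs_basis(np.atleast_1d(time), self.spec.time_knots)
        return tensor_design(bt, bs) @ self.z_tensor

    def fitted_range(self) -> tuple[float, float]:
        return self.percentiles["min"], self.percentiles["max"]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": self.params.tolist(),
            "cov": self.cov.tolist(),
            "temp_knots": self.spec.temp_knots.tolist(),
            "time_knots": self.spec.time_knots.tolist(),
            "dos_knots": self.spec.dos_knots.tolist(),
            "z_tensor": self.z_tensor.tolist(),
            "layout": {k: list(v) for k, v in self.layout.items()},
            "percentiles": self.percentiles,
            "times": self.times.tolist(),
            "exposures": self.exposures.tolist(),
            "dispersion": self.dispersion,
            "converged": self.converged,
            "deviance": self.deviance,
            "n_obs": self.n_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        spec = BasisSpec(np.asarray(d["temp_knots"]), np.asarray(d["time_knots"]),
                         np.asarray(d["dos_knots"]))
        return cls(params=np.asarray(d["params"]), cov=np.asarray(d["cov"]),
                   spec=spec, z_tensor=np.asarray(d["z_tensor"]),
                   layout={k: tuple(v) for k, v in d["layout"].items()},
                   percentiles=dict(d["percentiles"]),
                   times=np.asarray(d["times"]),
                   exposures=np.asarray(d["exposures"]),
                   dispersion=float(d["dispersion"]),
                   converged=bool(d["converged"]),
                   deviance=float(d["deviance"]), n_obs=int(d["n_obs"]))

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def assemble_design(frame: pd.DataFrame, spec: BasisSpec,
                    check_rank: bool = True,
                    ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Full design matrix, the tensor constraint transform and the layout.

    ``check_rank=False`` skips the hard collinearity error; a penalized fit
    regularizes weakly identified tensor directions itself, whereas an
    unpenalized fit must fail loudly on a rank-deficient design.
    """
    n = len(frame)
    bt = crs_basis(frame["tmean_n"].to_numpy(), spec.temp_knots)
    bs = crs_basis(frame["time"].to_numpy(), spec.time_knots)
    tensor_raw = tensor_design(bt, bs)
    tensor_red, z_tensor = sum_to_zero_transform(tensor_raw)

    dos_raw = crs_basis(frame["dos"].to_numpy(), spec.dos_knots)
    dos_red, _ = sum_to_zero_transform(dos_raw)
    # dos is centered the same way; its transform is not needed for contrasts.

    dow = frame["dow"].to_numpy()
    dow_cols = np.column_stack([(dow == d).astype(float) for d in range(1, 7)])

    hol_col = frame["hol"].to_numpy(dtype=float)[:, None]
    wdd_col = frame["wdd"].to_numpy(dtype=float)[:, None]
    cols = [np.ones((n, 1)), tensor_red, dos_red, dow_cols, hol_col, wdd_col]
    names = ["intercept", "tensor", "dos", "dow", "hol", "wdd"]
    # A zero-variance hol or wdd column carries no information and is
    # collinear with the intercept; drop it rather than fail.
    for name, col in (("hol", hol_col), ("wdd", wdd_col)):
        if np.ptp(col) == 0:
            logger.warning("covariate %s is constant over the frame; dropped", name)
            i = names.index(name)
            cols[i] = np.empty((n, 0))
    x = np.hstack(cols)

    layout, start = {}, 0
    for name, c in zip(names, cols):
        layout[name] = (start, start + c.shape[1])
        start += c.shape[1]

    if not check_rank:
        return x, z_tensor, layout
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # Locate offending blocks for the error message.
        bad = []
        for name, (a, b) in layout.items():
            sub = np.delete(x, range(a, b), axis=1)
            if np.linalg.matrix_rank(sub) + (b - a) > rank:
                bad.append(name)
        raise ValueError(
            f"design matrix rank-deficient (rank {rank} < {x.shape[1]}); "
            f"collinearity involves blocks: {bad or 'unknown'}")
    return x, z_tensor, layout


def _time_curvature_penalty(spec: BasisSpec, z_tensor: np.ndarray,
                            p: int, layout: dict) -> np.ndarray:
    """Second-difference penalty along the time margin of the tensor.

    For every temperature basis index the coefficients over the yearly time
    knots are penalized by their squared second differences, so year-scale
    wiggle is shrunk toward locally linear trends (the penalty's null
    space); temperature shape and long-term trends are untouched.  Returned
    on the full parameter space, mapped through the tensor's constraint
    transform.
    """
    n1, n2 = len(spec.temp_knots), len(spec.time_knots)
    d2 = np.zeros((n2 - 2, n2))
    for j in range(n2 - 2):
        d2[j, j: j + 3] = [1.0, -2.0, 1.0]
    s_full = np.kron(np.eye(n1), d2.T @ d2)   # time index fastest per column
    s = np.zeros((p, p))
    a, b = layout["tensor"]
    s[a:b, a:b] = z_tensor.T @ s_full @ z_tensor
    return s


def _penalized_irls(x: np.ndarray, y: np.ndarray, s: np.ndarray,
                    lam: float) -> tuple[np.ndarray, np.ndarray, bool]:
    """Poisson log-link IRLS with a fixed quadratic penalty lam * theta'S theta."""
    theta = np.zeros(x.shape[1])
    theta[0] = math.log(max(y.mean(), 1e-8))
    converged = False
    a_mat = None
    dev_old = np.inf
    for _ in range(IRLS_MAXITER):
        eta = np.clip(x @ theta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu
        z = eta + (y - mu) / mu
        a_mat = x.T @ (x * w[:, None]) + lam * s
        theta = np.linalg.solve(a_mat, x.T @ (w * z))
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = 2.0 * np.sum(np.where(y > 0, y * np.log(y / mu), 0.0)
                               - (y - mu))
        if abs(dev_old - dev) < IRLS_TOL * (abs(dev) + 0.1):
            converged = True
            break
        dev_old = dev
    return theta, a_mat, converged


def fit_model(frame: pd.DataFrame, spec: BasisSpec | None = None,
              time_penalty: float = 0.0) -> FittedModel:
    """Maximum quasi-likelihood fit of the warm-season model.

    Poisson log-link IRLS; the dispersion is estimated as Pearson
    chi-square over residual degrees of freedom and scales the coefficient
    covariance (quasi-Poisson).  Non-convergence and degenerate outcome
    years are flagged, not fatal.

    ``time_penalty`` > 0 adds a fixed second-difference penalty along the
    tensor's time margin (see :func:`_time_curvature_penalty`).  Summers
    with almost no day near the evaluated exposures leave the unpenalized
    time-varying curve nearly unidentified there and its estimates can
    diverge; the mild fixed penalty (10 is the recommended robust setting,
    results are insensitive over 1-10) shrinks such data-free year-scale
    wiggle toward neighboring years while leaving well-supported contrasts
    essentially unchanged.  The covariance is then the Bayesian
    (penalized-information) one.
    """
    if len(frame) == 0:
        raise ValueError("empty model frame")
    if frame["year"].nunique() < 2:
        raise ValueError("need at least 2 study years")
    if spec is None:
        spec = BasisSpec.from_frame(frame)

    zero_years = [int(y) for y, g in frame.groupby("year") if g["y"].sum() == 0]
    if zero_years:
        logger.warning("years with all-zero death counts: %s", zero_years)

    x, z_tensor, layout = assemble_design(frame, spec,
                                          check_rank=(time_penalty == 0.0))
    y = frame["y"].to_numpy(dtype=float)

    if time_penalty > 0.0:
        s = _time_curvature_penalty(spec, z_tensor, x.shape[1], layout)
        # minuscule ridge on the tensor block: numerical safeguard against
        # exactly collinear tail directions; bias is negligible relative to
        # the Fisher information of any supported direction
        a, b = layout["tensor"]
        s[a:b, a:b] += (1e-6 / max(time_penalty, 1e-12)) * np.eye(b - a)
        theta, a_mat, converged = _penalized_irls(x, y, s, time_penalty)
        if not converged:
            logger.warning("penalized IRLS did not converge within %d "
                           "iterations", IRLS_MAXITER)
        mu = np.exp(np.clip(x @ theta, -30.0, 30.0))
        # n - p is conservative: the penalty lowers the effective dof
        dispersion = float(np.sum((y - mu) ** 2 / mu) / (len(y) - x.shape[1]))
        cov = np.linalg.inv(a_mat) * max(dispersion, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            deviance = float(2.0 * np.sum(
                np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)))
        params = theta
    else:
        glm = sm.GLM(y, x, family=sm.families.Poisson())
        res = glm.fit(maxiter=IRLS_MAXITER, tol=IRLS_TOL)
        converged = bool(getattr(res, "converged", True))
        if not converged:
            logger.warning("IRLS did not converge within %d iterations",
                           IRLS_MAXITER)
        # Quasi-Poisson: dispersion = Pearson chi-square / residual dof; it
        # scales the (unit-scale) Fisher covariance.  A perfect fit gives 0.
        dispersion = float(res.pearson_chi2 / res.df_resid)
        cov = np.asarray(res.cov_params()) * max(dispersion, 1e-300)
        deviance = float(res.deviance)
        params = np.asarray(res.params)

    tm = frame["tmean_n"].to_numpy()
    percentiles = {
        "min": float(tm.min()),
        "p25": float(np.percentile(tm, 25)),
        "p90": float(np.percentile(tm, 90)),
        "p95": float(np.percentile(tm, 95)),
        "max": float(tm.max()),
    }

    return FittedModel(params=params, cov=cov,
                       spec=spec, z_tensor=z_tensor, layout=layout,
                       percentiles=percentiles,
                       times=frame["time"].to_numpy(dtype=float),
                       exposures=tm.astype(float),
                       dispersion=dispersion, converged=converged,
                       deviance=deviance, n_obs=len(frame))


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

def tensor_contrast(model: FittedModel, t1, t0, time,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (log-RR, SE) for temperature contrasts t0 -> t1 at ``time``.

    Only the tensor block differs between the two predictions; every other
    covariate cancels in the contrast.
    """
    t1 = np.atleast_1d(np.asarray(t1, dtype=float))
    t0 = np.atleast_1d(np.asarray(t0, dtype=float))
    time = np.atleast_1d(np.asarray(time, dtype=float))
    t1, t0, time = np.broadcast_arrays(t1, t0, time)

    rows = model.tensor_row(t1, time) - model.tensor_row(t0, time)
    a, b = model.layout["tensor"]
    theta = model.params[a:b]
    sigma = model.cov[a:b, a:b]
    logrr = rows @ theta
    var = np.einsum("ij,jk,ik->i", rows, sigma, rows)
    se = np.sqrt(np.maximum(var, 0.0))
    return logrr, se


def predict_logrr(model: FittedModel, t1: float, t0: float, time: float,
                  clamp: bool = False) -> tuple[float, float]:
    """Log relative risk and SE for a t0 -> t1 temperature contrast.

    Contrast vector c = tensor row at (t1, time) minus the row at
    (t0, time); log-RR = c'theta, SE = sqrt(c' Sigma c) with Sigma the
    dispersion-scaled covariance.  Percent change downstream is
    (e^logRR - 1) * 100.  Temperatures outside the fitted exposure range
    are rejected unless ``clamp`` is set.
    """
    lo, hi = model.fitted_range()
    for t in (t0, t1):
        if (t < lo - 1e-9 or t > hi + 1e-9) and not clamp:
            raise ValueError(
                f"temperature {t:.2f} outside fitted range [{lo:.2f}, {hi:.2f}]; "
                "pass clamp=True to clamp to the boundary")
    if t1 == t0:
        return 0.0, 0.0
    logrr, se = tensor_contrast(model, t1, t0, time)
    return float(logrr[0]), float(se[0])
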