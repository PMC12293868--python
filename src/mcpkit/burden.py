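"""Gaussian tumor-burden decay: fitting sparse flow-cytometry observations
and extrapolating the malignant-cell fraction to every treatment visit.

The model is a four-parameter Gaussian f(t) = floor + p0·exp(−(t−t0)²/(2σ²))
with the peak constrained at or before the first observation, encoding the
monotone post-peak decay seen in a responding patient.  Fitting is nonlinear
least squares from five deterministic method-of-moments starts.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "GaussianBurdenModel",
    "fit_gaussian_burden",
    "extrapolate_burden",
    "goodness_of_fit",
]


@dataclass
class GaussianBurdenModel:
    p0: float
    t0: float
    sigma: float
    floor: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.floor < 0:
            raise ValueError("floor must be non-negative")
        if self.floor + self.p0 > 1.0 + 1e-9:
            raise ValueError("floor + p0 must not exceed 1")

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        raw = self.floor + self.p0 * np.exp(
            -((t - self.t0) ** 2) / (2.0 * self.sigma**2)
        )
        return np.clip(raw, 0.0, 1.0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GaussianBurdenModel":
        return cls(**{k: float(d[k]) for k in ("p0", "t0", "sigma", "floor",
                                               "r_squared")})


class BurdenFitError(RuntimeError):
    """Raised when no start converges; carries the best attempt."""

    def __init__(self, message, best_params=None, residuals=None):
        super().__init__(message)
        self.best_params = best_params
        self.residuals = residuals


def goodness_of_fit(observed, fitted) -> float:
    """R² = 1 − SS_res/SS_tot.

    Convention for degenerate inputs: zero observed variance with zero
    residuals is a perfect (if uninformative) fit, R² = 1; zero variance with
    nonzero residuals is undefined and raises.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.size < 2:
        raise ValueError("observed and fitted must share length >= 2")
    ss_res = float(np.sum((obs - fit) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        if ss_res <= 1e-24:
            return 1.0
        raise ValueError("R² undefined: observations constant, residuals nonzero")
    return 1.0 - ss_res / ss_tot


def _starts(times: np.ndarray, obs: np.ndarray) -> list:
    t_first = float(times.min())
    floor0 = float(obs.min())
    p00 = max(float(obs.max() - obs.min()), 1e-3)
    span = max(float(times.max() - times.min()), 1.0)
    # half-decay heuristic for sigma
    half = floor0 + p00 / 2.0
    below = times[obs <= half]
    t_half = float(below.min()) if below.size else t_first + span / 2.0
    sigma0 = max((t_half - t_first) / 1.1774, span / 20.0)
    starts = []
    for mult in (1.0, 0.5, 2.0, 4.0, 0.25):
        starts.append((p00, t_first, sigma0 * mult, floor0))
    return starts


def fit_gaussian_burden(times, observed_fractions) -> GaussianBurdenModel:
    """Least-squares Gaussian decay fit to observed malignant fractions.

    Requires at least 4 observations (four free parameters); fractions must
    lie in [0, 1].  The peak time t0 is bounded above by the first observed
    time so the fitted curve decays monotonically over the observation
    window.
    """
    times = np.asarray(times, dtype=float)
    obs = np.asarray(observed_fractions, dtype=float)
    if times.shape != obs.shape:
        raise ValueError("times and observations must align")
    if obs.size < 4:
        raise ValueError("need at least 4 observations for a 4-parameter fit")
    if ((obs < 0) | (obs > 1)).any():
        raise ValueError("observed fractions must lie in [0, 1]")

    if np.allclose(obs, obs[0]):
        # degenerate: constant observations -> flat model at the constant
        sigma = max(float(times.max() - times.min()), 1.0)
        return GaussianBurdenModel(
            p0=0.0, t0=float(times.min()), sigma=sigma,
            floor=float(obs[0]), r_squared=1.0,
        )

    t_first = float(times.min())
    span = max(float(times.max() - times.min()), 1.0)

    def resid(theta):
        p0, t0, sigma, floor = theta
        pred = floor + p0 * np.exp(-((times - t0) ** 2) / (2.0 * sigma**2))
        return pred - obs

    lower = np.array([0.0, t_first - 10.0 * span, 1e-6, 0.0])
    upper = np.array([1.0, t_first, 10.0 * span, 1.0])
    best = None
    for x0 in _starts(times, obs):
        x0 = np.minimum(np.maximum(np.asarray(x0, dtype=float), lower), upper)
        try:
            res = least_squares(
                resid, x0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14,
                gtol=1e-14, max_nfev=5000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise BurdenFitError(
            "Gaussian burden fit failed to converge from all starts",
            best_params=None if best is None else best.x,
            residuals=None if best is None else best.fun,
        )
    p0, t0, sigma, floor = (float(v) for v in best.x)
    if floor + p0 > 1.0:  # renormalize tiny numerical overshoot
        p0 = min(p0, 1.0 - floor)
    fitted = floor + p0 * np.exp(-((times - t0) ** 2) / (2.0 * sigma**2))
    r2 = goodness_of_fit(obs, fitted)
    return GaussianBurdenModel(p0=p0, t0=t0, sigma=sigma, floor=floor,
                               r_squared=r2)


def extrapolate_burden(
    model: GaussianBurdenModel,
    all_times,
    observed_map: Optional[Mapping] = None,
    sample_ids=None,
) -> pd.DataFrame:
    """Burden trajectory over all visits: observed values pass through
    unchanged, unobserved visits take clipped model predictions.

    ``observed_map`` maps time → observed fraction.  Returns a DataFrame
    indexed by sample ID (or time) with columns ``time``, ``fraction``,
    ``source`` ∈ {observed, extrapolated}.
    """
    all_times = np.asarray(all_times, dtype=float)
    observed_map = dict(observed_map or {})
    preds = model.predict(all_times)
    fractions, sources = [], []
    for t, pred in zip(all_times, preds):
        if t in observed_map:
            fractions.append(float(observed_map[t]))
            sources.append("observed")
        else:
            fractions.append(float(pred))
            sources.append("extrapolated")
    index = sample_ids if sample_ids is not None else all_times
    return pd.DataFrame(
        {"time": all_times, "fraction": fractions, "source": sources},
        index=pd.Index(index, name="sample_id"),
    )


def trajectory_from_sample_table(samples: pd.DataFrame) -> tuple:
    """Fit + extrapolate from a cohort sample table.

    Patient visit order (sample-table row order) provides the time axis;
    rows with ``observed_fraction`` provide the fit targets.  The relapse
    sample keeps its observed value and is never extrapolated from the decay
    model.  Returns ``(model, trajectory DataFrame indexed by sample_id)``.
    """
    visits = samples[(samples["group"] == "patient")
                     & (samples["phase"] != "relapse")].reset_index(drop=True)
    times = np.arange(len(visits), dtype=float)
    obs_mask = visits["observed_fraction"].notna()
    model = fit_gaussian_burden(
        times[obs_mask.to_numpy()],
        visits.loc[obs_mask, "observed_fraction"].to_numpy(dtype=float),
    )
    observed_map = dict(
        zip(times[obs_mask.to_numpy()],
            visits.loc[obs_mask, "observed_fraction"].astype(float))
    )
    traj = extrapolate_burden(model, times, observed_map,
                              sample_ids=visits["sample_id"].tolist())
    relapse = samples[samples["phase"] == "relapse"]
    for _, row in relapse.iterrows():
        if pd.notna(row.get("observed_fraction")):
            traj.loc[row["sample_id"]] = [np.nan, float(row["observed_fraction"]),
                                          "observed"]
    return model, traj
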