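"""2AFC psychometric fitting: PSE, JND, and two-target alignment pooling.

For each subject and cycle type the probability of reporting the probe
"left" (CCW) of the hand is fit as a logistic function of the probe's
angular offset from the actual hand position, by maximum likelihood
(binomial GLM with a logit link).  The point of subjective equivalence
(PSE) is the offset at which "left" is reported in 50% of trials,
``-intercept/slope``; the just noticeable difference (JND) is the
distance between the 75% and 25% points, ``2*ln(3)/slope``.

With two targets (exp1) a joint precision estimate is obtained by first
subtracting each target's own PSE from that target's probe offsets —
aligning the two psychometric curves at zero — and refitting on the
pooled, shifted data.

Perfect separation (a step-like data set) is handled by refitting with a
weak ridge penalty on the slope and raising ``separation_flag``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

_LN3 = math.log(3.0)
_SEPARATION_RIDGE = 1e-2   # penalty weight on the slope under separation
_SLOPE_CAP = 50.0          # |slope| beyond this is treated as separation


class FitError(RuntimeError):
    """Insufficient or unusable data for a psychometric fit."""


@dataclass
class PsychometricFit:
    intercept: float
    slope: float
    pse_deg: float
    jnd_deg: float
    n_trials: int
    converged: bool
    separation_flag: bool = False
    degenerate: bool = False      # non-positive slope: flat/inverted curve
    target: Optional[float] = None

    def predict(self, offsets) -> np.ndarray:
        return expit(self.intercept + self.slope * np.asarray(offsets, dtype=float))


def _derive(intercept: float, slope: float, n: int, converged: bool,
            separation: bool, target=None) -> PsychometricFit:
    if slope > 0:
        pse = -intercept / slope
        jnd = 2 * _LN3 / slope
        degenerate = False
    else:
        pse, jnd, degenerate = float("nan"), float("inf"), True
    return PsychometricFit(intercept=float(intercept), slope=float(slope),
                           pse_deg=float(pse), jnd_deg=float(jnd), n_trials=n,
                           converged=converged, separation_flag=separation,
                           degenerate=degenerate, target=target)


def _penalized_fit(x: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
    def nll(beta):
        eta = beta[0] + beta[1] * x
        # log-likelihood via logaddexp for numerical stability
        ll = y * eta - np.logaddexp(0.0, eta)
        return -ll.sum() + 0.5 * ridge * beta[1] ** 2
    res = minimize(nll, x0=np.array([0.0, 0.1]), method="BFGS")
    return res.x


def fit_logistic(reports: pd.DataFrame, target: Optional[float] = None,
                 offset_col: str = "probe_offset_deg") -> PsychometricFit:
    """Maximum-likelihood logistic fit of P("left") against probe offset."""
    offsets = reports[offset_col].to_numpy(dtype=float)
    resp = reports["response"]
    y = (resp == "left").to_numpy(dtype=float) if resp.dtype == object \
        else resp.to_numpy(dtype=float)
    if np.unique(offsets).size < 2:
        raise FitError("need at least 2 distinct probe offsets")
    if y.size < 2:
        raise FitError("need at least 2 responses")
    X = sm.add_constant(offsets)
    # complete separation: the offsets of "left" and "right" responses do
    # not overlap, so the unpenalized MLE slope is infinite
    left, right = offsets[y == 1], offsets[y == 0]
    separation = bool(left.size and right.size
                      and (left.min() > right.max() or left.max() < right.min()))
    if not separation:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            beta = np.asarray(res.params, dtype=float)
            converged = bool(res.converged)
            if not np.all(np.isfinite(beta)) or abs(beta[1]) > _SLOPE_CAP:
                separation = True
        except Exception:
            separation = True
    if separation:
        beta = _penalized_fit(offsets, y, _SEPARATION_RIDGE)
        converged = True
    return _derive(beta[0], beta[1], y.size, converged, separation, target)


def align_and_pool(reports_by_target: dict[float, pd.DataFrame],
                   offset_col: str = "probe_offset_deg") -> PsychometricFit:
    """PSE-aligned pooled fit across targets.

    Each target's PSE is estimated from its own fit and subtracted from
    that target's probe offsets; the shifted data are pooled and refit.
    The joint PSE is ~0 by construction and the joint JND is the reported
    precision measure.  A single target reduces to a plain fit.
    """
    fits = {t: fit_logistic(df, target=t, offset_col=offset_col)
            for t, df in reports_by_target.items()}
    if len(fits) == 1:
        return next(iter(fits.values()))
    bad = [t for t, f in fits.items() if f.degenerate or not np.isfinite(f.pse_deg)]
    if bad:
        raise FitError(f"per-target fit degenerate for target(s) {bad}; "
                       "joint fit skipped")
    shifted = []
    for t, df in reports_by_target.items():
        d = df.copy()
        d[offset_col] = d[offset_col] - fits[t].pse_deg
        shifted.append(d)
    joint = fit_logistic(pd.concat(shifted, ignore_index=True),
                         offset_col=offset_col)
    return replace(joint, target=None)


def psychometric_summary(reports: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-subject PSE/JND by cycle type.

    ``reports`` must carry ``subject_id``, ``cycle_type``, ``sign_dir``,
    ``hand_target_base_deg``, ``probe_offset_deg`` and ``response``.
    The PSE bias is sign-corrected (CW-cycle PSEs are negated) and, with
    two targets, averaged across them; the JND comes from the PSE-aligned
    pooled fit.  Fits use all reports of a cycle type pooled across blocks.
    """
    rows = []
    for (sid, ct), grp in reports.groupby(["subject_id", "cycle_type"], sort=True):
        by_target = {t: sub for t, sub in grp.groupby("hand_target_base_deg")}
        fits = {}
        pses = []
        failed = False
        for t, sub in by_target.items():
            try:
                f = fit_logistic(sub, target=t)
            except FitError:
                failed = True
                break
            fits[t] = f
            s = -1.0 if (sub["sign_dir"] == "cw").all() else 1.0
            pses.append(s * f.pse_deg)
        if failed:
            continue
        try:
            joint = align_and_pool(by_target)
        except FitError:
            joint = None
        rows.append(dict(
            subject_id=sid, cycle_type=ct,
            pse_deg=float(np.mean(pses)),
            jnd_deg=float(joint.jnd_deg) if joint is not None else float("nan"),
            n_trials=len(grp),
            separation_flag=any(f.separation_flag for f in fits.values())
            or (joint is not None and joint.separation_flag),
            degenerate=any(f.degenerate for f in fits.values()),
        ))
    return pd.DataFrame(rows)


def group_summary(per_subject: pd.DataFrame,
                  value_cols=("pse_deg", "jnd_deg")) -> pd.DataFrame:
    """Group-level mean+-SD and median+-IQR per cycle type, for either
    reporting convention."""
    from .pointer import iqr as _iqr
    rows = []
    for ct, grp in per_subject.groupby("cycle_type", sort=True):
        for col in value_cols:
            v = grp[col].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size == 0:
                continue
            rows.append(dict(cycle_type=ct, measure=col, n=v.size,
                             mean=float(v.mean()),
                             sd=float(v.std(ddof=1)) if v.size > 1 else float("nan"),
                             median=float(np.median(v)), iqr=_iqr(v)))
    return pd.DataFrame(rows)
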