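"""Normative bivariate log-normal model and the BVNL decision rule.

The screening tool assumes that the natural logs of the two dried-blood-spot
analytes — alpha-L-iduronidase activity (IDUA, nmol/mg/hour) and heparan
sulfate (HS, ng/mL) — are bivariate normal in the healthy newborn population.
A normative cohort is used once to estimate per-analyte log-scale means and
SDs and the correlation of the standardized logs; those parameters are frozen
and every subsequent observation is standardized against them.

An infant screens positive under the bivariate normal limits (BVNL) rule only
if all three conditions hold strictly:

* standardized log IDUA below the low-enzyme threshold (default -3.62),
* standardized log HS above the high-GAG threshold (default +1.90),
* the point falls outside the (1 - p)100% prediction ellipse (default
  p = 1e-7), i.e. its squared Mahalanobis distance exceeds the ellipse
  radius.

Three univariate comparator rules (IDUA-only, HS-only, joint thresholds) and
the raw-scale Gifu protocol cut are evaluated alongside the BVNL verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    DegenerateCohortError,
    InsufficientDataError,
    InvalidProbabilityError,
    InvalidValueError,
    SingularCorrelationError,
)

__all__ = [
    "NormativeModel",
    "RuleThresholds",
    "BVNLScreen",
    "RULE_NAMES",
    "fit_normative_model",
    "standardize",
    "mahalanobis_sq",
    "ellipse_radius_sq",
    "classify",
    "normal_probability_plot",
]

#: Decision rules evaluated for every sample, in nesting order.
RULE_NAMES = ("bvnl", "idua_only", "hs_only", "joint", "gifu")

#: Design false-positive-rate target of the BVNL rule (one per 1e8 screens).
DEFAULT_FP_TARGET = 1e-8

#: Raw Gifu-protocol IDUA cut-off, nmol/mg/hour ("under 16.68" flags positive).
DEFAULT_GIFU_CUT_IDUA = 16.68


@dataclass(frozen=True)
class NormativeModel:
    """Frozen parameters of the fitted normative bivariate log-normal.

    ``mu``/``sd`` are the sample mean and SD (n-1 denominator) of the natural
    logs; ``rho`` is the Pearson correlation of the standardized log columns.
    Detection limits are in raw analyte units and are applied as floors
    before any log transform.
    """

    mu_log_idua: float
    sd_log_idua: float
    mu_log_hs: float
    sd_log_hs: float
    rho: float
    n: int
    detection_limit_idua: float = 0.5
    detection_limit_hs: float = 1.0

    def __post_init__(self) -> None:
        if self.sd_log_idua <= 0 or self.sd_log_hs <= 0:
            raise DegenerateCohortError("log-scale SDs must be positive")
        if not abs(self.rho) < 1:
            raise SingularCorrelationError(f"|rho| must be < 1, got {self.rho}")
        if self.n < 3:
            raise InsufficientDataError(f"normative n must be >= 3, got {self.n}")
        if self.detection_limit_idua <= 0 or self.detection_limit_hs <= 0:
            raise InvalidValueError("detection limits must be positive")


@dataclass(frozen=True)
class RuleThresholds:
    """Standardized-log cut-offs and prediction-ellipse settings.

    ``ellipse_p`` is the tail probability of the prediction region: the
    fraction of future healthy observations expected to fall outside the
    ellipse. ``radius_method`` selects between the large-sample chi-square
    radius and the exact small-sample F-based prediction bound.
    """

    z_idua_cut: float = -3.62
    z_hs_cut: float = 1.90
    ellipse_p: float = 1e-7
    radius_method: str = "chi_square"

    def __post_init__(self) -> None:
        if not 0 < self.ellipse_p < 1:
            raise InvalidProbabilityError(
                f"ellipse_p must be in (0, 1), got {self.ellipse_p}"
            )
        if not (self.z_idua_cut < 0 < self.z_hs_cut):
            raise InvalidValueError(
                "expected z_idua_cut < 0 < z_hs_cut, got "
                f"({self.z_idua_cut}, {self.z_hs_cut})"
            )
        if self.radius_method not in ("chi_square", "f_prediction"):
            raise InvalidValueError(
                f"unknown radius_method {self.radius_method!r}"
            )


def standardize(raw_value, mu_log: float, sd_log: float):
    """Standardized natural log: ``(ln(raw) - mu_log) / sd_log``.

    Accepts scalars or arrays. Raw values must be strictly positive;
    detection-limit flooring happens upstream.
    """
    if sd_log <= 0:
        raise InvalidValueError(f"sd_log must be positive, got {sd_log}")
    raw = np.asarray(raw_value, dtype=float)
    if np.any(raw <= 0) or not np.all(np.isfinite(raw)):
        raise InvalidValueError("raw values must be finite and > 0 (floor at the detection limit first)")
    z = (np.log(raw) - mu_log) / sd_log
    return float(z) if np.isscalar(raw_value) else z


def mahalanobis_sq(z_idua, z_hs, rho: float):
    """Squared Mahalanobis distance of standardized pairs from the origin.

    For unit-variance coordinates with correlation ``rho`` this is
    ``(z1^2 - 2 rho z1 z2 + z2^2) / (1 - rho^2)``.
    """
    if not abs(rho) < 1:
        raise SingularCorrelationError(f"|rho| must be < 1, got {rho}")
    z1 = np.asarray(z_idua, dtype=float)
    z2 = np.asarray(z_hs, dtype=float)
    d2 = (z1 * z1 - 2.0 * rho * z1 * z2 + z2 * z2) / (1.0 - rho * rho)
    return float(d2) if np.isscalar(z_idua) and np.isscalar(z_hs) else d2


def ellipse_radius_sq(p: float, n: int | None = None,
                      method: str = "chi_square") -> float:
    """Squared radius of the (1 - p)100% bivariate prediction region.

    ``chi_square`` uses the large-sample limit, the (1 - p) quantile of
    chi-square with 2 df, which closed-forms to ``-2 ln p``. ``f_prediction``
    uses the exact bound for a future observation given a normative sample of
    size n: ``2 (n^2 - 1) / (n (n - 2)) * F_{2, n-2}(1 - p)``; it exceeds the
    chi-square radius for every finite n and converges to it as n grows.
    """
    if not 0 < p <= 1:
        raise InvalidProbabilityError(f"p must be in (0, 1], got {p}")
    if method == "chi_square":
        return -2.0 * math.log(p)
    if method == "f_prediction":
        if n is None or n < 4:
            raise InsufficientDataError(
                "f_prediction radius needs normative n >= 4"
            )
        return 2.0 * (n * n - 1) / (n * (n - 2)) * stats.f.ppf(1.0 - p, 2, n - 2)
    raise InvalidValueError(f"unknown radius_method {method!r}")


def fit_normative_model(cohort, detection_limits: tuple[float, float] = (0.5, 1.0),
                        ) -> NormativeModel:
    """Fit the normative model from a cohort of raw analyte pairs.

    Parameters
    ----------
    cohort
        DataFrame with ``idua`` and ``hs`` columns (raw units), or an
        (n, 2) array-like ordered [idua, hs].
    detection_limits
        (idua, hs) raw-unit floors applied before the log transform.
    """
    idua, hs = _raw_columns(cohort)
    n = idua.shape[0]
    if n < 3:
        raise InsufficientDataError(f"need >= 3 rows to fit, got {n}")
    dl_i, dl_h = detection_limits
    if dl_i <= 0 or dl_h <= 0:
        raise InvalidValueError("detection limits must be positive")
    if np.any(~np.isfinite(idua)) or np.any(~np.isfinite(hs)):
        raise InvalidValueError("analyte values must be finite")
    if np.any(idua <= 0) or np.any(hs <= 0):
        raise InvalidValueError(
            "raw analyte values must be > 0; the detection-limit floor is "
            "for small positive readings, not missing or negative ones"
        )
    li = np.log(np.maximum(idua, dl_i))
    lh = np.log(np.maximum(hs, dl_h))
    sd_i = float(np.std(li, ddof=1))
    sd_h = float(np.std(lh, ddof=1))
    if sd_i == 0 or sd_h == 0:
        raise DegenerateCohortError("zero variance in a log-analyte column")
    rho = float(np.corrcoef(li, lh)[0, 1])
    return NormativeModel(
        mu_log_idua=float(np.mean(li)), sd_log_idua=sd_i,
        mu_log_hs=float(np.mean(lh)), sd_log_hs=sd_h,
        rho=rho, n=int(n),
        detection_limit_idua=float(dl_i), detection_limit_hs=float(dl_h),
    )


def classify(z_idua, z_hs, model: NormativeModel,
             thresholds: RuleThresholds = RuleThresholds()) -> dict:
    """Apply the BVNL rule and its univariate comparators to standardized pairs.

    Returns a dict of boolean verdict arrays (True = positive) under keys
    ``bvnl``, ``idua_only``, ``hs_only``, ``joint``, plus ``mahalanobis_sq``.
    All inequalities are strict: a point exactly on a threshold or on the
    ellipse boundary is negative.
    """
    z1 = np.asarray(z_idua, dtype=float)
    z2 = np.asarray(z_hs, dtype=float)
    d2 = mahalanobis_sq(z1, z2, model.rho)
    r2 = ellipse_radius_sq(thresholds.ellipse_p, model.n, thresholds.radius_method)
    low_idua = z1 < thresholds.z_idua_cut
    high_hs = z2 > thresholds.z_hs_cut
    joint = low_idua & high_hs
    return {
        "idua_only": low_idua,
        "hs_only": high_hs,
        "joint": joint,
        "bvnl": joint & (d2 > r2),
        "mahalanobis_sq": d2,
    }


def normal_probability_plot(values):
    """Normal probability plot coordinates and straightness correlation.

    Values are sorted and paired with standard-normal quantiles at plotting
    positions ``(i - 0.5) / n``. The Pearson correlation of the pairs is a
    scale-free straightness measure: near 1 for normal samples, lower for
    skewed ones.

    Returns ``(theoretical_quantiles, ordered_values, correlation)``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.shape[0] < 3 or np.any(~np.isfinite(v)):
        raise InsufficientDataError("need >= 3 finite values")
    ordered = np.sort(v)
    n = ordered.shape[0]
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    r = float(np.corrcoef(theo, ordered)[0, 1])
    return theo, ordered, r


def _raw_columns(X):
    """Extract raw (idua, hs) float arrays from a DataFrame or array-like."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in ("idua", "hs") if c not in X.columns]
        if missing:
            raise InvalidValueError(f"cohort missing column(s): {missing}")
        return (X["idua"].to_numpy(dtype=float),
                X["hs"].to_numpy(dtype=float))
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidValueError(
            f"expected an (n, 2) array of [idua, hs], got shape {arr.shape}"
        )
    return arr[:, 0], arr[:, 1]


class BVNLScreen(TransformerMixin, BaseEstimator):
    """Bivariate-normal-limits newborn-screening classifier.

    ``fit`` estimates the normative bivariate log-normal from raw
    (IDUA, HS) pairs of healthy newborns; ``transform`` standardizes new raw
    observations onto the frozen log scale; ``predict`` returns the BVNL
    verdict (1 = screen positive); ``screen`` returns the full per-sample
    verdict table across all rules.

    Parameters
    ----------
    z_idua_cut, z_hs_cut : float
        Standardized-log thresholds (strict) for low enzyme / high GAG.
    ellipse_p : float
        Tail probability of the (1 - p)100% prediction ellipse.
    radius_method : {"chi_square", "f_prediction"}
        Large-sample chi-square radius (default) or the exact F-based
        prediction bound for finite normative n.
    detection_limit_idua, detection_limit_hs : float
        Raw-unit assay floors; values at or below are floored before logging.
    gifu_cut_idua : float
        Raw IDUA cut of the univariate Gifu comparator protocol.

    Attributes
    ----------
    model_ : NormativeModel
        Frozen fitted parameters.
    mu_log_idua_, sd_log_idua_, mu_log_hs_, sd_log_hs_, rho_, n_ :
        Convenience copies of the fitted parameters.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> X = np.exp(rng.normal([4.15, 3.75], [0.47, 0.34], size=(500, 2)))
    >>> screen = BVNLScreen().fit(X)
    >>> screen.predict([[0.5, 400.0]])   # enzyme at assay floor, GAG elevated
    array([1])
    """

    def __init__(self, z_idua_cut: float = -3.62, z_hs_cut: float = 1.90,
                 ellipse_p: float = 1e-7, radius_method: str = "chi_square",
                 detection_limit_idua: float = 0.5,
                 detection_limit_hs: float = 1.0,
                 gifu_cut_idua: float = DEFAULT_GIFU_CUT_IDUA):
        self.z_idua_cut = z_idua_cut
        self.z_hs_cut = z_hs_cut
        self.ellipse_p = ellipse_p
        self.radius_method = radius_method
        self.detection_limit_idua = detection_limit_idua
        self.detection_limit_hs = detection_limit_hs
        self.gifu_cut_idua = gifu_cut_idua

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the normative model from raw (idua, hs) pairs.

        ``y`` is ignored; present for scikit-learn API compatibility.
        """
        self.thresholds_ = RuleThresholds(self.z_idua_cut, self.z_hs_cut,
                                          self.ellipse_p, self.radius_method)
        model = fit_normative_model(
            X, (self.detection_limit_idua, self.detection_limit_hs))
        self.model_ = model
        self.mu_log_idua_ = model.mu_log_idua
        self.sd_log_idua_ = model.sd_log_idua
        self.mu_log_hs_ = model.mu_log_hs
        self.sd_log_hs_ = model.sd_log_hs
        self.rho_ = model.rho
        self.n_ = model.n
        self.n_features_in_ = 2
        return self

    @classmethod
    def from_model(cls, model: NormativeModel, **params) -> "BVNLScreen":
        """Build a fitted screen from previously frozen parameters."""
        est = cls(detection_limit_idua=model.detection_limit_idua,
                  detection_limit_hs=model.detection_limit_hs, **params)
        est.thresholds_ = RuleThresholds(est.z_idua_cut, est.z_hs_cut,
                                         est.ellipse_p, est.radius_method)
        est.model_ = model
        est.mu_log_idua_ = model.mu_log_idua
        est.sd_log_idua_ = model.sd_log_idua
        est.mu_log_hs_ = model.mu_log_hs
        est.sd_log_hs_ = model.sd_log_hs
        est.rho_ = model.rho
        est.n_ = model.n
        est.n_features_in_ = 2
        return est

    # -- application -------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise InvalidValueError("this BVNLScreen instance is not fitted")

    def _floored(self, X):
        idua, hs = _raw_columns(X)
        if np.any(~np.isfinite(idua)) or np.any(~np.isfinite(hs)):
            raise InvalidValueError("analyte values must be finite")
        if np.any(idua <= 0) or np.any(hs <= 0):
            raise InvalidValueError("raw analyte values must be > 0")
        m = self.model_
        return (np.maximum(idua, m.detection_limit_idua),
                np.maximum(hs, m.detection_limit_hs))

    def transform(self, X):
        """Standardized natural logs of raw pairs, shape (n, 2)."""
        self._check_fitted()
        idua, hs = self._floored(X)
        m = self.model_
        return np.column_stack([
            standardize(idua, m.mu_log_idua, m.sd_log_idua),
            standardize(hs, m.mu_log_hs, m.sd_log_hs),
        ])

    def decision_function(self, X):
        """Signed BVNL margin: mahalanobis_sq - ellipse_radius_sq.

        Positive values lie outside the prediction ellipse. Note the full
        BVNL verdict additionally requires both univariate threshold
        exceedances; use ``predict`` or ``screen`` for verdicts.
        """
        self._check_fitted()
        z = self.transform(X)
        r2 = ellipse_radius_sq(self.thresholds_.ellipse_p, self.model_.n,
                               self.thresholds_.radius_method)
        return mahalanobis_sq(z[:, 0], z[:, 1], self.model_.rho) - r2

    def predict(self, X):
        """BVNL verdict per sample: 1 = screen positive, 0 = negative."""
        self._check_fitted()
        z = self.transform(X)
        verdicts = classify(z[:, 0], z[:, 1], self.model_, self.thresholds_)
        return verdicts["bvnl"].astype(int)

    def screen(self, X, sample_id=None) -> pd.DataFrame:
        """Full per-sample screening table across all decision rules.

        Columns: ``sample_id``, ``z_idua``, ``z_hs``, ``mahalanobis_sq`` and
        one ``verdict_<rule>`` column per rule in {bvnl, idua_only, hs_only,
        joint, gifu}, each "positive"/"negative". The Gifu comparator is the
        raw-scale univariate protocol (raw IDUA strictly under the cut).
        """
        self._check_fitted()
        idua_raw, _ = _raw_columns(X)
        z = self.transform(X)
        v = classify(z[:, 0], z[:, 1], self.model_, self.thresholds_)
        if sample_id is None:
            if isinstance(X, pd.DataFrame) and "sample_id" in X.columns:
                sample_id = X["sample_id"].to_numpy()
            else:
                sample_id = np.array([f"S{i + 1:05d}" for i in range(len(z))])
        out = pd.DataFrame({
            "sample_id": sample_id,
            "z_idua": z[:, 0],
            "z_hs": z[:, 1],
            "mahalanobis_sq": v["mahalanobis_sq"],
        })
        verdict_cols = dict(v)
        verdict_cols["gifu"] = idua_raw < self.gifu_cut_idua
        for rule in RULE_NAMES:
            out[f"verdict_{rule}"] = np.where(verdict_cols[rule],
                                              "positive", "negative")
        return out
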