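"""Screening-accuracy metrics and prevalence-based PPV.

For a rare disorder the positive predictive value is driven almost entirely
by the false positive rate:  PPV = Sens*Prev / (Sens*Prev + FP*(1 - Prev)).
At a prevalence of 1e-5 even a "good" univariate false positive rate of
0.2% yields a PPV of about 0.5%; pushing FP to the 1e-8 design target of the
BVNL rule lifts PPV to 99.9%.

``compare_rules`` builds the per-rule comparison table: empirical
sensitivity/specificity from a labelled cohort, with the PPV computed from
the empirical false positive rate when false positives were observed and
from a supplied theoretical rate when none were (the design target for the
BVNL rule; the independence product of the marginal normal tails for the
joint-threshold rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InvalidValueError, UndefinedPPVError
from .model import DEFAULT_FP_TARGET, RuleThresholds

__all__ = [
    "ScreeningMetrics",
    "ppv_from_rates",
    "empirical_rates",
    "expected_joint_fp_independent",
    "default_theoretical_fps",
    "compare_rules",
    "format_comparison",
]

#: MPS I prevalence used throughout: ~1 per 100,000 live births.
DEFAULT_PREVALENCE = 1e-5

_AFFECTED = "affected"
_NON_AFFECTED = ("normal", "pseudo_deficient")


@dataclass(frozen=True)
class ScreeningMetrics:
    """Accuracy measures of one decision rule on a labelled cohort.

    ``sensitivity``/``fn_rate`` are None when the cohort contains no affected
    samples (undefined, not 0 or 1). ``ppv`` is None when it could not be
    computed (no false positives observed and no theoretical rate supplied).
    Pseudo-deficient samples count as non-affected.
    """

    sensitivity: float | None
    specificity: float
    fp_rate: float
    fn_rate: float | None
    ppv: float | None
    prevalence: float
    n_cases: int
    n_normals: int
    n_false_pos: int
    n_false_neg: int


def ppv_from_rates(sens: float, prev: float, fp: float) -> float:
    """Positive predictive value from sensitivity, prevalence and FP rate.

    ``PPV = Sens*Prev / (Sens*Prev + FP*(1 - Prev))``. Monotone nonincreasing
    in fp; tends to 1 as fp -> 0 with sens > 0.
    """
    if not (0 <= sens <= 1) or not (0 <= fp <= 1):
        raise InvalidValueError("sens and fp must be in [0, 1]")
    if not (0 < prev < 1):
        raise InvalidValueError(f"prev must be in (0, 1), got {prev}")
    denom = sens * prev + fp * (1.0 - prev)
    if denom == 0:
        raise UndefinedPPVError("Sens*Prev + FP*(1-Prev) is zero")
    return sens * prev / denom


def expected_joint_fp_independent(z_idua_cut: float, z_hs_cut: float) -> float:
    """Expected FP rate of the joint-threshold rule under independence.

    ``Phi(z_idua_cut) * (1 - Phi(z_hs_cut))`` with standard-normal Phi:
    the product of the two marginal tail probabilities, appropriate when the
    biomarkers are (approximately) uncorrelated.
    """
    if not np.isfinite(z_idua_cut) or not np.isfinite(z_hs_cut):
        raise InvalidValueError("thresholds must be finite")
    return float(stats.norm.cdf(z_idua_cut) * stats.norm.sf(z_hs_cut))


def empirical_rates(verdicts, truth, prevalence: float = DEFAULT_PREVALENCE,
                    theoretical_fp: float | None = None) -> ScreeningMetrics:
    """Empirical accuracy of one rule's verdicts against truth labels.

    Parameters
    ----------
    verdicts
        Per-sample verdicts, "positive"/"negative" strings or booleans.
    truth
        Per-sample status labels; ``affected`` counts as diseased,
        ``normal`` and ``pseudo_deficient`` as non-affected, ``unknown``
        rows are excluded from every rate.
    theoretical_fp
        FP rate to use for the PPV when no false positives were observed.
    """
    v = np.asarray(verdicts)
    t = np.asarray(truth)
    if v.shape != t.shape or v.ndim != 1 or v.shape[0] == 0:
        raise InvalidValueError("verdicts and truth must be aligned, 1-D and nonempty")
    pos = v == "positive" if v.dtype.kind in "UOS" else v.astype(bool)

    affected = t == _AFFECTED
    non_affected = np.isin(t, _NON_AFFECTED)
    n_cases = int(affected.sum())
    n_normals = int(non_affected.sum())
    if n_cases == 0 and n_normals == 0:
        raise InvalidValueError("truth contains neither affected nor non-affected samples")

    n_fp = int((pos & non_affected).sum())
    fp_rate = n_fp / n_normals if n_normals else 0.0
    if n_cases:
        sens = float((pos & affected).sum()) / n_cases
        fn_rate = 1.0 - sens
        n_fn = int((~pos & affected).sum())
    else:
        sens = fn_rate = None
        n_fn = 0

    ppv = None
    fp_for_ppv = fp_rate if n_fp > 0 else theoretical_fp
    if sens is not None and fp_for_ppv is not None:
        ppv = ppv_from_rates(sens, prevalence, fp_for_ppv)

    return ScreeningMetrics(
        sensitivity=sens, specificity=1.0 - fp_rate, fp_rate=fp_rate,
        fn_rate=fn_rate, ppv=ppv, prevalence=prevalence,
        n_cases=n_cases, n_normals=n_normals,
        n_false_pos=n_fp, n_false_neg=n_fn,
    )


def default_theoretical_fps(thresholds: RuleThresholds = RuleThresholds(),
                            fp_target: float = DEFAULT_FP_TARGET) -> dict:
    """Theoretical FP rates for the zero-observed-FP rules.

    The BVNL rule uses its design target (1e-8 by default); the joint
    threshold rule uses the independence product of the marginal tails; the
    single-analyte rules fall back to their marginal normal tail
    probabilities — the rate expected under bivariate normality. The
    raw-scale Gifu comparator has no normality-based default.
    """
    return {
        "bvnl": fp_target,
        "joint": expected_joint_fp_independent(thresholds.z_idua_cut,
                                               thresholds.z_hs_cut),
        "idua_only": float(stats.norm.cdf(thresholds.z_idua_cut)),
        "hs_only": float(stats.norm.sf(thresholds.z_hs_cut)),
    }


def compare_rules(cohort_results: pd.DataFrame, truth,
                  prev: float = DEFAULT_PREVALENCE,
                  theoretical_fps: dict | None = None) -> pd.DataFrame:
    """Rule-by-rule comparison table from a screening verdict table.

    Parameters
    ----------
    cohort_results
        Output of :meth:`BVNLScreen.screen` (or any frame with
        ``verdict_<rule>`` columns).
    truth
        Per-sample status labels aligned with the rows.
    theoretical_fps
        Mapping rule -> FP rate used for the PPV of rules with zero observed
        false positives. A zero-FP rule missing from the mapping raises
        :class:`ConfigurationError`.

    Returns
    -------
    DataFrame indexed by rule with raw-proportion columns (sensitivity,
    specificity, fp_rate, fn_rate, ppv, counts). Use
    :func:`format_comparison` for the percentage table.
    """
    if theoretical_fps is None:
        theoretical_fps = default_theoretical_fps()
    rules = [c[len("verdict_"):] for c in cohort_results.columns
             if c.startswith("verdict_")]
    if not rules:
        raise ConfigurationError("no verdict_<rule> columns in cohort_results")
    rows = {}
    for rule in rules:
        m = empirical_rates(cohort_results[f"verdict_{rule}"].to_numpy(),
                            truth, prevalence=prev,
                            theoretical_fp=theoretical_fps.get(rule))
        if m.ppv is None and m.sensitivity is not None:
            raise ConfigurationError(
                f"rule {rule!r} observed zero false positives and no "
                "theoretical fp was supplied"
            )
        rows[rule] = {
            "sensitivity": m.sensitivity, "fn_rate": m.fn_rate,
            "specificity": m.specificity, "fp_rate": m.fp_rate,
            "n_false_pos": m.n_false_pos, "ppv": m.ppv,
            "n_cases": m.n_cases, "n_normals": m.n_normals,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "rule"
    return out


def format_comparison(table: pd.DataFrame) -> pd.DataFrame:
    """Percentage view of a comparison table, rounded to 2 decimals."""
    pct = pd.DataFrame(index=table.index)
    for col, src in [("sensitivity_pct", "sensitivity"), ("fn_pct", "fn_rate"),
                     ("specificity_pct", "specificity"), ("fp_pct", "fp_rate"),
                     ("ppv_pct", "ppv")]:
        pct[col] = (table[src] * 100).round(2)
    pct["n_false_pos"] = table["n_false_pos"]
    return pct[["sensitivity_pct", "fn_pct", "specificity_pct", "fp_pct",
                "n_false_pos", "ppv_pct"]]
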