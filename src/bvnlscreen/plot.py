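"""Prediction-ellipse figure on the standardized log scale.

Mirrors the study's scatter: normative newborns in grey, pseudo-deficient
newborns highlighted, affected cases as red crosses, the two univariate
thresholds as dashed lines and the (1 - p)100% prediction ellipse drawn from
the fitted correlation. The high-risk region is the corner beyond both
thresholds and outside the ellipse.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model import BVNLScreen, ellipse_radius_sq

__all__ = ["ellipse_path", "plot_screen"]


def ellipse_path(rho: float, radius_sq: float, n_points: int = 400):
    """Parametric boundary of {z : z' Sigma^{-1} z = r^2}, Sigma = [[1,rho],[rho,1]].

    Built from the Cholesky factor of Sigma applied to a circle of radius r.
    Returns (x, y) arrays.
    """
    r = math.sqrt(radius_sq)
    t = np.linspace(0.0, 2.0 * math.pi, n_points)
    x = r * np.cos(t)
    y = r * (rho * np.cos(t) + math.sqrt(1.0 - rho * rho) * np.sin(t))
    return x, y


def plot_screen(screen: BVNLScreen, cohort: pd.DataFrame, path) -> None:
    """Render the classification figure for a labelled cohort and save it.

    ``cohort`` is a cohort table (idua/hs raw columns, optional status);
    output format follows the file extension (.png or .svg).
    """
    z = screen.transform(cohort)
    status = (cohort["status"] if "status" in cohort.columns
              else pd.Series(["unknown"] * len(cohort)))
    fig, ax = plt.subplots(figsize=(6.5, 6))
    groups = [
        ("normal", dict(s=8, c="0.6", marker="o", label="normal", zorder=1)),
        ("unknown", dict(s=8, c="0.4", marker="o", label="unknown", zorder=1)),
        ("pseudo_deficient", dict(s=30, c="tab:orange", marker="s",
                                  label="pseudo-deficient", zorder=3)),
        ("affected", dict(s=60, c="tab:red", marker="x", linewidths=2,
                          label="affected (MPS I)", zorder=4)),
    ]
    for name, style in groups:
        mask = (status == name).to_numpy()
        if mask.any():
            ax.scatter(z[mask, 0], z[mask, 1], **style)

    th = screen.thresholds_
    r2 = ellipse_radius_sq(th.ellipse_p, screen.model_.n, th.radius_method)
    ex, ey = ellipse_path(screen.model_.rho, r2)
    ax.plot(ex, ey, "b-", lw=1.2,
            label=f"(1−{th.ellipse_p:g})100% prediction ellipse")
    ax.axvline(th.z_idua_cut, ls="--", c="k", lw=0.8)
    ax.axhline(th.z_hs_cut, ls="--", c="k", lw=0.8)
    ax.set_xlabel("standardized log$_e$ IDUA activity")
    ax.set_ylabel("standardized log$_e$ heparan sulfate")
    ax.set_title("BVNL screening regions")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
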