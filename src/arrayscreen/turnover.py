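"""Protein half-life models and screen-targetability classification.

Arrayed knockout screens read out phenotypes within a few days of
transfection, so long-lived proteins may persist past the assay window even
after successful gene disruption. Given per-protein degradation parameters,
this module computes half-lives and classifies each protein as "targetable"
or "hard to target" at a half-life threshold (default 120 h).

Degradation models:

* exponentially degraded (ED) proteins: one-state decay,
  ``R(t) = exp(-k t)``, half-life ``ln(2)/k``;
* non-exponentially degraded (NED) proteins: two-state mixture of a fast
  and a slow pool, ``R(t) = a exp(-k_fast t) + (1-a) exp(-k_slow t)``,
  half-life solved numerically (R is strictly decreasing from 1 to 0, so
  the root is unique).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from arrayscreen.errors import DomainError

LN2 = math.log(2.0)

TURNOVER_COLUMNS = [
    "protein_id", "deg_class", "k", "alpha", "k_fast", "k_slow",
]


def half_life_1state(k: float) -> float:
    """Half-life of one-state exponential decay: ``ln(2)/k`` (k per hour)."""
    if not (k > 0):
        raise DomainError(f"degradation rate must be positive, got {k}")
    return LN2 / k


def remaining_fraction(t, alpha: float, k_fast: float, k_slow: float):
    """Two-state remaining fraction R(t) = a e^(-k_fast t) + (1-a) e^(-k_slow t)."""
    t = np.asarray(t, dtype=float)
    out = alpha * np.exp(-k_fast * t) + (1.0 - alpha) * np.exp(-k_slow * t)
    return float(out) if out.ndim == 0 else out


def half_life_2state(
    alpha: float, k_fast: float, k_slow: float, tol: float = 1e-9
) -> float:
    """Half-life of the two-state mixture, by bracketing root finding.

    Requires ``0 <= alpha <= 1`` and positive rates with
    ``k_fast >= k_slow``. The root of ``R(t) = 1/2`` is bracketed between
    the pure-fast and pure-slow half-lives and solved to ``tol`` hours.
    """
    if not (0.0 <= alpha <= 1.0):
        raise DomainError(f"alpha must be in [0, 1], got {alpha}")
    if not (k_fast > 0 and k_slow > 0):
        raise DomainError("rates must be positive")
    if k_fast < k_slow:
        raise DomainError("k_fast must be >= k_slow")
    if k_fast == k_slow or alpha == 1.0:
        return half_life_1state(k_fast)
    if alpha == 0.0:
        return half_life_1state(k_slow)
    lo, hi = LN2 / k_fast, LN2 / k_slow  # R(lo) >= 1/2 >= R(hi)
    f = lambda t: remaining_fraction(t, alpha, k_fast, k_slow) - 0.5
    if f(lo) == 0:
        return lo
    return float(brentq(f, lo, hi, xtol=tol))


def classify_targetable(half_life_h: float, threshold_h: float = 120.0) -> str:
    """"hard_to_target" iff half-life strictly exceeds the threshold."""
    if not (half_life_h > 0):
        raise DomainError("half-life must be positive")
    return "hard_to_target" if half_life_h > threshold_h else "targetable"


def record_half_life(row) -> float:
    """Half-life of one turnover record (mapping or namedtuple-like)."""
    get = row.get if hasattr(row, "get") else lambda k, d=None: getattr(row, k, d)
    deg_class = get("deg_class")
    if deg_class == "ED":
        return half_life_1state(float(get("k")))
    if deg_class == "NED":
        return half_life_2state(
            float(get("alpha")), float(get("k_fast")), float(get("k_slow"))
        )
    raise DomainError(f"unknown degradation class {deg_class!r}")


def read_turnover_table(path) -> pd.DataFrame:
    """Read a turnover CSV (``protein_id,deg_class,k,alpha,k_fast,k_slow``;
    unused fields empty)."""
    df = pd.read_csv(path)
    missing = [c for c in TURNOVER_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"{path}: missing columns {missing}")
    return df


def proteome_targetability_summary(
    records: pd.DataFrame,
    threshold_h: float = 120.0,
    density_grid_points: int = 256,
) -> dict:
    """Half-life, class and proteome-wide hard-to-target fraction.

    Returns ``{"table": per-protein DataFrame, "fraction_hard": float,
    "density_curves": {deg_class: DataFrame(log10_half_life_h, density)}}``.
    Density curves are Gaussian KDEs of log10 half-life per degradation
    class (for plotting the targetable / hard-to-target split).
    """
    if len(records) == 0:
        raise DomainError("empty turnover table")
    half_lives = np.array(
        [record_half_life(row) for row in records.to_dict("records")]
    )
    classes = np.array(
        [classify_targetable(h, threshold_h) for h in half_lives]
    )
    table = records.copy()
    table["half_life_h"] = half_lives
    table["targetable"] = classes
    curves = {}
    log_hl = np.log10(half_lives)
    for deg_class, idx in table.groupby("deg_class").groups.items():
        vals = log_hl[table.index.get_indexer(idx)]
        if len(vals) >= 3 and np.std(vals) > 0:
            kde = stats.gaussian_kde(vals)
            grid = np.linspace(vals.min() - 0.5, vals.max() + 0.5,
                               density_grid_points)
            curves[deg_class] = pd.DataFrame(
                {"log10_half_life_h": grid, "density": kde(grid)}
            )
    return {
        "table": table,
        "fraction_hard": float(np.mean(classes == "hard_to_target")),
        "density_curves": curves,
    }
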