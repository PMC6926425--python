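"""Likelihood-ratio (LOD) scoring of knockout viability.

The score compares, for a guide's normalized viability ``x``, the
likelihood that ``x`` arose from the lethal positive-control distribution
(an essential-gene knockout such as POLR2A) against the likelihood that it
arose from the non-targeting scrambled-control distribution. Both control
distributions are modelled as normal, so

    LOD(x) = log10( p(x | positive model) / p(x | negative model) )

A LOD of 3 means the odds are a thousand to one in favour of the lethal
model, and is the classical significance threshold. Two probability models
are available: ``density`` (normal pdf; the default) and ``cdf_tail``
(lower-tail normal cdf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
import pandas as pd

from arrayscreen.errors import (
    DegenerateControlsError,
    InsufficientControlsError,
    InsufficientOverlapError,
)

LOG10 = math.log(10.0)


@dataclass(frozen=True)
class ControlModel:
    """Fitted normal models for the positive and negative control wells.

    ``separation`` is the standardized distance between the control means,
    (mu_neg - mu_pos) / pooled sd; narrow, well-separated controls are a
    screen-quality requirement because overlapping control distributions
    cannot yield high LOD scores. ``ks_p_*`` are Kolmogorov-Smirnov
    p-values of each control sample against its fitted normal, reported as
    a normality diagnostic (parameters are estimated from the same sample,
    so the p-values are conservative).
    """

    mu_pos: float
    sigma_pos: float
    mu_neg: float
    sigma_neg: float
    n_pos: int
    n_neg: int
    ks_p_pos: float
    ks_p_neg: float
    separation: float

    def to_dict(self) -> dict:
        return asdict(self)


def fit_control_model(pos_values, neg_values) -> ControlModel:
    """Fit normal models to positive- and negative-control viabilities.

    Each sample needs >= 3 finite values with positive sample sd.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    for name, arr in (("positive", pos), ("negative", neg)):
        if arr.size < 3 or not np.isfinite(arr).all():
            raise InsufficientControlsError(
                f"{name} controls: need >= 3 finite values, got {arr.size}"
            )
    mu_pos, sd_pos = float(pos.mean()), float(pos.std(ddof=1))
    mu_neg, sd_neg = float(neg.mean()), float(neg.std(ddof=1))
    tiny_pos = 1e-12 * max(1.0, abs(mu_pos))
    tiny_neg = 1e-12 * max(1.0, abs(mu_neg))
    if sd_pos <= tiny_pos or sd_neg <= tiny_neg:
        raise DegenerateControlsError(
            "control values have zero sample standard deviation"
        )
    pooled = math.sqrt(
        ((pos.size - 1) * sd_pos**2 + (neg.size - 1) * sd_neg**2)
        / (pos.size + neg.size - 2)
    )
    return ControlModel(
        mu_pos=mu_pos,
        sigma_pos=sd_pos,
        mu_neg=mu_neg,
        sigma_neg=sd_neg,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        ks_p_pos=float(stats.kstest(pos, "norm", args=(mu_pos, sd_pos)).pvalue),
        ks_p_neg=float(stats.kstest(neg, "norm", args=(mu_neg, sd_neg)).pvalue),
        separation=(mu_neg - mu_pos) / pooled,
    )


def lod_score(
    x,
    model: ControlModel,
    method: str = "density",
    eps: float = 1e-300,
):
    """LOD score(s) for normalized viability ``x`` under a fitted model.

    ``density`` uses normal pdfs; ``cdf_tail`` uses lower-tail normal cdfs.
    Probabilities are floored at ``eps`` before the ratio so the score stays
    finite for extreme ``x`` without altering rankings.
    """
    x = np.asarray(x, dtype=float)
    if method == "density":
        p_pos = stats.norm.pdf(x, model.mu_pos, model.sigma_pos)
        p_neg = stats.norm.pdf(x, model.mu_neg, model.sigma_neg)
    elif method == "cdf_tail":
        p_pos = stats.norm.cdf(x, model.mu_pos, model.sigma_pos)
        p_neg = stats.norm.cdf(x, model.mu_neg, model.sigma_neg)
    else:
        raise ValueError(f"unknown LOD method {method!r}")
    out = np.log10(np.maximum(p_pos, eps)) - np.log10(np.maximum(p_neg, eps))
    return float(out) if out.ndim == 0 else out


class LodHitCaller(BaseEstimator, ClassifierMixin):
    """Hit caller built from the two control distributions.

    A Gaussian likelihood-ratio classifier for 1-D viability values:
    ``fit`` learns normal models from labelled control wells,
    ``decision_function`` returns LOD scores, and ``predict`` calls a well
    a hit when its LOD reaches ``threshold`` (inclusive).

    Parameters
    ----------
    method : {"density", "cdf_tail"}
        Probability model for the likelihood ratio.
    threshold : float, default 3.0
        Hit threshold on the LOD score; 3 corresponds to thousand-to-one
        odds.
    eps : float
        Probability floor keeping scores finite.
    """

    def __init__(
        self, method: str = "density", threshold: float = 3.0,
        eps: float = 1e-300,
    ):
        self.method = method
        self.threshold = threshold
        self.eps = eps

    def fit(self, X, y):
        """Fit control models.

        ``X`` is an array of normalized viabilities (n,) or (n, 1); ``y``
        labels each value ``1``/"positive_control" (lethal control) or
        ``0``/"scrambled" (neutral control).
        """
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y)
        if y.dtype.kind in "USO":
            is_pos = y == "positive_control"
            is_neg = y == "scrambled"
            if not (is_pos | is_neg).all():
                raise ValueError(
                    "labels must be 'positive_control' or 'scrambled'"
                )
        else:
            is_pos = y.astype(bool)
            is_neg = ~is_pos
        self.model_ = fit_control_model(X[is_pos], X[is_neg])
        self.classes_ = np.array([False, True])
        return self

    def decision_function(self, X):
        """LOD scores for viabilities ``X``."""
        X = np.asarray(X, dtype=float).reshape(-1)
        return lod_score(X, self.model_, method=self.method, eps=self.eps)

    def predict(self, X):
        """Boolean hit calls at the configured threshold (inclusive)."""
        return self.decision_function(X) >= self.threshold


def call_hits(
    summary: pd.DataFrame,
    model: ControlModel,
    threshold: float = 3.0,
    method: str = "density",
    value_column: str = "mean",
    cell_line: str | None = None,
) -> pd.DataFrame:
    """Score per-guide mean viabilities and call hits at ``lod >= threshold``.

    ``summary`` is a per-guide table with at least ``gene_symbol``,
    ``guide_id``, ``n`` and ``value_column``. The result is sorted by
    descending LOD.
    """
    caller = LodHitCaller(method=method, threshold=threshold)
    caller.model_ = model
    lod = caller.decision_function(summary[value_column].to_numpy())
    out = pd.DataFrame(
        {
            "cell_line": cell_line if cell_line is not None else summary.get(
                "cell_line", pd.Series([""] * len(summary))
            ),
            "gene_symbol": summary["gene_symbol"].to_numpy(),
            "guide_id": summary["guide_id"].to_numpy(),
            "n_replicates": summary["n"].to_numpy(),
            "mean_normalized_viability": summary[value_column].to_numpy(),
            "lod": lod,
            "hit": lod >= threshold,
        }
    )
    return out.sort_values("lod", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def screen_qc(
    model: ControlModel,
    min_separation: float = 3.0,
    alpha: float = 0.01,
) -> dict:
    """Quality verdict on a screen's control distributions.

    Fails when the controls are not separated by at least
    ``min_separation`` pooled standard deviations, or when either control
    sample departs from normality at level ``alpha`` (KS test).
    """
    reasons = []
    if model.separation < min_separation:
        reasons.append(
            f"controls not separated (separation {model.separation:.3g} "
            f"< {min_separation})"
        )
    if model.ks_p_pos < alpha:
        reasons.append(
            f"positive controls non-normal (KS p {model.ks_p_pos:.3g})"
        )
    if model.ks_p_neg < alpha:
        reasons.append(
            f"negative controls non-normal (KS p {model.ks_p_neg:.3g})"
        )
    return {
        "separation": model.separation,
        "ks_p_pos": model.ks_p_pos,
        "ks_p_neg": model.ks_p_neg,
        "verdict": "pass" if not reasons else "fail",
        "reasons": reasons,
    }


def replicate_concordance(rep1: pd.Series, rep2: pd.Series):
    """Correlate per-guide means between two replicate screens.

    Inputs are Series indexed by guide id; correlation is computed over
    the intersection of guides (>= 3 required). Returns the paired table
    plus Pearson r and Spearman rho.
    """
    shared = rep1.index.intersection(rep2.index)
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared guides; need >= 3"
        )
    paired = pd.DataFrame(
        {"rep1": rep1.loc[shared], "rep2": rep2.loc[shared]}
    )
    r = float(stats.pearsonr(paired["rep1"], paired["rep2"]).statistic)
    rho = float(stats.spearmanr(paired["rep1"], paired["rep2"]).statistic)
    return paired, r, rho
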