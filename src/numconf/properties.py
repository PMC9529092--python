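"""Theory-based confidence signatures as reusable diagnostics.

A statistical notion of confidence — the posterior probability of being
correct given choice and evidence — implies three signatures in any
trial table carrying a confidence proxy (model confidence or button
pressure):

1. accuracy increases across proxy bins,
2. the proxy is higher on correct than on error trials at fixed
   difficulty,
3. above-median-proxy trials are more accurate at fixed difficulty.

Each check reduces to a sign claim on a contrast from an ordinary
least-squares linear probability model with per-subject intercepts
(full random-effects panel machinery is deliberately out of scope: the
signatures are monotonicity statements, not coefficient reproductions).
A check passes when the 95% CI of its contrast excludes zero on the
expected side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "PropertyReport",
    "bin_accuracy_by_confidence",
    "confidence_by_correctness",
    "median_split_accuracy",
    "run_property_checks",
    "normative_illustration",
    "bic_distance_comparison",
]


@dataclass
class PropertyReport:
    """Bundle of the three signature diagnostics."""

    binned_curve: pd.DataFrame
    correct_vs_error: pd.DataFrame
    split_curve: pd.DataFrame
    slopes: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    passed: dict[str, bool] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "binned_curve": self.binned_curve.to_dict(orient="list"),
            "correct_vs_error": self.correct_vs_error.to_dict(orient="list"),
            "split_curve": self.split_curve.to_dict(orient="list"),
            "slopes": {k: list(v) for k, v in self.slopes.items()},
            "passed": self.passed,
            "flags": self.flags,
        }


def _ols_contrast(y, x, subject) -> tuple[float, float, float]:
    """OLS slope of y on x with per-subject intercepts; (est, lo, hi)."""
    subj = pd.get_dummies(pd.Series(subject).astype("category"), drop_first=True, dtype=float)
    X = pd.DataFrame({"x": np.asarray(x, dtype=float)})
    X = pd.concat([X.reset_index(drop=True), subj.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X)
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    ci = res.conf_int()
    if isinstance(ci, pd.DataFrame):
        lo, hi = ci.loc["x", 0], ci.loc["x", 1]
    else:  # ndarray
        idx = list(X.columns).index("x")
        lo, hi = ci[idx]
    return float(res.params["x"]), float(lo), float(hi)


def bin_accuracy_by_confidence(
    trials: pd.DataFrame, n_bins: int = 10, proxy: str = "confidence"
) -> tuple[pd.DataFrame, tuple[float, float, float], bool]:
    """Equal-count proxy bins vs accuracy, plus the linear-probability
    slope of accuracy on the proxy with subject intercepts.

    Passes iff the slope CI lies above zero.
    """
    if len(trials) < n_bins * 20:
        raise ValueError("need at least 20 trials per bin")
    x = trials[proxy].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("constant proxy: bins are degenerate")
    bins = pd.qcut(x, n_bins, duplicates="drop")
    curve = (
        pd.DataFrame({"bin": bins, "correct": trials["correct"].to_numpy(dtype=float), "proxy": x})
        .groupby("bin", observed=True)
        .agg(proxy_center=("proxy", "mean"), accuracy=("correct", "mean"), n=("correct", "size"))
        .reset_index(drop=True)
    )
    slope = _ols_contrast(trials["correct"], x, trials["subject"])
    return curve, slope, slope[1] > 0


def confidence_by_correctness(
    trials: pd.DataFrame, proxy: str = "confidence"
) -> tuple[pd.DataFrame, tuple[float, float, float] | None, bool | None]:
    """Mean proxy for correct vs error per distance, and the overall
    correct-error contrast with subject intercepts.

    Returns (curve, contrast, passed); passed is None (not evaluable)
    when error trials are absent at fewer than 3 distances.
    """
    g = trials.groupby(["log_distance", "correct"], observed=True)[proxy].mean().unstack()
    curve = pd.DataFrame(
        {
            "log_distance": g.index.to_numpy(dtype=float),
            "mean_conf_correct": g.get(True, pd.Series(index=g.index, dtype=float)).to_numpy(),
            "mean_conf_error": g.get(False, pd.Series(index=g.index, dtype=float)).to_numpy(),
        }
    )
    n_both = int(np.isfinite(curve["mean_conf_error"]).sum()) if False in g.columns else 0
    if False not in g.columns or n_both < 3:
        return curve, None, None
    contrast = _ols_contrast(trials[proxy], trials["correct"].astype(float), trials["subject"])
    return curve, contrast, contrast[1] > 0


def median_split_accuracy(
    trials: pd.DataFrame, proxy: str = "confidence"
) -> tuple[pd.DataFrame, tuple[float, float, float], bool]:
    """Within-subject median split of the proxy; accuracy of the high vs
    low half per distance, and the overall high-low accuracy contrast
    with subject intercepts.  Ties go to the low half.
    """
    x = trials[proxy]
    if np.allclose(x, x.iloc[0]):
        raise ValueError("all proxy values identical: split is degenerate")
    med = trials.groupby("subject")[proxy].transform("median")
    high = (x > med).to_numpy()
    work = trials.assign(_high=high)
    g = (
        work.groupby(["log_distance", "_high"], observed=True)["correct"]
        .mean()
        .unstack()
    )
    curve = pd.DataFrame(
        {
            "log_distance": g.index.to_numpy(dtype=float),
            "acc_high": g.get(True, pd.Series(index=g.index, dtype=float)).to_numpy(),
            "acc_low": g.get(False, pd.Series(index=g.index, dtype=float)).to_numpy(),
        }
    )
    contrast = _ols_contrast(work["correct"], high.astype(float), work["subject"])
    return curve, contrast, contrast[1] > 0


def run_property_checks(
    trials: pd.DataFrame, proxy: str = "confidence", n_bins: int = 10
) -> PropertyReport:
    """Run all three signature checks on a trial table."""
    binned, slope1, pass1 = bin_accuracy_by_confidence(trials, n_bins=n_bins, proxy=proxy)
    cve, contrast2, pass2 = confidence_by_correctness(trials, proxy=proxy)
    split, contrast3, pass3 = median_split_accuracy(trials, proxy=proxy)
    report = PropertyReport(binned_curve=binned, correct_vs_error=cve, split_curve=split)
    report.slopes["accuracy_by_proxy"] = slope1
    report.passed["accuracy_by_proxy"] = bool(pass1)
    if contrast2 is None:
        report.flags["proxy_by_correctness"] = "not evaluable: too few error trials"
    else:
        report.slopes["proxy_by_correctness"] = contrast2
        report.passed["proxy_by_correctness"] = bool(pass2)
    report.slopes["median_split"] = contrast3
    report.passed["median_split"] = bool(pass3)
    return report


def normative_illustration(
    n_trials: int = 100_000, percept_sd: float = 0.3, seed: int | None = None
) -> pd.DataFrame:
    """Generative illustration of the three signatures outside any
    decision model.

    Discriminability d ~ U(0,1); true side s = +/-1 equiprobable; percept
    x ~ N(s*d, percept_sd); choice = sign(x); confidence is the exact
    posterior probability the choice is correct under this generative
    model, marginalizing d:

        p(x | s=+1) = Phi(x/sd) - Phi((x-1)/sd)  (and mirrored for -1),
        confidence  = max(p+, p-) / (p+ + p-).

    Returns the trial table (columns subject, log_distance == d bin
    center proxying difficulty, correct, confidence) ready for the
    signature checks.
    """
    if percept_sd <= 0:
        raise ValueError("percept_sd must be > 0")
    if n_trials < 10_000:
        raise ValueError("need at least 1e4 trials for stable curves")
    rng = np.random.default_rng(seed)
    d = rng.uniform(0.0, 1.0, n_trials)
    s = rng.choice([-1.0, 1.0], n_trials)
    x = rng.normal(s * d, percept_sd)
    choice = np.where(x >= 0, 1.0, -1.0)
    p_pos = norm.cdf(x / percept_sd) - norm.cdf((x - 1.0) / percept_sd)
    p_neg = norm.cdf((x + 1.0) / percept_sd) - norm.cdf(x / percept_sd)
    conf = np.where(choice > 0, p_pos, p_neg) / (p_pos + p_neg)
    return pd.DataFrame(
        {
            "subject": 0,
            "log_distance": np.round(d, 1),  # difficulty bins for per-level curves
            "correct": choice == s,
            "confidence": conf,
        }
    )


def bic_distance_comparison(
    trials: pd.DataFrame, outcome: str = "rt"
) -> tuple[float, float, float]:
    """BIC of the subject-intercept OLS of ``outcome`` on log vs linear
    numerical distance.  Returns (bic_log, bic_linear, delta); negative
    delta favors the logarithmic scale.
    """
    lin = (trials["num_a"] - trials["num_b"]).to_numpy(dtype=float)
    logd = trials["log_distance"].to_numpy(dtype=float)
    if np.allclose(lin, lin[0]) or np.allclose(logd, logd[0]):
        raise ValueError("constant distance regressor: models are collinear")
    y = trials[outcome].to_numpy(dtype=float)
    subj = pd.get_dummies(trials["subject"].astype("category"), drop_first=True, dtype=float)

    def _bic(x):
        X = sm.add_constant(
            pd.concat(
                [pd.Series(x, name="dist").reset_index(drop=True), subj.reset_index(drop=True)],
                axis=1,
            )
        )
        return float(sm.OLS(y, X).fit().bic)

    bic_log = _bic(logd)
    bic_lin = _bic(lin)
    return bic_log, bic_lin, bic_log - bic_lin
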