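"""Bayesian confidence readout at the moment of choice.

With a normal likelihood for the decision-variable samples and a flat
prior on their mean mu_dv, the posterior after n samples is

    mu_dv | dv  ~  Normal(dv_bar, UN / sqrt(n))

where dv_bar is the time-average of the decision-variable stream and UN
is the inference-uncertainty parameter.  Because positive dv codes the
objectively correct option, confidence is the posterior probability that
mu_dv > 0 evaluated when the trace hits a threshold:

    confidence = Phi(dv_bar * sqrt(n) / UN).

UN never enters the choice/RT fit; it is a free parameter read out after
fitting.  Lower UN means more certainty gained per sample, so numeral
types can differ in confidence even with identical choice behaviour.

The sample count n is defined on a 5 ms sampling of the decision-variable
stream (``DEFAULT_SAMPLE_DT``), independent of the finer integration step
of the simulator: the reference UN values are calibrated to that stream
resolution, and a finer n would tighten the posterior by the square root
of the refinement factor and saturate the readout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ddm import Choice, DDMParams, SimConfig, TrialOutcome, drift_for_distance, simulate_batch
from .design import ExperimentDesign

__all__ = [
    "PosteriorSummary",
    "posterior_of_mean",
    "confidence_at_choice",
    "confidence_from_summary",
    "effective_samples",
    "apply_un",
    "simulate_confidence_table",
    "UN_PRESETS",
    "DEFAULT_SAMPLE_DT",
]

#: Sampling interval (s) of the decision-variable stream for the
#: confidence readout; the UN presets are calibrated to this resolution.
DEFAULT_SAMPLE_DT = 0.005

#: Inference-uncertainty presets used in the published qualitative
#: demonstrations: one equal-UN setting and one where positive numerals
#: carry lower uncertainty per sample.
UN_PRESETS: dict[str, dict[str, dict[str, float]]] = {
    "exp1": {
        "equal": {"positive": 2.5, "negative": 2.5, "one_over": 2.5},
        "different": {"positive": 1.65, "negative": 2.4, "one_over": 2.4},
    },
    "exp2": {
        "equal": {"positive": 4.5, "negative": 4.5, "one_over": 4.5},
        "different": {"positive": 3.5, "negative": 4.3, "one_over": 4.3},
    },
    "exp3": {
        "equal": {"positive": 4.5, "negative": 4.5, "one_over": 4.5},
        "different": {"positive": 2.5, "negative": 4.0, "one_over": 4.5},
    },
}


@dataclass(frozen=True)
class PosteriorSummary:
    """Normal posterior over the mean decision variable."""

    dv_mean: float
    n: int
    un: float
    post_sd: float
    confidence: float


def posterior_of_mean(dv_mean: float, n: int, un: float) -> PosteriorSummary:
    """Posterior Normal(dv_mean, un/sqrt(n)) and the implied confidence."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if un <= 0:
        raise ValueError("un must be > 0")
    post_sd = un / np.sqrt(n)
    conf = float(norm.cdf(dv_mean / post_sd))
    return PosteriorSummary(dv_mean=dv_mean, n=int(n), un=un, post_sd=float(post_sd), confidence=conf)


def confidence_from_summary(dv_mean, n, un):
    """Vectorized Phi(dv_bar * sqrt(n) / UN)."""
    dv_mean = np.asarray(dv_mean, dtype=float)
    n = np.asarray(n, dtype=float)
    return norm.cdf(dv_mean * np.sqrt(n) / un)


def effective_samples(n_steps, dt: float, sample_dt: float = DEFAULT_SAMPLE_DT):
    """Sample count of the decision stream at the readout resolution."""
    n = np.ceil(np.asarray(n_steps, dtype=float) * dt / sample_dt)
    return np.maximum(n, 1.0)


def confidence_at_choice(
    trial: TrialOutcome, un: float, dt: float = 0.001,
    sample_dt: float = DEFAULT_SAMPLE_DT,
) -> float:
    """P(mu_dv > 0 | trace) at threshold crossing; undefined for timeouts."""
    if trial.choice is Choice.TIMEOUT:
        raise ValueError("confidence is undefined for timeout trials")
    n = int(effective_samples(trial.n_steps, dt, sample_dt))
    return posterior_of_mean(trial.dv_mean, n, un).confidence


def apply_un(
    table: pd.DataFrame, un_by_type: Mapping[str, float], dt: float = 0.001,
    sample_dt: float = DEFAULT_SAMPLE_DT,
) -> pd.DataFrame:
    """Recompute confidence of a simulated table under a different UN
    assignment (the fit is UN-free, so the same simulated trials serve
    every UN setting)."""
    out = table.copy()
    n_eff = effective_samples(out["n_steps"].to_numpy(), dt, sample_dt)
    conf = np.full(len(out), np.nan)
    for t, un in un_by_type.items():
        sel = (out["numeral_type"] == t).to_numpy()
        conf[sel] = confidence_from_summary(
            out.loc[sel, "dv_mean"].to_numpy(), n_eff[sel], un
        )
    out["confidence"] = conf
    return out


def un_ordering_margins(
    table: pd.DataFrame,
    experiment: str = "exp1",
    dt: float = 0.001,
    sample_dt: float = DEFAULT_SAMPLE_DT,
) -> dict[str, float]:
    """Positive-vs-negative mean-confidence contrast under the equal and
    different UN presets, from one simulated table (the simulation is
    UN-free, so both settings reuse the same trials).

    The contrast is computed on correct trials, matching the plotting
    convention of the published by-distance confidence panels.  Returns
    ``{"equal": mean_pos - mean_neg, "different": mean_pos - mean_neg}``;
    the expected signs are negative and positive respectively.
    """
    correct = table[table["correct"].astype(bool)]
    out = {}
    for mode in ("equal", "different"):
        re_read = apply_un(correct, UN_PRESETS[experiment][mode], dt=dt, sample_dt=sample_dt)
        by_type = re_read.groupby("numeral_type")["confidence"].mean()
        out[mode] = float(by_type["positive"] - by_type["negative"])
    return out


def simulate_confidence_table(
    params_by_type: Mapping[str, DDMParams],
    design: ExperimentDesign,
    sims_per_distance: int = 150,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    subject: int = 0,
) -> pd.DataFrame:
    """Simulate ``sims_per_distance`` trials per numeral type and distance
    and attach confidence at choice (timeouts dropped).

    Returns a table with columns subject, numeral_type, log_distance,
    correct, rt, dv_mean, n_steps, confidence.
    """
    if sims_per_distance < 1:
        raise ValueError("sims_per_distance must be >= 1")
    if len(design.pairs) == 0:
        raise ValueError("design has no pairs")
    if config is None:
        config = SimConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    frames = []
    for pair in design.pairs:
        t = pair.numeral_type.value
        if t not in params_by_type:
            continue
        params = params_by_type[t]
        v = drift_for_distance(params, pair.log_distance)
        batch = simulate_batch(
            v, params, sims_per_distance, rng, dt=config.dt, deadline_s=config.deadline_s
        )
        ok = batch["choice"] != 0
        n_eff = effective_samples(batch["n_steps"][ok], config.dt)
        conf = confidence_from_summary(batch["dv_mean"][ok], n_eff, params.un)
        frames.append(
            pd.DataFrame(
                {
                    "subject": subject,
                    "numeral_type": t,
                    "log_distance": pair.log_distance,
                    "correct": batch["choice"][ok] == 1,
                    "rt": batch["rt"][ok],
                    "dv_mean": batch["dv_mean"][ok],
                    "n_steps": batch["n_steps"][ok],
                    "confidence": conf,
                }
            )
        )
    if not frames:
        raise ValueError("no numeral type in the design matches params_by_type")
    return pd.concat(frames, ignore_index=True)
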