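"""Synthetic cohorts for the numeral-comparison confidence pipeline.

Generates complete experiments — participants with heterogeneous
decision parameters, trial-by-trial choices/RTs from the diffusion
simulator, model confidence, and a noisy monotone confidence-to-button-
pressure transfer — so every downstream stage (exclusion, fitting,
signature checks) is testable without any human data.

Subject parameters are independent truncated-normal draws around the
published group means/SDs for each numeral type (reference presets for
all three experiments ship with the module).  The pressure transfer is
an explicit construction of this package: no published transfer function
from confidence to motor output exists, so a linear map with Gaussian
sensor noise on the 0-1023 scale stands in, with a zero-gain setting as
the falsification control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .confidence import UN_PRESETS, confidence_from_summary, effective_samples
from .ddm import DDMParams, drift_for_distance, simulate_batch
from .design import ExperimentDesign, build_design, design_to_frame
from .fitting import FitBounds

__all__ = [
    "COHORT_PARAM_PRESETS",
    "CohortSpec",
    "sample_participant_params",
    "generate_cohort",
    "pressure_from_confidence",
    "normalize_pressure",
    "exclude_slow_rts",
]

#: Reference group-level parameter estimates (mean, sd) per numeral type
#: for the three experiments: (dr, sym, bo, ic, ndt).
COHORT_PARAM_PRESETS: dict[str, dict[str, dict[str, dict[str, float]]]] = {
    "exp1": {
        "one_over": {
            "mean": {"dr": 3.01, "sym": 0.22, "bo": 1.03, "ic": 0.32, "ndt": 0.43},
            "sd": {"dr": 0.88, "sym": 0.11, "bo": 0.65, "ic": 0.21, "ndt": 0.09},
        },
        "negative": {
            "mean": {"dr": 2.56, "sym": 0.19, "bo": 0.92, "ic": 0.33, "ndt": 0.43},
            "sd": {"dr": 0.71, "sym": 0.10, "bo": 0.20, "ic": 0.18, "ndt": 0.07},
        },
        "positive": {
            "mean": {"dr": 2.46, "sym": 0.09, "bo": 0.77, "ic": 0.22, "ndt": 0.41},
            "sd": {"dr": 0.77, "sym": 0.12, "bo": 0.13, "ic": 0.09, "ndt": 0.06},
        },
    },
    "exp2": {
        "one_over": {
            "mean": {"dr": 3.00, "sym": 0.14, "bo": 1.59, "ic": 0.37, "ndt": 0.69},
            "sd": {"dr": 1.04, "sym": 0.13, "bo": 1.77, "ic": 0.27, "ndt": 0.20},
        },
        "negative": {
            "mean": {"dr": 2.79, "sym": 0.14, "bo": 1.32, "ic": 0.45, "ndt": 0.72},
            "sd": {"dr": 0.85, "sym": 0.13, "bo": 0.77, "ic": 0.23, "ndt": 0.16},
        },
        "positive": {
            "mean": {"dr": 2.65, "sym": 0.09, "bo": 1.20, "ic": 0.30, "ndt": 0.67},
            "sd": {"dr": 0.91, "sym": 0.14, "bo": 0.76, "ic": 0.18, "ndt": 0.16},
        },
    },
    "exp3": {
        "one_over": {
            "mean": {"dr": 2.93, "sym": 0.16, "bo": 1.27, "ic": 0.40, "ndt": 0.67},
            "sd": {"dr": 0.85, "sym": 0.12, "bo": 0.61, "ic": 0.27, "ndt": 0.12},
        },
        "negative": {
            "mean": {"dr": 2.49, "sym": 0.14, "bo": 1.12, "ic": 0.49, "ndt": 0.71},
            "sd": {"dr": 0.61, "sym": 0.14, "bo": 0.26, "ic": 0.23, "ndt": 0.14},
        },
        "positive": {
            "mean": {"dr": 2.31, "sym": 0.11, "bo": 0.88, "ic": 0.23, "ndt": 0.66},
            "sd": {"dr": 0.55, "sym": 0.12, "bo": 0.15, "ic": 0.10, "ndt": 0.08},
        },
    },
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative specification of a synthetic experiment.

    Defaults emulate the first experiment: 50 subjects drawn around the
    exp1 reference means/SDs, the ten fixed digit pairs, equal-UN
    confidence, and a pressure transfer chosen so normalized pressure
    spans roughly the observed (0.025, 1] range.
    """

    n_subjects: int = 50
    experiment: str = "exp1"
    param_means: Mapping[str, Mapping[str, float]] | None = None
    param_sds: Mapping[str, Mapping[str, float]] | None = None
    un_by_type: Mapping[str, float] | None = None
    pressure_gain: float = 400.0
    pressure_intercept: float = 300.0
    pressure_noise_sd: float = 80.0
    design: ExperimentDesign | None = None
    seed: int = 0
    dt: float = 0.001
    bounds: FitBounds = field(default_factory=FitBounds)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    def resolved_means(self) -> dict[str, dict[str, float]]:
        if self.param_means is not None:
            return {k: dict(v) for k, v in self.param_means.items()}
        return {t: d["mean"] for t, d in COHORT_PARAM_PRESETS[self.experiment].items()}

    def resolved_sds(self) -> dict[str, dict[str, float]]:
        if self.param_sds is not None:
            return {k: dict(v) for k, v in self.param_sds.items()}
        return {t: d["sd"] for t, d in COHORT_PARAM_PRESETS[self.experiment].items()}

    def resolved_un(self) -> dict[str, float]:
        if self.un_by_type is not None:
            return dict(self.un_by_type)
        return dict(UN_PRESETS[self.experiment]["equal"])

    def resolved_design(self) -> ExperimentDesign:
        if self.design is not None:
            return self.design
        return build_design(self.experiment, seed=self.seed)


_PARAM_ORDER = ("dr", "sym", "bo", "ic", "ndt")


def sample_participant_params(
    spec: CohortSpec, subject_index: int
) -> dict[str, DDMParams]:
    """Parameter draws per numeral type, truncated to the fit bounds;
    deterministic given (spec.seed, subject_index).

    A single standard-normal factor per parameter is shared across
    numeral types within a subject (value = mean_type + sd_type * z,
    clipped to bounds): the same person drives all three types, so a
    subject fast with positive numerals is fast with negative ones too.
    Marginal means/sds per type are preserved.
    """
    rng = np.random.default_rng([spec.seed, subject_index])
    means, sds, uns = spec.resolved_means(), spec.resolved_sds(), spec.resolved_un()
    for t in sds:
        if any(v < 0 for v in sds[t].values()):
            raise ValueError("parameter sds must be >= 0")
    b = spec.bounds
    z = {p: rng.standard_normal() for p in _PARAM_ORDER}
    out: dict[str, DDMParams] = {}
    for t in sorted(means):
        m, s = means[t], sds[t]
        box = {"dr": b.dr, "sym": b.sym, "bo": b.bo, "ndt": b.ndt}
        vals = {
            p: float(np.clip(m[p] + s[p] * z[p], *box[p]))
            for p in ("dr", "sym", "bo", "ndt")
        }
        lo_ic, hi_ic = b.ic_bounds(vals["bo"])
        vals["ic"] = float(np.clip(m["ic"] + s["ic"] * z["ic"], lo_ic, hi_ic))
        out[t] = DDMParams(**vals, un=uns.get(t, 2.5))
    return out


def pressure_from_confidence(
    confidence, spec: CohortSpec, rng: np.random.Generator
):
    """Raw sensor peak: clip(intercept + gain*confidence + noise, 0, 1023).

    Gain 0 yields pressure independent of confidence — the null transfer
    used to falsify the signature checks.
    """
    confidence = np.asarray(confidence, dtype=float)
    raw = (
        spec.pressure_intercept
        + spec.pressure_gain * confidence
        + rng.normal(0.0, spec.pressure_noise_sd, size=confidence.shape)
    )
    return np.clip(raw, 0.0, 1023.0)


def normalize_pressure(trials: pd.DataFrame) -> pd.DataFrame:
    """Divide each raw pressure peak by that subject's per-side session
    maximum; the maximal record maps to exactly 1."""
    if "pressure_raw" not in trials:
        raise ValueError("table has no pressure_raw column")
    out = trials.copy()
    grp = out.groupby(["subject", "response_side"])["pressure_raw"]
    session_max = grp.transform("max")
    if (session_max <= 0).any():
        raise ValueError("a session has all-zero pressure; cannot normalize")
    out["pressure_norm"] = out["pressure_raw"] / session_max
    return out


def exclude_slow_rts(trials: pd.DataFrame, k_sd: float = 2.0) -> tuple[pd.DataFrame, float]:
    """One-sided slow-RT exclusion: drop rt > mean + k_sd * sd, moments
    pooled over all supplied trials.  Returns (kept, fraction_excluded)."""
    if len(trials) < 2:
        raise ValueError("need at least two trials")
    rt = trials["rt"].to_numpy(dtype=float)
    finite = np.isfinite(rt)
    cutoff = rt[finite].mean() + k_sd * rt[finite].std(ddof=0)
    keep = finite & (rt <= cutoff)
    return trials.loc[keep].reset_index(drop=True), float(1.0 - keep.mean())


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a full synthetic experiment as one trial table.

    Columns: subject, trial_index, numeral_type, num_a, num_b,
    log_distance, is_dummy, correct_side, response_side, choice, correct,
    rt, dv_mean, n_steps, confidence, pressure_raw, pressure_norm,
    excluded, exclusion_reason.  Dummy trials carry no analyzable fields;
    timeouts are retained with reason "timeout"; slow-RT exclusions are
    marked (not dropped) for auditability.
    """
    design = spec.resolved_design()
    root = np.random.SeedSequence([spec.seed, 987654321])
    frames = []
    for s in range(spec.n_subjects):
        params_by_type = sample_participant_params(spec, s)
        rng = np.random.default_rng(root.spawn(1)[0])
        table = design_to_frame(design, seed=rng.integers(2**31), subject=s)
        n = len(table)
        table["choice"] = pd.array([pd.NA] * n, dtype="string")
        for col in ("rt", "dv_mean", "confidence", "pressure_raw"):
            table[col] = np.nan
        table["n_steps"] = pd.array([pd.NA] * n, dtype="Int64")
        table["correct"] = pd.array([pd.NA] * n, dtype="boolean")

        real = ~table["is_dummy"]
        for (t, d), idx in table.loc[real].groupby(
            ["numeral_type", "log_distance"], observed=True
        ).groups.items():
            p = params_by_type[t]
            v = drift_for_distance(p, d)
            batch = simulate_batch(
                v, p, len(idx), rng, dt=spec.dt, deadline_s=design.deadline_s
            )
            ch = batch["choice"]
            table.loc[idx, "choice"] = np.where(
                ch == 1, "upper", np.where(ch == -1, "lower", "timeout")
            )
            table.loc[idx, "correct"] = ch == 1
            table.loc[idx, "rt"] = batch["rt"]
            table.loc[idx, "dv_mean"] = batch["dv_mean"]
            table.loc[idx, "n_steps"] = batch["n_steps"]
            ok = ch != 0
            conf = np.full(len(idx), np.nan)
            conf[ok] = confidence_from_summary(
                batch["dv_mean"][ok], effective_samples(batch["n_steps"][ok], spec.dt), p.un
            )
            table.loc[idx, "confidence"] = conf
        frames.append(table)
    cohort = pd.concat(frames, ignore_index=True)

    # response side: correct side if correct, the other if error
    other = cohort["correct_side"].map({"left": "right", "right": "left"})
    cohort["response_side"] = np.where(
        cohort["correct"].fillna(False).astype(bool), cohort["correct_side"], other
    )

    # pressure transfer on responded, non-dummy trials
    prng = np.random.default_rng([spec.seed, 24681357])
    responded = cohort["confidence"].notna()
    cohort.loc[responded, "pressure_raw"] = pressure_from_confidence(
        cohort.loc[responded, "confidence"].to_numpy(), spec, prng
    )
    cohort["pressure_norm"] = np.nan
    if responded.any():
        normed = normalize_pressure(cohort.loc[responded])
        cohort.loc[responded, "pressure_norm"] = normed["pressure_norm"]

    # exclusion flags: dummy, timeout, slow RT (pooled non-dummy responded)
    cohort["excluded"] = False
    cohort["exclusion_reason"] = ""
    cohort.loc[cohort["is_dummy"], ["excluded", "exclusion_reason"]] = [True, "dummy"]
    timeout = (cohort["choice"] == "timeout") & ~cohort["is_dummy"]
    cohort.loc[timeout, ["excluded", "exclusion_reason"]] = [True, "timeout"]
    analyzable = ~cohort["is_dummy"] & ~timeout
    if analyzable.sum() >= 2:
        rt = cohort.loc[analyzable, "rt"].to_numpy(dtype=float)
        cutoff = rt.mean() + 2.0 * rt.std(ddof=0)
        slow = analyzable & (cohort["rt"] > cutoff)
        cohort.loc[slow, ["excluded", "exclusion_reason"]] = [True, "slow_rt"]
    return cohort
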