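"""End-to-end pipeline: synthesize -> exclude -> fit -> confidence ->
signature checks, with every intermediate written to disk and a JSON
summary at the end.  All randomness flows from the single root seed in
the configuration, split per stage, so a run is reproducible from
(config, seed) alone."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortSpec, exclude_slow_rts, generate_cohort
from .confidence import UN_PRESETS, simulate_confidence_table
from .ddm import DDMParams, SimConfig
from .design import build_design
from .fitting import FitOptions, InsufficientDataError, fit_participant
from .io import RunConfig, write_json, write_table

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("numconf")

FAST_FIT = FitOptions(de_maxiter=8, de_popsize=6, polish_maxiter=80)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage, partial outputs stay."""


def _stage_seed(root: int, k: int) -> int:
    return int(np.random.SeedSequence([root, k]).generate_state(1)[0] % 2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and return the summary dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"experiment": config.experiment, "un_mode": config.un_mode}
    stage = "synth"
    try:
        design = build_design(
            config.experiment,
            config.trials_per_pair_per_type,
            config.n_dummy,
            seed=_stage_seed(config.seed, 0),
        )
        un = UN_PRESETS[config.experiment][config.un_mode]
        spec = CohortSpec(
            n_subjects=config.n_subjects,
            experiment=config.experiment,
            un_by_type=un,
            design=design,
            seed=_stage_seed(config.seed, 1),
        )
        cohort = generate_cohort(spec)
        write_table(cohort, out / "trials.csv", seed=config.seed, config=config)
        log.info("synth: %d trials (%d subjects)", len(cohort), config.n_subjects)

        stage = "exclude"
        analyzable = cohort[~cohort["is_dummy"] & (cohort["choice"] != "timeout")]
        kept, frac = exclude_slow_rts(analyzable)
        write_table(kept, out / "trials_clean.csv", seed=config.seed, config=config)
        summary["n_trials_raw"] = int(len(cohort))
        summary["n_trials_clean"] = int(len(kept))
        summary["rt_exclusion_fraction"] = frac
        log.info("exclude: kept %d trials (%.1f%% excluded)", len(kept), 100 * frac)

        stage = "fit"
        fits_rows = []
        fitted_params: dict[int, dict[str, DDMParams]] = {}
        if config.fit:
            opts = FAST_FIT if config.fast_fit else FitOptions()
            fseed = _stage_seed(config.seed, 2)
            for (subj, ntype), grp in kept.groupby(["subject", "numeral_type"], observed=True):
                try:
                    fit = fit_participant(
                        grp, seed=fseed, options=opts, subject=subj, numeral_type=ntype
                    )
                except InsufficientDataError:
                    log.warning("fit: skipping subject %s / %s (too few trials)", subj, ntype)
                    continue
                p = fit.params.with_un(un.get(ntype, 2.5))
                fitted_params.setdefault(subj, {})[ntype] = p
                fits_rows.append(
                    {
                        "subject": subj, "numeral_type": ntype,
                        "DR": p.dr, "SYM": p.sym, "BO": p.bo, "IC": p.ic, "NDT": p.ndt,
                        "nll": fit.nll, "n_trials": fit.n_trials, "converged": fit.converged,
                    }
                )
            fits = pd.DataFrame(fits_rows)
            write_table(fits, out / "fits.csv", seed=config.seed, config=config)
            if fits.empty:
                log.warning("fit: no subject had enough trials; skipping fit summary")
                summary["fitted_param_means"] = {}
            else:
                summary["fitted_param_means"] = (
                    fits.groupby("numeral_type")[["DR", "SYM", "BO", "IC", "NDT"]]
                    .mean().round(4).to_dict(orient="index")
                )

        stage = "confidence"
        cseed = _stage_seed(config.seed, 3)
        rng = np.random.default_rng(cseed)
        conf_frames = []
        source = fitted_params if (config.fit and fitted_params) else {
            s: {t: DDMParams(**spec.resolved_means()[t], un=un.get(t, 2.5)) for t in un}
            for s in range(config.n_subjects)
        }
        for subj, params_by_type in source.items():
            conf_frames.append(
                simulate_confidence_table(
                    params_by_type, design,
                    sims_per_distance=config.sims_per_distance,
                    config=SimConfig(), rng=rng, subject=subj,
                )
            )
        conf = pd.concat(conf_frames, ignore_index=True)
        write_table(conf, out / "confidence.csv", seed=config.seed, config=config)
        by_type = conf.groupby("numeral_type")["confidence"].mean()
        summary["mean_confidence_by_type"] = by_type.round(4).to_dict()
        correct_by_type = conf[conf["correct"]].groupby("numeral_type")["confidence"].mean()
        if {"positive", "negative"} <= set(correct_by_type.index):
            summary["confidence_pos_minus_neg"] = float(
                correct_by_type["positive"] - correct_by_type["negative"]
            )

        stage = "properties"
        from .properties import run_property_checks

        report = run_property_checks(conf, proxy="confidence")
        summary["confidence_properties"] = report.passed
        if "pressure_norm" in kept and kept["pressure_norm"].notna().any():
            pressed = kept[kept["pressure_norm"].notna()]
            preport = run_property_checks(pressed, proxy="pressure_norm")
            summary["pressure_properties"] = preport.passed
        write_json(
            {"summary": summary, "slopes": {k: list(v) for k, v in report.slopes.items()}},
            out / "summary.json", seed=config.seed, config=config,
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    return summary
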