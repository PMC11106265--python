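"""Top-level pipeline driver: fit -> decode -> reactivation -> group stats -> RT probe.

The driver runs on a synthetic cohort generated from the configuration
(every stage consumes the documented in-memory containers, so externally
prepared data in the same containers can be substituted stage by stage).
All randomness flows from config-declared seeds and the JSON report embeds
a hash of the resolved configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .decode import train_bank
from .fit import fit_em, ibic
from .reactivation import apply_bank_to_task, first_level_maps
from .rtprobe import fit_rt_weights, link_rt_to_choice
from .simulate import CohortSpec, simulate_cohort, simulate_probe_cohort
from .stats import permutation_fwe

log = logging.getLogger("riskreact")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

DEFAULTS = {
    "seed": 0,
    "cohort": {},  # CohortSpec field overrides
    "lam": 0.002,
    "sigma": 1.5,
    "n_perm": 5000,
    "em_max_iter": 100,
    "models": ["additive"],
    "analyses": [
        {"metric": "prob", "covariate": "fit:beta_prob", "tail": "max"},
        {"metric": "rew", "covariate": "fit:beta_rew", "tail": "max"},
        {"metric": "prob", "covariate": "bis", "tail": "min"},
    ],
    "run_probe_arm": True,
}


@dataclasses.dataclass
class PipelineConfig:
    values: dict

    def __getitem__(self, key):
        return self.values[key]

    @property
    def hash(self) -> str:
        blob = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(source=None) -> PipelineConfig:
    """Resolve a config mapping (or YAML path) against the defaults."""
    values = json.loads(json.dumps(DEFAULTS))
    if source is not None:
        if isinstance(source, (str, Path)):
            with open(source) as f:
                user = yaml.safe_load(f) or {}
        else:
            user = dict(source)
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(user)
    # validate against the cohort schema eagerly
    CohortSpec(**values["cohort"], seed=values["seed"])
    return PipelineConfig(values)


def _subject_maps(bundle, lam: float, seed: int):
    """Decode + reactivation for every subject; returns map stacks."""
    prob_maps, rew_maps, safe_maps = [], [], []
    for sb in bundle.subjects:
        bank = train_bank(sb.localizer, lam=lam, seed=seed + sb.subject)
        tensor = apply_bank_to_task(bank, sb.task_epochs, sb.responses_s)
        maps = first_level_maps(tensor, sb.design.decision_trials)
        prob_maps.append(maps.beta_prob)
        rew_maps.append(maps.beta_rew)
        safe_maps.append(maps.rp_os_mean)
    return {
        "prob": np.stack(prob_maps),
        "rew": np.stack(rew_maps),
        "safe": np.stack(safe_maps),
    }


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the configured analysis end to end; returns the report dict."""
    seed = int(config["seed"])
    spec = CohortSpec(**config["cohort"], seed=seed)
    log.info("simulating cohort (seed=%d, n=%d)", seed, spec.n_subjects)
    bundle = simulate_cohort(spec)

    report: dict = {
        "version": __version__,
        "config_hash": config.hash,
        "config": config.values,
        "seeds": {"master": seed},
    }

    # --- behavioral model fitting and comparison
    cohort = bundle.choice_cohort()
    fits = {}
    ibics = {}
    for model_id in config["models"]:
        fit = fit_em(model_id, cohort, seed=seed, max_iter=int(config["em_max_iter"]))
        fit.ibic = ibic(fit, cohort, seed=seed)
        fits[model_id] = fit
        ibics[model_id] = fit.ibic
        log.info("fit %s: iBIC=%.1f converged=%s", model_id, fit.ibic, fit.converged)
    report["ibic"] = ibics
    best = fits.get("additive", next(iter(fits.values())))
    report["choice_weights"] = {
        "beta_prob": list(best.param_series("beta_prob")) if best.model_id == "additive" else None,
        "beta_rew": list(best.param_series("beta_rew")) if best.model_id == "additive" else None,
    }

    # --- decoding and reactivation maps
    metric_maps = _subject_maps(bundle, lam=float(config["lam"]), seed=seed)

    # --- second-level permutation inference
    report["group_stats"] = {}
    alpha = 0.05
    for analysis in config["analyses"]:
        metric, cov_name, tail = analysis["metric"], analysis["covariate"], analysis["tail"]
        if cov_name.startswith("fit:"):
            covariate = best.param_series(cov_name.split(":", 1)[1])
        else:
            covariate = bundle.covariates[cov_name].to_numpy()
        result = permutation_fwe(
            metric_maps[metric],
            covariate,
            n_perm=int(config["n_perm"]),
            tail=tail,
            sigma=float(config["sigma"]),
            seed=seed,
        )
        key = f"{metric}~{cov_name}"
        report["group_stats"][key] = {
            "peak_t": result.peak_value,
            "peak_location": list(result.peak_location),
            "p_fwe": result.p_fwe,
            "tail": tail,
            "significant": bool(result.p_fwe <= alpha),
        }
        log.info("%s: peak t=%.3f p_fwe=%.4f", key, result.peak_value, result.p_fwe)

    # --- RT-probe arm
    if config["run_probe_arm"]:
        probe_bundle = simulate_probe_cohort(spec)
        probe_cohort = probe_bundle.choice_cohort()
        probe_fit = fit_em("additive", probe_cohort, seed=seed + 1,
                           max_iter=int(config["em_max_iter"]))
        all_probes = [t for sb in probe_bundle.subjects for t in sb.probe_trials]
        rt_weights = fit_rt_weights(all_probes)
        import pandas as pd

        report["rt_probe"] = {}
        for pairing in ("prob", "rew"):
            weights = pd.Series(
                probe_fit.param_series(f"beta_{pairing}"),
                index=pd.RangeIndex(len(probe_cohort), name="subject"),
            )
            r, t, p = link_rt_to_choice(rt_weights, weights, pairing=pairing)
            report["rt_probe"][pairing] = {"r": r, "t": t, "p": p}
            log.info("rt link %s: r=%.3f t=%.2f p=%.4f", pairing, r, t, p)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as f:
            json.dump(report, f, indent=2, default=float)
        bundle.write_truth(out_dir / "truth.json")
    return report
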