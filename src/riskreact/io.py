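"""Delimited-text I/O for behavioral data and covariates.

Choice tables follow the task-design schema plus ``subject`` and ``accept``
columns; probe tables carry the probed/non-probed contrasts and the
response time.  Readers validate required columns and row-level constraints
and report offending row numbers.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .models import ChoiceObservation
from .rtprobe import ProbeTrial
from .task import design_to_frame, frame_to_trials

log = logging.getLogger("riskreact")

__all__ = [
    "write_choices",
    "read_choices",
    "write_probes",
    "read_probes",
    "read_covariate",
]

CHOICE_REQUIRED = [
    "subject", "block", "frame", "prob_stim", "trigger",
    "r_O1", "r_O2", "r_OS", "is_catch", "accept",
    "base_trigger_points", "base_safe_points",
    "common_noise", "item_noise_O1", "item_noise_O2", "item_noise_OS",
]
PROBE_REQUIRED = [
    "subject", "probed_stimulus", "p_probed", "p_nonprobed",
    "abs_r_probed", "abs_r_nonprobed", "rt",
]


class SchemaError(ValueError):
    pass


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def write_choices(cohort: dict[int, list[ChoiceObservation]], path) -> None:
    """Write a per-subject choice cohort as one delimited table."""
    frames = []
    for subject, observations in cohort.items():
        from .task import TaskDesign

        design = TaskDesign(
            trials=[o.trial for o in observations], seed=-1, variant="meg"
        )
        df = design_to_frame(design)
        df.insert(0, "subject", subject)
        df["accept"] = [o.accept for o in observations]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_choices(path) -> dict[int, list[ChoiceObservation]]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""],
                     dtype={"prob_stim": str})
    _require(df, CHOICE_REQUIRED, path)
    bad = df.index[~df["accept"].isin([0, 1])]
    if len(bad):
        raise SchemaError(f"{path}: accept must be 0/1 (first bad row {bad[0] + 2})")
    out: dict[int, list[ChoiceObservation]] = {}
    for subject, sub in df.groupby("subject", sort=True):
        trials = frame_to_trials(sub)
        out[int(subject)] = [
            ChoiceObservation(trial=t, accept=int(a))
            for t, a in zip(trials, sub["accept"])
            if not t.is_catch
        ]
    return out


def write_probes(trials: list[ProbeTrial], path) -> None:
    pd.DataFrame(
        [
            {
                "subject": t.subject,
                "probed_stimulus": t.probed_stimulus,
                "p_probed": t.p_probed,
                "p_nonprobed": t.p_nonprobed,
                "abs_r_probed": t.abs_r_probed,
                "abs_r_nonprobed": t.abs_r_nonprobed,
                "rt": t.rt,
            }
            for t in trials
        ]
    ).to_csv(path, sep="\t", index=False)


def read_probes(path) -> list[ProbeTrial]:
    """Read probe trials; rows with non-positive RT are rejected with a warning."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require(df, PROBE_REQUIRED, path)
    out = []
    n_rejected = 0
    for i, row in df.iterrows():
        if not row["rt"] > 0:
            n_rejected += 1
            log.warning("%s: row %d rejected (rt <= 0)", path, i + 2)
            continue
        out.append(
            ProbeTrial(
                subject=int(row["subject"]),
                probed_stimulus=str(row["probed_stimulus"]),
                p_probed=float(row["p_probed"]) if pd.notna(row["p_probed"]) else np.nan,
                p_nonprobed=float(row["p_nonprobed"]) if pd.notna(row["p_nonprobed"]) else np.nan,
                abs_r_probed=float(row["abs_r_probed"]),
                abs_r_nonprobed=float(row["abs_r_nonprobed"]) if pd.notna(row["abs_r_nonprobed"]) else np.nan,
                rt=float(row["rt"]),
            )
        )
    if n_rejected:
        warnings.warn(f"{path}: rejected {n_rejected} probe rows with rt <= 0")
    return out


def read_covariate(path, column: str = "value") -> pd.Series:
    """Read a per-subject covariate table (columns: subject, <column>)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require(df, ["subject", column], path)
    return df.set_index("subject")[column]
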