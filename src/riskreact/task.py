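"""Risky-decision task structure: trials, blocks, rewards, probability stimuli.

The task presents a gamble that can be accepted (leading to one of two gamble
outcomes, O1 or O2, with probabilities signalled by a pretrained probability
stimulus) or rejected (leading to a safe outcome OS).  On each trial one gamble
outcome -- the *trigger* -- carries a large absolute point value while the
other gamble outcome carries points near zero; the safe value lies in between.
Blocks alternate between gain and loss framing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ProbabilityStimulus",
    "TrialSpec",
    "TaskDesign",
    "PROBABILITY_STIMULI",
    "REWARD_PRESETS",
    "generate_task",
    "baseline_correct",
    "write_design",
    "read_design",
]

#: the four pretrained cues and their implied p(O1)
PROBABILITY_STIMULI = {"P1": 0.2, "P2": 0.4, "P3": 0.6, "P4": 0.8}

#: named reward-level presets.  "balanced" is the default: it is the unique
#: 3x3 product grid of trigger x safe levels from the printed figure values in
#: which every pair satisfies |trigger| > |safe|, which is required for the
#: fully balanced 288-trial construction.  "methods" uses the alternative
#: printed levels; it admits only 7 valid pairs and yields a smaller,
#: still-balanced design (flagged in metadata).
REWARD_PRESETS = {
    "balanced": {"trigger": (45.0, 65.0, 75.0), "safe": (20.0, 32.0, 44.0)},
    "methods": {"trigger": (47.5, 60.0, 75.0), "safe": (20.0, 40.0, 60.0, 80.0)},
}

COMMON_NOISE_RANGE = 20.0  # uniform(0, 20), negated on loss frames
ITEM_NOISE_RANGE = 5.0  # uniform(0, 5) per outcome, negated on loss frames
CATCH_FRACTION = 0.10  # catch trials as a fraction of all presented trials

N_BLOCKS = 8
VARIANTS = ("meg", "online")


@dataclass(frozen=True)
class ProbabilityStimulus:
    """One of the four pretrained probability cues."""

    id: str  # P1..P4
    p_O1: float

    @property
    def p_O2(self) -> float:
        return 1.0 - self.p_O1


@dataclass
class TrialSpec:
    """A single gamble trial.

    ``r_x = base_x + common_noise + item_noise_x`` for each outcome; the
    non-trigger gamble outcome has base 0, so its realized points are pure
    noise.
    """

    block_index: int
    frame: str  # "gain" | "loss"
    prob_stim: Optional[ProbabilityStimulus]  # None on catch trials
    trigger: str  # "O1" | "O2"
    base_trigger_points: float
    base_safe_points: float
    common_noise: float
    item_noise_O1: float
    item_noise_O2: float
    item_noise_OS: float
    r_O1: float = field(init=False)
    r_O2: float = field(init=False)
    r_OS: float = field(init=False)
    is_catch: bool = False

    def __post_init__(self) -> None:
        base_O1 = self.base_trigger_points if self.trigger == "O1" else 0.0
        base_O2 = self.base_trigger_points if self.trigger == "O2" else 0.0
        self.r_O1 = base_O1 + self.common_noise + self.item_noise_O1
        self.r_O2 = base_O2 + self.common_noise + self.item_noise_O2
        self.r_OS = self.base_safe_points + self.common_noise + self.item_noise_OS

    @property
    def p_O1(self) -> float:
        if self.prob_stim is None:
            raise ValueError("catch trial has no probability stimulus")
        return self.prob_stim.p_O1

    @property
    def p_O2(self) -> float:
        return 1.0 - self.p_O1

    @property
    def r_trigger(self) -> float:
        return self.r_O1 if self.trigger == "O1" else self.r_O2

    @property
    def r_nontrigger(self) -> float:
        return self.r_O2 if self.trigger == "O1" else self.r_O1


@dataclass
class TaskDesign:
    trials: list  # list[TrialSpec]
    seed: int
    variant: str
    metadata: dict = field(default_factory=dict)

    @property
    def decision_trials(self) -> list:
        return [t for t in self.trials if not t.is_catch]

    def __len__(self) -> int:
        return len(self.trials)


def baseline_correct(trial: TrialSpec) -> tuple[float, float]:
    """Subtract the non-trigger outcome's realized reward from all rewards.

    Returns ``(r*_trigger, r*_safe)``; the non-trigger outcome's corrected
    reward is exactly 0 by construction.
    """
    if trial.is_catch:
        raise ValueError("baseline_correct is undefined for catch trials")
    base = trial.r_nontrigger
    return trial.r_trigger - base, trial.r_OS - base


def _valid_pairs(trigger_levels, safe_levels) -> list[tuple[float, float]]:
    return [
        (t, s) for t in trigger_levels for s in safe_levels if abs(t) > abs(s)
    ]


def _make_frame_trials(
    frame: str,
    block_indices: list[int],
    pairs: list[tuple[float, float]],
    rng: np.random.Generator,
) -> list[TrialSpec]:
    """All decision trials for one frame, dealt into its four blocks.

    Each (trigger level, safe level, trigger assignment, probability stimulus)
    configuration appears exactly twice in the task; within each probability
    stimulus the trials are dealt evenly across the frame's blocks so each
    stimulus appears equally often per block.
    """
    sign = 1.0 if frame == "gain" else -1.0
    trials: list[TrialSpec] = []
    per_block: dict[int, list[TrialSpec]] = {b: [] for b in block_indices}
    for stim_id, p1 in PROBABILITY_STIMULI.items():
        configs = []
        for trig_level, safe_level in pairs:
            for assignment in ("O1", "O2"):
                for _repeat in range(2):
                    configs.append((trig_level, safe_level, assignment))
        order = rng.permutation(len(configs))
        n_per_block = len(configs) // len(block_indices)
        for slot, idx in enumerate(order):
            trig_level, safe_level, assignment = configs[idx]
            block = block_indices[slot // n_per_block]
            common = sign * rng.uniform(0.0, COMMON_NOISE_RANGE)
            item = sign * rng.uniform(0.0, ITEM_NOISE_RANGE, size=3)
            per_block[block].append(
                TrialSpec(
                    block_index=block,
                    frame=frame,
                    prob_stim=ProbabilityStimulus(stim_id, p1),
                    trigger=assignment,
                    base_trigger_points=sign * trig_level,
                    base_safe_points=sign * safe_level,
                    common_noise=common,
                    item_noise_O1=item[0],
                    item_noise_O2=item[1],
                    item_noise_OS=item[2],
                )
            )
    for block in block_indices:
        trials.extend(per_block[block])
    return trials


def _make_catch_trials(
    n_catch: int,
    block_cycle: list[tuple[int, str]],
    pairs_by_frame: dict[str, list[tuple[float, float]]],
    rng: np.random.Generator,
) -> list[TrialSpec]:
    trials = []
    for k in range(n_catch):
        block, frame = block_cycle[k % len(block_cycle)]
        sign = 1.0 if frame == "gain" else -1.0
        pairs = pairs_by_frame[frame]
        trig_level, safe_level = pairs[rng.integers(len(pairs))]
        trials.append(
            TrialSpec(
                block_index=block,
                frame=frame,
                prob_stim=None,
                trigger=("O1", "O2")[rng.integers(2)],
                base_trigger_points=sign * trig_level,
                base_safe_points=sign * safe_level,
                common_noise=sign * rng.uniform(0.0, COMMON_NOISE_RANGE),
                item_noise_O1=sign * rng.uniform(0.0, ITEM_NOISE_RANGE),
                item_noise_O2=sign * rng.uniform(0.0, ITEM_NOISE_RANGE),
                item_noise_OS=sign * rng.uniform(0.0, ITEM_NOISE_RANGE),
                is_catch=True,
            )
        )
    return trials


def generate_task(
    seed: int, variant: str = "meg", reward_preset: str = "balanced"
) -> TaskDesign:
    """Generate a complete task design.

    Eight blocks alternate gain/loss (four of each).  Decision trials cross
    every valid (trigger level, safe level) pair with both trigger
    assignments and all four probability stimuli, each exact configuration
    twice.  Catch trials (no probability stimulus) are added on top, at 10%
    of presented trials, and are excluded from the decision-trial count.
    Identical seeds give identical designs.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    preset = REWARD_PRESETS[reward_preset]
    rng = np.random.default_rng(seed)

    frames = ["gain" if b % 2 == 1 else "loss" for b in range(1, N_BLOCKS + 1)]
    pairs = _valid_pairs(preset["trigger"], preset["safe"])
    pairs_by_frame = {"gain": pairs, "loss": pairs}

    trials: list[TrialSpec] = []
    for frame in ("gain", "loss"):
        block_indices = [b for b in range(1, N_BLOCKS + 1) if frames[b - 1] == frame]
        trials.extend(_make_frame_trials(frame, block_indices, pairs, rng))

    n_decision = len(trials)
    n_catch = int(round(n_decision * CATCH_FRACTION / (1.0 - CATCH_FRACTION)))
    block_cycle = [(b, frames[b - 1]) for b in range(1, N_BLOCKS + 1)]
    trials.extend(_make_catch_trials(n_catch, block_cycle, pairs_by_frame, rng))

    # uniform random order within each block
    by_block: dict[int, list[TrialSpec]] = {b: [] for b in range(1, N_BLOCKS + 1)}
    for t in trials:
        by_block[t.block_index].append(t)
    ordered: list[TrialSpec] = []
    for b in range(1, N_BLOCKS + 1):
        block_trials = by_block[b]
        for idx in rng.permutation(len(block_trials)):
            ordered.append(block_trials[idx])

    fully_balanced = len({p[0] for p in pairs}) * len({p[1] for p in pairs}) == len(pairs)
    metadata = {
        "reward_preset": reward_preset,
        "trigger_levels": list(preset["trigger"]),
        "safe_levels": list(preset["safe"]),
        "grid_pairs": [list(p) for p in pairs],
        "fully_crossed_grid": fully_balanced,
        "n_decision_trials": n_decision,
        "n_catch_trials": n_catch,
        "seed": seed,
        "variant": variant,
    }
    return TaskDesign(trials=ordered, seed=seed, variant=variant, metadata=metadata)


# ---------------------------------------------------------------------------
# serialization

_COLUMNS = [
    "block", "frame", "prob_stim", "p_O1", "trigger",
    "r_O1", "r_O2", "r_OS", "is_catch",
    "base_trigger_points", "base_safe_points",
    "common_noise", "item_noise_O1", "item_noise_O2", "item_noise_OS",
]


def design_to_frame(design: TaskDesign) -> pd.DataFrame:
    rows = []
    for t in design.trials:
        rows.append({
            "block": t.block_index,
            "frame": t.frame,
            "prob_stim": t.prob_stim.id if t.prob_stim else "",
            "p_O1": t.prob_stim.p_O1 if t.prob_stim else np.nan,
            "trigger": t.trigger,
            "r_O1": t.r_O1,
            "r_O2": t.r_O2,
            "r_OS": t.r_OS,
            "is_catch": int(t.is_catch),
            "base_trigger_points": t.base_trigger_points,
            "base_safe_points": t.base_safe_points,
            "common_noise": t.common_noise,
            "item_noise_O1": t.item_noise_O1,
            "item_noise_O2": t.item_noise_O2,
            "item_noise_OS": t.item_noise_OS,
        })
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialSpec]:
    trials = []
    for _, row in df.iterrows():
        stim = None
        if isinstance(row["prob_stim"], str) and row["prob_stim"]:
            stim = ProbabilityStimulus(row["prob_stim"], PROBABILITY_STIMULI[row["prob_stim"]])
        trials.append(
            TrialSpec(
                block_index=int(row["block"]),
                frame=row["frame"],
                prob_stim=stim,
                trigger=row["trigger"],
                base_trigger_points=float(row["base_trigger_points"]),
                base_safe_points=float(row["base_safe_points"]),
                common_noise=float(row["common_noise"]),
                item_noise_O1=float(row["item_noise_O1"]),
                item_noise_O2=float(row["item_noise_O2"]),
                item_noise_OS=float(row["item_noise_OS"]),
                is_catch=bool(row["is_catch"]),
            )
        )
    return trials


def write_design(design: TaskDesign, path: str | Path) -> None:
    """Write a design as a TSV plus a JSON metadata sidecar."""
    path = Path(path)
    design_to_frame(design).to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(design.metadata, indent=2))


def read_design(path: str | Path) -> TaskDesign:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     na_values=[""], dtype={"prob_stim": str})
    sidecar = path.with_suffix(path.suffix + ".json")
    metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return TaskDesign(
        trials=frame_to_trials(df),
        seed=int(metadata.get("seed", -1)),
        variant=metadata.get("variant", "meg"),
        metadata=metadata,
    )
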