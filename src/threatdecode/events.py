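"""Trial schedules for the two-day conditioning/extinction/recall paradigm.

Every trial presents a context image for 3 s, then the CS for 6 s. On a
reinforced CS+ trial the shock fills the last 0.5 s of the CS. Inter-trial
intervals are uniform on [12, 18] s (mean 15 s). Trial order is pseudorandom
with at most three consecutive trials of the same CS category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conditions import CS_MINUS, CS_PLUS, CS_PLUS_E, CS_PLUS_U, PHASES, Condition

CONTEXT_LEAD_S = 3.0
CS_DURATION_S = 6.0
SHOCK_DURATION_S = 0.5
ITI_RANGE_S = (12.0, 18.0)
REINFORCED_PER_CUE = 5  # 5 of 8 CS+ trials per cue -> 62.5% reinforcement
MAX_CONSECUTIVE = 3
TRIALS_PER_BLOCK_PER_CS = 4


@dataclass(frozen=True)
class Trial:
    index: int
    cs_type: str              # pooled CS category (CSplus / CSplusE / CSplusU / CSminus)
    cue: str                  # distinct physical cue, e.g. CSplus-a / CSplus-b
    context_onset_s: float
    cs_onset_s: float
    cs_duration_s: float
    reinforced: bool
    shock_onset_s: float | None
    iti_s: float


@dataclass
class EventSchedule:
    """Ordered trial table for one experimental phase."""

    phase: str
    trials: list[Trial] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def duration_s(self) -> float:
        """Time from run start to the end of the last trial's ITI."""
        last = self.trials[-1]
        return last.cs_onset_s + last.cs_duration_s + last.iti_s

    def to_events_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type)."""
        rows = []
        for t in self.trials:
            rows.append((t.context_onset_s, CONTEXT_LEAD_S, "context"))
            rows.append((t.cs_onset_s, t.cs_duration_s, t.cs_type))
            if t.reinforced:
                rows.append((t.shock_onset_s, SHOCK_DURATION_S, "shock"))
        return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])

    def save_events_tsv(self, path) -> None:
        self.to_events_frame().to_csv(path, sep="\t", index=False)

    def block_assignments(self, pool_csplus: bool = True) -> list[tuple[Condition, list[int]]]:
        """Partition trials into trial-block conditions.

        Trials of each CS category are chunked, in presentation order, into
        consecutive groups. CS+ categories use 4 trials per block. The CS-
        trials of conditioning and extinction also chunk by 4 (4 blocks);
        the 16 recall CS- trials chunk by 8 into 2 blocks, each shared by the
        CS+E and CS+U contrast of the same trial-block index.

        With ``pool_csplus=False`` the two conditioning CS+ cues are kept as
        separate conditions (labeled by cue) instead of one pooled CS+.
        """
        by_cs: dict[str, list[int]] = {}
        for t in self.trials:
            key = t.cs_type
            if not pool_csplus and self.phase == "conditioning" and t.cs_type == CS_PLUS:
                key = t.cue
            by_cs.setdefault(key, []).append(t.index)
        out: list[tuple[Condition, list[int]]] = []
        for cs, idx in by_cs.items():
            per = 8 if (self.phase == "recall" and cs == CS_MINUS) else TRIALS_PER_BLOCK_PER_CS
            for b, start in enumerate(range(0, len(idx), per), start=1):
                out.append((Condition(self.phase, b, cs), idx[start:start + per]))
        out.sort(key=lambda pair: pair[0])
        return out

    def validate(self) -> None:
        counts: dict[str, int] = {}
        for i, t in enumerate(self.trials):
            if t.index != i:
                raise ValueError("trial indices must be consecutive from 0")
            if abs(t.cs_onset_s - t.context_onset_s - CONTEXT_LEAD_S) > 1e-9:
                raise ValueError("context must precede CS by exactly 3 s")
            if t.cs_duration_s != CS_DURATION_S:
                raise ValueError("CS duration must be 6 s")
            if not (ITI_RANGE_S[0] <= t.iti_s <= ITI_RANGE_S[1]):
                raise ValueError("ITI outside [12, 18] s")
            if t.reinforced:
                expected = t.cs_onset_s + CS_DURATION_S - SHOCK_DURATION_S
                if abs(t.shock_onset_s - expected) > 1e-9:
                    raise ValueError("shock must start 0.5 s before CS offset")
            elif t.shock_onset_s is not None:
                raise ValueError("unreinforced trial cannot carry a shock onset")
            counts[t.cs_type] = counts.get(t.cs_type, 0) + 1
        expected_counts = {
            "conditioning": {CS_PLUS: 16, CS_MINUS: 16},
            "extinction": {CS_PLUS: 16, CS_MINUS: 16},
            "recall": {CS_PLUS_E: 8, CS_PLUS_U: 8, CS_MINUS: 16},
        }[self.phase]
        if counts != expected_counts:
            raise ValueError(f"trial counts {counts} != paradigm table {expected_counts}")


def _pseudorandom_order(categories: list[str], rng: np.random.Generator) -> list[int]:
    """Uniform shuffle rejected until no CS category repeats > 3 times in a row."""
    n = len(categories)
    while True:
        perm = rng.permutation(n)
        run, ok = 1, True
        for a, b in zip(perm[:-1], perm[1:]):
            run = run + 1 if categories[a] == categories[b] else 1
            if run > MAX_CONSECUTIVE:
                ok = False
                break
        if ok:
            return list(perm)


def generate_event_schedule(phase: str, seed: int) -> EventSchedule:
    """Generate one phase's pseudorandom trial schedule.

    Conditioning: 8 trials of each of two CS+ cues (5 reinforced per cue,
    chosen uniformly) and 16 CS-. Extinction: 16 CS+ / 16 CS-, none
    reinforced. Recall: 8 CS+E, 8 CS+U, 16 CS-, none reinforced.
    Deterministic for a fixed seed.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    rng = np.random.default_rng(seed)

    if phase == "conditioning":
        cues = [(CS_PLUS, "CSplus-a")] * 8 + [(CS_PLUS, "CSplus-b")] * 8
        cues += [(CS_MINUS, "CSminus")] * 16
    elif phase == "extinction":
        cues = [(CS_PLUS, "CSplus-a")] * 16 + [(CS_MINUS, "CSminus")] * 16
    else:
        cues = [(CS_PLUS_E, "CSplus-a")] * 8 + [(CS_PLUS_U, "CSplus-b")] * 8
        cues += [(CS_MINUS, "CSminus")] * 16

    order = _pseudorandom_order([c[0] for c in cues], rng)
    ordered = [cues[i] for i in order]

    reinforced = [False] * len(ordered)
    if phase == "conditioning":
        for cue in ("CSplus-a", "CSplus-b"):
            slots = [i for i, (_, c) in enumerate(ordered) if c == cue]
            for i in rng.choice(slots, size=REINFORCED_PER_CUE, replace=False):
                reinforced[i] = True

    trials, t0 = [], 0.0
    for i, ((cs, cue), hit) in enumerate(zip(ordered, reinforced)):
        cs_onset = t0 + CONTEXT_LEAD_S
        iti = rng.uniform(*ITI_RANGE_S)
        trials.append(
            Trial(
                index=i,
                cs_type=cs,
                cue=cue,
                context_onset_s=t0,
                cs_onset_s=cs_onset,
                cs_duration_s=CS_DURATION_S,
                reinforced=hit,
                shock_onset_s=cs_onset + CS_DURATION_S - SHOCK_DURATION_S if hit else None,
                iti_s=iti,
            )
        )
        t0 = cs_onset + CS_DURATION_S + iti

    sched = EventSchedule(phase=phase, trials=trials)
    sched.validate()
    return sched
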