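"""Labels for experimental phases, CS conditions, trial-blocks, and decoding contrasts.

The two-day paradigm has three phases. Day 1: threat conditioning (two CS+
cues paired with shock at a 62.5% reinforcement rate, one CS- never paired)
followed by extinction learning (one CS+ and the CS- presented without
shock). Day 2: extinction memory recall (extinguished CS+E, unextinguished
CS+U, and CS-, all without shock). Each phase splits into trial-blocks (TB)
of 8 trials, 4 per CS type in a given contrast, and every trial-block is
decoded separately.
"""

from __future__ import annotations

from dataclasses import dataclass

PHASES = ("conditioning", "extinction", "recall")

CS_PLUS = "CSplus"
CS_PLUS_E = "CSplusE"
CS_PLUS_U = "CSplusU"
CS_MINUS = "CSminus"

#: CS types whose maps carry the positive (threat) class in forced choice.
POSITIVE_CS = frozenset({CS_PLUS, CS_PLUS_E, CS_PLUS_U})


@dataclass(frozen=True, order=True)
class Condition:
    """One (phase, trial-block, CS type) cell of the activation-map grid."""

    phase: str
    block: int
    cs: str

    @property
    def label(self) -> str:
        return f"{self.phase}/TB{self.block}/{self.cs}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        phase, tb, cs = label.split("/")
        return cls(phase, int(tb[2:]), cs)


@dataclass(frozen=True, order=True)
class Contrast:
    """A decoded CS+ vs CS- pairing within one trial-block."""

    phase: str
    block: int
    cs_pos: str
    cs_neg: str = CS_MINUS

    @property
    def label(self) -> str:
        return f"{self.phase}/TB{self.block}/{self.cs_pos}-vs-{self.cs_neg}"

    @property
    def positive(self) -> Condition:
        return Condition(self.phase, self.block, self.cs_pos)

    @property
    def negative(self) -> Condition:
        return Condition(self.phase, self.block, self.cs_neg)

    @classmethod
    def from_label(cls, label: str) -> "Contrast":
        phase, tb, pair = label.split("/")
        pos, neg = pair.split("-vs-")
        return cls(phase, int(tb[2:]), pos, neg)


def _build_contrasts() -> tuple[Contrast, ...]:
    out = [Contrast("conditioning", b, CS_PLUS) for b in range(1, 5)]
    out += [Contrast("extinction", b, CS_PLUS) for b in range(1, 5)]
    for b in (1, 2):
        out.append(Contrast("recall", b, CS_PLUS_E))
        out.append(Contrast("recall", b, CS_PLUS_U))
    return tuple(out)


#: Every decoded trial-block across the two-day experiment (12 contrasts).
ALL_CONTRASTS: tuple[Contrast, ...] = _build_contrasts()

#: The 7 trial-blocks with robust decoding in discovery *and* both validation
#: cohorts: all conditioning blocks, the first extinction block, and the first
#: recall block for both the extinguished and unextinguished CS+. These score
#: the extended-circuit voxel selection and the community assignment.
ROBUST_CONTRASTS: tuple[Contrast, ...] = (
    Contrast("conditioning", 1, CS_PLUS),
    Contrast("conditioning", 2, CS_PLUS),
    Contrast("conditioning", 3, CS_PLUS),
    Contrast("conditioning", 4, CS_PLUS),
    Contrast("extinction", 1, CS_PLUS),
    Contrast("recall", 1, CS_PLUS_E),
    Contrast("recall", 1, CS_PLUS_U),
)


def all_conditions() -> tuple[Condition, ...]:
    """The full condition grid implied by ``ALL_CONTRASTS`` (22 cells).

    Recall CS- blocks are shared between the CS+E and CS+U contrasts of the
    same trial-block, so they appear once.
    """
    seen: dict[Condition, None] = {}
    for con in ALL_CONTRASTS:
        seen.setdefault(con.positive)
        seen.setdefault(con.negative)
    return tuple(seen)


COMMUNITY_CSPLUS = "consistent_CSplus"
COMMUNITY_CSMINUS = "consistent_CSminus"
COMMUNITY_FLEXIBLE = "flexible"
COMMUNITIES = (COMMUNITY_CSPLUS, COMMUNITY_CSMINUS, COMMUNITY_FLEXIBLE)
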