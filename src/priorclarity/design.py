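"""Trial-schedule generators for the written-cue / vocoded-word paradigm.

Three schedules are produced:

* **Experiment 1** (in-scanner): a fully crossed 2 (cue congruency:
  match/mismatch) x 3 (vocoder channels: 4/8/16) design, 108 trials per
  condition spread over six blocks of 108 trials (18 per cell per block).
  A written cue is followed 1050 (+/-50) ms later by a vocoded spoken word,
  and a clarity probe 1050 (+/-50) ms after that.
* **Experiment 2** (identification): 90 four-alternative forced-choice
  trials in one block, 30 response sets each presented three times, with
  the number of phonological neighbours in the response array manipulated.
* **Neutral replication**: Experiment 1 repeated outside the scanner with
  an additional uninformative-cue condition, 18 trials per cell in a
  single block.

Key word-reuse constraints for Experiment 1: each spoken word occurs at
most twice per participant, and at most once under each congruency level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CHANNEL_LEVELS: tuple[int, ...] = (4, 8, 16)
CONGRUENCY_LEVELS: tuple[str, ...] = ("match", "mismatch")
NEUTRAL_CUE_TOKEN = "<UNINFORMATIVE>"

CUE_TO_SPEECH_MS = 1050.0
SPEECH_TO_PROBE_MS = 1050.0
JITTER_MS = 50.0

EXP1_TRIALS_PER_CONDITION = 108
EXP1_N_BLOCKS = 6
EXP2_N_SETS = 30
EXP2_N_TRIALS = 90
REPLICATION_TRIALS_PER_CONDITION = 18


class ScheduleConstraintError(ValueError):
    """Raised when a word pool or response-set list cannot satisfy the design."""


@dataclass(frozen=True)
class Condition:
    """A congruency x sensory-detail cell of the factorial design."""

    congruency: str
    channels: int
    allow_neutral: bool = False

    def __post_init__(self) -> None:
        allowed = CONGRUENCY_LEVELS + (("neutral",) if self.allow_neutral else ())
        if self.congruency not in allowed:
            raise ValueError(f"congruency must be one of {allowed}, got {self.congruency!r}")
        if self.channels not in CHANNEL_LEVELS:
            raise ValueError(f"channels must be in {CHANNEL_LEVELS}, got {self.channels}")


@dataclass(frozen=True)
class Exp1Trial:
    block: int
    condition: Condition
    written_word: str
    spoken_word: str
    cue_onset_to_speech_ms: float
    speech_onset_to_probe_ms: float
    cue_is_informative: bool = True

    def __post_init__(self) -> None:
        if self.condition.congruency == "match" and self.written_word != self.spoken_word:
            raise ValueError("match trial requires written_word == spoken_word")
        if self.condition.congruency == "mismatch" and self.written_word == self.spoken_word:
            raise ValueError("mismatch trial requires distinct written and spoken words")
        for v in (self.cue_onset_to_speech_ms, self.speech_onset_to_probe_ms):
            if abs(v - CUE_TO_SPEECH_MS) > JITTER_MS + 1e-9:
                raise ValueError(f"interval {v} ms outside 1050 +/- 50 ms")


@dataclass
class Exp1Schedule:
    trials: list[Exp1Trial]
    order_label: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": [t.block for t in self.trials],
                "congruency": [t.condition.congruency for t in self.trials],
                "channels": [t.condition.channels for t in self.trials],
                "written_word": [t.written_word for t in self.trials],
                "spoken_word": [t.spoken_word for t in self.trials],
                "cue_onset_to_speech_ms": [t.cue_onset_to_speech_ms for t in self.trials],
                "speech_onset_to_probe_ms": [t.speech_onset_to_probe_ms for t in self.trials],
                "cue_is_informative": [t.cue_is_informative for t in self.trials],
                "order_label": self.order_label,
            }
        )

    def summary(self) -> dict:
        """Realised tallies: condition-cell counts and spoken-word reuse."""
        df = self.to_frame()
        cell_counts = (
            df.groupby(["congruency", "channels"]).size().rename("n").reset_index()
        )
        spoken_counts = df["spoken_word"].value_counts()
        return {
            "n_trials": len(df),
            "n_blocks": int(df["block"].nunique()),
            "order_label": self.order_label,
            "cell_counts": {
                f"{r.congruency}/{r.channels}": int(r.n) for r in cell_counts.itertuples()
            },
            "words_used_twice_spoken": int((spoken_counts == 2).sum()),
            "words_used_once_spoken": int((spoken_counts == 1).sum()),
        }


@dataclass(frozen=True)
class ResponseSet:
    """A 4AFC response array built around a target and its phonological neighbours."""

    set_id: str
    target: str
    offset_neighbour: str
    onset_neighbour: str
    unrelated: str

    def __post_init__(self) -> None:
        members = (self.target, self.offset_neighbour, self.onset_neighbour, self.unrelated)
        if len(set(members)) != 4:
            raise ValueError("response set requires four distinct members")

    def members(self) -> tuple[str, str, str, str]:
        return (self.target, self.offset_neighbour, self.onset_neighbour, self.unrelated)

    def spoken_word_for_case(self, case_label: int) -> str:
        return {
            1: self.target,
            2: self.offset_neighbour,
            3: self.onset_neighbour,
            4: self.unrelated,
        }[case_label]


CASE_N_NEIGHBOURS = {1: 2, 2: 1, 3: 1, 4: 0}

# Fixed difficulty template per sensory-detail level: counts (10, 5, 5, 10)
# for cases (1, 2, 3, 4), interleaved so no case is blocked at one end.
_EXP2_CASE_TEMPLATE: tuple[int, ...] = (1, 4, 2, 1, 4, 3) * 5


@dataclass(frozen=True)
class Exp2Trial:
    channels: int
    response_set: ResponseSet
    spoken_word: str
    n_neighbours_in_array: int
    case_label: int

    def __post_init__(self) -> None:
        if self.channels not in CHANNEL_LEVELS:
            raise ValueError(f"channels must be in {CHANNEL_LEVELS}")
        if self.case_label not in CASE_N_NEIGHBOURS:
            raise ValueError("case_label must be 1..4")
        if self.n_neighbours_in_array != CASE_N_NEIGHBOURS[self.case_label]:
            raise ValueError("n_neighbours inconsistent with case_label")
        if self.spoken_word != self.response_set.spoken_word_for_case(self.case_label):
            raise ValueError("spoken_word inconsistent with case_label")


def default_word_pool(n: int = 400, prefix: str = "word") -> list[str]:
    """Synthetic word identifiers; phonology is represented only by identity."""
    width = len(str(n - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def default_response_sets(n: int = EXP2_N_SETS) -> list[ResponseSet]:
    sets = []
    for i in range(n):
        sets.append(
            ResponseSet(
                set_id=f"set{i:02d}",
                target=f"tgt{i:02d}",
                offset_neighbour=f"off{i:02d}",
                onset_neighbour=f"ons{i:02d}",
                unrelated=f"unr{i:02d}",
            )
        )
    return sets


def _jitter(rng: np.random.Generator) -> float:
    return float(CUE_TO_SPEECH_MS + rng.uniform(-JITTER_MS, JITTER_MS))


def build_exp1_schedule(
    word_pool: Sequence[str], order_label: str, seed: int
) -> Exp1Schedule:
    """Build the six-block Experiment 1 schedule.

    Each of the 324 spoken words selected from the pool is heard exactly
    twice: once with a congruent written cue and once with an incongruent
    one, never twice under the same congruency.  Channel levels are
    balanced so every congruency x channels cell totals 108 trials, 18 per
    block.  ``order_label`` ('A' or 'B') selects one of two fixed
    seed-derived trial orders.
    """
    if order_label not in ("A", "B"):
        raise ValueError("order_label must be 'A' or 'B'")
    n_words_needed = EXP1_TRIALS_PER_CONDITION * len(CHANNEL_LEVELS)  # 324
    pool = list(dict.fromkeys(word_pool))
    if len(pool) < n_words_needed:
        raise ScheduleConstraintError(
            f"word pool of {len(pool)} distinct words cannot supply {n_words_needed} "
            "spoken words each heard once per congruency level"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    words = [pool[i] for i in rng.permutation(len(pool))[:n_words_needed]]

    # Channel assignment per congruency: 108 words per level, independently
    # permuted so a word's match and mismatch presentations vary in detail.
    per_level = EXP1_TRIALS_PER_CONDITION
    base_levels = np.repeat(CHANNEL_LEVELS, per_level)
    match_channels = base_levels[rng.permutation(n_words_needed)]
    mismatch_channels = base_levels[rng.permutation(n_words_needed)]

    # Mismatch written cues: a derangement of the spoken words so written
    # and spoken identities never coincide.
    shift = int(rng.integers(1, n_words_needed))
    mismatch_written = [words[(i + shift) % n_words_needed] for i in range(n_words_needed)]

    trials_by_cell: dict[tuple[str, int], list[Exp1Trial]] = {
        (cong, ch): [] for cong in CONGRUENCY_LEVELS for ch in CHANNEL_LEVELS
    }
    for i, w in enumerate(words):
        trials_by_cell[("match", int(match_channels[i]))].append(
            Exp1Trial(0, Condition("match", int(match_channels[i])), w, w,
                      _jitter(rng), _jitter(rng))
        )
        trials_by_cell[("mismatch", int(mismatch_channels[i]))].append(
            Exp1Trial(0, Condition("mismatch", int(mismatch_channels[i])),
                      mismatch_written[i], w, _jitter(rng), _jitter(rng))
        )

    # Distribute each cell's 108 trials as 18 per block, then apply one of
    # the two fixed within-block orders.
    per_block = EXP1_TRIALS_PER_CONDITION // EXP1_N_BLOCKS
    blocks: list[list[Exp1Trial]] = [[] for _ in range(EXP1_N_BLOCKS)]
    for cell, cell_trials in trials_by_cell.items():
        order = rng.permutation(len(cell_trials))
        for b in range(EXP1_N_BLOCKS):
            for j in order[b * per_block : (b + 1) * per_block]:
                t = cell_trials[j]
                blocks[b].append(
                    Exp1Trial(b + 1, t.condition, t.written_word, t.spoken_word,
                              t.cue_onset_to_speech_ms, t.speech_onset_to_probe_ms)
                )

    order_rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), 2, 0 if order_label == "A" else 1])
    )
    trials: list[Exp1Trial] = []
    for b in range(EXP1_N_BLOCKS):
        perm = order_rng.permutation(len(blocks[b]))
        trials.extend(blocks[b][j] for j in perm)
    return Exp1Schedule(trials=trials, order_label=order_label)


def build_exp2_schedule(response_sets: Sequence[ResponseSet], seed: int) -> list[Exp2Trial]:
    """Build the 90-trial 4AFC identification schedule.

    Every response set is presented once per channel level (three times in
    total, so three of its four members are heard).  Each set contributes
    its 2-neighbour target case and 0-neighbour unrelated case plus one of
    the two 1-neighbour cases; case-to-level allocation is balanced by
    cyclic rotation so each level realises case counts (10, 5, 5, 10).
    The (channels, difficulty) slot sequence is fixed; the seed randomises
    only which set occupies each slot.
    """
    sets = list(response_sets)
    if len(sets) != EXP2_N_SETS:
        raise ScheduleConstraintError(
            f"exactly {EXP2_N_SETS} response sets required, got {len(sets)}"
        )
    if len({s.set_id for s in sets}) != EXP2_N_SETS:
        raise ScheduleConstraintError("response set ids must be distinct")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))

    shuffled = [sets[i] for i in rng.permutation(EXP2_N_SETS)]
    halves = (shuffled[:15], shuffled[15:])
    case_triples = ((1, 2, 4), (1, 3, 4))  # which 1-neighbour case each half uses

    # case_at_level[set_id][channels] -> case label
    case_at_level: dict[str, dict[int, int]] = {}
    for half, triple in zip(halves, case_triples):
        rotations = [tuple(np.roll(triple, -k)) for k in range(3)]
        for j, s in enumerate(half):
            rot = rotations[j // 5]  # 5 sets per rotation -> balanced per level
            case_at_level[s.set_id] = {
                ch: int(rot[k]) for k, ch in enumerate(CHANNEL_LEVELS)
            }

    trials: list[Exp2Trial] = []
    for ch in CHANNEL_LEVELS:
        by_case: dict[int, list[ResponseSet]] = {c: [] for c in CASE_N_NEIGHBOURS}
        for s in sets:
            by_case[case_at_level[s.set_id][ch]].append(s)
        for c in by_case:
            by_case[c] = [by_case[c][i] for i in rng.permutation(len(by_case[c]))]
        iters = {c: iter(v) for c, v in by_case.items()}
        for c in _EXP2_CASE_TEMPLATE:
            s = next(iters[c])
            trials.append(
                Exp2Trial(
                    channels=ch,
                    response_set=s,
                    spoken_word=s.spoken_word_for_case(c),
                    n_neighbours_in_array=CASE_N_NEIGHBOURS[c],
                    case_label=c,
                )
            )
    return trials


def exp2_to_frame(trials: Iterable[Exp2Trial]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "channels": [t.channels for t in trials],
            "set_id": [t.response_set.set_id for t in trials],
            "spoken_word": [t.spoken_word for t in trials],
            "n_neighbours": [t.n_neighbours_in_array for t in trials],
            "case_label": [t.case_label for t in trials],
        }
    )


def build_neutral_replication_schedule(
    word_pool: Sequence[str], seed: int
) -> list[Exp1Trial]:
    """Single-block replication with an added uninformative-cue condition.

    3 congruency levels (match / mismatch / neutral) x 3 channel levels,
    18 trials each (162 total).  Every spoken word is heard once; neutral
    trials carry the ``<UNINFORMATIVE>`` cue token.
    """
    n_needed = REPLICATION_TRIALS_PER_CONDITION * 9
    pool = list(dict.fromkeys(word_pool))
    if len(pool) < n_needed:
        raise ScheduleConstraintError(
            f"word pool of {len(pool)} distinct words cannot supply {n_needed} "
            "unique spoken words for the replication block"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    words = [pool[i] for i in rng.permutation(len(pool))[:n_needed]]
    shift = int(rng.integers(1, n_needed))
    trials: list[Exp1Trial] = []
    i = 0
    for cong in ("match", "mismatch", "neutral"):
        for ch in CHANNEL_LEVELS:
            for _ in range(REPLICATION_TRIALS_PER_CONDITION):
                w = words[i]
                if cong == "match":
                    written, informative = w, True
                elif cong == "mismatch":
                    written, informative = words[(i + shift) % n_needed], True
                else:
                    written, informative = NEUTRAL_CUE_TOKEN, False
                trials.append(
                    Exp1Trial(
                        block=1,
                        condition=Condition(cong, ch, allow_neutral=True),
                        written_word=written,
                        spoken_word=w,
                        cue_onset_to_speech_ms=_jitter(rng),
                        speech_onset_to_probe_ms=_jitter(rng),
                        cue_is_informative=informative,
                    )
                )
                i += 1
    perm = rng.permutation(len(trials))
    return [trials[j] for j in perm]
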