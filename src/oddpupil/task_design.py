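"""Passive auditory oddball schedule generation.

A task run consists of four blocks of 103 trials each: three leading
standard tones that establish the standard, followed by 100 pseudorandom
tones of which exactly 20 are oddballs.  Tones last 100 ms and are
separated by an interstimulus interval jittered uniformly between 1800
and 2000 ms.  Oddball/standard pitches are drawn from {500, 750} Hz; the
initial assignment is pseudo-random per subject and swapped between the
forward and reverse block of each manipulation half so that pitch is
counterbalanced within subjects.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PITCHES_HZ = (500.0, 750.0)
TONE_DURATION_MS = 100.0
ISI_RANGE_MS = (1800.0, 2000.0)

N_BLOCKS = 4
N_LEADING_STANDARDS = 3
N_PSEUDORANDOM = 100
N_ODDBALLS = 20
TRIALS_PER_BLOCK = N_LEADING_STANDARDS + N_PSEUDORANDOM
MANIPULATION_AFTER_BLOCK = 2

#: blocks labelled "forward"; the remaining blocks are "reverse".  One
#: forward and one reverse block fall in each manipulation half.
FORWARD_BLOCKS = (1, 3)


@dataclass(frozen=True)
class TrialSpec:
    """A single scheduled tone presentation."""

    block: int
    index_in_block: int
    stimulus: str  # "oddball" | "standard"
    pitch_hz: float
    onset_ms: float  # onset relative to block start
    isi_ms: float
    manipulation_phase: str  # "before" | "after"
    block_direction: str  # "forward" | "reverse"
    tone_duration_ms: float = TONE_DURATION_MS

    def __post_init__(self) -> None:
        if self.stimulus not in ("oddball", "standard"):
            raise ValueError(f"unknown stimulus {self.stimulus!r}")
        if not ISI_RANGE_MS[0] <= self.isi_ms <= ISI_RANGE_MS[1]:
            raise ValueError(f"isi_ms {self.isi_ms} outside {ISI_RANGE_MS}")


@dataclass
class TaskSchedule:
    """Ordered trial list for one subject."""

    subject_id: str
    trials: list[TrialSpec] = field(default_factory=list)
    manipulation_after_block: int = MANIPULATION_AFTER_BLOCK

    def block(self, block: int) -> list[TrialSpec]:
        return [t for t in self.trials if t.block == block]

    @property
    def n_blocks(self) -> int:
        return len({t.block for t in self.trials})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": self.subject_id,
                "block": t.block,
                "index_in_block": t.index_in_block,
                "stimulus": t.stimulus,
                "pitch_hz": t.pitch_hz,
                "onset_ms": t.onset_ms,
                "isi_ms": t.isi_ms,
                "manipulation_phase": t.manipulation_phase,
                "block_direction": t.block_direction,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)


def sample_isi(rng: np.random.Generator) -> float:
    """Draw one interstimulus interval, uniform on [1800, 2000] ms."""
    return float(rng.uniform(*ISI_RANGE_MS))


def _subject_rng(subject_id: str, seed: int) -> np.random.Generator:
    # stable per-subject stream: mix a CRC of the id into the seed sequence
    tag = zlib.crc32(str(subject_id).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _oddball_positions(
    rng: np.random.Generator,
    n: int = N_PSEUDORANDOM,
    k: int = N_ODDBALLS,
    no_consecutive: bool = True,
) -> np.ndarray:
    """Positions (0-based, within the pseudorandom portion) of the oddballs.

    With ``no_consecutive`` the k positions are drawn uniformly from all
    k-subsets of {0..n-1} with no two adjacent, via the standard gap
    bijection with subsets of {0..n-k}.
    """
    if no_consecutive:
        if n - k + 1 < k:
            raise ValueError("cannot place oddballs without adjacency")
        base = np.sort(rng.choice(n - k + 1, size=k, replace=False))
        return base + np.arange(k)
    return np.sort(rng.choice(n, size=k, replace=False))


def build_schedule(
    subject_id: str,
    seed: int,
    *,
    no_consecutive_oddballs: bool = True,
    forward_blocks: tuple[int, ...] = FORWARD_BLOCKS,
) -> TaskSchedule:
    """Generate the full four-block schedule for one subject.

    Parameters
    ----------
    subject_id
        Identifier; mixed into the random stream so that subjects sharing
        a master seed still receive independent pseudo-random assignments.
    seed
        Non-negative master seed; the schedule is deterministic in
        ``(subject_id, seed)``.
    no_consecutive_oddballs
        Forbid two adjacent oddballs within the pseudorandom portion.
    forward_blocks
        Which block numbers carry the "forward" pitch assignment; must
        contain one block from each manipulation half.
    """
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError("seed must be a non-negative integer")
    halves = ({1, 2}, {3, 4})
    for half in halves:
        if len(half & set(forward_blocks)) != 1:
            raise ValueError(
                "forward_blocks must contain exactly one block per half"
            )

    rng = _subject_rng(subject_id, seed)
    pitch_a = float(rng.choice(PITCHES_HZ))  # per-subject initial oddball pitch
    pitch_b = PITCHES_HZ[0] if pitch_a == PITCHES_HZ[1] else PITCHES_HZ[1]

    schedule = TaskSchedule(subject_id=str(subject_id))
    for block in range(1, N_BLOCKS + 1):
        direction = "forward" if block in forward_blocks else "reverse"
        phase = "before" if block <= MANIPULATION_AFTER_BLOCK else "after"
        oddball_pitch = pitch_a if direction == "forward" else pitch_b
        standard_pitch = pitch_b if direction == "forward" else pitch_a

        positions = set(
            _oddball_positions(rng, no_consecutive=no_consecutive_oddballs)
        )
        onset = 0.0
        for i in range(TRIALS_PER_BLOCK):
            is_oddball = (
                i >= N_LEADING_STANDARDS
                and (i - N_LEADING_STANDARDS) in positions
            )
            isi = sample_isi(rng)
            schedule.trials.append(
                TrialSpec(
                    block=block,
                    index_in_block=i + 1,
                    stimulus="oddball" if is_oddball else "standard",
                    pitch_hz=oddball_pitch if is_oddball else standard_pitch,
                    onset_ms=onset,
                    isi_ms=isi,
                    manipulation_phase=phase,
                    block_direction=direction,
                )
            )
            onset += TONE_DURATION_MS + isi
    return schedule


def pitch_assignment(schedule: TaskSchedule) -> dict[int, tuple[float, float]]:
    """Map each block to its ``(oddball_pitch, standard_pitch)`` pair."""
    out: dict[int, tuple[float, float]] = {}
    for block in sorted({t.block for t in schedule.trials}):
        trials = schedule.block(block)
        odd = {t.pitch_hz for t in trials if t.stimulus == "oddball"}
        std = {t.pitch_hz for t in trials if t.stimulus == "standard"}
        if len(odd) != 1 or len(std) != 1:
            raise ValueError(f"block {block} has inconsistent pitches")
        out[block] = (odd.pop(), std.pop())
    return out
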