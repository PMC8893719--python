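"""Local-global auditory oddball paradigm: sequences, blocks, and runs.

The paradigm nests two temporal regularities.  Each trial is a sequence of
five tones (50 ms each).  At the *local* level a sequence is either five
identical tones (``xx``), four identical tones plus a deviant fifth tone
(``xY``), or four tones with the fifth omitted (``x_``).  At the *global*
level one sequence type is habituated at the start of a run and then
presented as the frequent standard (80% of test trials) while the other
type appears as a rare deviant (20%).  Condition labels follow the
``<sequence>|<task>`` convention: ``xY|xx`` is an xY sequence inside a block
habituated to xx.  A dedicated omission-block run presents the four-tone
``xxxx`` sequence only, providing *expected* omissions as a reference.

Two protocol variants exist with different timing and carrier frequencies:
the ECoG protocol (150 ms inter-tone interval, 850 ms sequence, 3 s
sequence-onset asynchrony, 707/4000 Hz) and the fMRI protocol (100 ms
interval, 650 ms sequence, 3.5 s asynchrony, 800/6000 Hz).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "TASKS",
    "ParadigmConfig",
    "ToneEvent",
    "TrialSpec",
    "RunSpec",
    "build_sequence",
    "build_run",
    "events_table",
    "EVENT_COLUMNS",
]

#: all recognised condition labels
CONDITIONS = ("xx|xx", "xY|xx", "xx|xY", "xY|xY", "x_|xx", "x_|xY", "xxxx_expected")

#: task -> (standard condition, admissible deviant conditions)
TASKS = {
    "xx": ("xx|xx", ("xY|xx", "x_|xx")),
    "xY": ("xY|xY", ("xx|xY", "x_|xY")),
    "omission_block": ("xxxx_expected", ()),
}

EVENT_COLUMNS = [
    "onset",
    "duration",
    "frequency",
    "amplitude",
    "position",
    "condition",
    "role",
    "block",
    "trial_index",
]


@dataclass(frozen=True)
class ParadigmConfig:
    """Timing and composition parameters of one run.

    ``inter_tone_interval_s`` is offset-to-onset; ``inter_sequence_onset_s``
    is onset-to-onset.  ``rest_s`` (leading rest before the first
    habituation sequence) is metadata only and does not shift event times.
    """

    tone_duration_s: float = 0.050
    inter_tone_interval_s: float = 0.150
    inter_sequence_onset_s: float = 3.0
    freq_x_hz: float = 707.0
    freq_y_hz: float = 4000.0
    n_habituation: int = 20
    block_size: int = 25
    deviant_fraction: float = 0.2
    n_test_blocks: int = 3
    protocol: str = "ecog"
    rest_s: float = 0.0

    def __post_init__(self) -> None:
        if self.tone_duration_s <= 0:
            raise ValueError("tone_duration_s must be > 0")
        if self.inter_tone_interval_s < 0:
            raise ValueError("inter_tone_interval_s must be >= 0")
        if not 0.0 < self.deviant_fraction < 1.0:
            raise ValueError("deviant_fraction must lie in (0, 1)")
        if self.protocol not in ("ecog", "fmri"):
            raise ValueError(f"unknown protocol {self.protocol!r}")

    @classmethod
    def ecog(cls, **kw) -> "ParadigmConfig":
        return cls(protocol="ecog", **kw)

    @classmethod
    def fmri(cls, **kw) -> "ParadigmConfig":
        return cls(
            tone_duration_s=0.050,
            inter_tone_interval_s=0.100,
            inter_sequence_onset_s=3.5,
            freq_x_hz=800.0,
            freq_y_hz=6000.0,
            protocol="fmri",
            rest_s=14.0,
            **kw,
        )

    @property
    def tone_onset_asynchrony_s(self) -> float:
        return self.tone_duration_s + self.inter_tone_interval_s

    @property
    def sequence_duration_s(self) -> float:
        """Total sequence duration: 5 tones + 4 gaps."""
        return 5 * self.tone_duration_s + 4 * self.inter_tone_interval_s

    @property
    def fifth_tone_onset_s(self) -> float:
        return 4 * self.tone_onset_asynchrony_s

    @property
    def n_deviants_per_block(self) -> int:
        n = self.block_size * self.deviant_fraction
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"block_size*deviant_fraction = {n} is not an integer"
            )
        return int(round(n))

    def replace(self, **kw) -> "ParadigmConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ToneEvent:
    """One tone within a sequence; ``frequency_hz=None`` marks an omission."""

    onset_s: float
    duration_s: float
    frequency_hz: float | None
    position: int

    @property
    def omitted(self) -> bool:
        return self.frequency_hz is None


@dataclass(frozen=True)
class TrialSpec:
    condition: str
    role: str  # habituation | standard | deviant
    tones: tuple[ToneEvent, ...]
    sequence_onset_s: float

    @property
    def duration_s(self) -> float:
        last = self.tones[-1]
        return last.onset_s + last.duration_s


def _sequence_kind(condition: str) -> str:
    """Local sequence type for a condition label: xx, xY or x_ (omission)."""
    if condition == "xxxx_expected":
        return "x_"
    return condition.split("|")[0]


def build_sequence(
    condition: str,
    config: ParadigmConfig,
    role: str = "standard",
    sequence_onset_s: float = 0.0,
) -> TrialSpec:
    """Build the five tone events of one sequence.

    Positions 1-4 always carry the x frequency.  Position 5 carries the Y
    frequency for xY sequences and is an omission marker (``frequency_hz``
    None, zero amplitude downstream) for x_ sequences and the expected
    omission condition.
    """
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; valid conditions: {CONDITIONS}"
        )
    kind = _sequence_kind(condition)
    soa = config.tone_onset_asynchrony_s
    tones = []
    for pos in range(1, 5):
        tones.append(
            ToneEvent((pos - 1) * soa, config.tone_duration_s, config.freq_x_hz, pos)
        )
    if kind == "xx":
        f5: float | None = config.freq_x_hz
    elif kind == "xY":
        f5 = config.freq_y_hz
    else:  # omission
        f5 = None
    tones.append(ToneEvent(4 * soa, config.tone_duration_s, f5, 5))
    return TrialSpec(condition, role, tuple(tones), sequence_onset_s)


@dataclass(frozen=True)
class RunSpec:
    """One recording run: habituation phase followed by test blocks."""

    task: str
    deviant_type: str | None
    habituation: tuple[TrialSpec, ...]
    blocks: tuple[tuple[TrialSpec, ...], ...]
    config: ParadigmConfig
    seed: int

    @property
    def trials(self) -> list[TrialSpec]:
        out = list(self.habituation)
        for block in self.blocks:
            out.extend(block)
        return out

    @property
    def n_trials(self) -> int:
        return len(self.habituation) + sum(len(b) for b in self.blocks)

    @property
    def duration_s(self) -> float:
        return self.n_trials * self.config.inter_sequence_onset_s


def _draw_deviant_positions(
    rng: np.random.Generator, block_size: int, n_dev: int
) -> np.ndarray:
    """Uniform draw among deviant placements with no two consecutive deviants
    and none in the block-final position (rejection sampling over the uniform
    combination draw, hence uniform over admissible sets)."""
    if n_dev == 0:
        return np.empty(0, dtype=int)
    admissible = block_size - 1  # last position excluded
    for _ in range(100_000):
        pos = np.sort(rng.choice(admissible, size=n_dev, replace=False))
        if n_dev == 1 or np.all(np.diff(pos) > 1):
            return pos
    raise RuntimeError("could not place deviants under the spacing constraint")


def build_run(
    task: str,
    deviant_type: str | None,
    config: ParadigmConfig,
    seed: int,
) -> RunSpec:
    """Generate a full run: habituation standards, then test blocks with
    randomly placed deviants.  Deterministic given (task, deviant_type,
    config, seed)."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; valid tasks: {tuple(TASKS)}")
    standard, allowed_dev = TASKS[task]
    if task == "omission_block":
        if deviant_type is not None:
            raise ValueError("omission_block runs have no deviant trials")
        n_dev = 0
    else:
        if deviant_type not in allowed_dev:
            raise ValueError(
                f"deviant_type {deviant_type!r} invalid for task {task!r}; "
                f"allowed: {allowed_dev}"
            )
        n_dev = config.n_deviants_per_block  # validates integrality

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    iso = config.inter_sequence_onset_s

    habituation = tuple(
        build_sequence(standard, config, role="habituation", sequence_onset_s=i * iso)
        for i in range(config.n_habituation)
    )
    blocks = []
    trial_idx = config.n_habituation
    for _ in range(config.n_test_blocks):
        dev_pos = set(_draw_deviant_positions(rng, config.block_size, n_dev).tolist())
        block = []
        for j in range(config.block_size):
            if j in dev_pos:
                cond, role = deviant_type, "deviant"
            else:
                cond, role = standard, "standard"
            block.append(
                build_sequence(cond, config, role=role, sequence_onset_s=trial_idx * iso)
            )
            trial_idx += 1
        blocks.append(tuple(block))
    return RunSpec(task, deviant_type, habituation, tuple(blocks), config, seed)


def events_table(run: RunSpec) -> pd.DataFrame:
    """Flatten a run into one row per tone event (omissions retained with
    zero amplitude and NaN frequency).  Onsets are in run time, seconds.
    Habituation trials carry block -1; test blocks are 0-based."""
    rows = []
    trial_idx = 0
    for block_id, trials in [(-1, run.habituation)] + [
        (b, blk) for b, blk in enumerate(run.blocks)
    ]:
        for trial in trials:
            for tone in trial.tones:
                rows.append(
                    {
                        "onset": trial.sequence_onset_s + tone.onset_s,
                        "duration": tone.duration_s,
                        "frequency": np.nan if tone.omitted else tone.frequency_hz,
                        "amplitude": 0.0 if tone.omitted else 1.0,
                        "position": tone.position,
                        "condition": trial.condition,
                        "role": trial.role,
                        "block": block_id,
                        "trial_index": trial_idx,
                    }
                )
            trial_idx += 1
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
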