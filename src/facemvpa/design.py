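"""Event-related and blocked experimental designs.

The experimental run emulates a rapid event-related whole/part discrimination
session: per run, 36 four-second trials with face parts in a veridical
configuration, 36 with the parts scrambled, and twelve 2-s fixation trials as
temporal jitter, bracketed by 8-s lead-in/lead-out fixation.  With TR = 2 s a
default run spans 328 s (164 scans).

The localizer is a blocked design: sixteen 16-s stimulus blocks (4 categories
x 4 blocks, each category once per quarter) interleaved with five 16-s
fixation periods, spanning 336 s.  Each block shows 20 stimuli at 300 ms on /
500 ms off.

Trial order is a seeded random permutation; a first-order transition-count
diagnostic is provided in place of a counterbalancing optimizer.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from ._seeds import child_seed

__all__ = [
    "Event",
    "EventDesign",
    "DesignParams",
    "LocalizerParams",
    "generate_experimental_design",
    "generate_localizer_design",
    "transition_counts",
    "CONDITIONS",
]

CONDITIONS = ("veridical", "scrambled")
FIXATION = "fixation"


@dataclass(frozen=True)
class Event:
    """One timed element of a run: a stimulus trial, block, or fixation."""

    onset_s: float
    duration_s: float
    condition: str
    trial_id: int | None = None


@dataclass
class EventDesign:
    """Timed, labeled trial sequence for one run (the temporal skeleton)."""

    run_id: int
    events: list[Event]
    tr_s: float
    n_scans: int
    lead_in_s: float = 0.0
    lead_out_s: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def span_s(self) -> float:
        """Total run duration in seconds."""
        return self.n_scans * self.tr_s

    @property
    def n_trials(self) -> int:
        return sum(1 for e in self.events if e.trial_id is not None)

    def validate(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        prev_end = 0.0
        prev_onset = -np.inf
        for e in self.events:
            if e.onset_s < 0:
                raise ValueError(f"negative onset {e.onset_s}")
            if e.onset_s < prev_onset:
                raise ValueError("events must be sorted by onset")
            if e.onset_s + 1e-9 < prev_end:
                raise ValueError(
                    f"overlapping events at onset {e.onset_s} (previous ends {prev_end})"
                )
            prev_onset = e.onset_s
            prev_end = e.onset_s + e.duration_s
        # events may leave gaps (unmodeled rest) but must fit inside the run
        if prev_end > self.span_s + 1e-6:
            raise ValueError(
                f"events end at {prev_end} s, beyond n_scans x tr_s = {self.span_s} s"
            )

    def trial_frame(self) -> pd.DataFrame:
        """Stimulus trials as a tidy table (onset, duration, condition, trial_id)."""
        rows = [
            (e.onset_s, e.duration_s, e.condition, e.trial_id)
            for e in self.events
            if e.trial_id is not None
        ]
        return pd.DataFrame(rows, columns=["onset", "duration", "condition", "trial_id"])


class DesignParams(BaseModel):
    """Defaults reproduce the published event-related run timing (328 s)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_veridical: int = 36
    n_scrambled: int = 36
    trial_duration_s: float = 4.0
    n_fixation: int = 12
    fixation_duration_s: float = 2.0
    lead_in_s: float = 8.0
    lead_out_s: float = 8.0
    tr_s: float = 2.0


class LocalizerParams(BaseModel):
    """Defaults reproduce the published blocked localizer timing (336 s)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    categories: tuple[str, ...] = ("faces", "objects", "houses", "scrambled_objects")
    blocks_per_category: int = 4
    block_duration_s: float = 16.0
    n_fixation_blocks: int = 5
    stimuli_per_block: int = 20
    stim_on_s: float = 0.3
    stim_off_s: float = 0.5
    tr_s: float = 2.0


def generate_experimental_design(
    run_id: int, seed: int, params: DesignParams | None = None
) -> EventDesign:
    """Seeded random interleaving of stimulus and fixation trials for one run.

    Deterministic per ``(run_id, seed)``.  Rejects timings whose total span is
    not a whole number of TRs.
    """
    p = params or DesignParams()
    total = (
        (p.n_veridical + p.n_scrambled) * p.trial_duration_s
        + p.n_fixation * p.fixation_duration_s
        + p.lead_in_s
        + p.lead_out_s
    )
    n_scans_f = total / p.tr_s
    if abs(n_scans_f - round(n_scans_f)) > 1e-9:
        raise ValueError(
            f"total run duration {total} s is not a multiple of tr_s = {p.tr_s} s"
        )
    slots = (
        ["veridical"] * p.n_veridical
        + ["scrambled"] * p.n_scrambled
        + [FIXATION] * p.n_fixation
    )
    rng = np.random.default_rng(child_seed(seed, "design", run_id))
    order = rng.permutation(len(slots))
    events: list[Event] = []
    onset = p.lead_in_s
    trial_id = 0
    for i in order:
        cond = slots[i]
        if cond == FIXATION:
            events.append(Event(onset, p.fixation_duration_s, FIXATION))
            onset += p.fixation_duration_s
        else:
            events.append(Event(onset, p.trial_duration_s, cond, trial_id))
            trial_id += 1
            onset += p.trial_duration_s
    return EventDesign(
        run_id=run_id,
        events=events,
        tr_s=p.tr_s,
        n_scans=int(round(n_scans_f)),
        lead_in_s=p.lead_in_s,
        lead_out_s=p.lead_out_s,
    )


def generate_localizer_design(
    seed: int, params: LocalizerParams | None = None, run_id: int = 0
) -> EventDesign:
    """Blocked localizer: category blocks in seeded order, one per quarter.

    Fixation periods open and close the run and separate the quarters, so the
    default layout is F [4 blocks] F [4] F [4] F [4] F = 21 x 16 s = 336 s.
    """
    p = params or LocalizerParams()
    per_block = p.stimuli_per_block * (p.stim_on_s + p.stim_off_s)
    if not math.isclose(per_block, p.block_duration_s, abs_tol=1e-9):
        raise ValueError(
            f"stimulus accounting {per_block} s does not fill block of {p.block_duration_s} s"
        )
    n_cat = len(p.categories)
    rng = np.random.default_rng(child_seed(seed, "localizer", run_id))
    block_order: list[str] = []
    for _ in range(p.blocks_per_category):
        quarter = rng.permutation(n_cat)
        block_order.extend(p.categories[i] for i in quarter)
    n_blocks = len(block_order)
    # distribute fixation periods: start, end, and evenly between block groups
    n_groups = max(p.n_fixation_blocks - 1, 1)
    if n_blocks % n_groups:
        raise ValueError("fixation periods must evenly partition the blocks")
    blocks_per_group = n_blocks // n_groups
    events: list[Event] = []
    onset = 0.0
    bi = 0
    for g in range(p.n_fixation_blocks):
        events.append(Event(onset, p.block_duration_s, FIXATION))
        onset += p.block_duration_s
        if g < p.n_fixation_blocks - 1:
            for _ in range(blocks_per_group):
                events.append(Event(onset, p.block_duration_s, block_order[bi]))
                onset += p.block_duration_s
                bi += 1
    total = onset
    n_scans_f = total / p.tr_s
    if abs(n_scans_f - round(n_scans_f)) > 1e-9:
        raise ValueError(f"localizer span {total} s is not a multiple of tr_s")
    return EventDesign(
        run_id=run_id, events=events, tr_s=p.tr_s, n_scans=int(round(n_scans_f))
    )


def transition_counts(design: EventDesign) -> pd.DataFrame:
    """First-order condition-transition counts, the counterbalance diagnostic.

    Rows index the preceding condition, columns the following one.  A
    well-jittered run has roughly uniform counts.
    """
    conds = sorted({e.condition for e in design.events})
    table = pd.DataFrame(0, index=conds, columns=conds, dtype=int)
    seq = [e.condition for e in design.events]
    for a, b in zip(seq[:-1], seq[1:]):
        table.loc[a, b] += 1
    return table
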