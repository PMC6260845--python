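"""Experimental design: iTRAQ 8-plex reporter channels and their sample mapping.

An 8-plex run multiplexes eight labeled samples; each reporter channel
(m/z tag 113..121, no 120) carries one (condition, biological replicate)
pair.  The study design is four conditions -- an untreated Control and the
three leaf zones of the light gradient (Burned, Limit, Regular) -- with two
biological replicates each, which fills the plex exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CHANNELS: tuple[str, ...] = ("113", "114", "115", "116", "117", "118", "119", "121")
CONDITIONS: tuple[str, ...] = ("Control", "Burned", "Limit", "Regular")
TREATMENTS: tuple[str, ...] = ("Burned", "Limit", "Regular")
REPLICATES: tuple[int, ...] = (1, 2)

#: Column names used for reporter intensities in peptide/protein tables.
INTENSITY_COLUMNS: tuple[str, ...] = tuple(f"i{c}" for c in CHANNELS)


@dataclass(frozen=True)
class DesignMap:
    """Bijection between reporter channels and (condition, replicate) samples.

    Parameters
    ----------
    assignments
        Tuple of ``(channel, condition, replicate)`` triples.  Must cover all
        eight channels, with each of the four conditions appearing exactly
        twice, once per replicate index.
    """

    assignments: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        seen = {(a[1], a[2]) for a in self.assignments}
        expected = {(c, r) for c in CONDITIONS for r in REPLICATES}
        if seen != expected:
            missing = expected - seen
            raise ValueError(f"condition missing replicate: {sorted(missing)}")
        channels = [a[0] for a in self.assignments]
        if sorted(channels) != sorted(CHANNELS):
            raise ValueError(
                f"design must cover channels {CHANNELS} exactly once, got {channels}"
            )

    @classmethod
    def default(cls) -> "DesignMap":
        """Generator default layout: Control(1,2), Burned(1,2), Limit(1,2), Regular(1,2) on 113..121."""
        triples = []
        i = 0
        for cond in CONDITIONS:
            for rep in REPLICATES:
                triples.append((CHANNELS[i], cond, rep))
                i += 1
        return cls(tuple(triples))

    def channel(self, condition: str, replicate: int) -> str:
        for ch, cond, rep in self.assignments:
            if cond == condition and rep == replicate:
                return ch
        raise KeyError((condition, replicate))

    def sample(self, channel: str) -> tuple[str, int]:
        for ch, cond, rep in self.assignments:
            if ch == channel:
                return cond, rep
        raise KeyError(channel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.assignments, columns=["channel", "condition", "replicate"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DesignMap":
        required = {"channel", "condition", "replicate"}
        if not required.issubset(frame.columns):
            raise ValueError(f"design table needs columns {sorted(required)}")
        triples = tuple(
            (str(r.channel), str(r.condition), int(r.replicate))
            for r in frame.itertuples(index=False)
        )
        return cls(triples)
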