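"""Stimulus paradigm: isochronous tone sequences with softer deviants.

The experiment presents sequences of 13--16 pure tones at a fixed
inter-onset interval (IOI) of 650 ms, giving a stimulation frequency
``Sf = 1/IOI ~ 1.54 Hz``.  Each sequence contains one or two deviant
tones (4 dB softer); the first deviant falls on position 8, 9, 10 or 11
and the second, when present, always on position 12.  The event table
produced here timestamps every downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ParadigmSpec", "make_paradigm", "EVENT_COLUMNS"]

#: Columns of an event table, one row per tone.
EVENT_COLUMNS = ["sequence_id", "position", "onset", "is_deviant"]


@dataclass(frozen=True)
class ParadigmSpec:
    """Parameters of the isochronous-sequence paradigm.

    Attributes
    ----------
    n_sequences : int
        Number of tone sequences per session (default 96).
    tones_min, tones_max : int
        Range of tones per sequence (uniform over 13..16 by default).
    ioi : float
        Inter-onset interval between successive tones, seconds.
    tone_freq : float
        Carrier frequency of the tones, Hz (does not enter the EEG
        simulation; kept for provenance).
    tone_dur : float
        Tone duration, seconds.
    dev_atten : float
        Deviant attenuation relative to standards, dB.
    first_dev_positions : tuple of int
        1-based positions the first deviant may occupy.
    second_dev_position : int
        1-based position of the second deviant, when present.
    """

    n_sequences: int = 96
    tones_min: int = 13
    tones_max: int = 16
    ioi: float = 0.650
    tone_freq: float = 400.0
    tone_dur: float = 0.050
    dev_atten: float = 4.0
    first_dev_positions: tuple[int, ...] = (8, 9, 10, 11)
    second_dev_position: int = 12

    @property
    def sf(self) -> float:
        """Stimulation frequency in Hz, the reciprocal of the IOI."""
        return 1.0 / self.ioi

    def validate(self) -> None:
        if self.n_sequences < 1:
            raise ValueError(f"invalid n_sequences={self.n_sequences}: must be >= 1")
        if self.tones_min > self.tones_max:
            raise ValueError(
                f"invalid tones_min={self.tones_min} > tones_max={self.tones_max}"
            )
        if self.ioi <= 0:
            raise ValueError(f"invalid ioi={self.ioi}: must be > 0")
        if self.tone_dur <= 0 or self.tone_dur >= self.ioi:
            raise ValueError(f"invalid tone_dur={self.tone_dur}: must be in (0, ioi)")
        bad = [p for p in (*self.first_dev_positions, self.second_dev_position)
               if p > self.tones_min or p < 1]
        if bad:
            raise ValueError(
                f"invalid deviant positions {bad}: must lie within 1..tones_min="
                f"{self.tones_min}"
            )


def make_paradigm(
    spec: ParadigmSpec | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw an event schedule for one session.

    Tone counts are uniform over ``{tones_min..tones_max}``.  Each
    sequence carries one or two deviants (equiprobable): the first at a
    position drawn uniformly from ``first_dev_positions``, the second —
    when present — at ``second_dev_position``.

    Parameters
    ----------
    spec : ParadigmSpec
        Paradigm parameters; defaults describe the reference session.
    seed : int, SeedSequence or Generator
        Source of randomness; a fixed seed yields an identical table.

    Returns
    -------
    pandas.DataFrame
        One row per tone with columns ``sequence_id`` (0-based),
        ``position`` (1-based), ``onset`` (s from the first tone of the
        sequence, exactly ``(position - 1) * ioi``) and ``is_deviant``.
    """
    spec = spec or ParadigmSpec()
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows: list[tuple[int, int, float, bool]] = []
    n_tones = rng.integers(spec.tones_min, spec.tones_max + 1, size=spec.n_sequences)
    n_dev = rng.integers(1, 3, size=spec.n_sequences)
    first_dev = rng.choice(spec.first_dev_positions, size=spec.n_sequences)
    for sid in range(spec.n_sequences):
        devs = {int(first_dev[sid])}
        if n_dev[sid] == 2:
            devs.add(spec.second_dev_position)
        for pos in range(1, int(n_tones[sid]) + 1):
            rows.append((sid, pos, (pos - 1) * spec.ioi, pos in devs))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def sequence_lengths(events: pd.DataFrame) -> pd.Series:
    """Number of tones per sequence, indexed by sequence_id."""
    return events.groupby("sequence_id")["position"].max()
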