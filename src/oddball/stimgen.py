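"""Construction of oddball, cascade, and many-standards tone sequences.

The experimental design presents, for each neuron, pure tones drawn from a
grid of 10 frequencies evenly spaced on a log axis (0.5 octave by default).
A tone can occur in four roles:

* **deviant (DEV)** — rare (10%) interloper in an oddball sequence;
* **standard (STD)** — the repeated tone of an oddball sequence;
* **cascade control** — the 10 grid tones played in strict ascending or
  descending order, cyclically, so each tone is as rare as a deviant but
  conforms to a regular pattern;
* **many-standards control** — the 10 tones in balanced random order with
  no immediate repeats.

All sequences are 400 tones long at a constant presentation rate, so every
non-standard tone occurs exactly 40 times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "ToneGrid",
    "StimulusSequence",
    "ConstraintCheck",
    "make_tone_grid",
    "make_oddball",
    "make_cascade",
    "make_many_standards",
    "validate_sequence",
    "write_sequence",
    "read_sequence",
]

N_GRID = 10

#: stimulus-onset asynchrony in ms: 4 Hz for midbrain/thalamus, 3 Hz for cortex
SOA_SUBCORTICAL_MS = 250.0
SOA_CORTICAL_MS = 1000.0 / 3.0


class Condition(str, Enum):
    """Sequence type labels."""

    ODD_ASC = "ODD_ASC"
    ODD_DESC = "ODD_DESC"
    CAS_ASC = "CAS_ASC"
    CAS_DESC = "CAS_DESC"
    MSTD = "MSTD"


@dataclass(frozen=True)
class ToneGrid:
    """Ten tone frequencies geometrically spaced by ``octave_step`` octaves."""

    frequencies: tuple[float, ...]
    octave_step: float
    intensity_db_spl: float
    tone_duration_ms: float = 75.0
    ramp_ms: float = 5.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.size != N_GRID:
            raise ValueError(f"grid must hold {N_GRID} frequencies, got {f.size}")
        steps = np.log2(f[1:] / f[:-1])
        if np.any(steps <= 0):
            raise ValueError("frequencies must be strictly ascending")
        if not np.allclose(steps, self.octave_step, atol=1e-9):
            raise ValueError("adjacent frequencies must be octave_step apart")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.frequencies, dtype=float)


@dataclass
class StimulusSequence:
    """An ordered tone sequence with its design metadata.

    ``tone_index`` holds 0-based indices into the grid.  ``is_deviant`` is
    only meaningful for oddball sequences; for controls it is all-False.
    """

    condition: Condition
    grid: ToneGrid
    tone_index: np.ndarray
    is_deviant: np.ndarray
    soa_ms: float = SOA_SUBCORTICAL_MS
    seed: int | None = None
    std_index: int | None = None
    dev_index: int | None = None
    p_dev: float | None = None
    lead_in: int | None = None
    min_sep: int | None = None

    def __post_init__(self) -> None:
        self.tone_index = np.asarray(self.tone_index, dtype=int)
        self.is_deviant = np.asarray(self.is_deviant, dtype=bool)
        if self.is_deviant.shape != self.tone_index.shape:
            raise ValueError("is_deviant must align with tone_index")

    def __len__(self) -> int:
        return int(self.tone_index.size)

    @property
    def n_tones(self) -> int:
        return len(self)

    @property
    def frequencies_hz(self) -> np.ndarray:
        return self.grid.as_array()[self.tone_index]

    def deviant_positions(self) -> np.ndarray:
        """0-based positions of deviant tones."""
        return np.flatnonzero(self.is_deviant)


def make_tone_grid(
    center_freq_hz: float,
    octave_step: float = 0.5,
    intensity_db_spl: float = 40.0,
    *,
    tone_duration_ms: float = 75.0,
    ramp_ms: float = 5.0,
) -> ToneGrid:
    """Build a 10-tone grid centered on ``center_freq_hz``.

    The grid is geometric with ``octave_step`` octaves between neighbours;
    the center frequency falls midway (on the log axis) between the 5th and
    6th tones.
    """
    if center_freq_hz <= 0:
        raise ValueError("center_freq_hz must be positive")
    if octave_step <= 0:
        raise ValueError("octave_step must be positive")
    offsets = (np.arange(N_GRID) - (N_GRID - 1) / 2.0) * octave_step
    freqs = center_freq_hz * 2.0**offsets
    return ToneGrid(
        frequencies=tuple(freqs.tolist()),
        octave_step=octave_step,
        intensity_db_spl=intensity_db_spl,
        tone_duration_ms=tone_duration_ms,
        ramp_ms=ramp_ms,
    )


def _compose(rng: np.random.Generator, total: int, n_parts: int) -> np.ndarray:
    """Uniformly random composition of ``total`` into ``n_parts`` parts >= 0.

    Stars-and-bars bijection: choosing ``n_parts - 1`` cut points among
    ``total + n_parts - 1`` slots enumerates compositions exactly once, so
    sampling the cuts without replacement is exactly uniform.
    """
    if n_parts == 1:
        return np.array([total])
    cuts = np.sort(rng.choice(total + n_parts - 1, size=n_parts - 1, replace=False))
    ext = np.concatenate(([-1], cuts, [total + n_parts - 1]))
    return np.diff(ext) - 1


def make_oddball(
    grid: ToneGrid,
    std_index: int,
    dev_index: int,
    n_tones: int = 400,
    p_dev: float = 0.1,
    lead_in: int = 10,
    min_sep: int = 3,
    seed: int | None = None,
    soa_ms: float = SOA_SUBCORTICAL_MS,
) -> StimulusSequence:
    """Generate an oddball sequence for an adjacent standard/deviant pair.

    The deviant occupies ``round(p_dev * n_tones)`` pseudorandom positions:
    the first ``lead_in`` tones are always standards and every deviant is
    preceded by at least ``min_sep`` standards.  Placement is exactly uniform
    over admissible configurations: the deviant-to-deviant gap lengths are
    drawn by a stars-and-bars composition after reserving the mandatory
    ``min_sep`` standards in each gap.
    """
    if not 0 <= std_index < N_GRID or not 0 <= dev_index < N_GRID:
        raise ValueError("tone indices must lie in the grid")
    if abs(dev_index - std_index) != 1:
        raise ValueError("standard and deviant must be adjacent grid tones")
    n_dev = int(round(p_dev * n_tones))
    if n_dev < 1:
        raise ValueError("p_dev * n_tones must round to at least one deviant")
    slack = n_tones - lead_in - n_dev * (min_sep + 1)
    if slack < 0:
        raise ValueError(
            f"cannot place {n_dev} deviants with lead_in={lead_in}, "
            f"min_sep={min_sep} in {n_tones} tones"
        )
    rng = np.random.default_rng(seed)
    extra = _compose(rng, slack, n_dev + 1)  # last part = trailing standards
    gaps = extra[:-1] + min_sep  # standards before each deviant
    positions = lead_in + np.cumsum(gaps + 1) - 1

    tone_index = np.full(n_tones, std_index, dtype=int)
    tone_index[positions] = dev_index
    is_dev = np.zeros(n_tones, dtype=bool)
    is_dev[positions] = True
    condition = Condition.ODD_ASC if dev_index > std_index else Condition.ODD_DESC
    return StimulusSequence(
        condition=condition,
        grid=grid,
        tone_index=tone_index,
        is_deviant=is_dev,
        soa_ms=soa_ms,
        seed=seed,
        std_index=std_index,
        dev_index=dev_index,
        p_dev=p_dev,
        lead_in=lead_in,
        min_sep=min_sep,
    )


def make_cascade(
    grid: ToneGrid,
    direction: str = "ascending",
    n_tones: int = 400,
    soa_ms: float = SOA_SUBCORTICAL_MS,
) -> StimulusSequence:
    """Generate the deterministic cascade control sequence.

    The 10 grid tones are played in strict ascending (or descending)
    frequency order, cyclically.  In the ascending cascade the tone
    immediately preceding grid tone *k* is *k − 1*, matching the
    standard-to-deviant frequency step of the ascending oddball.
    """
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    if n_tones % N_GRID != 0:
        raise ValueError("n_tones must be a multiple of the grid size")
    cycle = np.arange(N_GRID) if direction == "ascending" else np.arange(N_GRID)[::-1]
    tone_index = np.tile(cycle, n_tones // N_GRID)
    condition = Condition.CAS_ASC if direction == "ascending" else Condition.CAS_DESC
    return StimulusSequence(
        condition=condition,
        grid=grid,
        tone_index=tone_index,
        is_deviant=np.zeros(n_tones, dtype=bool),
        soa_ms=soa_ms,
    )


def make_many_standards(
    grid: ToneGrid,
    n_tones: int = 400,
    seed: int | None = None,
    soa_ms: float = SOA_SUBCORTICAL_MS,
    max_restarts: int = 100,
) -> StimulusSequence:
    """Generate the many-standards control sequence.

    Each grid tone occurs exactly ``n_tones / 10`` times in random order,
    with no tone ever repeated back-to-back.  A Fisher-Yates shuffle is
    followed by local swap repair of adjacent duplicates (reshuffling in the
    rare event repair stalls).
    """
    if n_tones % N_GRID != 0:
        raise ValueError("n_tones must be a multiple of the grid size")
    rng = np.random.default_rng(seed)
    base = np.repeat(np.arange(N_GRID), n_tones // N_GRID)
    for _ in range(max_restarts):
        seq = base.copy()
        rng.shuffle(seq)
        if _repair_adjacent_repeats(seq, rng):
            return StimulusSequence(
                condition=Condition.MSTD,
                grid=grid,
                tone_index=seq,
                is_deviant=np.zeros(n_tones, dtype=bool),
                soa_ms=soa_ms,
                seed=seed,
            )
    raise RuntimeError("could not build a repeat-free many-standards sequence")


def _repair_adjacent_repeats(seq: np.ndarray, rng: np.random.Generator) -> bool:
    """Swap away adjacent duplicates in place; True on success."""
    n = seq.size
    for _ in range(10 * n):
        dups = np.flatnonzero(seq[1:] == seq[:-1]) + 1
        if dups.size == 0:
            return True
        i = dups[0]
        v = seq[i]
        # candidate j: seq[j] != v and swapping creates no new duplicate
        cand = []
        js = rng.permutation(n)
        for j in js:
            if seq[j] == v or j == i:
                continue
            if j > 0 and seq[j - 1] == v:
                continue
            if j < n - 1 and seq[j + 1] == v:
                continue
            w = seq[j]
            if i > 0 and seq[i - 1] == w:
                continue
            if i < n - 1 and seq[i + 1] == w and i + 1 != j:
                continue
            cand.append(j)
            break
        if not cand:
            return False
        j = cand[0]
        seq[i], seq[j] = seq[j], seq[i]
    return False


class ConstraintCheck(NamedTuple):
    """One design-constraint verdict from :func:`validate_sequence`."""

    name: str
    passed: bool
    positions: tuple[int, ...]


def _std_run_before(seq: StimulusSequence, pos: int) -> int:
    """Number of consecutive standards immediately preceding ``pos``."""
    run = 0
    k = pos - 1
    while k >= 0 and not seq.is_deviant[k]:
        run += 1
        k -= 1
    return run


def validate_sequence(seq: StimulusSequence) -> list[ConstraintCheck]:
    """Check every design constraint of a sequence; empty failures for
    generator output."""
    checks: list[ConstraintCheck] = []
    n = len(seq)
    bad_idx = np.flatnonzero((seq.tone_index < 0) | (seq.tone_index >= N_GRID))
    checks.append(ConstraintCheck("tone_index_in_grid", bad_idx.size == 0, tuple(bad_idx)))

    if seq.condition in (Condition.ODD_ASC, Condition.ODD_DESC):
        p_dev = seq.p_dev if seq.p_dev is not None else 0.1
        lead_in = seq.lead_in if seq.lead_in is not None else 10
        min_sep = seq.min_sep if seq.min_sep is not None else 3
        devs = seq.deviant_positions()
        n_expected = int(round(p_dev * n))
        checks.append(
            ConstraintCheck("deviant_count", devs.size == n_expected, tuple(devs))
        )
        early = tuple(int(p) for p in devs if p < lead_in)
        checks.append(ConstraintCheck("lead_in_all_standard", not early, early))
        short = tuple(
            int(p) for p in devs if _std_run_before(seq, int(p)) < min_sep
        )
        checks.append(ConstraintCheck("min_sep_before_deviant", not short, short))
        mismarked = np.flatnonzero(
            seq.is_deviant != (seq.tone_index == seq.dev_index)
        )
        checks.append(
            ConstraintCheck("deviant_flags_consistent", mismarked.size == 0, tuple(mismarked))
        )
    elif seq.condition in (Condition.CAS_ASC, Condition.CAS_DESC):
        cycle = (
            np.arange(N_GRID)
            if seq.condition is Condition.CAS_ASC
            else np.arange(N_GRID)[::-1]
        )
        expected = np.tile(cycle, int(np.ceil(n / N_GRID)))[:n]
        bad = np.flatnonzero(seq.tone_index != expected)
        checks.append(ConstraintCheck("cascade_cyclic_order", bad.size == 0, tuple(bad)))
    elif seq.condition is Condition.MSTD:
        counts = np.bincount(seq.tone_index, minlength=N_GRID)
        balanced = bool(np.all(counts == n // N_GRID))
        off = tuple(int(i) for i in np.flatnonzero(counts != n // N_GRID))
        checks.append(ConstraintCheck("balanced_presentation", balanced, off))
        rep = np.flatnonzero(seq.tone_index[1:] == seq.tone_index[:-1]) + 1
        checks.append(ConstraintCheck("no_adjacent_repeat", rep.size == 0, tuple(rep)))
    return checks


def sequence_to_frame(seq: StimulusSequence) -> pd.DataFrame:
    """Tabular view: 1-based position, grid index, frequency, flags."""
    return pd.DataFrame(
        {
            "position": np.arange(1, len(seq) + 1),
            "tone_index": seq.tone_index,
            "frequency_hz": seq.frequencies_hz,
            "condition": seq.condition.value,
            "is_deviant": seq.is_deviant.astype(int),
        }
    )


def write_sequence(seq: StimulusSequence, path: str | Path) -> None:
    """Write a sequence as CSV with a JSON sidecar of its parameters."""
    path = Path(path)
    sequence_to_frame(seq).to_csv(path, index=False)
    meta = {
        "condition": seq.condition.value,
        "soa_ms": seq.soa_ms,
        "seed": seq.seed,
        "std_index": seq.std_index,
        "dev_index": seq.dev_index,
        "p_dev": seq.p_dev,
        "lead_in": seq.lead_in,
        "min_sep": seq.min_sep,
        "grid": {
            "frequencies": list(seq.grid.frequencies),
            "octave_step": seq.grid.octave_step,
            "intensity_db_spl": seq.grid.intensity_db_spl,
            "tone_duration_ms": seq.grid.tone_duration_ms,
            "ramp_ms": seq.grid.ramp_ms,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_sequence(path: str | Path) -> StimulusSequence:
    """Read a sequence CSV written by :func:`write_sequence`."""
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    grid = ToneGrid(
        frequencies=tuple(meta["grid"]["frequencies"]),
        octave_step=meta["grid"]["octave_step"],
        intensity_db_spl=meta["grid"]["intensity_db_spl"],
        tone_duration_ms=meta["grid"]["tone_duration_ms"],
        ramp_ms=meta["grid"]["ramp_ms"],
    )
    return StimulusSequence(
        condition=Condition(meta["condition"]),
        grid=grid,
        tone_index=df["tone_index"].to_numpy(),
        is_deviant=df["is_deviant"].to_numpy().astype(bool),
        soa_ms=meta["soa_ms"],
        seed=meta["seed"],
        std_index=meta["std_index"],
        dev_index=meta["dev_index"],
        p_dev=meta["p_dev"],
        lead_in=meta["lead_in"],
        min_sep=meta["min_sep"],
    )
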