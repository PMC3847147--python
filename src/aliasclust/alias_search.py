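"""Candidate technical-alias pair generation.

A peak at apparent m/z ``M`` may be the same protein as a peak near ``M/z``
for charge states z = 2, 3, or near ``z * M`` for aggregates (dimers,
trimers), or near ``M`` itself in a spectrum acquired under a different
condition (laser energy, array surface, chromatographic fraction).  Because
SELDI mass accuracy is modest, matches are accepted inside a mass window
whose total width is a percentage of the expected mass, with the percentage
depending on the mass range (instrument calibration degrades with mass).

Candidate generation runs in four steps of increasing scope:

1. within one (fraction, surface, energy) condition — integer-multiple
   relations only;
2. across laser energies on one surface in one fraction;
3. across surfaces within one fraction;
4. across fractions.

Steps 2-4 test both same-mass matches (multiple = 1) and integer-multiple
relations.  Peaks below the lowest window bin (2,000 Da by default) are
excluded from the search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import pandas as pd

from .errors import MassOutOfRangeError, TableFormatError
from .io_tables import PeakTable, _sniff_separator

#: default mass-range -> window-percentage bins (low_da, high_da, total width
#: as a fraction of the expected mass).  The 0.5% bin is extended to
#: 100,000 Da and masses above 200,000 reuse the 1% bin.
DEFAULT_WINDOW_BINS = (
    (2_000.0, 10_000.0, 0.001),
    (10_000.0, 30_000.0, 0.0015),
    (30_000.0, 100_000.0, 0.005),
    (100_000.0, math.inf, 0.01),
)

#: charge states / aggregate orders beyond this are not searched for
DEFAULT_MAX_MULTIPLE = 3


@dataclass(frozen=True)
class MassWindowTable:
    """Ordered, non-overlapping mass bins mapping a mass to a window width."""

    bins: tuple[tuple[float, float, float], ...] = DEFAULT_WINDOW_BINS

    def __post_init__(self) -> None:
        prev_high = -math.inf
        for low, high, pct in self.bins:
            if not (low < high):
                raise TableFormatError(f"empty window bin ({low}, {high})")
            if low < prev_high:
                raise TableFormatError("window bins overlap or are unsorted")
            if not (0.0 < pct <= 0.05):
                raise TableFormatError(f"window percentage {pct} outside (0, 0.05]")
            prev_high = high

    @property
    def min_mass(self) -> float:
        return self.bins[0][0]

    def window_pct(self, mass_da: float) -> float:
        """Total window width as a fraction of ``mass_da``."""
        if mass_da < self.min_mass:
            raise MassOutOfRangeError(
                f"mass {mass_da} below lowest window bin ({self.min_mass})"
            )
        for low, high, pct in self.bins:
            if low <= mass_da < high:
                return pct
        # above the last finite bound: reuse the topmost bin
        return self.bins[-1][2]


def read_window_table(path) -> MassWindowTable:
    """Read a window table override (columns low_da, high_da, window_pct)."""
    with open(path, "r", encoding="utf-8") as fh:
        sep = _sniff_separator(fh.readline())
    df = pd.read_csv(path, sep=sep)
    required = {"low_da", "high_da", "window_pct"}
    if not required.issubset(df.columns):
        raise TableFormatError(f"window table must have columns {sorted(required)}")
    bins = tuple(
        (float(r.low_da), float(r.high_da), float(r.window_pct))
        for r in df.sort_values("low_da").itertuples(index=False)
    )
    return MassWindowTable(bins)


class WindowBounds(NamedTuple):
    """A search window: rounded bounds for reporting, exact for comparisons."""

    low: int
    high: int
    low_exact: float
    high_exact: float

    def contains(self, mass_da: float) -> bool:
        return self.low_exact <= mass_da <= self.high_exact


def window_bounds(
    expected_mass: float, windows: MassWindowTable | None = None
) -> WindowBounds:
    """Search window centered at ``expected_mass``.

    The total width is the bin's percentage of the expected mass, i.e. the
    interval ``expected_mass * (1 +/- pct/2)``.  Reported integer bounds are
    rounded half-to-even; membership tests use the exact floats.

    >>> window_bounds(33_000.0)[:2]
    (32918, 33082)
    """
    windows = windows or MassWindowTable()
    pct = windows.window_pct(expected_mass)
    half = 0.5 * pct * expected_mass
    low_exact = expected_mass - half
    high_exact = expected_mass + half
    return WindowBounds(round(low_exact), round(high_exact), low_exact, high_exact)


def integer_multiple_match(
    mass_a: float,
    mass_b: float,
    windows: MassWindowTable | None = None,
    max_multiple: int = DEFAULT_MAX_MULTIPLE,
) -> Optional[int]:
    """Smallest multiple m in 2..max_multiple with mass_b inside the window
    around mass_a / m, or None.

    The window is evaluated at the expected (divided) mass, so a dimer
    relation (a = 2b) and a charge-state z = 2 relation (b = a/2) are the
    same test.  Requires ``mass_a >= mass_b > 0``.
    """
    if not (mass_a >= mass_b > 0):
        raise ValueError(f"need mass_a >= mass_b > 0, got ({mass_a}, {mass_b})")
    windows = windows or MassWindowTable()
    for m in range(2, max_multiple + 1):
        expected = mass_a / m
        try:
            bounds = window_bounds(expected, windows)
        except MassOutOfRangeError:
            break  # expected masses only shrink as m grows
        if bounds.contains(mass_b):
            return m
    return None


def same_mass_match(
    mass_a: float, mass_b: float, windows: MassWindowTable | None = None
) -> bool:
    """True iff mass_b lies inside the window centered at mass_a (multiple 1)."""
    return window_bounds(mass_a, windows).contains(mass_b)


@dataclass(frozen=True)
class CandidatePair:
    """An unordered candidate pair, oriented so mass_a >= mass_b."""

    peak_a: tuple[str, str, str, str]
    peak_b: tuple[str, str, str, str]
    mass_a: float
    mass_b: float
    multiple: int
    step: int


def _in_step_scope(pa, pb, step: int) -> bool:
    """Whether an (unordered) peak pair belongs to a step's candidate scope.

    The scopes partition all pairs: step 1 same condition; step 2 same
    fraction+surface, different energy; step 3 same fraction, different
    surface; step 4 different fraction.
    """
    if step == 1:
        return (
            pa.fraction == pb.fraction
            and pa.surface == pb.surface
            and pa.energy == pb.energy
        )
    if step == 2:
        return (
            pa.fraction == pb.fraction
            and pa.surface == pb.surface
            and pa.energy != pb.energy
        )
    if step == 3:
        return pa.fraction == pb.fraction and pa.surface != pb.surface
    if step == 4:
        return pa.fraction != pb.fraction
    raise ValueError(f"step must be 1-4, got {step}")


def generate_candidates(
    table: PeakTable,
    step: int,
    windows: MassWindowTable | None = None,
    max_multiple: int = DEFAULT_MAX_MULTIPLE,
) -> list[CandidatePair]:
    """All candidate pairs for one algorithm step, deterministically ordered.

    Step 1 tests integer-multiple relations only (a same-mass pair within
    one condition would be two distinct detected peaks, not aliases); steps
    2-4 additionally test same-mass matches across conditions.  Pairs are
    sorted by (mass_a, mass_b, peak ids).
    """
    windows = windows or MassWindowTable()
    eligible = [p for p in table.peaks if p.mass_da >= windows.min_mass]
    out: list[CandidatePair] = []
    for i in range(len(eligible)):
        for j in range(i + 1, len(eligible)):
            p, q = eligible[i], eligible[j]
            if not _in_step_scope(p, q, step):
                continue
            # orient: a is the heavier peak (tie: stable input order)
            a, b = (p, q) if p.mass_da >= q.mass_da else (q, p)
            multiple: Optional[int] = None
            if step >= 2 and same_mass_match(a.mass_da, b.mass_da, windows):
                multiple = 1
            else:
                multiple = integer_multiple_match(
                    a.mass_da, b.mass_da, windows, max_multiple
                )
            if multiple is not None:
                out.append(
                    CandidatePair(
                        peak_a=a.peak_id,
                        peak_b=b.peak_id,
                        mass_a=a.mass_da,
                        mass_b=b.mass_da,
                        multiple=multiple,
                        step=step,
                    )
                )
    out.sort(key=lambda c: (c.mass_a, c.mass_b, c.peak_a, c.peak_b))
    return out


def applicable_steps(table: PeakTable) -> dict[int, bool]:
    """Which of the four steps can produce candidates for this table."""
    energies = {(p.fraction, p.surface, p.energy) for p in table.peaks}
    surfaces = {p.surface for p in table.peaks}
    fractions = {p.fraction for p in table.peaks}
    multi_energy = len({e for (_, _, e) in energies}) > 1
    return {
        1: True,
        2: multi_energy,
        3: len(surfaces) > 1,
        4: len(fractions) > 1,
    }
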