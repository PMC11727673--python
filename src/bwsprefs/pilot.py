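"""Pilot-phase Likert ceiling screen.

Before fielding the best-worst questionnaire, candidate outcomes were
rated on a 1-10 importance scale by a small pilot sample.  Likert ratings
of importance cluster at the scale ceiling, so the screen keeps only the
items whose mean rating clears a cutoff (default 8: items averaging below
8 are removed, a mean of exactly 8 is retained) — in the emulated study
this reduced 19 candidate outcomes to the final 13.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

RATING_MIN, RATING_MAX = 1.0, 10.0


@dataclass(frozen=True)
class PilotTable:
    """Respondents x items rating table on the 1-10 scale."""

    ratings: pd.DataFrame  # rows respondents, columns item labels

    def __post_init__(self) -> None:
        if self.ratings.shape[0] < 1:
            raise ValueError("pilot table needs at least one respondent")

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self.ratings.columns)

    @property
    def n_respondents(self) -> int:
        return len(self.ratings)


@dataclass(frozen=True)
class PilotScreenResult:
    retained: tuple[str, ...]
    dropped: tuple[str, ...]
    means: pd.Series


def screen_pilot(
    table: PilotTable, cutoff: float = 8.0, allow_missing: bool = False
) -> PilotScreenResult:
    """Partition items by mean rating: keep mean >= cutoff, drop mean < cutoff.

    Input column order is preserved in both partitions.  Ratings outside
    [1, 10] raise a data error naming the offending cell; missing ratings
    are disallowed unless ``allow_missing`` enables available-case means.
    """
    df = table.ratings
    for col in df.columns:
        series = df[col]
        bad_missing = series.isna()
        if bad_missing.any() and not allow_missing:
            row = df.index[bad_missing.argmax()]
            raise ValueError(
                f"missing rating at respondent {row!r}, item {col!r} "
                "(enable allow_missing for available-case means)"
            )
        valid = series.dropna()
        out = (valid < RATING_MIN) | (valid > RATING_MAX)
        if out.any():
            row = valid.index[np.argmax(out.values)]
            raise ValueError(
                f"rating {valid[row]!r} at respondent {row!r}, item {col!r} "
                f"is outside [{RATING_MIN:g}, {RATING_MAX:g}]"
            )
    means = df.mean(axis=0, skipna=allow_missing)
    retained = tuple(c for c in df.columns if means[c] >= cutoff)
    dropped = tuple(c for c in df.columns if means[c] < cutoff)
    return PilotScreenResult(retained, dropped, means)


#: Candidate outcomes dropped by the packaged pilot fixture.  Labels are
#: synthetic stand-ins: the real dropped candidates were not published.
_SYNTHETIC_DROPPED = (
    "scar appearance",
    "length of hospital stay",
    "out-of-pocket cost",
    "opioid use",
    "sleep quality",
    "return to work",
)

_FINAL_ITEMS = (
    "ADL", "Pain", "Reintervention", "Complication", "Quick ADL", "Hobby",
    "Quick Pain", "Quick Hobby", "Communication", "Knowledge", "Heard",
    "Positive emotions", "Negative emotions",
)


def example_pilot_table(n_respondents: int = 20, seed: int = 20230) -> PilotTable:
    """Synthetic 19-item pilot fixture with a visible ceiling effect.

    13 items average >= 8 (retained) and 6 average < 8 (dropped); several
    respondents rate everything 10, emulating the ceiling behaviour that
    motivates switching from ratings to best-worst scaling.  Individual
    ratings are synthetic — only the 19 -> 13 count structure mirrors the
    emulated study.
    """
    rng = np.random.default_rng(seed)
    items = list(_FINAL_ITEMS) + list(_SYNTHETIC_DROPPED)
    rng.shuffle(items)
    target = {name: (9.2 if name in _FINAL_ITEMS else 6.8) for name in items}
    n_ceiling = max(2, n_respondents // 5)  # raters who give 10 across the board
    rows = np.empty((n_respondents, len(items)))
    for j, name in enumerate(items):
        draws = np.clip(np.rint(rng.normal(target[name], 0.9, size=n_respondents)),
                        RATING_MIN, RATING_MAX)
        rows[:, j] = draws
    rows[:n_ceiling, :] = RATING_MAX
    df = pd.DataFrame(rows, columns=items,
                      index=[f"pilot{r + 1:02d}" for r in range(n_respondents)])
    table = PilotTable(df)
    result = screen_pilot(table)
    if len(result.retained) != len(_FINAL_ITEMS):  # pragma: no cover
        raise AssertionError("packaged pilot fixture drifted from the 19->13 structure")
    return table


def read_pilot_table(path) -> PilotTable:
    return PilotTable(pd.read_csv(path, sep="\t", index_col=0))


def write_pilot_table(path, table: PilotTable) -> None:
    table.ratings.to_csv(path, sep="\t", float_format="%.0f")
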