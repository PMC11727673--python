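"""Best-minus-worst counting scores.

Per choice set, the item picked most important scores +1, the item picked
least important scores -1, all other presented items 0.  Tallies are
summed over respondents and blocks, and standardized by the item's total
availability — its replication count ``r`` in the design times the number
of respondents — giving a score bounded in [-1, +1].  On complete data
the standardized scores sum to zero, since every choice set contributes
exactly one +1 and one -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .simulate import StudyDataset


class BWSDataError(ValueError):
    """Responses violate a structural requirement of the scorer."""


@dataclass(frozen=True)
class CountScore:
    item_id: str
    n_best: int
    n_worst: int
    availability: int

    @property
    def bw(self) -> int:
        return self.n_best - self.n_worst

    @property
    def standardized(self) -> float:
        return self.bw / self.availability


def count_scores(dataset: StudyDataset) -> list[CountScore]:
    """Tally best/worst picks per item over all complete respondents.

    Requires every response to be complete (apply the completeness filter
    first) so that availability — ``r`` appearances per questionnaire times
    the number of respondents — is exact.  Picks referencing an item not
    presented in their block raise a data-integrity error naming the
    respondent and block.
    """
    incomplete = [r.respondent_id for r in dataset.responses if not r.complete]
    if incomplete:
        raise BWSDataError(
            f"{len(incomplete)} incomplete response(s) present (e.g. {incomplete[0]!r}); "
            "apply the completeness filter before scoring"
        )
    q = dataset.questionnaire
    ids = q.item_ids
    block_members = [frozenset(ids[i] for i in blk) for blk in q.design.blocks]

    n_best = {i: 0 for i in ids}
    n_worst = {i: 0 for i in ids}
    for resp in dataset.responses:
        for bi, pick in resp.picks.items():
            best, worst = pick
            if best not in block_members[bi] or worst not in block_members[bi]:
                raise BWSDataError(
                    f"respondent {resp.respondent_id!r}, block {bi}: pick "
                    f"({best!r}, {worst!r}) references an item outside the block"
                )
            if best == worst:
                raise BWSDataError(
                    f"respondent {resp.respondent_id!r}, block {bi}: best equals worst"
                )
            n_best[best] += 1
            n_worst[worst] += 1

    availability = q.design.r * len(dataset.responses)
    return [CountScore(i, n_best[i], n_worst[i], availability) for i in ids]


def rank_items(scores: Sequence) -> list:
    """Stable descending sort by score; ties broken by item_id lexicographically.

    Accepts any sequence of objects exposing ``item_id`` and either
    ``standardized`` (counting scores) or ``beta`` (estimation results).
    """
    seen: set[str] = set()
    for s in scores:
        if s.item_id in seen:
            raise ValueError(f"duplicate item_id {s.item_id!r} in scores")
        seen.add(s.item_id)

    def key(s):
        value = s.standardized if hasattr(s, "standardized") else s.beta
        return (-value, s.item_id)

    return sorted(scores, key=key)
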