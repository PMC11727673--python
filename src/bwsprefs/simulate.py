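"""Synthetic best-worst scaling respondents.

The study whose structure this package emulates never deposited raw
choices, so every downstream stage is exercised on simulated data.  A
respondent carries a latent utility per item; in each block of ``k``
items they pick an ordered (best, worst) pair with probability
proportional to ``exp(u_best - u_worst)`` over the ``k*(k-1)`` ordered
pairs — the standard object-case MaxDiff choice rule, which matches the
package's default estimator so that simulation plus estimation form a
closed parameter-recovery loop.

Utility profiles are anchored on the published overall and per-phase
coefficient estimates for the anchored items (ADL, pain, reintervention,
complication, quick-ADL, quick-pain, negative emotions); the remaining
items, whose coefficients were not printed, are filled in by linear
interpolation of the rank gaps and flagged as interpolated.  Profiles are
centered to sum to zero, matching the sum-to-zero identification of the
estimator.

Respondent-level heterogeneity is a per-item normal perturbation drawn
once per respondent (default sd 0.3).  A master seed fans out to
per-respondent child seeds through a counter, so a dataset is
reproducible as a whole and any single respondent can be re-simulated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .design import BIBDesign, Questionnaire, build_questionnaire, generate_bibd
from .items import catalog_ids

PHASES = ("pre_op", "short_post", "long_post")
OVERALL = "overall"

#: Published overall coefficients for the items whose values were printed.
_OVERALL_ANCHORS = {
    "adl": 1.03,
    "pain": 0.65,
    "reintervention": 0.64,
    "complication": 0.58,
    "qadl": 0.29,
    "qpain": -0.04,
    "negative": -1.29,
}

#: Published per-phase coefficients (pre-op, short-term post, long-term post).
_PHASE_ANCHORS = {
    "pre_op": {"adl": 0.96, "pain": 0.66, "reintervention": 0.47, "complication": 0.76},
    "short_post": {"adl": 1.06, "pain": 0.57, "reintervention": 0.77, "complication": 0.50},
    "long_post": {"adl": 1.05, "pain": 0.71, "reintervention": 0.62, "complication": 0.56},
}

#: Items without printed coefficients, in the assumed rank order between
#: quick-ADL and negative emotions (physical outcomes above process items).
_INTERPOLATED_ORDER = ("hobby", "qhobby", "communication", "knowledge", "heard", "positive")

#: Published strata sizes: 36 pre-op, 55 short-term post, 62 long-term post
#: included, from 168 submitted questionnaires (15 incomplete).
STUDY_STRATA = {"pre_op": 36, "short_post": 55, "long_post": 62}
STUDY_N_EXCLUDED = 15

DEFAULT_HETEROGENEITY_SD = 0.3


@dataclass(frozen=True)
class UtilityProfile:
    """Latent mean utilities (sum-to-zero) plus respondent heterogeneity sd."""

    phase: str
    mean_utility: Mapping[str, float]
    heterogeneity_sd: float = DEFAULT_HETEROGENEITY_SD
    interpolated_items: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be nonnegative")
        total = sum(self.mean_utility.values())
        if abs(total) > 1e-8:
            raise ValueError(f"mean utilities must sum to 0, got {total!r}")

    def utilities_for(self, item_ids: Sequence[str]) -> np.ndarray:
        missing = [i for i in item_ids if i not in self.mean_utility]
        if missing:
            raise ValueError(f"profile {self.phase!r} lacks utilities for items {missing}")
        return np.array([self.mean_utility[i] for i in item_ids], dtype=float)


def _interpolated_profile(anchors: Mapping[str, float]) -> tuple[dict[str, float], tuple[str, ...]]:
    """Fill the unprinted items by linear rank-gap interpolation, then center.

    The unprinted items are spaced evenly between the quick-ADL and
    negative-emotions anchors (hobby above quick-pain, the process items
    below).  The full vector is then shifted to sum to zero: utilities are
    identified only up to an additive constant, so centering preserves
    every pairwise difference and the anchored ordering exactly.
    """
    hi, lo = anchors["qadl"], anchors["negative"]
    n_gap = len(_INTERPOLATED_ORDER) + 2  # slots between the two anchors
    step = (hi - lo) / n_gap
    values = dict(anchors)
    slot = 1
    for item in _INTERPOLATED_ORDER:
        values[item] = hi - slot * step
        if item == "hobby":
            slot += 2  # leave the next slot for the printed qpain anchor
        else:
            slot += 1
    shift = sum(values.values()) / len(values)
    values = {k: v - shift for k, v in values.items()}
    return values, _INTERPOLATED_ORDER


def default_profile(
    phase: str, heterogeneity_sd: float = DEFAULT_HETEROGENEITY_SD
) -> UtilityProfile:
    """Packaged utility profile for ``"overall"`` or one of the three phases.

    Reproduces the published ordering: ADL highest everywhere; pain dips in
    the short post-operative window; reintervention matters more after
    surgery; complication matters more before.
    """
    if phase == OVERALL:
        anchors = dict(_OVERALL_ANCHORS)
    elif phase in PHASES:
        anchors = dict(_OVERALL_ANCHORS)
        anchors.update(_PHASE_ANCHORS[phase])
    else:
        raise ValueError(f"unknown phase {phase!r}; expected {OVERALL!r} or one of {PHASES}")
    values, interp = _interpolated_profile(anchors)
    return UtilityProfile(phase, values, heterogeneity_sd, interp)


@dataclass
class ResponseSet:
    """One respondent's picks: per design block, (best_id, worst_id) or None."""

    respondent_id: str
    phase: str
    picks: dict[int, tuple[str, str] | None]

    @property
    def complete(self) -> bool:
        return all(p is not None for p in self.picks.values())

    def n_answered(self) -> int:
        return sum(p is not None for p in self.picks.values())


@dataclass
class StudyDataset:
    """A simulated (or loaded) study: questionnaire plus response sets."""

    questionnaire: Questionnaire
    responses: list[ResponseSet]
    master_seed: int | None = None
    profile_used: dict = field(default_factory=dict)

    @property
    def design(self) -> BIBDesign:
        return self.questionnaire.design

    @property
    def strata_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for resp in self.responses:
            counts[resp.phase] = counts.get(resp.phase, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.responses)

    def subset(self, responses: list[ResponseSet]) -> "StudyDataset":
        return StudyDataset(self.questionnaire, responses, self.master_seed,
                            dict(self.profile_used))


def _pair_table(k: int) -> np.ndarray:
    """All ordered (best, worst) position pairs within a block of size k."""
    return np.array([(i, j) for i in range(k) for j in range(k) if i != j], dtype=int)


def maxdiff_pair_probabilities(utilities: np.ndarray) -> dict[tuple[int, int], float]:
    """Exact choice probabilities for each ordered pair in one block.

    ``utilities`` holds the latent utilities of the k items in the block.
    Probability of picking item i best and item j worst is
    ``exp(u_i - u_j)`` normalized over all ordered pairs.
    """
    k = len(utilities)
    pairs = _pair_table(k)
    w = np.exp(utilities[pairs[:, 0]] - utilities[pairs[:, 1]])
    w /= w.sum()
    return {(int(i), int(j)): float(p) for (i, j), p in zip(pairs, w)}


def simulate_response(
    questionnaire: Questionnaire,
    profile: UtilityProfile,
    rng_seed: int | np.random.SeedSequence,
    respondent_id: str = "r0",
    phase: str | None = None,
) -> ResponseSet:
    """Draw one complete respondent under the MaxDiff choice rule.

    The respondent's utilities are the profile means plus one normal
    perturbation per item (sd = ``profile.heterogeneity_sd``), drawn once;
    each block's (best, worst) pair is then sampled independently.
    Reproducible given the seed.
    """
    rng = np.random.default_rng(rng_seed)
    ids = questionnaire.item_ids
    u = profile.utilities_for(ids)
    if profile.heterogeneity_sd > 0:
        u = u + rng.normal(0.0, profile.heterogeneity_sd, size=len(u))

    design = questionnaire.design
    blocks = np.asarray(design.blocks, dtype=int)          # (b, k)
    pairs = _pair_table(design.k)                           # (k*(k-1), 2)
    bu = u[blocks]                                          # (b, k)
    w = np.exp(bu[:, pairs[:, 0]] - bu[:, pairs[:, 1]])     # (b, n_pairs)
    cdf = np.cumsum(w, axis=1)
    draws = rng.random(design.b) * cdf[:, -1]
    picks: dict[int, tuple[str, str] | None] = {}
    for bi in range(design.b):
        pi = int(np.searchsorted(cdf[bi], draws[bi], side="right"))
        best_pos, worst_pos = pairs[pi]
        picks[bi] = (ids[blocks[bi, best_pos]], ids[blocks[bi, worst_pos]])
    return ResponseSet(respondent_id, phase or profile.phase, picks)


def mcar_missingness(
    response: ResponseSet, rng: np.random.Generator, n_missing_range: tuple[int, int] = (1, 3)
) -> ResponseSet:
    """Delete 1-3 pick pairs completely at random, making the response incomplete."""
    lo, hi = n_missing_range
    n_blocks = len(response.picks)
    n_missing = int(rng.integers(lo, min(hi, n_blocks) + 1))
    drop = rng.choice(sorted(response.picks), size=n_missing, replace=False)
    picks = dict(response.picks)
    for bi in drop:
        picks[int(bi)] = None
    return ResponseSet(response.respondent_id, response.phase, picks)


def simulate_study(
    questionnaire: Questionnaire,
    strata_counts: Mapping[str, int],
    profiles: Mapping[str, UtilityProfile],
    n_submitted_extra: int = 0,
    missingness_rule: Callable[[ResponseSet, np.random.Generator], ResponseSet] = mcar_missingness,
    master_seed: int = 0,
) -> StudyDataset:
    """Simulate a phase-stratified study with optional incomplete submissions.

    Produces ``strata_counts[phase]`` complete respondents per stratum plus
    ``n_submitted_extra`` incomplete ones whose phases are drawn in
    proportion to the strata.  Each incomplete respondent is a fully
    simulated respondent with at least one pick pair deleted by
    ``missingness_rule``.  Deterministic given ``master_seed``.
    """
    for phase, n in strata_counts.items():
        if n <= 0:
            raise ValueError(f"stratum {phase!r} has non-positive count {n}")
        if phase not in profiles:
            raise ValueError(f"no utility profile supplied for phase {phase!r}")

    ss = np.random.SeedSequence(master_seed)
    n_complete = sum(strata_counts.values())
    n_total = n_complete + n_submitted_extra
    child_seeds = ss.spawn(n_total + 1)
    aux_rng = np.random.default_rng(child_seeds[-1])

    phases_order = [p for p in list(PHASES) + [OVERALL] if p in strata_counts]
    phases_order += [p for p in strata_counts if p not in phases_order]

    responses: list[ResponseSet] = []
    counter = 0
    width = max(3, len(str(n_total)))
    for phase in phases_order:
        for _ in range(strata_counts[phase]):
            rid = f"p{counter + 1:0{width}d}"
            responses.append(
                simulate_response(questionnaire, profiles[phase], child_seeds[counter], rid, phase)
            )
            counter += 1

    phase_probs = np.array([strata_counts[p] for p in phases_order], dtype=float)
    phase_probs /= phase_probs.sum()
    for _ in range(n_submitted_extra):
        phase = phases_order[int(aux_rng.choice(len(phases_order), p=phase_probs))]
        rid = f"p{counter + 1:0{width}d}"
        full = simulate_response(questionnaire, profiles[phase], child_seeds[counter], rid, phase)
        incomplete = missingness_rule(full, aux_rng)
        if incomplete.complete:
            raise ValueError("missingness_rule returned a complete response")
        responses.append(incomplete)
        counter += 1

    return StudyDataset(
        questionnaire,
        responses,
        master_seed=master_seed,
        profile_used={p: profiles[p].phase for p in phases_order},
    )


def study_emulation(
    master_seed: int,
    questionnaire: Questionnaire | None = None,
    heterogeneity_sd: float = DEFAULT_HETEROGENEITY_SD,
) -> StudyDataset:
    """The packaged study-emulation preset.

    168 submitted questionnaires on the 13-item, 13-block, 4-per-block
    design: 36/55/62 complete respondents in the pre-op / short-term post /
    long-term post strata driven by the per-phase default profiles, plus 15
    incomplete submissions that the completeness filter removes.
    """
    if questionnaire is None:
        design = generate_bibd(13, 4)
        questionnaire = build_questionnaire(design, layout_seed=master_seed)
    profiles = {p: default_profile(p, heterogeneity_sd) for p in PHASES}
    return simulate_study(
        questionnaire,
        STUDY_STRATA,
        profiles,
        n_submitted_extra=STUDY_N_EXCLUDED,
        master_seed=master_seed,
    )


def apply_completeness_filter(
    dataset: StudyDataset,
) -> tuple[StudyDataset, list[ResponseSet]]:
    """Partition into included (complete) respondents and excluded (incomplete) ones.

    Mirrors the enrollment rule that respondents failing to answer every
    required question are dropped before analysis.
    """
    included = [r for r in dataset.responses if r.complete]
    excluded = [r for r in dataset.responses if not r.complete]
    return dataset.subset(included), excluded
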