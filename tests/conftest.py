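import numpy as np
import pytest

from bwsprefs import (
    BIBDesign,
    ResponseSet,
    StudyDataset,
    apply_completeness_filter,
    build_questionnaire,
    fit_maxdiff,
    generate_bibd,
    study_emulation,
)
from bwsprefs.items import generic_catalog


@pytest.fixture(scope="session")
def design13():
    return generate_bibd(13, 4)


@pytest.fixture(scope="session")
def questionnaire13(design13):
    return build_questionnaire(design13, layout_seed=0)


@pytest.fixture(scope="session")
def emulated():
    """One study-emulation dataset shared across tests (seed fixed)."""
    return study_emulation(master_seed=7)


@pytest.fixture(scope="session")
def included(emulated):
    inc, _ = apply_completeness_filter(emulated)
    return inc


@pytest.fixture(scope="session")
def overall_fit(included):
    return fit_maxdiff(included)


@pytest.fixture(scope="session")
def tiny_questionnaire():
    """Three identical blocks over three items: the smallest interesting case."""
    design = BIBDesign(v=3, b=3, k=3, r=3, lam=3,
                       blocks=((0, 1, 2), (0, 1, 2), (0, 1, 2)))
    return build_questionnaire(design, layout_seed=0, catalog=generic_catalog(3))


def scripted_dataset(questionnaire, picks_per_respondent):
    """Build a StudyDataset from explicit picks.

    ``picks_per_respondent``: list of dicts block_id -> (best_id, worst_id).
    """
    responses = [
        ResponseSet(f"s{i}", "overall", dict(picks))
        for i, picks in enumerate(picks_per_respondent)
    ]
    return StudyDataset(questionnaire, responses)


def random_scripted_picks(questionnaire, rng):
    """Uniformly random valid picks for every block of one respondent."""
    ids = questionnaire.item_ids
    picks = {}
    for bi, blk in enumerate(questionnaire.design.blocks):
        pair = rng.choice(len(blk), size=2, replace=False)
        picks[bi] = (ids[blk[pair[0]]], ids[blk[pair[1]]])
    return picks
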