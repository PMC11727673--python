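"""Choice-item catalogs for object-case best-worst scaling surveys.

A catalog is an ordered tuple of :class:`ChoiceItem`.  The packaged default
catalog holds the 13 quality-of-care outcomes used in the total joint
arthroplasty preference questionnaire (activities of daily living, pain,
reintervention, ...), three of which are "quick" time-to-achievement
variants of another item.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True)
class ChoiceItem:
    """One attribute a respondent can pick as most/least important.

    Parameters
    ----------
    item_id : str
        Short stable token used in files and result tables.
    label : str
        Display name, e.g. ``"ADL"``.
    description : str
        One-sentence description shown to respondents.
    is_quick_variant : bool
        True for "quick ..." time-to-achievement variants of another item.
    """

    item_id: str
    label: str
    description: str = ""
    is_quick_variant: bool = False


_DEFAULT_ROWS = [
    ("adl", "ADL",
     "Improved motion and daily function (e.g. walking stairs, getting out of a chair).", False),
    ("pain", "Pain", "Relief of pain.", False),
    ("reintervention", "Reintervention",
     "Avoiding needing a repeat surgery in the future.", False),
    ("complication", "Complication",
     "Avoiding complications (e.g. infection, readmission).", False),
    ("qadl", "Quick ADL",
     "Quick improvement in motion and daily function.", True),
    ("hobby", "Hobby",
     "Improvement in ability to participate in specific activities such as hobbies or sports.", False),
    ("qpain", "Quick Pain", "Quick resolution of pain.", True),
    ("qhobby", "Quick Hobby",
     "Quick improvement in ability to participate in hobbies or sports.", True),
    ("communication", "Communication",
     "Access to open, frequent communication with the care team.", False),
    ("knowledge", "Knowledge",
     "Gaining knowledge and feeling informed about the process of surgical care.", False),
    ("heard", "Heard", "Feeling heard and respected by the care team.", False),
    ("positive", "Positive emotions",
     "Increased positive emotions (e.g. confidence and peace of mind).", False),
    ("negative", "Negative emotions",
     "Minimized negative emotions (e.g. fear, uncertainty, sadness).", False),
]


def default_catalog() -> tuple[ChoiceItem, ...]:
    """The packaged 13-item quality-of-care outcome catalog."""
    return tuple(ChoiceItem(*row) for row in _DEFAULT_ROWS)


def generic_catalog(v: int) -> tuple[ChoiceItem, ...]:
    """A neutral catalog of ``v`` items with ids ``i00 .. i{v-1}``."""
    width = max(2, len(str(v - 1)))
    return tuple(
        ChoiceItem(f"i{j:0{width}d}", f"Item {j}") for j in range(v)
    )


def validate_catalog(catalog: Sequence[ChoiceItem]) -> None:
    """Raise ``ValueError`` on duplicate or empty item ids."""
    seen: set[str] = set()
    for item in catalog:
        if not item.item_id:
            raise ValueError("catalog contains an empty item_id")
        if item.item_id in seen:
            raise ValueError(f"duplicate item_id in catalog: {item.item_id!r}")
        seen.add(item.item_id)


def catalog_ids(catalog: Iterable[ChoiceItem]) -> tuple[str, ...]:
    return tuple(item.item_id for item in catalog)
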