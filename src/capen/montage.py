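"""The 10-site speech-articulation montage and its 21 analyzed pairs.

Ten 10-20-system electrodes cover five bilateral nodes of the cortical
speech articulation network: dorsolateral prefrontal cortex (F3/F4),
inferior frontal gyrus (F7/F8, with F7/F8 shifted onto the IFG at the
T3-Fz x F7-Cz crossing), primary motor cortex (C3/C4), the Sylvian
parietal-temporal region (T5/T6) and the inferior parietal lobe
(P3/P4). Connectivity is analyzed over 21 unordered pairs: 8 within
the left hemisphere, their 8 right-hemisphere mirrors, and the 5
homologous interhemispheric pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RecordingSite",
    "PairSet",
    "build_default_montage",
    "pairs_for",
    "ELECTRODE_REGIONS",
    "CATEGORIES",
    "LEFT_INTRA",
    "RIGHT_INTRA",
    "INTERHEMISPHERIC",
    "pair_name",
]

#: electrode -> (cortical region, hemisphere); F7/F8 placement is the
#: modified IFG position (metadata only, does not alter computation).
ELECTRODE_REGIONS: dict[str, tuple[str, str]] = {
    "F3": ("DLPFC", "left"),
    "F4": ("DLPFC", "right"),
    "F7": ("IFG", "left"),
    "F8": ("IFG", "right"),
    "C3": ("M1", "left"),
    "C4": ("M1", "right"),
    "T5": ("SPT", "left"),
    "T6": ("SPT", "right"),
    "P3": ("IPL", "left"),
    "P4": ("IPL", "right"),
}

F7_PLACEMENT_NOTE = (
    "F7/F8 placed over the inferior frontal gyrus at the crossing point "
    "of T3-Fz and F7-Cz (and its right mirror), not the standard 10-20 "
    "position."
)

CATEGORIES = ("left-intra", "right-intra", "interhemispheric")

# Report row order: left-intra block, right-intra block, homologous block.
LEFT_INTRA: tuple[tuple[str, str], ...] = (
    ("F3", "F7"),
    ("F3", "P3"),
    ("F7", "C3"),
    ("P3", "F7"),
    ("P3", "C3"),
    ("T5", "C3"),
    ("T5", "P3"),
    ("T5", "F7"),
)
RIGHT_INTRA: tuple[tuple[str, str], ...] = (
    ("F4", "F8"),
    ("F4", "P4"),
    ("F8", "C4"),
    ("P4", "F8"),
    ("P4", "C4"),
    ("T6", "C4"),
    ("T6", "P4"),
    ("T6", "F8"),
)
INTERHEMISPHERIC: tuple[tuple[str, str], ...] = (
    ("F3", "F4"),
    ("F7", "F8"),
    ("C3", "C4"),
    ("P3", "P4"),
    ("T5", "T6"),
)


def pair_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}-{pair[1]}"


@dataclass(frozen=True)
class RecordingSite:
    electrode: str
    region: str
    hemisphere: str


@dataclass(frozen=True)
class PairSet:
    """The analyzed electrode pairs with their hemisphere categories."""

    pairs: tuple[tuple[str, str], ...]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.categories):
            raise ValueError("pairs and categories must align")
        seen = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"pair joins {a} to itself")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate pair {a}-{b}")
            seen.add(key)

    def pairs_for(self, category: str) -> list[tuple[str, str]]:
        if category not in CATEGORIES:
            raise ValueError(
                f"unknown category {category!r}; expected one of {CATEGORIES}"
            )
        return [p for p, c in zip(self.pairs, self.categories) if c == category]

    def category_of(self, pair: tuple[str, str]) -> str:
        key = frozenset(pair)
        for p, c in zip(self.pairs, self.categories):
            if frozenset(p) == key:
                return c
        raise KeyError(f"pair {pair_name(pair)} not in pair set")

    def names(self) -> list[str]:
        return [pair_name(p) for p in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def build_default_montage() -> tuple[list[RecordingSite], PairSet]:
    """The 10 analyzed sites and their 21 categorized pairs, in report order."""
    sites = [
        RecordingSite(e, region, hemi)
        for e, (region, hemi) in ELECTRODE_REGIONS.items()
    ]
    pairs = LEFT_INTRA + RIGHT_INTRA + INTERHEMISPHERIC
    categories = (
        ("left-intra",) * len(LEFT_INTRA)
        + ("right-intra",) * len(RIGHT_INTRA)
        + ("interhemispheric",) * len(INTERHEMISPHERIC)
    )
    return sites, PairSet(pairs, categories)


def pairs_for(category: str) -> list[tuple[str, str]]:
    """Pairs of the default montage belonging to ``category``, in stable order."""
    _, pair_set = build_default_montage()
    return pair_set.pairs_for(category)


#: Channel order used throughout for 10-channel arrays.
CHANNEL_ORDER: tuple[str, ...] = tuple(ELECTRODE_REGIONS)
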