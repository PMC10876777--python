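"""Default content-unit dictionary for a picnic-scene description task.

The scene inventory has 32 units. Five units are central to the shipped
analyses — the theme unit "picnic", the small central "fisherman" (the
designated focus unit), "basket", "girl" (grouping the synonym
"daughter") and "clouds" — with morphological/synonym variants grouped.
The remaining 27 units are plausible scene items supplied so the
dictionary has the full instrument size; users reproducing a specific
study should supply their own dictionary file with the exact inventory.
"""

from __future__ import annotations

from .types import ContentUnitDictionary

THEME_UNIT = "picnic"
FOCUS_UNIT = "fisherman"

#: unit id -> variant forms (first form is the canonical single-word lemma).
PICNIC_UNITS: dict[str, list[str]] = {
    "picnic": ["picnic"],
    "fisherman": ["fisherman", "angler"],
    "basket": ["basket", "hamper", "picnic basket"],
    "girl": ["girl", "daughter"],
    "clouds": ["cloud"],
    "tree": ["tree"],
    "house": ["house", "home"],
    "flag": ["flag"],
    "sailboat": ["sailboat", "boat", "sail boat"],
    "lake": ["lake", "pond", "water"],
    "pier": ["pier", "dock"],
    "dog": ["dog", "puppy"],
    "man": ["man", "father", "husband"],
    "woman": ["woman", "mother", "wife"],
    "blanket": ["blanket"],
    "radio": ["radio"],
    "book": ["book"],
    "kite": ["kite"],
    "car": ["car"],
    "garage": ["garage"],
    "shore": ["shore", "beach"],
    "ball": ["ball"],
    "shoes": ["shoe"],
    "pail": ["pail", "bucket"],
    "shovel": ["shovel", "spade"],
    "sand": ["sand"],
    "bench": ["bench"],
    "fence": ["fence"],
    "bird": ["bird"],
    "hat": ["hat"],
    "cup": ["cup"],
    "bottle": ["bottle"],
}


def default_picnic_dictionary() -> ContentUnitDictionary:
    """The shipped 32-unit picnic dictionary with "picnic" as theme."""
    return ContentUnitDictionary(PICNIC_UNITS, theme_unit=THEME_UNIT)
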