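"""Free fatty acid (FFA) nomenclature and panel handling.

Analytes are identified by the lipid shorthand ``C<carbons>:<double bonds>``
with an optional omega/isomer suffix (e.g. ``C18:2n6c`` for linoleic acid).
Free-text names such as "nonanoic acid" are mapped onto the shorthand by a
built-in synonym dictionary; unknown names pass through unchanged with a
warning so that user-supplied panels are never silently truncated.

Radar-chart areas downstream depend on axis order, so the panel carries an
explicit, stable ordering.  The canonical rule sorts by carbon count, then
double-bond count, then the suffix lexicographically; ids that do not parse
sort after all parsable ids.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "AnalytePanel",
    "normalize_analyte_name",
    "canonical_sort_key",
    "parse_analyte_id",
]

_SHORTHAND_RE = re.compile(r"^[Cc](\d+):(\d+)(.*)$")

# Free-text name (lower-case) -> canonical shorthand.  Keys cover the common
# GC-MS FFA panel; the dictionary is extensible via register_synonym().
_SYNONYMS: dict[str, str] = {
    "hexanoic acid": "C6:0",
    "caproic acid": "C6:0",
    "octanoic acid": "C8:0",
    "caprylic acid": "C8:0",
    "nonanoic acid": "C9:0",
    "pelargonic acid": "C9:0",
    "decanoic acid": "C10:0",
    "capric acid": "C10:0",
    "undecanoic acid": "C11:0",
    "dodecanoic acid": "C12:0",
    "lauric acid": "C12:0",
    "tridecanoic acid": "C13:0",
    "myristic acid": "C14:0",
    "tetradecanoic acid": "C14:0",
    "pentadecanoic acid": "C15:0",
    "palmitic acid": "C16:0",
    "hexadecanoic acid": "C16:0",
    "palmitoleic acid": "C16:1",
    "cis-9-palmitoleic acid": "C16:1",
    "heptadecanoic acid": "C17:0",
    "margaric acid": "C17:0",
    "stearic acid": "C18:0",
    "octadecanoic acid": "C18:0",
    "oleic acid": "C18:1n9c",
    "elaidic acid": "C18:1n9t",
    "linoleic acid": "C18:2n6c",
    # Some published tables attach the C18:2n6c shorthand to
    # "trans-9-octadecenoic acid", which chemically is a C18:1 isomer.  The
    # mapping keys on the shorthand and keeps the name as a display synonym
    # rather than resolving the chemistry.
    "trans-9-octadecenoic acid": "C18:2n6c",
    "alpha-linolenic acid": "C18:3n3",
    "linolenic acid": "C18:3n3",
    "nonadecylic acid": "C19:0",
    "nonadecanoic acid": "C19:0",
    "arachidic acid": "C20:0",
    "eicosanoic acid": "C20:0",
    "gondoic acid": "C20:1",
    "arachidonic acid": "C20:4n6",
    "heneicosanoic acid": "C21:0",
    "behenic acid": "C22:0",
    "docosahexaenoic acid": "C22:6n3",
    "lignoceric acid": "C24:0",
}

# Reverse map for optional display names (first synonym registered wins).
_DISPLAY: dict[str, str] = {}
for _name, _sid in _SYNONYMS.items():
    _DISPLAY.setdefault(_sid, _name)


def register_synonym(name: str, analyte_id: str) -> None:
    """Extend the synonym dictionary at run time."""
    _SYNONYMS[name.strip().lower()] = analyte_id
    _DISPLAY.setdefault(analyte_id, name.strip().lower())


def parse_analyte_id(analyte_id: str) -> tuple[int, int, str] | None:
    """Split shorthand into (carbons, double bonds, suffix); None if unparsable."""
    m = _SHORTHAND_RE.match(analyte_id.strip())
    if m is None:
        return None
    return int(m.group(1)), int(m.group(2)), m.group(3)


def canonical_sort_key(analyte_id: str) -> tuple:
    """Canonical panel ordering: carbons, then double bonds, then suffix.

    Unparsable ids sort after all parsable ones, lexicographically.
    """
    parsed = parse_analyte_id(analyte_id)
    if parsed is None:
        return (1, analyte_id, 0, "")
    c, d, suffix = parsed
    return (0, "", c, d, suffix)


def normalize_analyte_name(raw: str) -> str:
    """Map a free-text or shorthand analyte name to its canonical id.

    Canonical shorthand is returned case-normalized (``c16:1`` -> ``C16:1``);
    known free-text names map through the synonym dictionary; unknown names
    pass through unchanged with a warning.

    Raises
    ------
    ValueError
        If `raw` is empty or whitespace-only.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError("analyte name must be a non-empty string")
    text = raw.strip()
    m = _SHORTHAND_RE.match(text)
    if m is not None:
        return f"C{int(m.group(1))}:{int(m.group(2))}{m.group(3)}"
    key = text.lower()
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    warnings.warn(f"unrecognized analyte name kept verbatim: {text!r}")
    return text


@dataclass(frozen=True)
class AnalytePanel:
    """An explicitly ordered list of analyte ids with optional display names."""

    analyte_ids: tuple[str, ...]
    display_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.analyte_ids)) != len(self.analyte_ids):
            raise ValueError("analyte ids must be unique within a panel")

    @classmethod
    def canonical(cls, analyte_ids) -> "AnalytePanel":
        """Build a panel in the canonical (carbon, double-bond, suffix) order."""
        ids = sorted(dict.fromkeys(analyte_ids), key=canonical_sort_key)
        display = {i: _DISPLAY[i] for i in ids if i in _DISPLAY}
        return cls(tuple(ids), display)

    def display_name(self, analyte_id: str) -> str:
        return self.display_names.get(analyte_id, analyte_id)

    def intersection(self, other: "AnalytePanel") -> "AnalytePanel":
        shared = set(self.analyte_ids) & set(other.analyte_ids)
        return AnalytePanel.canonical(shared)

    def __len__(self) -> int:
        return len(self.analyte_ids)

    def __iter__(self):
        return iter(self.analyte_ids)

    def __contains__(self, item) -> bool:
        return item in self.analyte_ids
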