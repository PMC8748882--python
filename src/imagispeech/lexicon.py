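"""Phoneme group tables and word decomposition into representation spaces.

Each phoneme belongs to groups along three representational dimensions:
articulatory (place: labial / coronal / dorsal), phonetic (manner: plosive /
fricative / nasal / approximant) and vocalic (vowel position: low/high x
front/back, or central).  A word is represented, per dimension, by the union
of its phonemes' groups; the discriminant groups of a word pair are those
present in exactly one of the two words (the set symmetric difference), and
the representation distance counts them.  An optional semantic dimension
uses a category-indicator distance (1 if the categories differ, else 0).
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

ARTICULATORY_GROUPS = frozenset({"labial", "coronal", "dorsal"})
PHONETIC_GROUPS = frozenset({"plosive", "fricative", "nasal", "approximant"})
VOCALIC_GROUPS = frozenset({"low-back", "low-front", "high-back", "high-front", "central"})
REPRESENTATIONS = ("articulatory", "phonetic", "vocalic")
ALLOWED = {
    "articulatory": ARTICULATORY_GROUPS,
    "phonetic": PHONETIC_GROUPS,
    "vocalic": VOCALIC_GROUPS,
}


def parse_ipa(ipa: str) -> list[str]:
    """Split an IPA string into phoneme symbols.

    One base character per phoneme; combining marks (e.g. the nasalization
    tilde) attach to the preceding base character.  Length marks, stress
    marks and whitespace are dropped.
    """
    drop = set(" ˈˌ.ː‿")
    out: list[str] = []
    for ch in ipa:
        if ch in drop:
            continue
        if unicodedata.combining(ch) and out:
            out[-1] += ch
        else:
            out.append(ch)
    return out


@dataclass
class GroupTable:
    """IPA symbol -> group memberships per representation."""

    groups: dict  # phoneme -> {representation: frozenset}

    def __post_init__(self) -> None:
        for ph, reps in self.groups.items():
            for rep, gs in reps.items():
                bad = set(gs) - ALLOWED[rep]
                if bad:
                    raise ValueError(f"unknown {rep} group(s) {sorted(bad)} for phoneme {ph!r}")
            is_consonant = bool(reps.get("articulatory") or reps.get("phonetic"))
            is_vowel = bool(reps.get("vocalic"))
            if is_consonant and is_vowel:
                raise ValueError(f"phoneme {ph!r} mixes consonant and vowel groups")
            if not (is_consonant or is_vowel):
                raise ValueError(f"phoneme {ph!r} belongs to no group")

    def __contains__(self, phoneme: str) -> bool:
        return phoneme in self.groups

    def lookup(self, phoneme: str, representation: str) -> frozenset:
        if phoneme not in self.groups:
            raise KeyError(f"unknown phoneme {phoneme!r}")
        return self.groups[phoneme].get(representation, frozenset())


def load_group_table(path: str | Path | None = None) -> GroupTable:
    """Load the long-format group table TSV (phoneme, representation, group).

    Without a path, the packaged curated table is used.
    """
    if path is None:
        source = resources.files("imagispeech.data").joinpath("group_table.tsv")
        df = pd.read_csv(source.open("r", encoding="utf-8"), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    groups: dict = {}
    for _, row in df.iterrows():
        ph = unicodedata.normalize("NFC", str(row["phoneme"]))
        rep = str(row["representation"])
        if rep not in ALLOWED:
            raise ValueError(f"unknown representation {rep!r}")
        groups.setdefault(ph, {}).setdefault(rep, set()).add(str(row["group"]))
    groups = {
        ph: {rep: frozenset(gs) for rep, gs in reps.items()} for ph, reps in groups.items()
    }
    return GroupTable(groups=groups)


@dataclass
class LexiconEntry:
    """One speech item with its IPA decomposition and group sets."""

    item: str
    ipa: str
    phonemes: list[str] = field(default_factory=list)
    groups: dict = field(default_factory=dict)  # representation -> frozenset
    semantic_category: str | None = None


def decompose(
    item: str, ipa: str, table: GroupTable, semantic_category: str | None = None
) -> LexiconEntry:
    """Represent a word by its per-dimension group sets (order-insensitive)."""
    phonemes = parse_ipa(unicodedata.normalize("NFC", ipa))
    groups = {rep: set() for rep in REPRESENTATIONS}
    for ph in phonemes:
        if ph not in table:
            raise KeyError(f"unknown phoneme {ph!r} in item {item!r}")
        for rep in REPRESENTATIONS:
            groups[rep] |= table.lookup(ph, rep)
    return LexiconEntry(
        item=item,
        ipa=ipa,
        phonemes=phonemes,
        groups={rep: frozenset(gs) for rep, gs in groups.items()},
        semantic_category=semantic_category,
    )


def load_lexicon(path: str | Path, table: GroupTable | None = None) -> list[LexiconEntry]:
    """Read a lexicon TSV (item, ipa[, category]) and decompose every item."""
    table = load_group_table() if table is None else table
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"item", "ipa"}.issubset(df.columns):
        raise ValueError("lexicon must have columns item, ipa")
    entries = []
    for _, row in df.iterrows():
        cat = row.get("category")
        cat = None if pd.isna(cat) else str(cat)
        entries.append(decompose(str(row["item"]), str(row["ipa"]), table, cat))
    return entries


def packaged_lexicon(name: str = "study1", table: GroupTable | None = None) -> list[LexiconEntry]:
    """One of the shipped lexica: 'study1' (six English words),
    'study2_fr' (twelve French words), or 'study3' (three syllables)."""
    source = resources.files("imagispeech.data").joinpath(f"lexicon_{name}.tsv")
    table = load_group_table() if table is None else table
    import io

    df = pd.read_csv(io.StringIO(source.read_text(encoding="utf-8")), sep="\t", dtype=str)
    entries = []
    for _, row in df.iterrows():
        cat = row.get("category")
        cat = None if pd.isna(cat) else str(cat)
        entries.append(decompose(str(row["item"]), str(row["ipa"]), table, cat))
    return entries


def discriminant_groups(a: LexiconEntry, b: LexiconEntry, representation: str) -> frozenset:
    """Groups present in exactly one of the two items (symmetric difference)."""
    if representation == "semantic":
        if a.semantic_category is None or b.semantic_category is None:
            raise ValueError("semantic representation requires category labels")
        if a.semantic_category == b.semantic_category:
            return frozenset()
        return frozenset({a.semantic_category, b.semantic_category})
    return frozenset(a.groups[representation] ^ b.groups[representation])


def pair_distance(a: LexiconEntry, b: LexiconEntry, representation: str) -> int:
    """Count of discriminant groups; for semantic, a 0/1 category indicator."""
    if representation == "semantic":
        return int(a.semantic_category != b.semantic_category)
    return len(discriminant_groups(a, b, representation))


def representation_distance_matrix(
    entries: list[LexiconEntry], representation: str
) -> pd.DataFrame:
    """Symmetric item-by-item matrix of discriminant-group counts."""
    if len(entries) < 2:
        raise ValueError("need at least 2 items")
    items = [e.item for e in entries]
    n = len(items)
    mat = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = pair_distance(entries[i], entries[j], representation)
            mat[i][j] = mat[j][i] = d
    return pd.DataFrame(mat, index=items, columns=items)
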