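"""Drug-name normalization and the renal preferred-term dictionary.

Spontaneous reports carry verbatim drug names (brand names, generics, trade
dress, typos).  :class:`DrugVocabulary` maps name variants to canonical drug
ids and assigns each canonical drug to one of five classes used throughout the
analysis: ``anti-PD-1``, ``anti-PD-L1``, ``anti-CTLA-4``, ``chemotherapy`` and
``other``.  :class:`EventDictionary` holds the set of MedDRA preferred terms
(PTs) counted as renal/urinary adverse events.

Dictionaries are plain text (one entry per line, ``#`` comments) so that a
study can substitute its own PT list or chemotherapy list without touching
code.  The bundled defaults cover the eight approved immune checkpoint
inhibitors with their brand names and a list of common cytotoxics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "DRUG_CLASSES",
    "ICI_CLASSES",
    "DrugVocabulary",
    "EventDictionary",
    "builtin_ici_vocabulary",
    "builtin_event_dictionary",
    "load_drug_vocabulary",
    "load_event_dictionary",
    "is_renal_event",
    "normalize_drugs",
    "normalize_dataset",
    "normalize_name",
]

DRUG_CLASSES = ("anti-PD-1", "anti-PD-L1", "anti-CTLA-4", "chemotherapy", "other")
#: the three immune-checkpoint-inhibitor classes
ICI_CLASSES = ("anti-PD-1", "anti-PD-L1", "anti-CTLA-4")

OTHER_PREFIX = "other:"


def normalize_name(name: str) -> str:
    """Canonical lookup key: uppercase, internal whitespace collapsed."""
    return " ".join(str(name).upper().split())


@dataclass(frozen=True)
class DrugVocabulary:
    """Maps verbatim drug-name variants to canonical drug ids and classes.

    ``entries`` keys are normalized variants (see :func:`normalize_name`);
    ``classes`` maps each canonical id to exactly one class.  Lookup never
    fails: an unrecognized name maps to ``other:<normalized name>`` with
    class ``other``, so normalization is total and loses no drug.
    """

    entries: Mapping[str, str]
    classes: Mapping[str, str]

    def __post_init__(self) -> None:
        for variant, canonical in self.entries.items():
            if canonical not in self.classes:
                raise ValueError(f"variant {variant!r} maps to {canonical!r} which has no class")
        bad = {c for c in self.classes.values()} - set(DRUG_CLASSES)
        if bad:
            raise ValueError(f"unknown drug classes: {sorted(bad)}")

    def lookup(self, name: str) -> tuple[str, str]:
        """Return ``(canonical_id, class)`` for a verbatim name."""
        name = str(name)
        if name.startswith(OTHER_PREFIX):  # already-canonical fallback id
            return name, "other"
        key = normalize_name(name)
        canonical = self.entries.get(key)
        if canonical is None:
            return OTHER_PREFIX + key, "other"
        return canonical, self.classes[canonical]

    def canonical(self, name: str) -> str:
        return self.lookup(name)[0]

    def drug_class(self, canonical_id: str) -> str:
        """Class of a canonical drug id (``other`` for unmapped ids)."""
        return self.classes.get(canonical_id, "other")

    def drugs_of_class(self, cls: str) -> frozenset[str]:
        return frozenset(d for d, c in self.classes.items() if c == cls)

    @property
    def ici_drugs(self) -> frozenset[str]:
        return frozenset(d for d, c in self.classes.items() if c in ICI_CLASSES)

    @property
    def chemo_drugs(self) -> frozenset[str]:
        return self.drugs_of_class("chemotherapy")

    def merged_with(self, other: "DrugVocabulary") -> "DrugVocabulary":
        """New vocabulary with ``other``'s entries added (other wins on clash)."""
        entries = dict(self.entries) | dict(other.entries)
        classes = dict(self.classes) | dict(other.classes)
        return DrugVocabulary(entries=entries, classes=classes)


@dataclass(frozen=True)
class EventDictionary:
    """The preferred terms counted as renal/urinary adverse events.

    ``pt_of_interest_order`` optionally ranks PTs for "top k" tables; when
    empty, ranking is computed from the data (most frequently reported first).
    """

    renal_pts: frozenset[str]
    pt_of_interest_order: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.renal_pts:
            raise ValueError("renal PT set must be nonempty")
        norm = frozenset(normalize_name(p) for p in self.renal_pts)
        object.__setattr__(self, "_normalized", norm)

    def __contains__(self, pt: str) -> bool:
        return normalize_name(pt) in self._normalized  # type: ignore[attr-defined]

    @property
    def normalized_pts(self) -> frozenset[str]:
        return self._normalized  # type: ignore[attr-defined]


def is_renal_event(pt: str, dictionary: EventDictionary) -> bool:
    """True iff ``pt`` is a renal/urinary preferred term (case-insensitive)."""
    return pt in dictionary


def _iter_dictionary_lines(text: str) -> Iterable[str]:
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            yield line


def _parse_drug_lines(text: str, source: str) -> tuple[dict[str, str], dict[str, str]]:
    entries: dict[str, str] = {}
    classes: dict[str, str] = {}
    for line in _iter_dictionary_lines(text):
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != 3:
            raise ValueError(
                f"{source}: expected 'variant<TAB>canonical<TAB>class', got {line!r}"
            )
        variant, canonical, cls = parts
        if cls not in DRUG_CLASSES:
            raise ValueError(f"{source}: unknown class {cls!r} for {canonical!r}")
        canonical = canonical.lower()
        prev = classes.get(canonical)
        if prev is not None and prev != cls:
            raise ValueError(f"{source}: {canonical!r} assigned two classes ({prev}, {cls})")
        classes[canonical] = cls
        entries[normalize_name(variant)] = canonical
        entries.setdefault(normalize_name(canonical), canonical)
    return entries, classes


def load_drug_vocabulary(path: str | Path) -> DrugVocabulary:
    """Read a ``variant<TAB>canonical<TAB>class`` dictionary file."""
    p = Path(path)
    entries, classes = _parse_drug_lines(p.read_text(encoding="utf-8"), str(p))
    return DrugVocabulary(entries=entries, classes=classes)


def load_event_dictionary(path: str | Path) -> EventDictionary:
    """Read a one-PT-per-line event dictionary file."""
    p = Path(path)
    pts = tuple(_iter_dictionary_lines(p.read_text(encoding="utf-8")))
    return EventDictionary(renal_pts=frozenset(pts), pt_of_interest_order=())


def _read_bundled(name: str) -> str:
    return resources.files("renalpv.data").joinpath(name).read_text(encoding="utf-8")


def builtin_ici_vocabulary(chemotherapy_file: str | Path | None = None) -> DrugVocabulary:
    """Vocabulary of the eight approved ICIs plus a chemotherapy list.

    The ICI entries cover the anti-PD-1 antibodies (nivolumab/Opdivo,
    pembrolizumab/Keytruda, cemiplimab/Libtayo), the anti-PD-L1 antibodies
    (atezolizumab/Tecentriq, avelumab/Bavencio, durvalumab/Imfinzi) and the
    anti-CTLA-4 antibodies (ipilimumab/Yervoy, tremelimumab), generic and
    brand variants alike.  ``chemotherapy_file`` overrides the bundled list
    of common cytotoxics (pass a ``variant<TAB>canonical<TAB>class`` file).
    """
    ici_entries, ici_classes = _parse_drug_lines(_read_bundled("ici_drugs.tsv"), "ici_drugs.tsv")
    if chemotherapy_file is None:
        chemo_entries, chemo_classes = _parse_drug_lines(
            _read_bundled("chemotherapy.tsv"), "chemotherapy.tsv"
        )
    else:
        chemo = load_drug_vocabulary(chemotherapy_file)
        chemo_entries, chemo_classes = dict(chemo.entries), dict(chemo.classes)
    return DrugVocabulary(
        entries={**chemo_entries, **ici_entries},
        classes={**chemo_classes, **ici_classes},
    )


def builtin_event_dictionary() -> EventDictionary:
    """The bundled renal/urinary PT dictionary (editable text file)."""
    pts = tuple(_iter_dictionary_lines(_read_bundled("renal_pts.txt")))
    return EventDictionary(renal_pts=frozenset(pts), pt_of_interest_order=())


def normalize_drugs(report, vocab: DrugVocabulary):
    """Replace a report's verbatim drug names with canonical drug ids.

    Total mapping: every name resolves, unrecognized ones to ``other:<name>``.
    Idempotent because canonical ids resolve to themselves.
    """
    drugs = frozenset(vocab.canonical(name) for name in report.drugs)
    return replace(report, drugs=drugs)


def normalize_dataset(dataset, vocab: DrugVocabulary):
    """Vectorized :func:`normalize_drugs` over a ``ReportDataset``.

    Maps each distinct verbatim name once, then collapses drug rows that
    became identical within a report (brand + generic of the same drug).
    """
    drugs = dataset.drugs.copy()
    unique = drugs["value"].unique()
    mapping = {name: vocab.canonical(name) for name in unique}
    drugs["value"] = drugs["value"].map(mapping)
    drugs = drugs.drop_duplicates(["report_id", "value"])
    out = dataset.replace(drugs=drugs)
    out.meta = {**dataset.meta, "normalized": True}
    return out
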