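"""Regimen classification and subgroup selection.

A report's regimen is determined solely by its normalized drug set: which
immune checkpoint inhibitors (ICIs) it lists, whether it lists more than one
(polytherapy) or exactly one (monotherapy), and whether any chemotherapy-class
drug is co-listed.  Four ICI combinations common enough to analyse separately
carry short labels:

    poly1  pembrolizumab + ipilimumab + nivolumab
    poly2  ipilimumab + nivolumab
    poly3  pembrolizumab + ipilimumab
    poly4  durvalumab + tremelimumab

Any other multi-ICI set is ``other`` (still counted in aggregate
polytherapy-vs-monotherapy comparisons).  Chemotherapy co-listing is
orthogonal to the ICI category, which yields the two analysis panels
(ICI regimens without / with chemotherapy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .faers_io import ReportDataset, SafetyReport
from .vocabulary import DrugVocabulary, ICI_CLASSES

__all__ = ["NAMED_COMBOS", "RegimenAssignment", "assign_regimen", "assign_regimens", "select"]

NAMED_COMBOS: dict[str, frozenset[str]] = {
    "poly1": frozenset({"pembrolizumab", "ipilimumab", "nivolumab"}),
    "poly2": frozenset({"ipilimumab", "nivolumab"}),
    "poly3": frozenset({"pembrolizumab", "ipilimumab"}),
    "poly4": frozenset({"durvalumab", "tremelimumab"}),
}
_COMBO_BY_SET = {v: k for k, v in NAMED_COMBOS.items()}


@dataclass(frozen=True)
class RegimenAssignment:
    """Per-report regimen label derived from the normalized drug set."""

    ici_set: frozenset[str]
    has_chemo: bool
    category: str      # "none" | "monotherapy:<drug>" | "polytherapy:<d1+d2+...>"
    named_combo: str   # poly1..poly4 | "other" (unnamed combo) | "n/a" (not poly)
    ici_classes: frozenset[str] = frozenset()

    @property
    def kind(self) -> str:
        return self.category.split(":", 1)[0]


def _categorize(ici_set: frozenset[str]) -> tuple[str, str]:
    if not ici_set:
        return "none", "n/a"
    if len(ici_set) == 1:
        return f"monotherapy:{next(iter(ici_set))}", "n/a"
    label = "+".join(sorted(ici_set))
    return f"polytherapy:{label}", _COMBO_BY_SET.get(ici_set, "other")


def assign_regimen(report: SafetyReport, vocab: DrugVocabulary) -> RegimenAssignment:
    """Classify one report; pure function of its (normalized) drug set."""
    ici_set = frozenset(d for d in report.drugs if d in vocab.ici_drugs)
    has_chemo = any(vocab.drug_class(d) == "chemotherapy" for d in report.drugs)
    category, named = _categorize(ici_set)
    classes = frozenset(vocab.drug_class(d) for d in ici_set)
    return RegimenAssignment(
        ici_set=ici_set,
        has_chemo=has_chemo,
        category=category,
        named_combo=named,
        ici_classes=classes,
    )


def assign_regimens(dataset: ReportDataset, vocab: DrugVocabulary) -> pd.DataFrame:
    """Vectorized regimen assignment for every report in a dataset.

    Returns a DataFrame indexed by report id with columns ``ici_set``
    (frozenset), ``n_ici``, ``kind`` (none/monotherapy/polytherapy),
    ``category``, ``named_combo``, ``has_chemo`` and ``ici_classes``.
    """
    ici_rows = dataset.drugs[dataset.drugs["value"].isin(vocab.ici_drugs)]
    ici_sets = ici_rows.groupby("report_id", sort=False)["value"].agg(frozenset)
    ici_sets = ici_sets.reindex(dataset.index.index, fill_value=frozenset())

    unique_sets = ici_sets.unique()
    cat_map = {s: _categorize(s) for s in unique_sets}
    cls_map = {s: frozenset(vocab.drug_class(d) for d in s) for s in unique_sets}

    out = pd.DataFrame(index=dataset.index.index)
    out["ici_set"] = ici_sets
    out["n_ici"] = ici_sets.map(len)
    out["category"] = ici_sets.map(lambda s: cat_map[s][0])
    out["kind"] = out["category"].str.split(":", n=1).str[0]
    out["named_combo"] = ici_sets.map(lambda s: cat_map[s][1])
    out["has_chemo"] = dataset.drug_mask(vocab.chemo_drugs)
    out["ici_classes"] = ici_sets.map(cls_map)
    return out


_FILTER_KEYS = (
    "class", "regimen", "named_combo", "drug", "has_chemo",
    "sex", "age_min", "age_max", "age_group",
    "year", "year_min", "year_max", "country", "event",
)


def select(
    dataset: ReportDataset,
    filters: Mapping[str, object],
    vocab: DrugVocabulary | None = None,
    assignments: pd.DataFrame | None = None,
    age_cutoff: float = 65,
) -> ReportDataset:
    """Pure conjunctive filter over reports.

    Supported keys: ``class`` (report lists an ICI of that class),
    ``regimen`` (kind or full category string), ``named_combo``, ``drug``
    (canonical id listed), ``has_chemo``, ``sex``, ``age_min``/``age_max``
    (inclusive, missing ages excluded), ``age_group`` (``younger``/``older``
    split at ``age_cutoff``), ``year``/``year_min``/``year_max``,
    ``country`` and ``event`` (PT or PT collection).  Unknown keys raise
    ``KeyError``; an empty filter is the identity.
    """
    unknown = [k for k in filters if k not in _FILTER_KEYS]
    if unknown:
        raise KeyError(f"unknown filter key(s): {unknown}")

    needs_regimen = any(k in filters for k in ("class", "regimen", "named_combo", "has_chemo"))
    if needs_regimen and assignments is None:
        if vocab is None:
            raise ValueError("regimen filters require a vocabulary or precomputed assignments")
        assignments = assign_regimens(dataset, vocab)

    mask = pd.Series(True, index=dataset.index.index)
    idx = dataset.index

    for key, value in filters.items():
        if key == "class":
            if value not in ICI_CLASSES:
                raise ValueError(f"unknown ICI class {value!r}")
            mask &= assignments["ici_classes"].map(lambda s, v=value: v in s)
        elif key == "regimen":
            if ":" in str(value):
                mask &= assignments["category"] == value
            else:
                mask &= assignments["kind"] == value
        elif key == "named_combo":
            mask &= assignments["named_combo"] == value
        elif key == "has_chemo":
            mask &= assignments["has_chemo"] == bool(value)
        elif key == "drug":
            mask &= dataset.drug_mask([str(value)])
        elif key == "sex":
            mask &= idx["sex"] == value
        elif key == "age_min":
            mask &= idx["age_years"] >= float(value)  # type: ignore[arg-type]
        elif key == "age_max":
            mask &= idx["age_years"] <= float(value)  # type: ignore[arg-type]
        elif key == "age_group":
            if value == "younger":
                mask &= idx["age_years"] < age_cutoff
            elif value == "older":
                mask &= idx["age_years"] >= age_cutoff
            else:
                raise ValueError(f"age_group must be 'younger' or 'older', got {value!r}")
        elif key == "year":
            mask &= idx["event_year"] == int(value)  # type: ignore[arg-type]
        elif key == "year_min":
            mask &= idx["event_year"] >= int(value)  # type: ignore[arg-type]
        elif key == "year_max":
            mask &= idx["event_year"] <= int(value)  # type: ignore[arg-type]
        elif key == "country":
            mask &= idx["country"] == value
        elif key == "event":
            pts = [value] if isinstance(value, str) else list(value)  # type: ignore[arg-type]
            mask &= dataset.event_mask(pts)

    mask = mask.fillna(False).astype(bool)
    return dataset.subset(dataset.index.index[mask])
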