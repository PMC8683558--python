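"""Full-study orchestration: baseline, signal, comparison and fatality tables.

The analysis proceeds: ingest quarterly tables -> assemble reports -> drop
duplicate case versions -> normalize drug names -> assign regimens -> compute

* a baseline characteristics table (ICI renal-event reports vs renal-event
  reports under any other drug, stratified by sex, age group, year, outcome
  and reporting country);
* a regimen-level signal table (ROR with 95% CI and IC with credibility
  bounds, each regimen vs rest of database, in two panels: ICI regimens
  without and with co-listed chemotherapy) plus head-to-head comparative
  RORs (anti-PD-1/PD-L1 vs anti-CTLA-4, polytherapy vs monotherapy,
  ICI+chemotherapy vs ICI alone);
* a per-PT ROR025 matrix for the most frequently reported renal events;
* death-outcome proportions per (regimen, PT).

Counting is report-level throughout: one deduplicated report contributes at
most one to any contingency-table cell.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import date
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .cohort import NAMED_COMBOS, assign_regimens
from .disproportionality import (
    build_contingency,
    comparative_ror,
    estimate_signal,
)
from .faers_io import ReportDataset, assemble_reports, deduplicate, read_quarter
from .vocabulary import (
    DrugVocabulary,
    EventDictionary,
    builtin_event_dictionary,
    builtin_ici_vocabulary,
    load_drug_vocabulary,
    load_event_dictionary,
    normalize_dataset,
)

__all__ = [
    "AnalysisConfig",
    "prepare_dataset",
    "baseline_table",
    "signal_table_total",
    "signal_table_by_pt",
    "fatality_table",
    "run_all",
]

logger = logging.getLogger(__name__)

MONOTHERAPY_DRUGS = (
    "nivolumab", "pembrolizumab", "cemiplimab", "atezolizumab",
    "avelumab", "durvalumab", "ipilimumab", "tremelimumab",
)
PD1_PDL1 = ("anti-PD-1", "anti-PD-L1")

# FAERS outcome codes by clinical severity; each report is tabulated once,
# under its most serious outcome, so baseline percentages sum to 100.
OUTCOME_SEVERITY = ("DE", "LT", "DS", "HO", "CA", "RI", "OT")
OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "DS": "Disability",
    "HO": "Hospitalization",
    "CA": "Congenital anomaly",
    "RI": "Required intervention",
    "OT": "Other serious",
}


class AnalysisConfig(BaseModel):
    """Configuration of one full analysis run."""

    input_dir: Path | None = None
    synthetic: dict | None = None          # GeneratorConfig overrides for synthetic mode
    drug_vocabulary_file: Path | None = None
    chemotherapy_file: Path | None = None
    event_dictionary_file: Path | None = None
    window_start: date = date(2014, 1, 1)
    window_end: date = date(2019, 6, 30)
    min_reports: int = Field(default=3, ge=1)
    alpha: float = Field(default=0.95, gt=0, lt=1)
    age_cutoff: float = 65
    top_k: int = Field(default=10, ge=1)
    rank_events_within: str = "ici"        # "ici" or "all"
    restrict_to_suspect: bool = False      # keep only PS/SS drug rows
    output_dir: Path = Path("renalpv_out")
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        if self.window_start >= self.window_end:
            raise ValueError("window_start must precede window_end")
        if self.rank_events_within not in ("ici", "all"):
            raise ValueError("rank_events_within must be 'ici' or 'all'")
        if self.input_dir is None and self.synthetic is None:
            raise ValueError("either input_dir or synthetic mode must be configured")
        return self

    def load_vocabulary(self) -> DrugVocabulary:
        vocab = builtin_ici_vocabulary(chemotherapy_file=self.chemotherapy_file)
        if self.drug_vocabulary_file is not None:
            vocab = vocab.merged_with(load_drug_vocabulary(self.drug_vocabulary_file))
        return vocab

    def load_event_dictionary(self) -> EventDictionary:
        if self.event_dictionary_file is not None:
            return load_event_dictionary(self.event_dictionary_file)
        return builtin_event_dictionary()


def prepare_dataset(config: AnalysisConfig) -> tuple[ReportDataset, DrugVocabulary, EventDictionary]:
    """Ingest -> assemble -> window -> dedup -> normalize, per the config."""
    vocab = config.load_vocabulary()
    events = config.load_event_dictionary()
    if config.input_dir is not None:
        paths = {t: Path(config.input_dir) / f"{t}.txt" for t in ("demo", "drug", "reac", "outc")}
        quarter = read_quarter(paths)
    else:
        from .synthetic_data import GeneratorConfig, PlantedAssociation, generate

        overrides = dict(config.synthetic or {})
        planted = [
            PlantedAssociation(frozenset(p["drugs"]), p["pt"], float(p["theta"]))
            for p in overrides.pop("planted", [])
        ]
        quarter, _ = generate(
            GeneratorConfig(planted=tuple(planted), **overrides), seed=config.seed
        )
    if config.restrict_to_suspect and "role_cod" in quarter.drug.columns:
        roles = quarter.drug["role_cod"].astype(str).str.strip()
        quarter.drug = quarter.drug[roles.isin(["PS", "SS"]) | (roles == "")]
    dataset = assemble_reports(quarter)
    dataset = _apply_window(dataset, config)
    dataset = deduplicate(dataset)
    dataset = normalize_dataset(dataset, vocab)
    return dataset, vocab, events


def _apply_window(dataset: ReportDataset, config: AnalysisConfig) -> ReportDataset:
    """Keep reports received inside the study window (missing dates kept)."""
    lo = config.window_start.strftime("%Y%m%d")
    hi = config.window_end.strftime("%Y%m%d")
    dates = dataset.index["receipt_date"].astype(str)
    ok = (dates == "") | ((dates >= lo) & (dates <= hi))
    if ok.all():
        return dataset
    out = dataset.subset(dataset.index.index[ok])
    out.meta = {**dataset.meta, "excluded_outside_window": int((~ok).sum())}
    return out


def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 2) if total else 0.0


def _severest_outcome(dataset: ReportDataset) -> pd.Series:
    """Most serious outcome code per report ('' when none reported)."""
    rank = {code: i for i, code in enumerate(OUTCOME_SEVERITY)}
    outc = dataset.outcomes.copy()
    outc["rank"] = outc["value"].map(rank)
    outc = outc.dropna(subset=["rank"]).sort_values(["report_id", "rank"], kind="stable")
    best = outc.drop_duplicates("report_id")[["report_id", "value"]].set_index("report_id")["value"]
    return best.reindex(dataset.index.index, fill_value="")


def baseline_table(
    dataset: ReportDataset,
    vocab: DrugVocabulary,
    events: EventDictionary,
    config: AnalysisConfig,
    assignments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Characteristics of renal-event reports: ICI regimens vs any other drug.

    One row per stratum level with counts and percentages for both groups;
    within each stratum the percentages sum to 100 (each report tabulated
    once per stratum, missing as its own level, most serious outcome only).
    """
    if assignments is None:
        assignments = assign_regimens(dataset, vocab)
    renal = dataset.event_mask(events.normalized_pts)
    is_ici = assignments["n_ici"] > 0
    groups = {
        "ici": dataset.index.index[renal & is_ici],
        "other": dataset.index.index[renal & ~is_ici],
    }
    idx = dataset.index
    severest = _severest_outcome(dataset)

    rows: list[dict] = []

    def _add(stratum: str, level: str, member: pd.Series) -> None:
        row = {"stratum": stratum, "level": level}
        for g, ids in groups.items():
            count = int(member.loc[ids].sum())
            row[f"{g}_count"] = count
            row[f"{g}_pct"] = _pct(count, len(ids))
        rows.append(row)

    for level in ("male", "female"):
        _add("sex", level, idx["sex"] == level)
    _add("sex", "missing", idx["sex"].isna())

    age = idx["age_years"]
    _add("age", f"<{config.age_cutoff:g}", age < config.age_cutoff)
    _add("age", f">={config.age_cutoff:g}", age >= config.age_cutoff)
    _add("age", "missing", age.isna())

    years = idx["event_year"]
    for year in sorted(years.dropna().unique()):
        _add("year", str(int(year)), years == year)
    _add("year", "missing", years.isna())

    for code in OUTCOME_SEVERITY:
        _add("outcome", OUTCOME_LABELS[code], severest == code)
    _add("outcome", "missing", severest == "")

    country = idx["country"]
    top = (
        country.loc[groups["ici"]].dropna().value_counts().head(10).index.tolist()
        if len(groups["ici"])
        else country.dropna().value_counts().head(10).index.tolist()
    )
    for c in top:
        _add("country", str(c), country == c)
    _add("country", "others", country.notna() & ~country.isin(top))
    _add("country", "missing", country.isna())

    out = pd.DataFrame(rows)
    out.attrs["n_ici_renal"] = len(groups["ici"])
    out.attrs["n_other_renal"] = len(groups["other"])
    return out


def _regimen_groups(assignments: pd.DataFrame, panel_chemo: bool | None) -> dict[str, pd.Series]:
    """Target-group masks for the signal table, one per regimen row."""
    chemo_ok = (
        pd.Series(True, index=assignments.index)
        if panel_chemo is None
        else assignments["has_chemo"] == panel_chemo
    )
    groups: dict[str, pd.Series] = {}
    for drug in MONOTHERAPY_DRUGS:
        groups[drug.capitalize()] = (assignments["category"] == f"monotherapy:{drug}") & chemo_ok
    for combo in NAMED_COMBOS:
        groups[combo.capitalize()] = (assignments["named_combo"] == combo) & chemo_ok
    return groups


def signal_table_total(
    dataset: ReportDataset,
    vocab: DrugVocabulary,
    events: EventDictionary,
    config: AnalysisConfig,
    assignments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Regimen-level renal-event signal table with comparative ROR rows.

    Panel ``no-chemo``/``chemo`` rows test each regimen against the rest of
    the database; ``comparison`` rows contrast two regimen groups directly
    (only the ROR is meaningful there, so IC columns are empty).  Regimens
    absent from the data yield zero-count, ineligible rows.
    """
    if assignments is None:
        assignments = assign_regimens(dataset, vocab)
    if not (assignments["n_ici"] > 0).any():
        logger.warning("no ICI reports in dataset; signal table is empty")
        return pd.DataFrame(
            columns=["panel", "row", "a", "b", "c", "d", "ror", "ror_025", "ror_975",
                     "ic", "ic_025", "ic_975", "n", "eligible", "signal"]
        )
    pts = events.normalized_pts
    is_ici = assignments["n_ici"] > 0
    is_mono = assignments["kind"] == "monotherapy"
    is_poly = assignments["kind"] == "polytherapy"
    has_chemo = assignments["has_chemo"]
    pd1_classes = assignments["ici_classes"].map(lambda s: bool(s & set(PD1_PDL1)))
    ctla4_mono = is_mono & assignments["ici_classes"].map(lambda s: s == {"anti-CTLA-4"})
    pd1_mono = is_mono & pd1_classes & assignments["ici_classes"].map(
        lambda s: not (s - set(PD1_PDL1))
    )

    rows: list[dict] = []

    def _vs_rest(panel: str, label: str, mask: pd.Series) -> None:
        table = build_contingency(dataset, mask, pts, comparator="rest")
        est = estimate_signal(table, alpha=config.alpha, min_reports=config.min_reports)
        rows.append(
            {
                "panel": panel, "row": label,
                "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                "ror": est.ror, "ror_025": est.ror_025, "ror_975": est.ror_975,
                "ic": est.ic, "ic_025": est.ic_025, "ic_975": est.ic_975,
                "n": est.n_observed, "eligible": est.eligible, "signal": est.is_signal,
            }
        )

    def _versus(panel: str, label: str, g1: pd.Series, g2: pd.Series) -> None:
        table = build_contingency(dataset, g1, pts, comparator=g2)
        r = comparative_ror(dataset, g1, g2, pts, alpha=config.alpha)
        rows.append(
            {
                "panel": panel, "row": label,
                "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                "ror": r.ror, "ror_025": r.ror_025, "ror_975": r.ror_975,
                "ic": np.nan, "ic_025": np.nan, "ic_975": np.nan,
                "n": table.a,
                "eligible": table.a >= config.min_reports,
                "signal": table.a >= config.min_reports and r.ror_025 > 1.0,
            }
        )

    _vs_rest("total", "Total", is_ici)
    for panel, chemo in (("no-chemo", False), ("chemo", True)):
        for label, mask in _regimen_groups(assignments, chemo).items():
            _vs_rest(panel, label, mask)
        _versus(panel, "PD-1/PD-L1 vs CTLA-4", pd1_mono & (has_chemo == chemo), ctla4_mono & (has_chemo == chemo))
        _versus(panel, "Poly vs mono", is_poly & (has_chemo == chemo), is_mono & (has_chemo == chemo))
    _versus("total", "PD-1/PD-L1 vs CTLA-4", pd1_mono, ctla4_mono)
    _versus("total", "Poly vs mono", is_poly, is_mono)
    _versus("total", "ICI+chemo vs ICI alone", is_ici & has_chemo, is_ici & ~has_chemo)
    return pd.DataFrame(rows)


def top_events(
    dataset: ReportDataset,
    events: EventDictionary,
    assignments: pd.DataFrame,
    k: int,
    within: str = "ici",
) -> list[str]:
    """The k most frequently reported renal PTs (ties broken alphabetically)."""
    reac = dataset.reactions.copy()
    from .vocabulary import normalize_name

    norm = reac["value"].map(normalize_name)
    reac = reac[norm.isin(events.normalized_pts)]
    if within == "ici":
        ici_ids = assignments.index[assignments["n_ici"] > 0]
        reac = reac[reac["report_id"].isin(ici_ids)]
    counts = (
        reac.groupby(reac["value"].str.capitalize())["report_id"].nunique().sort_index()
    )
    counts = counts.sort_values(ascending=False, kind="stable")
    return counts.head(k).index.tolist()


def signal_table_by_pt(
    dataset: ReportDataset,
    vocab: DrugVocabulary,
    events: EventDictionary,
    config: AnalysisConfig,
    assignments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-PT signal estimates for each regimen (long format).

    Rows: the ``top_k`` most frequent renal PTs crossed with every regimen in
    both chemotherapy panels, each vs rest of database.  ``ror_025`` is the
    reportable cell; pairs with fewer than ``min_reports`` reports are
    ineligible (blank in the matrix view).  Pivot with
    ``df.pivot_table(index="pt", columns=["panel", "regimen"], values="ror_025")``.
    """
    if assignments is None:
        assignments = assign_regimens(dataset, vocab)
    ranked = top_events(dataset, events, assignments, config.top_k, config.rank_events_within)
    rows: list[dict] = []
    for panel, chemo in (("no-chemo", False), ("chemo", True)):
        for label, mask in _regimen_groups(assignments, chemo).items():
            for pt in ranked:
                table = build_contingency(dataset, mask, [pt], comparator="rest")
                est = estimate_signal(table, alpha=config.alpha, min_reports=config.min_reports)
                rows.append(
                    {
                        "panel": panel, "regimen": label, "pt": pt,
                        "a": table.a,
                        "ror_025": est.ror_025 if est.eligible else np.nan,
                        "ic_025": est.ic_025 if est.eligible else np.nan,
                        "eligible": est.eligible,
                        "signal": est.is_signal,
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["pt_order"] = ranked
    return out


def fatality_table(
    dataset: ReportDataset,
    vocab: DrugVocabulary,
    events: EventDictionary,
    config: AnalysisConfig,
    assignments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Death-outcome proportion per (panel, regimen, PT), plus overall rows.

    A death is any report carrying outcome code DE.  The overall row
    (regimen ``All ICIs``, pt ``Any renal PT``) equals the baseline table's
    death proportion among ICI renal reports.  No direction of the
    with-vs-without-chemotherapy difference is asserted; both panels are
    reported side by side.
    """
    if assignments is None:
        assignments = assign_regimens(dataset, vocab)
    ranked = top_events(dataset, events, assignments, config.top_k, config.rank_events_within)
    death = dataset.outcome_mask("DE")
    is_ici = assignments["n_ici"] > 0
    rows: list[dict] = []

    def _add(panel: str, regimen: str, pt_label: str, member: pd.Series) -> None:
        n = int(member.sum())
        n_death = int((member & death).sum())
        rows.append(
            {
                "panel": panel, "regimen": regimen, "pt": pt_label,
                "n_reports": n, "n_death": n_death,
                "death_proportion": n_death / n if n else 0.0,
            }
        )

    renal_any = dataset.event_mask(events.normalized_pts)
    _add("total", "All ICIs", "Any renal PT", is_ici & renal_any)
    for panel, chemo in (("no-chemo", False), ("chemo", True)):
        for label, mask in _regimen_groups(assignments, chemo).items():
            for pt in ranked:
                _add(panel, label, pt, mask & dataset.event_mask([pt]))
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: AnalysisConfig) -> dict:
    """Execute the full study and write all outputs; returns the manifest.

    Outputs (CSV) land in ``config.output_dir``: ``baseline.csv``,
    ``signal_total.csv``, ``signal_by_pt.csv``, ``fatality.csv``,
    ``reports.csv`` (report-drug-reaction triples) and ``manifest.json``.
    Identical inputs and config produce byte-identical outputs.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "ingest"
    try:
        dataset, vocab, events = prepare_dataset(config)
        assignments = assign_regimens(dataset, vocab)
        stage = "baseline_table"
        baseline = baseline_table(dataset, vocab, events, config, assignments)
        stage = "signal_table_total"
        total = signal_table_total(dataset, vocab, events, config, assignments)
        stage = "signal_table_by_pt"
        by_pt = signal_table_by_pt(dataset, vocab, events, config, assignments)
        stage = "fatality_table"
        fatality = fatality_table(dataset, vocab, events, config, assignments)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    tables = {
        "baseline.csv": baseline,
        "signal_total.csv": total,
        "signal_by_pt.csv": by_pt,
        "fatality.csv": fatality,
        "reports.csv": dataset.to_triples(),
    }
    for name, frame in tables.items():
        frame.to_csv(out_dir / name, index=False, float_format="%.6g", lineterminator="\n")

    input_hashes = {}
    if config.input_dir is not None:
        for t in ("demo", "drug", "reac", "outc"):
            p = Path(config.input_dir) / f"{t}.txt"
            input_hashes[t] = _sha256(p)
    manifest = {
        "package_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "n_reports": len(dataset),
        "ingest_meta": dataset.meta,
        "input_hashes": input_hashes,
        "outputs": sorted(tables),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
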