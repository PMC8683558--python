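"""Reading FAERS-style quarterly tables and assembling deduplicated reports.

FAERS quarters are distributed as ``$``-delimited ASCII tables, one file per
entity: DEMO (one row per report version), DRUG (one row per drug mention),
REAC (one row per MedDRA preferred term) and OUTC (one row per outcome code).
This module parses those tables into a :class:`RawQuarter`, assembles one
record per report id (:func:`assemble_reports`) and removes duplicate case
versions (:func:`deduplicate`).

Two report representations are provided.  :class:`ReportDataset` keeps the
long tables as pandas DataFrames and is what the pipeline operates on (set
operations over millions of rows stay vectorized); :class:`SafetyReport` is a
frozen per-report record for small-scale, readable work.  The two convert
losslessly via :meth:`ReportDataset.to_reports` / ``from_reports``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .vocabulary import normalize_name

__all__ = [
    "FaersDialect",
    "RawQuarter",
    "ReportDataset",
    "SafetyReport",
    "ReferentialIntegrityError",
    "read_quarter",
    "write_quarter",
    "assemble_reports",
    "deduplicate",
]

logger = logging.getLogger(__name__)

TABLES = ("demo", "drug", "reac", "outc")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
ROLE_CODES = ("PS", "SS", "C", "I")

#: canonical column names per table (the 2014+ FAERS ASCII layout)
MANDATORY_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid"),
    "drug": ("primaryid", "drugname"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
}
OPTIONAL_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("caseversion", "fda_dt", "event_dt", "age", "age_cod", "sex", "occr_country"),
    "drug": ("drug_seq", "role_cod"),
    "reac": (),
    "outc": (),
}

# age-unit code -> factor converting to years; unknown codes become missing
_AGE_FACTORS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12.0, "WK": 1 / 52.18, "DY": 1 / 365.25, "HR": 1 / 8766.0}


class ReferentialIntegrityError(ValueError):
    """A child-table row references a report id absent from DEMO."""


@dataclass(frozen=True)
class FaersDialect:
    """Delimiter and column-name configuration absorbing FAERS schema drift.

    ``column_maps[table]`` maps canonical column names (see
    ``MANDATORY_COLUMNS`` / ``OPTIONAL_COLUMNS``) to the names used in the
    files, e.g. ``{"sex": "gndr_cod"}`` for pre-2014 quarters.
    """

    delimiter: str = "$"
    column_maps: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    def file_column(self, table: str, canonical: str) -> str:
        return dict(self.column_maps.get(table, {})).get(canonical, canonical)


@dataclass
class RawQuarter:
    """Parsed quarterly tables, one DataFrame per FAERS entity."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    parse_stats: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def validate(self) -> None:
        """Check referential integrity and role-code domain; raise on violation."""
        known = set(self.demo["primaryid"].astype(str))
        for name in ("drug", "reac", "outc"):
            ids = self.table(name)["primaryid"].astype(str)
            orphans = sorted(set(ids) - known)
            if orphans:
                raise ReferentialIntegrityError(
                    f"{name.upper()} rows reference report ids absent from DEMO: "
                    f"{orphans[:5]}{'...' if len(orphans) > 5 else ''}"
                )
        if "role_cod" in self.drug.columns:
            roles = self.drug["role_cod"].dropna()
            roles = roles[roles.astype(str).str.strip() != ""]
            bad = sorted(set(roles) - set(ROLE_CODES))
            if bad:
                raise ValueError(f"unknown drug role codes: {bad}")


def _read_table(path: Path, table: str, dialect: FaersDialect) -> tuple[pd.DataFrame, int]:
    if not path.exists():
        raise FileNotFoundError(f"{table.upper()} file not found: {path}")
    bad_rows: list[int] = []

    def _on_bad(row: list[str]) -> None:
        bad_rows.append(1)
        return None

    frame = pd.read_csv(
        path,
        sep=dialect.delimiter,
        dtype=str,
        engine="python",
        on_bad_lines=_on_bad,
        keep_default_na=False,
    )
    rename = {
        dialect.file_column(table, canon): canon
        for canon in MANDATORY_COLUMNS[table] + OPTIONAL_COLUMNS[table]
    }
    frame = frame.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS[table] if c not in frame.columns]
    if missing:
        raise ValueError(f"{table.upper()} file {path} lacks mandatory column(s): {missing}")
    for col in OPTIONAL_COLUMNS[table]:
        if col not in frame.columns:
            frame[col] = ""
    frame["primaryid"] = frame["primaryid"].astype(str)
    for col in ("drugname", "pt", "outc_cod"):
        if col in frame.columns:
            frame[col] = frame[col].astype(str).str.strip()
    return frame, len(bad_rows)


def read_quarter(paths: Mapping[str, str | Path], dialect: FaersDialect | None = None) -> RawQuarter:
    """Parse one quarter's DEMO/DRUG/REAC/OUTC files.

    ``paths`` maps table name (``demo``/``drug``/``reac``/``outc``) to file
    location.  Unparseable rows are counted in ``parse_stats`` and logged,
    never silently dropped; a missing file or mandatory column is fatal.
    Referential integrity (every child row's report id present in DEMO) is
    enforced.
    """
    dialect = dialect or FaersDialect()
    missing = [t for t in TABLES if t not in paths]
    if missing:
        raise ValueError(f"paths must include all of {TABLES}; missing {missing}")
    frames: dict[str, pd.DataFrame] = {}
    stats: dict[str, int] = {}
    for table in TABLES:
        frames[table], n_bad = _read_table(Path(paths[table]), table, dialect)
        stats[f"{table}_rows"] = len(frames[table])
        stats[f"{table}_unparseable"] = n_bad
        if n_bad:
            logger.warning("%s: skipped %d unparseable row(s)", table.upper(), n_bad)
    quarter = RawQuarter(parse_stats=stats, **frames)
    quarter.validate()
    return quarter


def write_quarter(quarter: RawQuarter, directory: str | Path, dialect: FaersDialect | None = None) -> dict[str, Path]:
    """Write a quarter back to ``$``-delimited files; returns the path map."""
    dialect = dialect or FaersDialect()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for table in TABLES:
        frame = quarter.table(table).copy()
        frame = frame.rename(
            columns={c: dialect.file_column(table, c) for c in frame.columns}
        )
        path = directory / f"{table}.txt"
        frame.to_csv(path, sep=dialect.delimiter, index=False)
        paths[table] = path
    return paths


@dataclass(frozen=True)
class SafetyReport:
    """One deduplicated spontaneous report.

    ``drugs`` holds verbatim names until vocabulary normalization replaces
    them with canonical drug ids; ``reactions`` are MedDRA preferred terms;
    ``outcomes`` are FAERS outcome codes (``DE`` = death, ``HO`` =
    hospitalization, ...).
    """

    report_id: str
    case_id: str
    drugs: frozenset[str]
    reactions: frozenset[str]
    outcomes: frozenset[str] = frozenset()
    sex: str | None = None            # "male" / "female" / None
    age_years: float | None = None
    event_year: int | None = None
    country: str | None = None


class ReportDataset:
    """Deduplicated report collection backed by long-format DataFrames.

    ``index`` has one row per report (indexed by ``report_id``) with columns
    ``case_id, case_version, sex, age_years, event_year, country, receipt_date``;
    ``drugs``, ``reactions`` and ``outcomes`` are long tables with columns
    ``(report_id, value)``.  All operations return new objects; nothing
    mutates in place.
    """

    def __init__(
        self,
        index: pd.DataFrame,
        drugs: pd.DataFrame,
        reactions: pd.DataFrame,
        outcomes: pd.DataFrame,
        meta: dict | None = None,
    ) -> None:
        self.index = index
        self.index.index.name = "report_id"
        self.drugs = drugs.reset_index(drop=True)
        self.reactions = reactions.reset_index(drop=True)
        self.outcomes = outcomes.reset_index(drop=True)
        self.meta = dict(meta or {})

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.index)

    @property
    def report_ids(self) -> pd.Index:
        return self.index.index

    def replace(self, **parts) -> "ReportDataset":
        kwargs = dict(
            index=self.index,
            drugs=self.drugs,
            reactions=self.reactions,
            outcomes=self.outcomes,
            meta=self.meta,
        )
        kwargs.update(parts)
        return ReportDataset(**kwargs)

    def subset(self, report_ids: Iterable[str]) -> "ReportDataset":
        wanted = set(map(str, report_ids))
        ids = self.index.index[self.index.index.isin(wanted)]
        return ReportDataset(
            index=self.index.loc[ids],
            drugs=self.drugs[self.drugs["report_id"].isin(ids)],
            reactions=self.reactions[self.reactions["report_id"].isin(ids)],
            outcomes=self.outcomes[self.outcomes["report_id"].isin(ids)],
            meta=self.meta,
        )

    # -- vectorized membership masks (indexed by report_id) ----------------
    def _mask(self, long: pd.DataFrame, values: set[str], key: pd.Series | None = None) -> pd.Series:
        col = long["value"] if key is None else key
        hits = long.loc[col.isin(values), "report_id"]
        mask = pd.Series(False, index=self.index.index)
        mask.loc[pd.unique(hits)] = True
        return mask

    @property
    def _reaction_keys(self) -> pd.Series:
        """Uppercased, stripped PT column, computed once per dataset."""
        cached = self.__dict__.get("_reaction_keys_cache")
        if cached is None:
            cached = self.reactions["value"].astype(str).str.upper().str.strip()
            self.__dict__["_reaction_keys_cache"] = cached
        return cached

    def drug_mask(self, drug_ids: Iterable[str]) -> pd.Series:
        """Boolean per report: lists at least one of ``drug_ids``."""
        return self._mask(self.drugs, set(drug_ids))

    def event_mask(self, pts: Iterable[str]) -> pd.Series:
        """Boolean per report: mentions at least one PT (case-insensitive)."""
        return self._mask(
            self.reactions,
            {normalize_name(p) for p in pts},
            key=self._reaction_keys,
        )

    def outcome_mask(self, code: str) -> pd.Series:
        """Boolean per report: carries the outcome code (e.g. ``DE``)."""
        return self._mask(self.outcomes, {code})

    def drug_sets(self) -> pd.Series:
        """Series report_id -> frozenset of drug values."""
        sets = self.drugs.groupby("report_id", sort=False)["value"].agg(frozenset)
        return sets.reindex(self.index.index, fill_value=frozenset())

    # -- conversion --------------------------------------------------------
    def to_reports(self) -> list[SafetyReport]:
        drug_sets = self.drug_sets()
        reac_sets = (
            self.reactions.groupby("report_id", sort=False)["value"]
            .agg(frozenset)
            .reindex(self.index.index, fill_value=frozenset())
        )
        outc_sets = (
            self.outcomes.groupby("report_id", sort=False)["value"]
            .agg(frozenset)
            .reindex(self.index.index, fill_value=frozenset())
        )

        def _opt(v):
            return None if pd.isna(v) else v

        reports = []
        for rid, row in self.index.iterrows():
            reports.append(
                SafetyReport(
                    report_id=str(rid),
                    case_id=str(row["case_id"]),
                    drugs=drug_sets[rid],
                    reactions=reac_sets[rid],
                    outcomes=outc_sets[rid],
                    sex=_opt(row["sex"]),
                    age_years=_opt(row["age_years"]),
                    event_year=int(row["event_year"]) if pd.notna(row["event_year"]) else None,
                    country=_opt(row["country"]),
                )
            )
        return reports

    @classmethod
    def from_reports(cls, reports: Sequence[SafetyReport]) -> "ReportDataset":
        index = pd.DataFrame(
            {
                "case_id": [r.case_id for r in reports],
                "case_version": 1,
                "sex": [r.sex for r in reports],
                "age_years": [np.nan if r.age_years is None else r.age_years for r in reports],
                "event_year": [np.nan if r.event_year is None else r.event_year for r in reports],
                "country": [r.country for r in reports],
                "receipt_date": "",
            },
            index=pd.Index([r.report_id for r in reports], name="report_id"),
        )

        def _long(attr: str) -> pd.DataFrame:
            rows = [(r.report_id, v) for r in reports for v in sorted(getattr(r, attr))]
            return pd.DataFrame(rows, columns=["report_id", "value"]).astype(str)

        return cls(index=index, drugs=_long("drugs"), reactions=_long("reactions"), outcomes=_long("outcomes"))

    def to_triples(self) -> pd.DataFrame:
        """One row per report-drug-reaction triple (inspection export)."""
        merged = self.drugs.merge(self.reactions, on="report_id", suffixes=("_drug", "_pt"))
        merged = merged.rename(columns={"value_drug": "drug", "value_pt": "pt"})
        return merged.sort_values(["report_id", "drug", "pt"]).reset_index(drop=True)


def _ages_to_years(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    values = pd.to_numeric(age.mask(age.astype(str) == ""), errors="coerce")
    codes = age_cod.astype(str).str.strip().str.upper().replace("", "YR")
    factors = codes.map(_AGE_FACTORS)
    years = values * factors
    return years.where(years >= 0)


def _event_years(event_dt: pd.Series) -> pd.Series:
    years = pd.to_numeric(event_dt.astype(str).str.strip().str.slice(0, 4), errors="coerce")
    return years.where((years >= 1900) & (years <= 2100))


def _clean_long(frame: pd.DataFrame, value_col: str) -> pd.DataFrame:
    # values arrive stripped (read_quarter) or clean (the generator)
    out = frame[["primaryid", value_col]].rename(columns={"primaryid": "report_id", value_col: "value"})
    return out[out["value"] != ""]


def assemble_reports(quarter: RawQuarter) -> ReportDataset:
    """Build one record per report id; drop reports lacking drugs or reactions.

    Exclusions are counted (``meta['excluded_no_drug']`` /
    ``meta['excluded_no_reaction']``), never raised: a spontaneous report
    without a drug name or without an adverse event cannot enter any
    contingency table.  Ages are converted to years from their unit codes
    (non-convertible values become missing); sex is normalized to
    ``male``/``female``/missing; the event year is taken from the event date.
    """
    demo = quarter.demo

    def _col(name: str, default: str = "") -> pd.Series:
        if name in demo.columns:
            return demo[name]
        return pd.Series(default, index=demo.index)

    drugs = _clean_long(quarter.drug, "drugname")
    reacs = _clean_long(quarter.reac, "pt")
    outcs = _clean_long(quarter.outc, "outc_cod")

    sex = (
        _col("sex").astype(str).str.strip().str.upper().map({"M": "male", "F": "female"})
    )
    version = pd.to_numeric(_col("caseversion").replace("", "1"), errors="coerce").fillna(1)
    index = pd.DataFrame(
        {
            "case_id": demo["caseid"].astype(str).to_numpy(),
            "case_version": version.astype(int).to_numpy(),
            "sex": sex.to_numpy(),
            "age_years": _ages_to_years(_col("age"), _col("age_cod")).to_numpy(),
            "event_year": _event_years(_col("event_dt")).to_numpy(),
            "country": _col("occr_country").astype(str).str.strip().replace("", None).to_numpy(),
            "receipt_date": _col("fda_dt").astype(str).str.strip().to_numpy(),
        },
        index=pd.Index(demo["primaryid"].astype(str).to_numpy(), name="report_id"),
    )
    index = index[~index.index.duplicated(keep="last")]

    with_drug = pd.Index(pd.unique(drugs["report_id"]))
    with_reac = pd.Index(pd.unique(reacs["report_id"]))
    keep = index.index.intersection(with_drug).intersection(with_reac)
    n_no_drug = len(index.index.difference(with_drug))
    n_no_reac = len(index.index.difference(with_reac))
    dataset = ReportDataset(
        index=index.loc[keep],
        drugs=drugs[drugs["report_id"].isin(keep)],
        reactions=reacs[reacs["report_id"].isin(keep)],
        outcomes=outcs[outcs["report_id"].isin(keep)],
        meta={
            "excluded_no_drug": int(n_no_drug),
            "excluded_no_reaction": int(n_no_reac),
            "n_input_reports": int(len(index)),
        },
    )
    return dataset


def deduplicate(dataset: ReportDataset) -> ReportDataset:
    """Remove duplicate case versions and repeated within-report entries.

    FAERS convention: a case resubmitted with corrections appears under a new
    report id with an incremented case version; only the highest version
    (ties broken by latest receipt date, then report id) is retained.  Within
    a report, repeated drug names and repeated PTs collapse, so drug and
    reaction multisets become sets (case/spacing variants of one drug merge
    later, at vocabulary normalization).  Idempotent.
    """
    order = dataset.index.reset_index().sort_values(
        ["case_id", "case_version", "receipt_date", "report_id"]
    )
    keep_ids = pd.Index(order.drop_duplicates("case_id", keep="last")["report_id"])
    n_dropped = len(dataset) - len(keep_ids)

    def _unique_rows(long: pd.DataFrame) -> pd.DataFrame:
        # exact repeated rows collapse here; case/spacing variants of the same
        # drug collapse at vocabulary normalization, which maps then dedups
        long = long[long["report_id"].isin(keep_ids)]
        return long.loc[~long.duplicated(["report_id", "value"])]

    out = ReportDataset(
        index=dataset.index.loc[dataset.index.index.isin(keep_ids)],
        drugs=_unique_rows(dataset.drugs),
        reactions=_unique_rows(dataset.reactions),
        outcomes=_unique_rows(dataset.outcomes),
        meta={**dataset.meta, "dropped_duplicate_cases": int(n_dropped)},
    )
    return out
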