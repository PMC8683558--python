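"""Synthetic FAERS-schema data with known ground truth.

Real spontaneous-report databases cannot ship with a package, so every stage
of the pipeline is exercised against generated quarters whose data-generating
process is fully known.  The generator emulates the FAERS report structure —
one DEMO row per report version, long DRUG/REAC/OUTC tables, ``$``-delimited
files — and plants the features the pipeline must detect or survive:

* drug-event associations with a configurable reporting-rate ratio ``theta``
  (``theta`` multiplies the event's baseline reporting probability in reports
  listing the drug or combination);
* duplicate cases, re-submitted with an incremented case version and
  identical content (what deduplication must remove);
* reports with blank drug names or no reactions (what assembly must drop);
* brand-name and misspelled drug-name variants (what normalization must map
  or fall through to ``other:*``).

Event reporting is independent Bernoulli per (report, event) with a
multiplicative ``theta`` — the simplest mechanism whose true reporting-rate
ratio equals the planted value.  Reports that would otherwise list no event
receive one background event drawn from the marginals, since a spontaneous
report without any adverse event does not occur in practice; the resulting
marginal inflation is a fraction of a binomial standard error at the default
settings.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .disproportionality import ContingencyTable
from .faers_io import RawQuarter, write_quarter

__all__ = [
    "PlantedAssociation",
    "CoPrescription",
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "generate_files",
    "simulate_contingency",
    "table2_fixture",
    "default_drug_probs",
    "default_event_probs",
]

# ---------------------------------------------------------------------------
# configuration

ICI_BRANDS = {
    "nivolumab": "OPDIVO",
    "pembrolizumab": "KEYTRUDA",
    "cemiplimab": "LIBTAYO",
    "atezolizumab": "TECENTRIQ",
    "avelumab": "BAVENCIO",
    "durvalumab": "IMFINZI",
    "ipilimumab": "YERVOY",
}

DEFAULT_RENAL_PTS = (
    "Acute kidney injury",
    "Renal failure",
    "Renal impairment",
    "Urinary tract infection",
    "Tubulointerstitial nephritis",
    "Chronic kidney disease",
    "Nephritis",
    "Hematuria",
    "Urinary retention",
    "Chromaturia",
)

_BACKGROUND_PT_NAMES = (
    "Nausea", "Fatigue", "Headache", "Diarrhoea", "Vomiting",
    "Pyrexia", "Dyspnoea", "Rash", "Pruritus", "Dizziness",
)


def default_drug_probs() -> dict[str, float]:
    """Marginal use probability per drug: 8 ICIs, 12 cytotoxics, 30 background.

    ICI probabilities mirror relative real-world reporting volume (nivolumab
    and pembrolizumab dominant); background drugs carry most of the database
    mass, as in FAERS where ICI reports are a small minority.
    """
    probs = {
        "nivolumab": 0.030,
        "pembrolizumab": 0.018,
        "cemiplimab": 0.001,
        "atezolizumab": 0.008,
        "avelumab": 0.002,
        "durvalumab": 0.005,
        "ipilimumab": 0.006,
        "tremelimumab": 0.002,
        "carboplatin": 0.030,
        "cisplatin": 0.020,
        "paclitaxel": 0.025,
        "pemetrexed": 0.012,
        "gemcitabine": 0.012,
        "docetaxel": 0.010,
        "oxaliplatin": 0.010,
        "fluorouracil": 0.010,
        "cyclophosphamide": 0.012,
        "doxorubicin": 0.010,
        "etoposide": 0.008,
        "capecitabine": 0.008,
    }
    rng = np.random.default_rng(20140101)  # fixed: catalogue is part of the defaults
    for i in range(30):
        probs[f"backgrounddrug{i + 1:02d}"] = float(rng.uniform(0.02, 0.09))
    return probs


def default_event_probs() -> dict[str, float]:
    """Baseline reporting probability per PT: 10 renal + 90 background."""
    probs = {
        "Acute kidney injury": 0.009,
        "Renal failure": 0.004,
        "Renal impairment": 0.003,
        "Urinary tract infection": 0.004,
        "Tubulointerstitial nephritis": 0.0008,
        "Chronic kidney disease": 0.002,
        "Nephritis": 0.0006,
        "Hematuria": 0.002,
        "Urinary retention": 0.002,
        "Chromaturia": 0.001,
    }
    rng = np.random.default_rng(20190630)
    for i, name in enumerate(_BACKGROUND_PT_NAMES):
        probs[name] = float(rng.uniform(0.02, 0.06))
    for i in range(80):
        probs[f"Background event {i + 1:02d}"] = float(rng.uniform(0.01, 0.05))
    return probs


@dataclass(frozen=True)
class PlantedAssociation:
    """Reporting-rate ratio ``theta`` for an event in reports listing ``drugs``."""

    drugs: frozenset[str]
    pt: str
    theta: float

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        object.__setattr__(self, "drugs", frozenset(self.drugs))


@dataclass(frozen=True)
class CoPrescription:
    """Reports listing ``trigger`` additionally list ``partner`` at ``rate``."""

    trigger: str
    partner: str
    rate: float


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic reporting process; defaults emulate a small FAERS.

    Probabilities are per report; rates in [0, 1].  ``duplicate_rate`` and
    ``drug_missing_rate`` plant exact counts (``round(rate * n_reports)``)
    so ground truth is sharp, not stochastic.
    """

    n_reports: int = 20_000
    drug_probs: Mapping[str, float] = field(default_factory=default_drug_probs)
    event_probs: Mapping[str, float] = field(default_factory=default_event_probs)
    renal_pts: Sequence[str] = DEFAULT_RENAL_PTS
    planted: Sequence[PlantedAssociation] = ()
    co_prescription: Sequence[CoPrescription] = (
        CoPrescription("nivolumab", "ipilimumab", 0.25),
        CoPrescription("durvalumab", "tremelimumab", 0.10),
        CoPrescription("pembrolizumab", "ipilimumab", 0.05),
    )
    chemo_drugs: Sequence[str] = (
        "carboplatin", "cisplatin", "paclitaxel", "pemetrexed", "gemcitabine",
        "docetaxel", "oxaliplatin", "fluorouracil", "cyclophosphamide",
        "doxorubicin", "etoposide", "capecitabine",
    )
    ici_drugs: Sequence[str] = tuple(ICI_BRANDS) + ("tremelimumab",)
    chemo_colist_rate: float = 0.30
    death_prob_base: float = 0.08
    death_probs: Mapping[tuple[frozenset[str], str], float] = field(default_factory=dict)
    other_outcome_probs: Mapping[str, float] = field(
        default_factory=lambda: {"HO": 0.30, "LT": 0.04, "DS": 0.02, "OT": 0.35}
    )
    brand_name_rate: float = 0.35
    misspell_rate: float = 0.0
    duplicate_rate: float = 0.05
    drug_missing_rate: float = 0.05
    reaction_missing_rate: float = 0.0
    sex_probs: Mapping[str, float] = field(
        default_factory=lambda: {"M": 0.44, "F": 0.44, "": 0.12}
    )
    age_mean: float = 62.0
    age_sd: float = 14.0
    age_missing_rate: float = 0.20
    year_probs: Mapping[int, float] = field(
        default_factory=lambda: {2014: 0.06, 2015: 0.10, 2016: 0.15, 2017: 0.17, 2018: 0.30, 2019: 0.22}
    )
    country_probs: Mapping[str, float] = field(
        default_factory=lambda: {"US": 0.55, "JP": 0.10, "FR": 0.07, "DE": 0.06, "GB": 0.05, "CA": 0.04, "": 0.13}
    )
    seed: int | None = None

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        for name, p in {**dict(self.drug_probs), **dict(self.event_probs)}.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {name!r} outside [0, 1]: {p}")
        for rate in (
            self.chemo_colist_rate, self.brand_name_rate, self.misspell_rate,
            self.duplicate_rate, self.drug_missing_rate, self.reaction_missing_rate,
        ):
            if not 0 <= rate <= 1:
                raise ValueError(f"rate outside [0, 1]: {rate}")


@dataclass
class GroundTruth:
    """What the generator actually planted, for exact downstream checks."""

    n_reports: int
    n_unique_cases: int
    n_expected_retained: int                 # after assembly exclusions + dedup
    missing_drug_case_ids: list[str]
    missing_reaction_case_ids: list[str]
    duplicate_case_ids: list[str]
    planted: list[dict]                      # drugs, pt, theta, expected_a, realized_a
    drug_counts: dict[str, int]              # Bernoulli draws, before min-one-drug fill
    event_counts: dict[str, int]             # Bernoulli draws, before min-one-event fill
    n_forced_events: int
    n_misspelled_rows: int
    n_truncated_probabilities: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _choice(rng: np.random.Generator, items: Sequence, probs: Sequence[float], n: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    return rng.choice(np.asarray(items, dtype=object), size=n, p=p / p.sum())


def generate(config: GeneratorConfig, seed: int | None = None) -> tuple[RawQuarter, GroundTruth]:
    """Draw one synthetic quarter; deterministic given ``seed``.

    Returns the raw tables (exactly what :func:`renalpv.faers_io.read_quarter`
    would parse from disk) and the :class:`GroundTruth` record.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_reports

    drug_names = list(config.drug_probs)
    pt_names = list(config.event_probs)
    drug_idx = {d: i for i, d in enumerate(drug_names)}
    pt_idx = {p: i for i, p in enumerate(pt_names)}

    # --- drug exposure ----------------------------------------------------
    X = np.zeros((n, len(drug_names)), dtype=bool)
    for j, name in enumerate(drug_names):
        X[:, j] = rng.random(n) < config.drug_probs[name]
    for co in config.co_prescription:
        t, p = drug_idx[co.trigger], drug_idx[co.partner]
        X[:, p] |= X[:, t] & (rng.random(n) < co.rate)
    ici_cols = [drug_idx[d] for d in config.ici_drugs if d in drug_idx]
    chemo_cols = [drug_idx[d] for d in config.chemo_drugs if d in drug_idx]
    if ici_cols and chemo_cols:
        has_ici = X[:, ici_cols].any(axis=1)
        add = has_ici & (rng.random(n) < config.chemo_colist_rate)
        picks = rng.integers(0, len(chemo_cols), size=n)
        for k, col in enumerate(chemo_cols):
            X[add & (picks == k), col] = True
    # counts of the Bernoulli draws themselves, before the fill that gives
    # every report at least one drug (as every real report lists one)
    drug_counts = {d: int(X[:, j].sum()) for d, j in drug_idx.items()}
    drugless = ~X.any(axis=1)
    if drugless.any():
        bg = [j for j in range(len(drug_names)) if j not in set(ici_cols) | set(chemo_cols)]
        weights = np.array([config.drug_probs[drug_names[j]] for j in bg])
        fill = rng.choice(bg, size=int(drugless.sum()), p=weights / weights.sum())
        X[np.nonzero(drugless)[0], fill] = True

    # --- events -----------------------------------------------------------
    planted_rows: list[dict] = []
    n_truncated = 0
    E = np.zeros((n, len(pt_names)), dtype=bool)
    combo_masks: dict[frozenset[str], np.ndarray] = {}
    for assoc in config.planted:
        cols = [drug_idx[d] for d in assoc.drugs]
        combo_masks.setdefault(assoc.drugs, X[:, cols].all(axis=1))
    for j, pt in enumerate(pt_names):
        p_eff = np.full(n, config.event_probs[pt])
        for assoc in config.planted:
            if assoc.pt != pt:
                continue
            mask = combo_masks[assoc.drugs]
            p_eff[mask] = np.maximum(p_eff[mask], config.event_probs[pt] * assoc.theta)
        over = p_eff > 1.0
        n_truncated += int(over.sum())
        np.clip(p_eff, 0.0, 1.0, out=p_eff)
        E[:, j] = rng.random(n) < p_eff
    event_counts = {p: int(E[:, j].sum()) for p, j in pt_idx.items()}

    eventless = ~E.any(axis=1)
    n_forced = int(eventless.sum())
    if n_forced:
        # fill from background (non-renal) PTs only, so the study-event
        # reporting rates stay exactly at their configured values
        renal = {str(p) for p in config.renal_pts}
        pool = [j for j, p in enumerate(pt_names) if p not in renal] or list(range(len(pt_names)))
        weights = np.array([config.event_probs[pt_names[j]] for j in pool])
        fill = rng.choice(pool, size=n_forced, p=weights / weights.sum())
        E[np.nonzero(eventless)[0], fill] = True

    for assoc in config.planted:
        mask = combo_masks[assoc.drugs]
        base = config.event_probs[assoc.pt]
        p1 = min(base * assoc.theta, 1.0)
        planted_rows.append(
            {
                "drugs": sorted(assoc.drugs),
                "pt": assoc.pt,
                "theta": assoc.theta,
                "n_exposed": int(mask.sum()),
                "expected_a": float(mask.sum() * p1),
                "realized_a": int((mask & E[:, pt_idx[assoc.pt]]).sum()),
            }
        )

    # --- outcomes ---------------------------------------------------------
    death_p = np.full(n, config.death_prob_base)
    for (drugs, pt), prob in config.death_probs.items():
        key = frozenset(drugs) if not isinstance(drugs, str) else frozenset([drugs])
        cols = [drug_idx[d] for d in key]
        mask = X[:, cols].all(axis=1) & E[:, pt_idx[pt]]
        death_p[mask] = prob
    death = rng.random(n) < death_p
    other_outcomes = {
        code: rng.random(n) < prob for code, prob in config.other_outcome_probs.items()
    }

    # --- demographics -----------------------------------------------------
    sex = _choice(rng, list(config.sex_probs), list(config.sex_probs.values()), n)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 18, 95).round(0)
    age_missing = rng.random(n) < config.age_missing_rate
    age_str = age.astype(int).astype("U3")
    age_str[age_missing] = ""
    age_cod = np.where(age_missing, "", "YR")
    year = _choice(rng, list(config.year_probs), list(config.year_probs.values()), n).astype(int)
    year_str = year.astype("U4")
    country = _choice(rng, list(config.country_probs), list(config.country_probs.values()), n)

    case_ids = (np.arange(n) + 10_000_000).astype("U8")
    primary_ids = np.char.add(case_ids, "1")

    # --- planted missingness (exact counts) -------------------------------
    n_missing_drug = int(round(config.drug_missing_rate * n))
    n_missing_reac = int(round(config.reaction_missing_rate * n))
    exclusion_pool = rng.permutation(n)
    missing_drug_rows = set(exclusion_pool[:n_missing_drug].tolist())
    missing_reac_rows = set(exclusion_pool[n_missing_drug:n_missing_drug + n_missing_reac].tolist())

    # --- duplicates: identical resubmission, case version 2 ---------------
    n_dup = int(round(config.duplicate_rate * n))
    dup_rows = np.sort(rng.choice(n, size=n_dup, replace=False)) if n_dup else np.array([], dtype=int)

    # --- long tables ------------------------------------------------------
    r_idx, d_idx = np.nonzero(X)
    names_arr = np.array([d.upper() for d in drug_names], dtype=object)[d_idx]
    brand_mask = (rng.random(len(r_idx)) < config.brand_name_rate) & np.isin(
        np.array(drug_names, dtype=object)[d_idx], list(ICI_BRANDS)
    )
    brand_map = {k.upper(): v for k, v in ICI_BRANDS.items()}
    names_arr[brand_mask] = [brand_map[name] for name in names_arr[brand_mask]]
    misspelled = rng.random(len(r_idx)) < config.misspell_rate
    names_arr[misspelled] = np.char.add(names_arr[misspelled].astype(str), "XQ").astype(object)
    verbatim = names_arr
    verbatim[np.isin(r_idx, list(missing_drug_rows))] = ""

    first_of_report = np.r_[True, r_idx[1:] != r_idx[:-1]]
    roles = np.where(first_of_report, "PS", _choice(rng, ["SS", "C"], [0.6, 0.4], len(r_idx)))
    # position of each drug row within its report, 1-based
    seq = np.arange(len(r_idx)) - np.maximum.accumulate(
        np.where(first_of_report, np.arange(len(r_idx)), -1)
    ) + 1

    drug_frame = pd.DataFrame(
        {
            "primaryid": primary_ids[r_idx],
            "drug_seq": seq,
            "drugname": verbatim,
            "role_cod": roles,
        }
    )

    er_idx, ep_idx = np.nonzero(E)
    keep_reac = ~np.isin(er_idx, list(missing_reac_rows))
    reac_frame = pd.DataFrame(
        {
            "primaryid": primary_ids[er_idx[keep_reac]],
            "pt": np.array(pt_names, dtype=object)[ep_idx[keep_reac]],
        }
    )

    outc_parts = [pd.DataFrame({"primaryid": primary_ids[death], "outc_cod": "DE"})]
    for code, mask in other_outcomes.items():
        outc_parts.append(pd.DataFrame({"primaryid": primary_ids[mask], "outc_cod": code}))
    outc_frame = pd.concat(outc_parts, ignore_index=True)
    outc_frame = outc_frame.sort_values(["primaryid", "outc_cod"], kind="stable").reset_index(drop=True)

    fda_dt = np.char.add(year_str, "0215")
    event_dt = np.char.add(year_str, "0110")
    demo_frame = pd.DataFrame(
        {
            "primaryid": primary_ids,
            "caseid": case_ids,
            "caseversion": "1",
            "fda_dt": fda_dt,
            "event_dt": event_dt,
            "age": age_str,
            "age_cod": age_cod,
            "sex": sex,
            "occr_country": country,
        }
    )

    if n_dup:
        dup_primary = np.char.add(case_ids[dup_rows], "2")
        dup_demo = demo_frame.iloc[dup_rows].copy()
        dup_demo["primaryid"] = dup_primary
        dup_demo["caseversion"] = "2"
        dup_demo["fda_dt"] = np.char.add(year_str[dup_rows], "0901")
        remap = dict(zip(primary_ids[dup_rows], dup_primary))

        def _dup(frame: pd.DataFrame) -> pd.DataFrame:
            part = frame[frame["primaryid"].isin(remap)].copy()
            part["primaryid"] = part["primaryid"].map(remap)
            return pd.concat([frame, part], ignore_index=True)

        demo_frame = pd.concat([demo_frame, dup_demo], ignore_index=True)
        drug_frame = _dup(drug_frame)
        reac_frame = _dup(reac_frame)
        outc_frame = _dup(outc_frame)

    quarter = RawQuarter(
        demo=demo_frame, drug=drug_frame, reac=reac_frame, outc=outc_frame,
        parse_stats={"generated": n, "duplicates": int(n_dup)},
    )

    truth = GroundTruth(
        n_reports=n + n_dup,
        n_unique_cases=n,
        n_expected_retained=n - len(set(missing_drug_rows) | missing_reac_rows),
        missing_drug_case_ids=sorted(case_ids[sorted(missing_drug_rows)].tolist()),
        missing_reaction_case_ids=sorted(case_ids[sorted(missing_reac_rows)].tolist()),
        duplicate_case_ids=sorted(case_ids[dup_rows].tolist()),
        planted=planted_rows,
        drug_counts=drug_counts,
        event_counts=event_counts,
        n_forced_events=n_forced,
        n_misspelled_rows=int(misspelled.sum()),
        n_truncated_probabilities=n_truncated,
    )
    return quarter, truth


def generate_files(
    config: GeneratorConfig, directory: str | Path, seed: int | None = None
) -> tuple[dict[str, Path], GroundTruth]:
    """Generate a quarter and write it in the FAERS dialect plus ground truth JSON."""
    quarter, truth = generate(config, seed=seed)
    paths = write_quarter(quarter, directory)
    truth.to_json(Path(directory) / "ground_truth.json")
    return paths, truth


def simulate_contingency(
    n_target: int, n_comparator: int, baseline: float, theta: float, rng: np.random.Generator
) -> ContingencyTable:
    """One synthetic study collapsed to its 2x2 sufficient statistic.

    ``n_target`` reports carry the drug and report the event independently
    with probability ``baseline * theta``; ``n_comparator`` reports report it
    with ``baseline``.  Binomial draws of the two event counts are exactly
    equivalent to drawing the report-level Bernoulli dataset and counting.
    """
    p1 = min(baseline * theta, 1.0)
    a = int(rng.binomial(n_target, p1))
    c = int(rng.binomial(n_comparator, baseline))
    return ContingencyTable(a=a, b=n_target - a, c=c, d=n_comparator - c)


_TABLE2_CELLS: dict[str, tuple[int, int, int, int]] = {
    # ICI regimens without chemotherapy, vs rest of database
    "Total": (4578, 138168, 1104288, 29367235),
    "Nivolumab": (1838, 56234, 1107028, 29437715),
    "Pembrolizumab": (851, 28811, 1108015, 29465138),
    "Cemiplimab": (6, 188, 1108860, 29493761),
    "Atezolizumab": (337, 5861, 1108529, 29488088),
    "Avelumab": (28, 833, 1108838, 29493116),
    "Durvalumab": (58, 2327, 1108808, 29491622),
    "Ipilimumab": (203, 10940, 1108663, 29483009),
    "Poly1": (18, 316, 1108848, 29493633),
    "Poly2": (798, 22428, 1108068, 29471521),
    "Poly3": (37, 672, 1108829, 29493277),
    # ICI regimens with chemotherapy, vs rest of database
    "Nivolumab+chemo": (103, 2481, 1108763, 29491468),
    "Pembrolizumab+chemo": (49, 1723, 1108817, 29492226),
    "Atezolizumab+chemo": (93, 2005, 1108773, 29491944),
    "Avelumab+chemo": (15, 364, 1108851, 29493585),
    "Durvalumab+chemo": (11, 547, 1108855, 29493402),
    "Ipilimumab+chemo": (12, 299, 1108854, 29493650),
    "Poly2+chemo": (76, 1234, 1108790, 29492715),
    "Poly4+chemo": (18, 164, 1108848, 29493785),
    # head-to-head regimen comparisons (group1 vs group2)
    "PD-1/PD-L1 vs CTLA-4 (no chemo)": (3118, 94254, 203, 10940),
    "Poly vs mono (no chemo)": (853, 23484, 3322, 105228),
    "PD-1/PD-L1 vs CTLA-4 (chemo)": (271, 7120, 12, 299),
    "Poly vs mono (chemo)": (94, 1509, 284, 7439),
    "PD-1/PD-L1 vs CTLA-4 (total)": (3389, 101374, 215, 11239),
    "Poly vs mono (total)": (947, 24993, 3606, 112667),
    "ICI+chemo vs ICI alone": (378, 8948, 4175, 128712),
}


def table2_fixture() -> dict[str, ContingencyTable]:
    """Published regimen-level 2x2 report counts, keyed by row label.

    These pre-aggregated cells let the statistics be validated end to end
    without simulating a thirty-million-report database: each value is a
    report count (``a`` = regimen with renal event, ``b`` = regimen without,
    ``c``/``d`` = comparator with/without).  Comparison rows use the two
    regimen groups as the margins instead of regimen vs rest-of-database.
    """
    return {k: ContingencyTable(*cells) for k, cells in _TABLE2_CELLS.items()}
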