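"""Disproportionality statistics for spontaneous-report signal detection.

Every statistic here is computed from a 2x2 contingency table of report
counts::

                      event   no event
    target group        a        b          (n_drug  = a + b)
    comparator          c        d          (n_event = a + c)

Two estimators are provided.  The reporting odds ratio (ROR) is the classical
odds ratio ``ad / bc`` with a Woolf (log-normal) confidence interval,

    CI = exp( ln ROR  +/-  z * sqrt(1/a + 1/b + 1/c + 1/d) ).

The information component (IC) is the base-2 log of the shrunken
observed-to-expected ratio,

    IC = log2( (a + 0.5) / (E + 0.5) ),    E = n_drug * n_event / n_total,

whose +0.5 shrinkage pulls small-count estimates toward zero; its credibility
bounds use the standard closed-form approximation to the BCPNN posterior
(Noren et al.):

    IC025 = IC - 3.3 (a+0.5)^-1/2 - 2.0 (a+0.5)^-3/2
    IC975 = IC + 2.4 (a+0.5)^-1/2 - 0.5 (a+0.5)^-3/2

A drug-event pair is a *signal* when it has at least ``min_reports`` reports
(default 3) and ROR025 exceeds 1 or IC025 exceeds 0 — both strictly: a bound
sitting exactly on the threshold is not a signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Union

import numpy as np
from scipy.stats import norm

__all__ = [
    "ContingencyTable",
    "SignalEstimate",
    "RorResult",
    "IcResult",
    "build_contingency",
    "ror_classical",
    "ror_shrunken",
    "ic",
    "classify_signal",
    "estimate_signal",
    "comparative_ror",
]

DEFAULT_MIN_REPORTS = 3


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of report counts; derived margins are always recomputed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_event(self) -> int:
        return self.a + self.c

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell ``a`` under row/column independence."""
        if self.n_total == 0:
            return 0.0
        return self.n_drug * self.n_event / self.n_total

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def corrected(self) -> tuple[float, float, float, float]:
        """Haldane-Anscombe +0.5 on every cell (zero-cell fallback)."""
        return self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5

    def swapped(self) -> "ContingencyTable":
        """Exchange target and comparator rows."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class RorResult:
    ror: float
    ror_025: float
    ror_975: float
    continuity_corrected: bool = False

    def __iter__(self):
        return iter((self.ror, self.ror_025, self.ror_975))


@dataclass(frozen=True)
class IcResult:
    ic: float
    ic_025: float
    ic_975: float

    def __iter__(self):
        return iter((self.ic, self.ic_025, self.ic_975))


@dataclass(frozen=True)
class SignalEstimate:
    """ROR and IC with interval bounds, plus the signal classification."""

    ror: float
    ror_025: float
    ror_975: float
    ic: float
    ic_025: float
    ic_975: float
    n_observed: int
    eligible: bool = False
    is_signal: bool = False
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if self.is_signal and not self.eligible:
            raise ValueError("is_signal requires eligible")


def ror_classical(table: ContingencyTable, alpha: float = 0.95) -> RorResult:
    """Classical reporting odds ratio with a Woolf confidence interval.

    ``alpha`` is the two-sided confidence level (0.95 gives ROR025/ROR975).
    A zero cell triggers the Haldane-Anscombe +0.5 correction on all four
    cells, flagged in the result; nonzero tables are never altered.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    corrected = table.has_zero_cell
    a, b, c, d = table.corrected() if corrected else (table.a, table.b, table.c, table.d)
    z = norm.ppf(1 - (1 - alpha) / 2)
    log_ror = np.log(a) + np.log(d) - np.log(b) - np.log(c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorResult(
        ror=float(np.exp(log_ror)),
        ror_025=float(np.exp(log_ror - z * se)),
        ror_975=float(np.exp(log_ror + z * se)),
        continuity_corrected=corrected,
    )


def ror_shrunken(table: ContingencyTable) -> float:
    """Shrunken observed/expected ratio ``(a + 0.5) / (E + 0.5)``.

    A secondary, additively smoothed estimator of relative reporting: equal
    to 1 exactly when the observed count matches expectation (including the
    fully empty table).  Note this is an O/E ratio, not an odds ratio.
    """
    return (table.a + 0.5) / (table.expected + 0.5)


def ic(table: ContingencyTable) -> IcResult:
    """Information component with 95% credibility bounds (see module notes)."""
    center = float(np.log2(ror_shrunken(table)))
    s = table.a + 0.5
    return IcResult(
        ic=center,
        ic_025=center - 3.3 * s ** -0.5 - 2.0 * s ** -1.5,
        ic_975=center + 2.4 * s ** -0.5 - 0.5 * s ** -1.5,
    )


def estimate_signal(
    table: ContingencyTable,
    alpha: float = 0.95,
    min_reports: int = DEFAULT_MIN_REPORTS,
) -> SignalEstimate:
    """Compute ROR, IC and the signal classification for one table."""
    r = ror_classical(table, alpha=alpha)
    i = ic(table)
    est = SignalEstimate(
        ror=r.ror,
        ror_025=r.ror_025,
        ror_975=r.ror_975,
        ic=i.ic,
        ic_025=i.ic_025,
        ic_975=i.ic_975,
        n_observed=table.a,
        continuity_corrected=r.continuity_corrected,
    )
    return classify_signal(est, min_reports=min_reports)


def classify_signal(estimate: SignalEstimate, min_reports: int = DEFAULT_MIN_REPORTS) -> SignalEstimate:
    """Apply the signal rule: eligible (>= min_reports) and ROR025 > 1 or IC025 > 0.

    Both threshold comparisons are strict; pairs below ``min_reports`` are
    ineligible and therefore never signals regardless of their statistics.
    """
    if min_reports < 1:
        raise ValueError("min_reports must be >= 1")
    eligible = estimate.n_observed >= min_reports
    is_signal = bool(eligible and (estimate.ror_025 > 1.0 or estimate.ic_025 > 0.0))
    return SignalEstimate(
        ror=estimate.ror,
        ror_025=estimate.ror_025,
        ror_975=estimate.ror_975,
        ic=estimate.ic,
        ic_025=estimate.ic_025,
        ic_975=estimate.ic_975,
        n_observed=estimate.n_observed,
        eligible=eligible,
        is_signal=is_signal,
        continuity_corrected=estimate.continuity_corrected,
    )


EventSelector = Union[Iterable[str], Callable[[str], bool]]


def _event_mask(dataset, event_selector: EventSelector):
    import pandas as pd

    if callable(event_selector) and not isinstance(event_selector, (set, frozenset)):
        pts = dataset.reactions["value"]
        hit_pts = {p for p in pts.unique() if event_selector(p)}
        return dataset.event_mask(hit_pts) if hit_pts else pd.Series(False, index=dataset.index.index)
    return dataset.event_mask(event_selector)


def build_contingency(dataset, target, event_selector: EventSelector, comparator="rest") -> ContingencyTable:
    """Count the 2x2 table for a target report group against a comparator.

    ``target`` and ``comparator`` are report-id collections or boolean masks
    indexed by report id; ``comparator="rest"`` uses every report not in the
    target group (rest-of-database).  ``event_selector`` is a PT collection
    (case-insensitive) or a predicate over PT strings.  Each report counts
    once; overlapping target/comparator groups are an error.
    """
    import pandas as pd

    def _as_mask(sel) -> pd.Series:
        if isinstance(sel, pd.Series):
            return sel.reindex(dataset.index.index, fill_value=False).astype(bool)
        ids = set(map(str, sel))
        return pd.Series(dataset.index.index.isin(ids), index=dataset.index.index)

    target_mask = _as_mask(target)
    if isinstance(comparator, str) and comparator == "rest":
        comp_mask = ~target_mask
    else:
        comp_mask = _as_mask(comparator)
        overlap = target_mask & comp_mask
        if overlap.any():
            raise ValueError(
                f"target and comparator overlap in {int(overlap.sum())} report(s)"
            )
    event = _event_mask(dataset, event_selector)
    return ContingencyTable(
        a=int((target_mask & event).sum()),
        b=int((target_mask & ~event).sum()),
        c=int((comp_mask & event).sum()),
        d=int((comp_mask & ~event).sum()),
    )


def comparative_ror(dataset, group1, group2, event_selector: EventSelector, alpha: float = 0.95) -> RorResult:
    """ROR contrasting event reporting between two disjoint report groups.

    Used for regimen-vs-regimen comparisons (e.g. combination vs monotherapy),
    where only the ROR — not the IC — is meaningful because neither group is
    the whole-database background.
    """
    table = build_contingency(dataset, group1, event_selector, comparator=group2)
    return ror_classical(table, alpha=alpha)
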