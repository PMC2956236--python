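"""Contingency tables and inferential statistics for coded transitions.

Five table families are built from coded transitions, each cross-
classified by study arm:

* ``profile`` — 3 profile codes × arms
* ``query`` — 4 reformulation codes × arms
* ``combo`` — 12 profile × reformulation combinations × arms
* ``position_by_action`` — one 4 action × arms table per position
* ``pair`` — 16 (current action, next action) pairs × arms

Statistics follow the conventions of two-arm behavioral log studies:
Pearson chi-square without continuity correction for table-level
independence, the Wilson score interval for per-cell binomial
proportions, and the unpooled two-proportion z-test for row-wise
between-arm comparisons.  No multiple-testing correction is applied; the
rendered report states the number of tests performed.

Rounding is applied at render time only: percentages to 1 decimal, CI
bounds and z to 2, chi-square to 2; p-values below .001 print as "<.001"
with the 3-decimal value alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats as sps

from .log_model import Arm, StudyLog, summarize_log
from .query_coder import CoderConfig, DEFAULT_CONFIG, ReformulationType
from .transition_coder import (
    ActionCategory,
    Position,
    ProfileCode,
    Transition,
    action_pairs_by_session,
    code_log,
    transitions_to_frame,
)

__all__ = [
    "ContingencyTable",
    "ProportionSummary",
    "ChiSquareResult",
    "ZTestResult",
    "StatsError",
    "DegenerateTableError",
    "build_table",
    "pearson_chi_square",
    "wilson_interval",
    "proportion_summary",
    "two_proportion_z",
    "full_report",
    "ReportBundle",
    "format_p",
    "PROFILE_ORDER",
    "QUERY_ORDER",
    "COMBO_ORDER",
    "ACTION_ORDER",
    "PAIR_ORDER",
    "TABLE_FILENAMES",
]


class StatsError(ValueError):
    """Base class for statistical-computation errors."""


class DegenerateTableError(StatsError):
    """A table (or proportion pair) on which the requested test is undefined."""


PROFILE_ORDER = (ProfileCode.SAME, ProfileCode.PREVIOUS, ProfileCode.NEW)
QUERY_ORDER = (
    ReformulationType.NONE,
    ReformulationType.SYNTACTIC_ONLY,
    ReformulationType.SEMANTIC_ONLY,
    ReformulationType.SYNTACTIC_AND_SEMANTIC,
)
COMBO_ORDER = tuple((pc, qc) for pc in PROFILE_ORDER for qc in QUERY_ORDER)
ACTION_ORDER = (
    ActionCategory.NO_CHANGE,
    ActionCategory.CHANGE_QUERY_ONLY,
    ActionCategory.CHANGE_PROFILE_ONLY,
    ActionCategory.CHANGE_QUERY_AND_PROFILE,
)
PAIR_ORDER = tuple((a, b) for a in ACTION_ORDER for b in ACTION_ORDER)
POSITION_ORDER = (Position.FIRST, Position.MIDDLE, Position.LAST)


@dataclass(frozen=True)
class ContingencyTable:
    """Labeled counts cross-classified by a row category and study arm."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray  # shape (rows, cols), non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def column(self, label: str) -> np.ndarray:
        return self.counts[:, self.col_labels.index(label)]


@dataclass(frozen=True)
class ProportionSummary:
    """A cell's count out of its column total with a Wilson interval,
    mirroring an "N (%) (95% CI)" table entry.  Unrounded values are
    stored; rounding happens at render time."""

    count: int
    n: int
    pct: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ZTestResult:
    z: float
    p_value: float
    diff: float  # percentage-point difference, col1 − col2


def _row_key(axis: str, t: Transition):
    if axis == "profile":
        return t.profile_code
    if axis == "query":
        return t.query_code.value
    if axis == "combo":
        return (t.profile_code, t.query_code.value)
    raise ValueError(axis)


def _combo_label(pc: ProfileCode, qc: ReformulationType) -> str:
    return f"{pc.value}+{qc.value}"


def _pair_label(a: ActionCategory, b: ActionCategory) -> str:
    return f"{a.value}->{b.value}"


def build_table(
    transitions: Sequence[Transition],
    axis: Literal["profile", "query", "combo", "position_by_action", "pair"],
) -> ContingencyTable | dict[Position, ContingencyTable]:
    """Aggregate coded transitions into one of the five table families.

    Column order is resource then task, restricted to the arms present.
    ``position_by_action`` returns one table per position; all other axes
    a single :class:`ContingencyTable`.  Raises
    :class:`DegenerateTableError` on an empty transition set.
    """
    transitions = list(transitions)
    if not transitions:
        raise DegenerateTableError("cannot build a table from an empty transition set")
    arms = [a for a in (Arm.RESOURCE, Arm.TASK) if any(t.arm == a for t in transitions)]
    col_labels = tuple(a.value for a in arms)
    arm_idx = {a: i for i, a in enumerate(arms)}

    if axis in ("profile", "query", "combo"):
        if axis == "profile":
            rows = list(PROFILE_ORDER)
            labels = tuple(r.value for r in rows)
        elif axis == "query":
            rows = list(QUERY_ORDER)
            labels = tuple(r.value for r in rows)
        else:
            rows = list(COMBO_ORDER)
            labels = tuple(_combo_label(*r) for r in rows)
        row_idx = {r: i for i, r in enumerate(rows)}
        counts = np.zeros((len(rows), len(arms)), dtype=np.int64)
        for t in transitions:
            counts[row_idx[_row_key(axis, t)], arm_idx[t.arm]] += 1
        return ContingencyTable(labels, col_labels, counts)

    if axis == "position_by_action":
        out: dict[Position, ContingencyTable] = {}
        labels = tuple(a.value for a in ACTION_ORDER)
        row_idx = {a: i for i, a in enumerate(ACTION_ORDER)}
        for pos in POSITION_ORDER:
            counts = np.zeros((len(ACTION_ORDER), len(arms)), dtype=np.int64)
            for t in transitions:
                if t.position is pos:
                    counts[row_idx[t.action], arm_idx[t.arm]] += 1
            out[pos] = ContingencyTable(labels, col_labels, counts)
        return out

    if axis == "pair":
        labels = tuple(_pair_label(a, b) for a, b in PAIR_ORDER)
        row_idx = {p: i for i, p in enumerate(PAIR_ORDER)}
        counts = np.zeros((len(PAIR_ORDER), len(arms)), dtype=np.int64)
        for arm, a, b in action_pairs_by_session(transitions):
            counts[row_idx[(a, b)], arm_idx[arm]] += 1
        return ContingencyTable(labels, col_labels, counts)

    raise ValueError(f"unknown axis {axis!r}")


def pearson_chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction.

    ``statistic = Σ (observed − expected)² / expected`` with
    ``expected = row total × column total / grand total``; the p-value is
    the upper tail of χ² with (r−1)(c−1) degrees of freedom.  Raises
    :class:`DegenerateTableError` when any row or column total is zero.
    """
    obs = table.counts
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateTableError("chi-square needs at least a 2x2 table")
    row_tot = table.row_totals
    col_tot = table.col_totals
    if (row_tot == 0).any() or (col_tot == 0).any():
        raise DegenerateTableError("zero row or column total: expected counts undefined")
    expected = np.outer(row_tot, col_tot) / table.grand_total
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return ChiSquareResult(statistic=stat, df=df, p_value=p)


def wilson_interval(count: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, in percent.

    Center ``(p + z²/2n)/(1 + z²/n)``, half-width
    ``z·sqrt(p(1−p)/n + z²/4n²)/(1 + z²/n)`` with z the standard normal
    quantile for ``conf``.  Raises on n = 0 or count outside [0, n].
    """
    if n < 1:
        raise StatsError("wilson_interval requires n >= 1")
    if not 0 <= count <= n:
        raise StatsError(f"count {count} outside [0, {n}]")
    z = float(sps.norm.ppf(0.5 + conf / 2.0))
    p = count / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    # the Wilson bounds lie in [0, 1] analytically; clamp fp round-off
    return (max(0.0, 100.0 * (center - half)), min(100.0, 100.0 * (center + half)))


def proportion_summary(count: int, n: int, conf: float = 0.95) -> ProportionSummary:
    low, high = wilson_interval(count, n, conf)
    return ProportionSummary(
        count=count, n=n, pct=100.0 * count / n, ci_low=low, ci_high=high, conf_level=conf
    )


def two_proportion_z(count1: int, n1: int, count2: int, n2: int) -> ZTestResult:
    """Unpooled two-proportion z-test (each sample's own proportion in the
    standard error); two-sided p.  Raises :class:`DegenerateTableError`
    when both proportions are 0 or both are 1 (zero standard error)."""
    if n1 < 1 or n2 < 1:
        raise StatsError("two_proportion_z requires n1, n2 >= 1")
    p1, p2 = count1 / n1, count2 / n2
    se2 = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    if se2 == 0.0:
        raise DegenerateTableError("zero standard error: both proportions degenerate")
    z = (p1 - p2) / math.sqrt(se2)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return ZTestResult(z=z, p_value=p, diff=100.0 * (p1 - p2))


def format_p(p: float) -> str:
    """Conventional p-value string: '<.001' below 0.001, else 3 decimals."""
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0")


# ---------------------------------------------------------------------------
# full report


@dataclass(frozen=True)
class RowComparison:
    """One table row: per-arm proportion summaries and the between-arm z."""

    row_label: str
    summaries: dict[str, ProportionSummary]  # keyed by arm label
    z: ZTestResult | None
    note: str = ""


@dataclass(frozen=True)
class TableReport:
    name: str
    table: ContingencyTable
    rows: tuple[RowComparison, ...]
    chi_square: ChiSquareResult | None
    note: str = ""


@dataclass(frozen=True)
class ReportBundle:
    summary: "object"
    tables: dict[str, TableReport | dict[Position, TableReport]]
    n_tests: int


TABLE_FILENAMES = {
    "profile": "profile_actions.csv",
    "query": "query_actions.csv",
    "combo": "combined_actions.csv",
    "position_by_action": "actions_by_position.csv",
    "pair": "consecutive_pairs.csv",
}


def _report_for_table(name: str, table: ContingencyTable, conf: float) -> TableReport:
    two_arms = len(table.col_labels) == 2
    n_cols = {lab: int(tot) for lab, tot in zip(table.col_labels, table.col_totals)}
    rows = []
    for i, rl in enumerate(table.row_labels):
        summaries = {
            lab: proportion_summary(int(table.counts[i, j]), n_cols[lab], conf)
            for j, lab in enumerate(table.col_labels)
            if n_cols[lab] > 0
        }
        z = None
        note = ""
        if two_arms and all(n_cols[lab] > 0 for lab in table.col_labels):
            c1, c2 = int(table.counts[i, 0]), int(table.counts[i, 1])
            try:
                z = two_proportion_z(c1, n_cols[table.col_labels[0]], c2, n_cols[table.col_labels[1]])
            except DegenerateTableError:
                note = "z-test undefined (degenerate proportions)"
        elif not two_arms:
            note = "single arm: between-arm test skipped"
        rows.append(RowComparison(row_label=rl, summaries=summaries, z=z, note=note))
    chi = None
    note = ""
    if two_arms:
        try:
            chi = pearson_chi_square(table)
        except DegenerateTableError as exc:
            note = f"chi-square skipped: {exc}"
    else:
        note = "single arm: chi-square skipped"
    return TableReport(name=name, table=table, rows=tuple(rows), chi_square=chi, note=note)


def full_report(
    log: StudyLog,
    out_dir: str | Path | None = None,
    config: CoderConfig = DEFAULT_CONFIG,
    conf: float = 0.95,
) -> ReportBundle:
    """Code a whole log and compute every table family with its statistics.

    With ``out_dir`` set, writes the coded transitions, one CSV per table
    family, and a human-readable ``report.txt``.  A single-arm log yields
    tables and proportion summaries only, with between-arm tests skipped
    and a notice recorded.  Raises on an empty log.
    """
    if log.n_sessions == 0:
        raise StatsError("empty log: nothing to report")
    transitions = code_log(log, config)
    if not transitions:
        raise StatsError("log contains no codable transitions (all sessions have one search)")
    summary = summarize_log(log)

    tables: dict[str, TableReport | dict[Position, TableReport]] = {}
    for name in ("profile", "query", "combo", "pair"):
        tables[name] = _report_for_table(name, build_table(transitions, name), conf)
    pos_tables = build_table(transitions, "position_by_action")
    tables["position_by_action"] = {
        pos: _report_for_table(f"position_{pos.value}", tab, conf)
        for pos, tab in pos_tables.items()
    }

    n_tests = 0
    for rep in _iter_reports(tables):
        n_tests += (rep.chi_square is not None) + sum(r.z is not None for r in rep.rows)

    bundle = ReportBundle(summary=summary, tables=tables, n_tests=n_tests)
    if out_dir is not None:
        _write_report(bundle, transitions, Path(out_dir))
    return bundle


def _iter_reports(tables) -> Iterable[TableReport]:
    for v in tables.values():
        if isinstance(v, dict):
            yield from v.values()
        else:
            yield v


def _table_csv_rows(rep: TableReport) -> list[list[str]]:
    rows = []
    for r in rep.rows:
        row: list[str] = [r.row_label]
        for lab in rep.table.col_labels:
            s = r.summaries.get(lab)
            if s is None:
                row += ["", "", "", ""]
            else:
                row += [str(s.count), f"{s.pct:.1f}", f"{s.ci_low:.2f}", f"{s.ci_high:.2f}"]
        if r.z is not None:
            row += [f"{r.z.z:.2f}", format_p(r.z.p_value)]
        else:
            row += ["", ""]
        rows.append(row)
    return rows


def _write_report(bundle: ReportBundle, transitions: Sequence[Transition], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    transitions_to_frame(transitions).to_csv(out_dir / "coded_transitions.csv", index=False)

    import csv as _csv

    def write_csv(name: str, reps: list[TableReport], extra_col: bool) -> None:
        with (out_dir / name).open("w", encoding="utf-8", newline="") as fh:
            w = _csv.writer(fh)
            header = ["row"]
            if extra_col:
                header = ["position"] + header
            for lab in reps[0].table.col_labels:
                header += [f"{lab}_count", f"{lab}_pct", f"{lab}_ci_low", f"{lab}_ci_high"]
            header += ["z", "p"]
            w.writerow(header)
            for rep in reps:
                for row in _table_csv_rows(rep):
                    w.writerow(([rep.name.removeprefix("position_")] if extra_col else []) + row)

    for axis, fname in TABLE_FILENAMES.items():
        entry = bundle.tables[axis]
        if isinstance(entry, dict):
            write_csv(fname, [entry[pos] for pos in POSITION_ORDER], extra_col=True)
        else:
            write_csv(fname, [entry], extra_col=False)

    lines: list[str] = []
    s = bundle.summary
    lines.append("Search-action coding report")
    lines.append("===========================")
    lines.append(f"Sessions: {s.sessions}   Searches: {s.searches}   Transitions: {s.transitions}")
    for arm, a in s.per_arm.items():
        lines.append(
            f"  {arm.value}: {a.sessions} sessions, {a.searches} searches, "
            f"{a.transitions} transitions"
        )
    lines.append("")
    for axis in ("profile", "query", "combo", "position_by_action", "pair"):
        entry = bundle.tables[axis]
        reps = (
            [entry[pos] for pos in POSITION_ORDER] if isinstance(entry, dict) else [entry]
        )
        for rep in reps:
            lines.append(f"[{rep.name}]")
            if rep.chi_square is not None:
                c = rep.chi_square
                lines.append(
                    f"  chi-square({c.df}) = {c.statistic:.2f}, p = {format_p(c.p_value)}"
                )
            if rep.note:
                lines.append(f"  note: {rep.note}")
            for r in rep.rows:
                cells = "  ".join(
                    f"{lab}: {smr.count}/{smr.n} ({smr.pct:.1f}%, "
                    f"{int(100 * smr.conf_level)}% CI {smr.ci_low:.2f}-{smr.ci_high:.2f})"
                    for lab, smr in r.summaries.items()
                )
                ztxt = (
                    f"  Z = {r.z.z:.2f}, p = {format_p(r.z.p_value)}" if r.z is not None else ""
                )
                lines.append(f"  {r.row_label}: {cells}{ztxt}")
            lines.append("")
    lines.append(
        f"{bundle.n_tests} significance tests performed; no multiple-testing correction applied."
    )
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
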