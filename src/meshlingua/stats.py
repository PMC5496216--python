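"""Trial-level statistics: Fisher's exact test, two-proportion sample size,
Mann-Whitney, and two-arm error-rate summaries.

The evaluation design these serve: two arms of participants (querying in
their own language vs. in English) each translate the same questions into
MeSH queries; every query gets an error report; arm proportions are
compared with Fisher's exact test, times with Mann-Whitney, and the study
was sized for an improvement in the perfect-query proportion from 25% to
40% at alpha = 0.05 (two-sided) and beta = 0.1 with binomial variance
p(1-p)/n, at the observation (query) level.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats as sps

from .grading import ErrorKind, ErrorReport

DIFFICULTIES = ("low", "medium", "high")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows are arms, columns with/without the property."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value.

    Minimum-likelihood convention: the p-value sums hypergeometric
    probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (the convention of
    R's ``fisher.test``).
    """
    if table.a + table.b == 0 and table.c + table.d == 0:
        raise ValueError("both row margins are zero")
    _, p = sps.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return float(min(p, 1.0))


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design parameters for a two-proportion comparison.

    ``alpha`` is the two-sided type-I level, ``beta`` the type-II rate;
    ``queries_per_subject`` converts observation-level n into subjects.
    """

    p1: float
    p2: float
    alpha: float = 0.05
    beta: float = 0.10
    queries_per_subject: int = 12

    def __post_init__(self) -> None:
        for name, v in (("p1", self.p1), ("p2", self.p2)):
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.p1 == self.p2:
            raise ValueError("p1 and p2 must differ")
        for name, v in (("alpha", self.alpha), ("beta", self.beta)):
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.queries_per_subject < 1:
            raise ValueError("queries_per_subject must be positive")


def sample_size_two_proportions(spec: SampleSizeSpec) -> tuple[int, int]:
    """Observation-level n per group and subjects per group.

    n = ceil( (z_{1-a/2} + z_{1-b})^2 (p1 q1 + p2 q2) / (p2 - p1)^2 ),
    then subjects = ceil(n / queries_per_subject).
    """
    z_a = sps.norm.ppf(1 - spec.alpha / 2)
    z_b = sps.norm.ppf(1 - spec.beta)
    var = spec.p1 * (1 - spec.p1) + spec.p2 * (1 - spec.p2)
    n = ceil((z_a + z_b) ** 2 * var / (spec.p2 - spec.p1) ** 2)
    return n, ceil(n / spec.queries_per_subject)


def mann_whitney(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (for ``xs``) with a two-sided p-value.

    Midranks for ties.  The p-value is exact (full enumeration of rank
    assignments) for small untied samples, and the tie-corrected normal
    approximation otherwise.
    """
    if len(xs) == 0 or len(ys) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = list(xs) + list(ys)
    has_ties = len(set(pooled)) < len(pooled)
    small = max(len(xs), len(ys)) <= 20
    method = "exact" if small and not has_ties else "asymptotic"
    res = sps.mannwhitneyu(xs, ys, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# two-arm summaries
# ---------------------------------------------------------------------------


@dataclass
class ArmSummary:
    arm: str
    n_queries: int
    error_counts: dict[ErrorKind, int]
    perfect_count: int

    @property
    def perfect_pct(self) -> float:
        return 100.0 * self.perfect_count / self.n_queries

    def error_pct(self, kind: ErrorKind) -> float:
        return 100.0 * self.error_counts[kind] / self.n_queries


@dataclass
class TrialSummary:
    """Per-arm flag counts, row-wise Fisher p-values, difficulty strata."""

    arms: tuple[str, str]
    arm_summaries: dict[str, ArmSummary]
    p_values: dict[str, float]  # per error kind + "perfect"
    by_difficulty: dict[str, dict] = field(default_factory=dict)
    mode: str = "flag"

    def to_frame(self) -> pd.DataFrame:
        a1, a2 = self.arms
        s1, s2 = self.arm_summaries[a1], self.arm_summaries[a2]
        rows = []
        rows.append(
            {
                "row": "perfect",
                f"{a1}_n": s1.perfect_count,
                f"{a1}_pct": round(s1.perfect_pct, 1),
                f"{a2}_n": s2.perfect_count,
                f"{a2}_pct": round(s2.perfect_pct, 1),
                "p": self.p_values["perfect"],
            }
        )
        for kind in ErrorKind:
            rows.append(
                {
                    "row": kind.value,
                    f"{a1}_n": s1.error_counts[kind],
                    f"{a1}_pct": round(s1.error_pct(kind), 1),
                    f"{a2}_n": s2.error_counts[kind],
                    f"{a2}_pct": round(s2.error_pct(kind), 1),
                    "p": self.p_values[kind.value],
                }
            )
        return pd.DataFrame(rows)


def summarize(
    reports: Iterable[tuple[str, str, ErrorReport]],
    arms: Optional[tuple[str, str]] = None,
    mode: str = "flag",
) -> TrialSummary:
    """Aggregate per-query error reports into a two-arm comparison table.

    ``reports`` yields (arm label, difficulty level, report).  In ``flag``
    mode each query contributes at most one unit per error row (the
    query-level reading of the results table); in ``count`` mode the full
    error counts are summed.  Fisher p-values are always computed on the
    query-level flags.
    """
    if mode not in ("flag", "count"):
        raise ValueError(f"unknown mode {mode!r}")
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to summarize")
    seen_arms = []
    for arm, _, _ in reports:
        if arm not in seen_arms:
            seen_arms.append(arm)
    if arms is None:
        if len(seen_arms) != 2:
            raise ValueError(f"expected exactly two arms, saw {seen_arms}")
        arms = tuple(seen_arms)
    else:
        unknown = [a for a in seen_arms if a not in arms]
        if unknown:
            raise ValueError(f"unknown arm label(s): {unknown}")

    n = Counter()
    flag_counts = {a: Counter() for a in arms}
    value_counts = {a: Counter() for a in arms}
    perfect = Counter()
    strata: dict[str, dict[str, list[int]]] = {
        d: {a: [0, 0] for a in arms} for d in DIFFICULTIES
    }
    for arm, difficulty, rep in reports:
        n[arm] += 1
        perfect[arm] += rep.perfect
        for kind, flagged in rep.flags().items():
            flag_counts[arm][kind] += flagged
            value_counts[arm][kind] += rep.counts[kind]
        if difficulty in strata:
            strata[difficulty][arm][0] += rep.perfect
            strata[difficulty][arm][1] += 1
    for a in arms:
        if n[a] == 0:
            raise ValueError(f"arm {a!r} has no reports")

    chosen = flag_counts if mode == "flag" else value_counts
    summaries = {
        a: ArmSummary(
            arm=a,
            n_queries=n[a],
            error_counts={k: chosen[a][k] for k in ErrorKind},
            perfect_count=perfect[a],
        )
        for a in arms
    }
    a1, a2 = arms
    p_values = {
        "perfect": fisher_exact(
            ContingencyTable(perfect[a1], n[a1] - perfect[a1], perfect[a2], n[a2] - perfect[a2])
        )
    }
    for kind in ErrorKind:
        f1, f2 = flag_counts[a1][kind], flag_counts[a2][kind]
        p_values[kind.value] = fisher_exact(
            ContingencyTable(f1, n[a1] - f1, f2, n[a2] - f2)
        )

    by_difficulty = {}
    for d in DIFFICULTIES:
        (k1, n1), (k2, n2) = strata[d][a1], strata[d][a2]
        if n1 == 0 or n2 == 0:
            continue
        by_difficulty[d] = {
            a1: {"perfect": k1, "n": n1, "pct": 100.0 * k1 / n1},
            a2: {"perfect": k2, "n": n2, "pct": 100.0 * k2 / n2},
            "p": fisher_exact(ContingencyTable(k1, n1 - k1, k2, n2 - k2)),
        }

    return TrialSummary(
        arms=arms,
        arm_summaries=summaries,
        p_values=p_values,
        by_difficulty=by_difficulty,
        mode=mode,
    )


def summarize_counts(
    flag_counts: dict[str, tuple[int, int]],
    totals: tuple[int, int],
    arms: tuple[str, str] = ("french", "english"),
) -> dict:
    """Summary statistics from an already-tabulated two-arm results table.

    ``flag_counts`` maps row name ("perfect" or an error kind value) to
    per-arm query-level flag counts; ``totals`` are the per-arm numbers of
    analysed queries.  Returns per-row percentages and Fisher p-values
    plus the pooled perfect and irrelevant-term rates.
    """
    n1, n2 = totals
    out: dict = {"arms": arms, "totals": totals, "rows": {}}
    for row, (c1, c2) in flag_counts.items():
        out["rows"][row] = {
            arms[0]: {"n": c1, "pct": 100.0 * c1 / n1},
            arms[1]: {"n": c2, "pct": 100.0 * c2 / n2},
            "p": fisher_exact(ContingencyTable(c1, n1 - c1, c2, n2 - c2)),
        }
    if "perfect" in flag_counts:
        c1, c2 = flag_counts["perfect"]
        out["perfect_overall"] = {
            "n": c1 + c2,
            "of": n1 + n2,
            "pct": 100.0 * (c1 + c2) / (n1 + n2),
        }
    key = ErrorKind.IRRELEVANT_TERM.value
    if key in flag_counts:
        c1, c2 = flag_counts[key]
        out["irrelevant_overall"] = {
            "n": c1 + c2,
            "of": n1 + n2,
            "pct": 100.0 * (c1 + c2) / (n1 + n2),
        }
    return out
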