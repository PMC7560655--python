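"""Cohort statistics: mutual exclusivity / co-occurrence, age associations,
multiple-testing control and mutation-burden comparisons.

The sample x alteration boolean matrix keeps only alterations recurrent in
at least five samples (rarer events lack power).  For each alteration pair a
two-sided Fisher's exact test is run on the 2x2 mutation-status table, after
*independence filtering*: any sample in which the two alterations co-occur
and are joined by SVs (per the linkage graph) is removed from that pair's
table entirely, so rearrangement-coupled events are never counted as
co-occurrence evidence.

Age analyses use three diagnosis-age groups: A (< 1.5 years), B (1.5–5
years, boundaries inclusive) and C (> 5 years).  Prevalence differences
among groups are tested with an exact Fisher–Freeman–Halton test on the
2 x 3 table (full enumeration over tables with the observed margins); age
distributions and mutation burdens are compared with two-sided Wilcoxon
rank-sum tests.  Family-wise error is controlled by Bonferroni adjustment
(alpha / number of tests; 0.05 / 17 = 2.94e-3 for the 17-alteration family).
Relapse samples are excluded from age and co-occurrence analyses by
default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.distributions.empirical_distribution import ECDF

MIN_RECURRENCE = 5
AGE_GROUP_A_MAX = 1.5   # exclusive upper bound of group A
AGE_GROUP_B_MAX = 5.0   # inclusive upper bound of group B


@dataclass
class AlterationMatrix:
    """Boolean samples x alterations matrix with aligned per-sample metadata."""

    data: pd.DataFrame            # bool, index = sample ids
    metadata: pd.DataFrame        # index = sample ids; age_years, purity, timepoint, stage
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.metadata.index):
            self.metadata = self.metadata.loc[self.data.index]
        self.data = self.data.astype(bool)

    @property
    def alterations(self) -> list[str]:
        return list(self.data.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def age_groups(self) -> pd.Series:
        return self.metadata["age_years"].map(assign_age_group)


@dataclass
class PairTestResult:
    """Two-sided Fisher test for one alteration pair after independence filtering."""

    alteration_a: str
    alteration_b: str
    table: np.ndarray             # [[both, a_only], [b_only, neither]]
    odds_ratio: float
    direction: str                # "co-occurrence", "exclusivity" or "none"
    p_value: float
    n_excluded_linked: int
    degenerate: bool = False


def build_alteration_matrix(
    events: pd.DataFrame,
    metadata: pd.DataFrame,
    min_recurrence: int = MIN_RECURRENCE,
    diagnosis_only: bool = True,
    stage4_only: bool = False,
) -> AlterationMatrix:
    """Assemble the boolean matrix from a long event table.

    ``events`` columns: sample, alteration.  ``metadata`` is indexed by (or
    has a column) sample, with at least age_years; a ``timepoint`` column
    ("diagnosis"/"relapse") drives the relapse exclusion.  Alterations seen
    in fewer than ``min_recurrence`` retained samples are dropped (logged in
    ``dropped``).
    """
    meta = metadata.copy()
    if "sample" in meta.columns:
        meta = meta.set_index("sample")
    if diagnosis_only and "timepoint" in meta.columns:
        meta = meta[meta["timepoint"] == "diagnosis"]
    if stage4_only and "stage" in meta.columns:
        meta = meta[meta["stage"] == 4]
    samples = meta.index

    if events.duplicated(subset=["sample", "alteration"]).any():
        raise ValueError("duplicate (sample, alteration) entries in event table")
    events = events[events["sample"].isin(samples)]
    data = pd.DataFrame(False, index=samples, columns=sorted(events["alteration"].unique()))
    for row in events.itertuples(index=False):
        data.loc[row.sample, row.alteration] = True

    counts = data.sum(axis=0)
    dropped = sorted(counts.index[counts < min_recurrence])
    data = data.drop(columns=dropped)
    return AlterationMatrix(data=data, metadata=meta, dropped=dropped)


def pairwise_fisher(
    matrix: AlterationMatrix,
    linked: Callable[[str, str, str], bool] | None = None,
) -> list[PairTestResult]:
    """Two-sided Fisher's exact test for every alteration pair.

    ``linked(sample, a, b)`` reports SV linkage (from
    :mod:`nbsomatic.sv_integration`); samples where a pair both co-occurs
    and is linked are dropped from that pair's 2x2 table.  Degenerate tables
    (an empty margin) get p = 1 with a flag.
    """
    results = []
    cols = matrix.alterations
    for a, b in itertools.combinations(cols, 2):
        has_a = matrix.data[a]
        has_b = matrix.data[b]
        if linked is not None:
            both = has_a & has_b
            excluded = [s for s in matrix.samples if both[s] and linked(s, a, b)]
        else:
            excluded = []
        keep = ~matrix.data.index.isin(excluded)
        va, vb = has_a[keep], has_b[keep]
        table = np.array(
            [
                [int((va & vb).sum()), int((va & ~vb).sum())],
                [int((~va & vb).sum()), int((~va & ~vb).sum())],
            ]
        )
        degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
        if degenerate:
            odds, p = float("nan"), 1.0
        else:
            odds, p = stats.fisher_exact(table, alternative="two-sided")
        if not np.isfinite(odds) and not degenerate:
            odds = float("inf")
        direction = "none"
        if not degenerate:
            if odds > 1:
                direction = "co-occurrence"
            elif odds < 1:
                direction = "exclusivity"
        results.append(
            PairTestResult(
                alteration_a=a,
                alteration_b=b,
                table=table,
                odds_ratio=float(odds),
                direction=direction,
                p_value=float(p),
                n_excluded_linked=len(excluded),
                degenerate=bool(degenerate),
            )
        )
    return results


def pair_tests_table(results: Sequence[PairTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "alteration_a": [r.alteration_a for r in results],
            "alteration_b": [r.alteration_b for r in results],
            "n_both": [r.table[0, 0] for r in results],
            "n_a_only": [r.table[0, 1] for r in results],
            "n_b_only": [r.table[1, 0] for r in results],
            "n_neither": [r.table[1, 1] for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "direction": [r.direction for r in results],
            "p_value": [r.p_value for r in results],
            "n_excluded_linked": [r.n_excluded_linked for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )


def assign_age_group(age_years: float) -> str:
    """A: < 1.5 years; B: 1.5–5 years inclusive; C: > 5 years."""
    if age_years < 0:
        raise ValueError("negative age")
    if age_years < AGE_GROUP_A_MAX:
        return "A"
    if age_years <= AGE_GROUP_B_MAX:
        return "B"
    return "C"


def fisher_exact_2xc(table: np.ndarray) -> float:
    """Exact Fisher–Freeman–Halton p-value for a 2 x C contingency table.

    Enumerates every table with the observed margins; the two-sided p-value
    sums the hypergeometric probabilities of tables no more probable than
    the observed one (with a relative tolerance for float ties).
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x C table")
    col_sums = table.sum(axis=0)
    m1 = int(table[0].sum())
    n_total = int(table.sum())
    if n_total == 0:
        raise ValueError("empty table")

    log_const = (
        gammaln(m1 + 1)
        + gammaln(n_total - m1 + 1)
        + gammaln(col_sums + 1).sum()
        - gammaln(n_total + 1)
    )

    def log_prob(cells: tuple[int, ...]) -> float:
        a = np.array(cells)
        return float(log_const - gammaln(a + 1).sum() - gammaln(col_sums - a + 1).sum())

    lp_obs = log_prob(tuple(table[0]))

    def enumerate_rows(j: int, remaining: int, prefix: tuple[int, ...]):
        if j == len(col_sums) - 1:
            if 0 <= remaining <= col_sums[j]:
                yield prefix + (remaining,)
            return
        lo = max(0, remaining - int(col_sums[j + 1 :].sum()))
        hi = min(int(col_sums[j]), remaining)
        for a in range(lo, hi + 1):
            yield from enumerate_rows(j + 1, remaining - a, prefix + (a,))

    total = 0.0
    for cells in enumerate_rows(0, m1, ()):
        lp = log_prob(cells)
        if lp <= lp_obs + 1e-7:
            total += np.exp(lp)
    return float(min(total, 1.0))


def age_group_prevalence_test(
    matrix: AlterationMatrix,
    alteration: str,
) -> tuple[float, pd.DataFrame]:
    """Exact test of prevalence differences among age groups.

    Returns the 2 x G Fisher–Freeman–Halton p-value and a per-group table
    (n, n_altered, prevalence) including pairwise 2x2 Fisher p-values.
    """
    groups = matrix.age_groups()
    altered = matrix.data[alteration]
    order = [g for g in ("A", "B", "C") if (groups == g).any()]
    if len(order) < 2:
        raise ValueError("need at least two non-empty age groups")
    n_alt = np.array([int(altered[groups == g].sum()) for g in order])
    n_tot = np.array([int((groups == g).sum()) for g in order])
    table = np.vstack([n_alt, n_tot - n_alt])
    p = fisher_exact_2xc(table)
    summary = pd.DataFrame(
        {"group": order, "n": n_tot, "n_altered": n_alt, "prevalence": n_alt / n_tot}
    )
    pairwise = {}
    for (i, gi), (j, gj) in itertools.combinations(enumerate(order), 2):
        sub = np.array(
            [[n_alt[i], n_tot[i] - n_alt[i]], [n_alt[j], n_tot[j] - n_alt[j]]]
        )
        pairwise[f"p_{gi}_vs_{gj}"] = stats.fisher_exact(sub, alternative="two-sided")[1]
    for key, val in pairwise.items():
        summary[key] = val
    return p, summary


def age_distribution_test(
    ages_by_set: Mapping[str, Iterable[float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare diagnosis-age distributions across alteration sets.

    Returns (pairwise two-sided Wilcoxon rank-sum p-values with per-set
    medians, an ECDF table giving for each set the fraction of patients
    diagnosed at or before each observed age).
    """
    ages = {k: np.asarray(list(v), dtype=float) for k, v in ages_by_set.items()}
    for name, arr in ages.items():
        if arr.size == 0:
            raise ValueError(f"empty age set {name!r}")
    rows = []
    for a, b in itertools.combinations(ages, 2):
        stat, p = stats.ranksums(ages[a], ages[b])
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "median_a": float(np.median(ages[a])),
                "median_b": float(np.median(ages[b])),
                "statistic": float(stat),
                "p_value": float(p),
            }
        )
    grid = np.unique(np.concatenate(list(ages.values())))
    ecdf_table = pd.DataFrame({"age_years": grid})
    for name, arr in ages.items():
        ecdf_table[name] = ECDF(arr)(grid)
    return pd.DataFrame(rows), ecdf_table


def bonferroni_alpha(family_alpha: float = 0.05, n_tests: int = 1) -> float:
    """Bonferroni-adjusted per-test significance level: alpha / n."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


def burden_comparison(
    counts_by_group: Mapping[str, Iterable[float]],
) -> pd.DataFrame:
    """Per-group median/IQR of coding-mutation burden plus pairwise two-sided
    Wilcoxon rank-sum tests; single-sample groups are flagged low_n."""
    groups = {k: np.asarray(list(v), dtype=float) for k, v in counts_by_group.items()}
    for name, arr in groups.items():
        if arr.size == 0:
            raise ValueError(f"empty group {name!r}")
        if (arr < 0).any():
            raise ValueError("negative mutation counts")
    rows = []
    for a, b in itertools.combinations(groups, 2):
        stat, p = stats.ranksums(groups[a], groups[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "median_a": float(np.median(groups[a])),
                "median_b": float(np.median(groups[b])),
                "iqr_a": float(np.subtract(*np.percentile(groups[a], [75, 25]))),
                "iqr_b": float(np.subtract(*np.percentile(groups[b], [75, 25]))),
                "p_value": float(p),
                "low_n": bool(min(groups[a].size, groups[b].size) < 2),
            }
        )
    return pd.DataFrame(rows)
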