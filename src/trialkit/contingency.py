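"""Categorical analyses for 2 x c outcome tables.

Association between treatment arm and a categorical outcome is tested with
a Pearson chi-square test (no continuity correction), switching to a Fisher
exact test when any cell count is below 5.  The Fisher test enumerates all
2 x c tables with the observed margins and sums the probabilities of those
no more probable than the observed table (the point-probability two-sided
rule).  For 2 x 2 collapses the odds ratio is reported with a Woolf
(log-scale Wald) confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import ValidationError

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of outcomes by arm: 2 rows (arms) x c outcome categories."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 2:
            raise ValidationError("table must have exactly 2 rows (arms)")
        if np.any(counts < 0):
            raise ValidationError("counts must be nonnegative")
        if np.any(counts.sum(axis=1) == 0):
            raise ValidationError("each arm must have at least one positive count")
        if len(self.row_labels) != 2 or len(self.col_labels) != counts.shape[1]:
            raise ValidationError("label lengths must match the table shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @classmethod
    def from_csv(cls, path) -> "ContingencyTable":
        frame = pd.read_csv(path, index_col=0)
        return cls(
            counts=frame.to_numpy(dtype=int),
            row_labels=tuple(str(r) for r in frame.index),
            col_labels=tuple(str(c) for c in frame.columns),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts, index=list(self.row_labels),
                     columns=list(self.col_labels)).to_csv(path)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


@dataclass(frozen=True)
class CategoricalResult:
    """Association test result; odds-ratio fields populated for 2 x 2 tables."""

    test: str                     # 'chi_square' or 'fisher'
    statistic: float | None
    df: int | None
    p_value: float
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    or_p_value: float | None = None
    continuity_corrected: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "test", "statistic", "df", "p_value", "odds_ratio",
            "or_ci_low", "or_ci_high", "or_p_value", "continuity_corrected")}


def fisher_exact_2xc(counts: np.ndarray) -> float:
    """Two-sided Fisher exact P for a 2 x c table by full enumeration.

    Enumerates every table with the observed row and column margins; the
    probability of a table under the null is the multivariate
    hypergeometric mass prod_j C(m_j, a_j) / C(N, r1).  The two-sided P
    sums the masses not exceeding the observed table's (with the usual
    1 + 1e-7 relative tolerance against floating-point ties).
    """
    counts = np.asarray(counts, dtype=int)
    col = counts.sum(axis=0)
    r1 = int(counts[0].sum())
    n_total = int(counts.sum())
    log_denom = _log_binom(n_total, r1)
    # per-column log C(m_j, a) lookup tables, a = 0..m_j
    lc = [gammaln(m + 1) - gammaln(np.arange(m + 1) + 1) - gammaln(m - np.arange(m + 1) + 1)
          for m in col]

    obs = sum(lc[j][a] for j, a in enumerate(counts[0])) - log_denom
    cutoff = obs + np.log(1 + 1e-7)
    total = 0.0
    # enumerate the first c-1 cells of the top row; the last is forced
    ranges = [range(int(m) + 1) for m in col[:-1]]
    for head in product(*ranges):
        tail = r1 - sum(head)
        if tail < 0 or tail > col[-1]:
            continue
        lm = sum(lc[j][a] for j, a in enumerate(head)) + lc[-1][tail] - log_denom
        if lm <= cutoff:
            total += np.exp(lm)
    return float(min(total, 1.0))


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def test_association(table: ContingencyTable) -> CategoricalResult:
    """Chi-square (all cells >= 5) or Fisher exact (otherwise) association test."""
    counts = table.counts
    if (counts < 5).any():
        p = fisher_exact_2xc(counts)
        result = CategoricalResult(test="fisher", statistic=None, df=None, p_value=p)
    else:
        stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
        result = CategoricalResult(
            test="chi_square", statistic=float(stat), df=int(df), p_value=float(p)
        )
    if counts.shape == (2, 2):
        orr = odds_ratio_2x2(table)
        result = CategoricalResult(
            test=result.test, statistic=result.statistic, df=result.df,
            p_value=result.p_value, odds_ratio=orr.odds_ratio,
            or_ci_low=orr.or_ci_low, or_ci_high=orr.or_ci_high,
            or_p_value=orr.or_p_value, continuity_corrected=orr.continuity_corrected,
        )
    return result


def odds_ratio_2x2(table: ContingencyTable, ci_level: float = 0.95) -> CategoricalResult:
    """Odds ratio with Woolf (log-scale Wald) CI and Wald P for a 2 x 2 table.

    Zero cells get the Haldane-Anscombe +0.5 correction, flagged in the
    result.
    """
    counts = table.counts
    if counts.shape != (2, 2):
        raise ValidationError(f"odds ratio needs a 2x2 table, got {counts.shape}")
    corrected = bool((counts == 0).any())
    a, b, c, d = (counts + 0.5).ravel() if corrected else counts.ravel().astype(float)
    log_or = float(np.log(a * d) - np.log(b * c))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    p = 2.0 * float(stats.norm.sf(abs(log_or) / se))
    return CategoricalResult(
        test="woolf", statistic=None, df=None, p_value=p,
        odds_ratio=float(np.exp(log_or)),
        or_ci_low=float(np.exp(log_or - z * se)),
        or_ci_high=float(np.exp(log_or + z * se)),
        or_p_value=p,
        continuity_corrected=corrected,
    )


def collapse(table: ContingencyTable, groups: dict[str, list[int]]) -> ContingencyTable:
    """Merge outcome columns; ``groups`` maps new label -> column indices.

    The groups must partition the columns exactly (no overlap, full cover);
    totals are preserved.
    """
    all_cols = [c for cols in groups.values() for c in cols]
    n_cols = table.counts.shape[1]
    if sorted(all_cols) != list(range(n_cols)):
        raise ValidationError(
            f"groups {groups} do not partition columns 0..{n_cols - 1}"
        )
    labels = list(groups)
    merged = np.column_stack(
        [table.counts[:, groups[lab]].sum(axis=1) for lab in labels]
    )
    return ContingencyTable(
        counts=merged, row_labels=table.row_labels, col_labels=tuple(labels)
    )


def load_packaged_table(name: str) -> ContingencyTable:
    """Load one of the packaged outcome tables from the lopinavir-ritonavir trial.

    Available: 'cao_mortality' (deaths in the earlier / later stage of
    illness, and survivors, by day 28) and 'cao_improvement' (clinical
    improvement in days 1-7 / 8-14 / 15-28, and non-improvement).
    """
    path = _DATA_DIR / f"{name}.csv"
    if not path.exists():
        available = sorted(p.stem for p in _DATA_DIR.glob("*.csv"))
        raise ValidationError(f"no packaged table {name!r}; available: {available}")
    return ContingencyTable.from_csv(path)
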