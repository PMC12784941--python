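"""Statistical layer: group tests, FDR correction, lateralization deltas,
and the uptake-vs-asymmetry correlation grid.

Per-animal lateralization is expressed as ipsilateral minus contralateral
values, Delta x = x(ipsi) - x(contra); for connectivity the difference is
taken on Fisher-z values. Group contrasts use Student's t (equal-variance
by default, Welch optional), within-group contrasts a paired t-test, and
families of p-values are Benjamini-Hochberg adjusted (reported as q).
Spearman rank correlations relate the uptake asymmetry of the
neuroinflammation tracer to every other lateralized metric.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    """Outcome of one hypothesis test."""

    label: str
    statistic: float
    df: float
    p: float
    n: int
    q: float | None = None

    @property
    def significant_p(self) -> bool:
        return self.p < ALPHA

    @property
    def significant_q(self) -> bool:
        return self.q is not None and self.q < ALPHA


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation plus the least-squares line for scatter overlays."""

    label: str
    rho: float
    p: float
    n: int
    slope: float
    intercept: float

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p) and self.p < ALPHA


def delta_metric(ipsi, contra):
    """Lateralization index: ipsilateral minus contralateral.

    Missing values (None/NaN on either side) propagate as NaN and are never
    imputed. Works element-wise on arrays.
    """
    a = np.asarray(ipsi, dtype=float)
    b = np.asarray(contra, dtype=float)
    out = a - b
    return float(out) if out.ndim == 0 else out


def two_sample_ttest(
    group_a, group_b, equal_variance: bool = True, label: str = ""
) -> StatResult:
    """Two-sided two-sample t-test (Student by default, Welch optional)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 finite values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero pooled variance: both groups are constant")
    res = stats.ttest_ind(a, b, equal_var=equal_variance)
    return StatResult(
        label=label,
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        n=a.size + b.size,
    )


def paired_ttest(values_a, values_b, label: str = "") -> StatResult:
    """Two-sided paired t-test (one-sample t on within-pair differences).

    Incomplete pairs are dropped with a log message. All-zero differences
    give t = 0, p = 1; a constant non-zero difference (zero variance but a
    deterministic shift) is a degenerate state and raises.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    complete = np.isfinite(a) & np.isfinite(b)
    if complete.sum() < a.size:
        logger.info("dropping %d incomplete pair(s)", int(a.size - complete.sum()))
    d = a[complete] - b[complete]
    if d.size < 2:
        raise ValueError("need at least 2 complete pairs")
    if np.all(d == 0):
        return StatResult(label=label, statistic=0.0, df=d.size - 1, p=1.0, n=d.size)
    if d.std(ddof=1) == 0:
        raise ValueError("degenerate pairing: constant non-zero difference")
    res = stats.ttest_rel(a[complete], b[complete])
    return StatResult(
        label=label,
        statistic=float(res.statistic),
        df=float(d.size - 1),
        p=float(res.pvalue),
        n=d.size,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Monotonicity is enforced by the cumulative minimum from the largest
    rank; input order is preserved. NaNs propagate (excluded from the
    family size).
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if finite.sum():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def spearman(
    x, y, label: str = "", exact: bool = False
) -> CorrelationResult:
    """Spearman rank correlation on pairwise-complete observations.

    rho is the Pearson correlation of mid-ranks (average ranks on ties);
    the two-sided p-value uses the t approximation, or an exact permutation
    distribution when ``exact`` is requested (n <= 10). The least-squares
    line of y on x (original scale) is attached for scatter overlays.
    Constant inputs leave rho undefined (NaN) with a log message.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    complete = np.isfinite(x) & np.isfinite(y)
    x, y = x[complete], y[complete]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 pairwise-complete observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant input: Spearman correlation undefined")
        return CorrelationResult(label, np.nan, np.nan, n, np.nan, np.nan)
    if exact:
        if n > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        rho = float(stats.spearmanr(x, y).statistic)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        observed = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = float(np.corrcoef(rx, perm)[0, 1])
            count += abs(r) >= observed - 1e-12
            total += 1
        p = count / total
    else:
        res = stats.spearmanr(x, y)
        rho, p = float(res.statistic), float(res.pvalue)
    line = stats.linregress(x, y)
    return CorrelationResult(
        label=label,
        rho=rho,
        p=float(p),
        n=n,
        slope=float(line.slope),
        intercept=float(line.intercept),
    )


def build_delta_correlation_matrix(
    deltas: pd.DataFrame,
    reference_metric: str = "U_FEPPA",
    nuclei: tuple = ("LN", "VPN"),
    alpha: float = ALPHA,
    min_n: int = 4,
) -> pd.DataFrame:
    """Correlate the reference uptake asymmetry against every other delta.

    Parameters
    ----------
    deltas : tidy long table with columns
        ``animal, nucleus, metric, timepoint, delta``; the reference metric
        appears once per (animal, nucleus).
    Returns one row per (nucleus, metric, timepoint) cell with Spearman rho,
    p, n, regression slope/intercept and a ``significant`` flag (p < alpha,
    uncorrected, following how such grids are reported). Cells with fewer
    than ``min_n`` complete pairs are returned with NaN statistics.
    """
    required = {"animal", "nucleus", "metric", "timepoint", "delta"}
    if not required.issubset(deltas.columns):
        raise ValueError(f"delta table must have columns {sorted(required)}")
    rows = []
    for nucleus in nuclei:
        sub = deltas[deltas["nucleus"] == nucleus]
        ref = (
            sub[sub["metric"] == reference_metric]
            .set_index("animal")["delta"]
            .dropna()
        )
        if ref.size < min_n:
            raise ValueError(
                f"reference metric {reference_metric!r} present for only "
                f"{ref.size} animals in nucleus {nucleus!r}"
            )
        cells = (
            sub[sub["metric"] != reference_metric][["metric", "timepoint"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        for metric, timepoint in cells:
            cell = sub[(sub["metric"] == metric) & (sub["timepoint"] == timepoint)]
            other = cell.set_index("animal")["delta"].dropna()
            joined = pd.concat([ref, other], axis=1, join="inner", keys=["u", "m"])
            label = f"{nucleus}:{metric}@{timepoint}"
            if len(joined) < min_n:
                logger.info("cell %s has n=%d < %d; left missing",
                            label, len(joined), min_n)
                rows.append(
                    dict(nucleus=nucleus, metric=metric, timepoint=timepoint,
                         rho=np.nan, p=np.nan, n=len(joined), slope=np.nan,
                         intercept=np.nan, significant=False)
                )
                continue
            res = spearman(joined["u"].to_numpy(), joined["m"].to_numpy(), label)
            rows.append(
                dict(nucleus=nucleus, metric=metric, timepoint=timepoint,
                     rho=res.rho, p=res.p, n=res.n, slope=res.slope,
                     intercept=res.intercept,
                     significant=bool(np.isfinite(res.p) and res.p < alpha))
            )
    return pd.DataFrame(rows)
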