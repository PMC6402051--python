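"""Method-agreement statistics: Bland–Altman, regression/correlation,
the exact paired Wilcoxon signed-rank test, and assembly of comparison
tables for validation study designs (test method vs reference per
vessel; same-scanner different-day repeatability vs different-scanner
same-day reproducibility).

Conventions: paired differences are oriented test − reference
throughout; bias ± SD uses the sample SD (n − 1 denominator); limits of
agreement are bias ∓ 1.96·SD; no multiple-testing correction is applied
(each comparison is reported with its own two-sided p at α = 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AgreementResult

__all__ = [
    "bland_altman",
    "pearson_regression",
    "wilcoxon_signed_rank",
    "compare_methods",
    "Comparison",
    "build_comparison_table",
]


def _paired(a, b):
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.size != b.size:
        raise ValueError(f"paired inputs differ in length: {a.size} vs {b.size}")
    keep = np.isfinite(a) & np.isfinite(b)
    return a[keep], b[keep]


def bland_altman(a, b) -> AgreementResult:
    """Bland–Altman agreement of method ``a`` (test) against ``b``
    (reference): bias = mean(a − b), SD with n − 1 denominator, limits
    of agreement bias ∓ 1.96·SD."""
    a, b = _paired(a, b)
    n = a.size
    if n < 2:
        raise ValueError("Bland–Altman analysis needs at least 2 complete pairs")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementResult(
        bias=bias, sd=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=n
    )


def pearson_regression(a, b) -> tuple[float, float, float]:
    """Pearson r and the least-squares line a = slope·b + intercept,
    with ``b`` (the reference method) as the x variable.

    Returns ``(r, slope, intercept)``.  Requires n ≥ 3 and nonzero
    variance in ``b``.
    """
    a, b = _paired(a, b)
    if a.size < 3:
        raise ValueError("regression needs at least 3 complete pairs")
    if np.ptp(b) == 0:
        raise ValueError("degenerate input: the reference values have zero variance")
    res = stats.linregress(b, a)
    return float(res.rvalue), float(res.slope), float(res.intercept)


def _exact_signed_rank_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p by full enumeration of the 2^n sign assignments:
    the proportion with min(W+, W−) ≤ the observed min statistic.
    Midranks are carried through, so ties are handled exactly."""
    n = ranks.size
    total = float(ranks.sum())
    m = 1 << n
    signs = (np.arange(m, dtype=np.uint32)[:, None] >> np.arange(n)) & 1
    w_plus = signs @ ranks
    w_all = np.minimum(w_plus, total - w_plus)
    return float(np.count_nonzero(w_all <= w_obs + 1e-9) / m)


def wilcoxon_signed_rank(a, b, exact_max_n: int = 20) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test of a vs b.

    Zero differences are dropped before ranking; |differences| are
    ranked with midranks for ties.  Returns ``(W, p)`` with
    W = min(W+, W−).  The p value is exact by full enumeration of the
    2^n sign assignments for n ≤ ``exact_max_n`` and uses the normal
    approximation with tie correction above that.
    """
    a, b = _paired(a, b)
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p set to 1", stacklevel=2)
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_max_n:
        return w, _exact_signed_rank_p(ranks, w)
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        return w, 1.0
    z = (w - mean) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def compare_methods(a, b) -> AgreementResult:
    """Full agreement panel for paired measurements a (test) vs b
    (reference): Bland–Altman, regression/correlation and Wilcoxon.
    Regression fields are NaN when n < 3 or the reference is constant."""
    res = bland_altman(a, b)
    try:
        res.r, res.slope, res.intercept = pearson_regression(a, b)
    except ValueError:
        pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, res.p_wilcoxon = wilcoxon_signed_rank(a, b)
    return res


@dataclass
class Comparison:
    """One paired comparison in a study design.

    ``select_a``/``select_b`` are column→value filters picking the test
    and reference measurements from a tidy table; rows are paired on
    ``pair_on`` (plus the metric column, which also groups the output).
    """

    label: str
    select_a: dict
    select_b: dict
    pair_on: tuple[str, ...] = ("subject",)
    metric_col: str = "metric"
    value_col: str = "value"


def _select(df: pd.DataFrame, flt: dict) -> pd.DataFrame:
    out = df
    for col, val in flt.items():
        out = out[out[col] == val]
    return out


def build_comparison_table(measurements: pd.DataFrame,
                           design: list[Comparison]) -> pd.DataFrame:
    """Assemble an agreement table from tidy measurements.

    ``measurements`` columns: the pairing keys (e.g. subject, occasion,
    scanner), a method column referenced by the selectors, a metric
    column (vessel or KE metric) and a value column.  One output row per
    (comparison, metric) with n, dropped-pair count and the full
    :class:`AgreementResult` panel, oriented test − reference.  Output
    is invariant to row order of the input.
    """
    rows = []
    for comp in design:
        da = _select(measurements, comp.select_a)
        db = _select(measurements, comp.select_b)
        keys = list(comp.pair_on) + [comp.metric_col]
        merged = da.merge(db, on=keys, suffixes=("_a", "_b"))
        va, vb = f"{comp.value_col}_a", f"{comp.value_col}_b"
        for metric, grp in merged.groupby(comp.metric_col, sort=True):
            n_possible = max(
                da[da[comp.metric_col] == metric].shape[0],
                db[db[comp.metric_col] == metric].shape[0],
            )
            grp = grp.sort_values(list(comp.pair_on))
            complete = grp[[va, vb]].notna().all(axis=1)
            grp = grp[complete]
            if grp.shape[0] < 2:
                raise ValueError(
                    f"comparison {comp.label!r}, metric {metric!r}: "
                    "fewer than 2 complete pairs"
                )
            res = compare_methods(grp[va].to_numpy(), grp[vb].to_numpy())
            rows.append(
                {
                    "comparison": comp.label,
                    "metric": metric,
                    "n": res.n,
                    "n_dropped": int(n_possible - res.n),
                    "bias": res.bias,
                    "sd": res.sd,
                    "loa_low": res.loa_low,
                    "loa_high": res.loa_high,
                    "r": res.r,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "p_wilcoxon": res.p_wilcoxon,
                }
            )
    if not rows:
        raise ValueError("no complete pairs in any comparison")
    return pd.DataFrame(rows)
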