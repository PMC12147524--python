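"""Per-site differential modification between conditions.

Replicate-level mutation rates (or deduced fractions) at each shared
site are compared with a two-sample t-test — Student's pooled-variance test by
default, Welch as an option — and the per-site p-values are
adjusted across all compared sites with the Holm-Sidak step-down
procedure.  The pooled test is the default because with only two
replicates per group the Satterthwaite degrees of freedom of Welch's
test collapse toward 1 whenever the two sample variances differ by
chance, which destroys power at exactly the group sizes this assay
uses; the pooled variant keeps the full n_a + n_b - 2 df.  This mirrors the replicate design of knockdown/knockout
contrasts (shControl vs shALKBH1, WT vs KO) run with two technical
replicates per condition; results computed from so few replicates carry
an explicit low-replicate warning flag.

Degenerate inputs follow a documented convention: when both groups have
zero variance, equal means give p = 1 and unequal means give p = 0.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["t_test", "holm_sidak", "compare_conditions", "significance_label"]

log = logging.getLogger(__name__)

_KEY = ["ref", "pos0", "strand"]


def t_test(
    group_a, group_b, variant: str = "student"
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test on replicate-level rates.

    Returns (t, p, degrees of freedom).  ``variant`` is ``welch``
    (unequal variance) or ``student`` (pooled variance).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    if variant not in ("welch", "student"):
        raise ValueError(f"variant must be 'welch' or 'student', got {variant!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # zero-variance convention: the test statistic is undefined, so
        # identical groups are a sure null and distinct groups a sure effect
        if a.mean() == b.mean():
            return 0.0, 1.0, float(a.size + b.size - 2)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return float(t), 0.0, float(a.size + b.size - 2)
    with warnings.catch_warnings():
        # near-identical replicates trip scipy's precision-loss warning;
        # the exactly-degenerate cases are already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue), float(res.df)


def holm_sidak(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjustment, returned in the input order.

    With m tests and ascending p_(1) <= ... <= p_(m), the i-th adjusted
    value is the running maximum of 1 - (1 - p_(j))^(m - j + 1) over
    j <= i, clamped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    exponents = m - np.arange(m)
    stepwise = 1.0 - (1.0 - p[order]) ** exponents
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepwise), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def significance_label(p_adj: float) -> str:
    """Star convention: * <0.05, ** <0.01, *** <0.001, else ns."""
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "ns"


def _to_long(calls, value: str) -> pd.DataFrame:
    """Normalize one condition's replicates to long (ref,pos0,strand,value)."""
    if isinstance(calls, pd.DataFrame):
        frames = [calls]
    else:
        frames = list(calls)
    rows = []
    for i, df in enumerate(frames):
        if value not in df:
            raise KeyError(f"replicate table lacks a {value!r} column")
        sub = df[_KEY + [value]].copy()
        sub["replicate"] = i
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def compare_conditions(
    calls_a,
    calls_b,
    sites: str = "intersection",
    use: str = "rate",
    variant: str = "student",
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Site-by-site condition contrast with Holm-Sidak family adjustment.

    ``calls_a`` / ``calls_b`` are lists of per-replicate call (or pileup)
    tables sharing ref/pos0/strand keys and the value column ``use``
    ('rate' for mutation rates, 'f_hat' for deduced fractions).  The
    Holm-Sidak family is every site tested in this run.  Sites lacking
    ``min_replicates`` in either condition are skipped and logged; with
    ``sites='union'`` they are retained as untested rows (NaN statistics).
    """
    if sites not in ("intersection", "union"):
        raise ValueError("sites must be 'intersection' or 'union'")
    long_a = _to_long(calls_a, use)
    long_b = _to_long(calls_b, use)
    ga = long_a.groupby(_KEY)[use].agg(list)
    gb = long_b.groupby(_KEY)[use].agg(list)
    all_sites = sorted(set(ga.index) | set(gb.index))
    rows = []
    for key in all_sites:
        va = np.asarray(ga.get(key, []), dtype=float)
        vb = np.asarray(gb.get(key, []), dtype=float)
        testable = va.size >= min_replicates and vb.size >= min_replicates
        if not testable:
            log.info("site %s skipped: %d vs %d replicates", key, va.size, vb.size)
            if sites == "intersection":
                continue
            t = p = df_dof = np.nan
        else:
            t, p, df_dof = t_test(va, vb, variant=variant)
        rows.append(
            {
                "ref": key[0],
                "pos0": key[1],
                "strand": key[2],
                "mean_a": va.mean() if va.size else np.nan,
                "sd_a": va.std(ddof=1) if va.size > 1 else np.nan,
                "n_a": va.size,
                "mean_b": vb.mean() if vb.size else np.nan,
                "sd_b": vb.std(ddof=1) if vb.size > 1 else np.nan,
                "n_b": vb.size,
                "t": t,
                "df": df_dof,
                "p": p,
                "tested": testable,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adj"] = np.nan
    tested = out.index[out["tested"]]
    if len(tested):
        out.loc[tested, "p_adj"] = holm_sidak(out.loc[tested, "p"].to_numpy())
    out["direction"] = np.select(
        [out["mean_b"] > out["mean_a"], out["mean_b"] < out["mean_a"]],
        ["gain", "loss"],
        default="none",
    )
    out["label"] = [
        significance_label(q) if np.isfinite(q) else "ns" for q in out["p_adj"]
    ]
    out["low_replicate_warning"] = (out["n_a"] <= 2) | (out["n_b"] <= 2)
    return out
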