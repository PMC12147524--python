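"""Transcriptome-wide f5C site calling.

Candidate cytosines (adequate coverage, mutation rate above a floor) are
tested against the background C-to-T error with a one-sided exact
binomial tail, adjusted for multiplicity (Benjamini-Hochberg by default,
matching the large-m FDR framing of a transcriptome-wide scan).  Called
sites are annotated with the calibrated fraction estimate and its
confidence interval, and an untreated input library can veto sites whose
unconverted mutation rate is already high (genomic SNPs, native C-to-U
editing).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .calibrate import CalibrationModel

__all__ = [
    "estimate_background",
    "test_site",
    "filter_by_input",
    "call_sites",
    "calls_to_bed",
    "InsufficientBackgroundError",
]

log = logging.getLogger(__name__)

_KEY = ["ref", "pos0", "strand"]


class InsufficientBackgroundError(ValueError):
    """Too few non-candidate sites to estimate the background error."""


def estimate_background(
    counts: pd.DataFrame,
    exclude: pd.Series | None = None,
    min_coverage: int = 10,
    min_sites: int = 100,
) -> float:
    """Pooled background C-to-T rate over non-candidate cytosines.

    ``exclude`` is a boolean mask (aligned with ``counts``) marking
    candidate/modified sites to leave out.  The estimate is the pooled
    n_T over pooled coverage of the remaining sites with coverage at
    least ``min_coverage``; surrounding-base mutation in the assay is
    minimal, so this pool is dominated by the chemistry's error floor.
    """
    mask = counts["coverage"] >= min_coverage
    if exclude is not None:
        mask &= ~exclude.astype(bool)
    bg = counts[mask]
    if len(bg) < min_sites:
        raise InsufficientBackgroundError(
            f"only {len(bg)} background sites with coverage >= {min_coverage}; "
            f"need at least {min_sites}"
        )
    e0 = float(bg["n_T"].sum() / bg["coverage"].sum())
    if not 0 <= e0 < 0.5:
        raise ValueError(f"implausible background rate {e0}")
    return e0


def test_site(rec: pd.Series | tuple[int, int], e0: float) -> float:
    """One-sided exact binomial tail P(X >= n_T | coverage, e0)."""
    if isinstance(rec, tuple):
        n_t, cov = rec
    else:
        n_t, cov = int(rec["n_T"]), int(rec["coverage"])
    if cov <= 0:
        raise ValueError("cannot test a zero-coverage site")
    if not 0 <= e0 < 1:
        raise ValueError(f"background rate out of range: {e0}")
    return float(stats.binom.sf(n_t - 1, cov, e0))


def filter_by_input(
    calls: pd.DataFrame,
    input_counts: pd.DataFrame,
    max_input_rate: float = 0.01,
    min_input_coverage: int = 10,
) -> pd.DataFrame:
    """Flag calls whose untreated input library already mutates.

    A site whose input-library C-to-T rate strictly exceeds
    ``max_input_rate`` is marked ``input_fail`` and dropped from the
    called set; a site the input library does not cover at
    ``min_input_coverage`` is marked ``input_uncovered`` but retained,
    with a warning.
    """
    inp = input_counts[_KEY + ["coverage", "n_T"]].rename(
        columns={"coverage": "input_coverage", "n_T": "input_n_T"}
    )
    out = calls.merge(inp, on=_KEY, how="left")
    out["input_coverage"] = out["input_coverage"].fillna(0).astype(int)
    out["input_n_T"] = out["input_n_T"].fillna(0).astype(int)
    covered = out["input_coverage"] >= min_input_coverage
    with np.errstate(invalid="ignore"):
        out["input_rate"] = np.where(
            out["input_coverage"] > 0,
            out["input_n_T"] / out["input_coverage"].clip(lower=1),
            np.nan,
        )
    out["input_fail"] = covered & (out["input_rate"] > max_input_rate)
    out["input_uncovered"] = ~covered
    n_unc = int(out["input_uncovered"].sum())
    if n_unc:
        log.warning("%d sites uncovered in the input library; retained", n_unc)
    if "called" in out:
        out.loc[out["input_fail"], "called"] = False
    return out


def call_sites(
    counts: pd.DataFrame,
    model: CalibrationModel,
    e0: float,
    min_coverage: int = 20,
    min_rate: float = 0.05,
    alpha: float = 0.05,
    method: str = "fdr_bh",
    input_counts: pd.DataFrame | None = None,
    max_input_rate: float = 0.01,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Call modified sites from a pileup table.

    Candidates are sites with coverage >= ``min_coverage`` and rate >=
    ``min_rate``; their binomial p-values are adjusted across candidates
    by ``method`` (any ``statsmodels.multipletests`` code) and a site is
    called at q <= ``alpha``.  Every input row is returned, with flag
    columns recording why a site was or was not called.
    """
    df = counts.copy().reset_index(drop=True)
    if df.empty:
        log.info("empty pileup: no candidates")
        return df.assign(
            candidate=pd.Series(dtype=bool), called=pd.Series(dtype=bool)
        )
    df["coverage_fail"] = df["coverage"] < min_coverage
    df["rate_fail"] = df["rate"] < min_rate
    df["candidate"] = ~(df["coverage_fail"] | df["rate_fail"])
    df["p"] = np.nan
    df["q"] = np.nan
    cand = df.index[df["candidate"]]
    if len(cand) == 0:
        log.info("no candidate sites passed coverage/rate thresholds")
    else:
        # vectorized exact binomial upper tail P(X >= n_T)
        pvals = stats.binom.sf(
            df.loc[cand, "n_T"].to_numpy() - 1,
            df.loc[cand, "coverage"].to_numpy(),
            e0,
        )
        # the step-up adjustment assigns equal q to tied discrete-binomial
        # p-values, so candidate order cannot change the called set
        df.loc[cand, "p"] = pvals
        df.loc[cand, "q"] = multipletests(pvals, method=method)[1]
    df["e0"] = e0
    covered = df["coverage"].to_numpy() > 0
    n_t = df["n_T"].to_numpy()
    cov = np.where(covered, df["coverage"].to_numpy(), 1)
    raw = (df["rate"].to_numpy() - model.intercept) / model.slope
    lo_m, hi_m = proportion_confint(n_t, cov, alpha=1 - ci_level, method="wilson")
    flo = np.clip((np.asarray(lo_m) - model.intercept) / model.slope, 0.0, 1.0)
    fhi = np.clip((np.asarray(hi_m) - model.intercept) / model.slope, 0.0, 1.0)
    flo[n_t == 0] = 0.0
    fhi[n_t == cov] = 1.0
    df["f_hat"] = np.where(covered, np.clip(raw, 0.0, 1.0), np.nan)
    df["f_lo"] = np.where(covered, flo, np.nan)
    df["f_hi"] = np.where(covered, fhi, np.nan)
    df["clamped"] = covered & ((raw < 0) | (raw > 1))
    df["called"] = df["candidate"] & (df["q"] <= alpha)
    if input_counts is not None:
        df = filter_by_input(df, input_counts, max_input_rate=max_input_rate)
    # deterministic output order, invariant to input row order
    return df.sort_values(_KEY, kind="stable").reset_index(drop=True)


def calls_to_bed(calls: pd.DataFrame, path: str | Path | None = None) -> pd.DataFrame:
    """Export called sites as BED6+ (0-based half-open, score=1000*f_hat)."""
    sub = calls[calls["called"]].copy()
    bed = pd.DataFrame(
        {
            "chrom": sub["ref"],
            "start": sub["pos0"],
            "end": sub["pos0"] + 1,
            "name": [
                f"f5C_{r}_{p}_{s}" for r, p, s in zip(sub["ref"], sub["pos0"], sub["strand"])
            ],
            "score": (1000 * sub["f_hat"]).round().astype(int).clip(0, 1000),
            "strand": sub["strand"],
            "rate": sub["rate"],
            "f_hat": sub["f_hat"],
            "f_lo": sub["f_lo"],
            "f_hi": sub["f_hi"],
            "p": sub["p"],
            "q": sub["q"],
        }
    )
    if path is not None:
        bed.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")
    return bed
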