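"""Spike-in calibration: modification fraction <-> C-to-T mutation rate.

Spike-in oligos of known f5C fraction establish a near-linear relation

    m = a * f + b

between the true modification fraction ``f`` and the observed C-to-T
mutation rate ``m``.  The slope ``a`` absorbs the pic-borane conversion
efficiency and the intercept ``b`` the background C-to-T error, so an
observed rate at a transcriptomic site can be inverted into an absolute
modification fraction estimate, f_hat = (m - b) / a.

Fitting is weighted least squares with binomial-variance weights
n / (m(1-m)), since spike-in points carry heterogeneous coverage.
Confidence intervals on inverted fractions propagate a Wilson binomial
interval on the rate through the inverse line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .simulate import SpikeInDesign, enumerate_contexts

__all__ = [
    "CalibrationModel",
    "ContextReport",
    "fit_calibration",
    "invert",
    "fraction_ci",
    "context_dependence",
    "extract_context_counts",
]


@dataclass
class CalibrationModel:
    """Fitted line mapping modification fraction to expected mutation rate."""

    slope: float
    intercept: float
    se_slope: float = float("nan")
    se_intercept: float = float("nan")
    cov_slope_intercept: float = float("nan")
    residual_sd: float = float("nan")
    r_squared: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")
        if self.intercept < 0 or self.slope + self.intercept > 1 + 1e-9:
            raise ValueError(
                "calibration line must keep predicted rates in [0, 1] over "
                f"f in [0, 1]; got a={self.slope}, b={self.intercept}"
            )

    def predict(self, f: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(f, dtype=float) + self.intercept

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        return cls(**json.loads(Path(path).read_text()))


def _as_points(points) -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        df = points.rename(
            columns={"fraction": "f", "rate": "m", "coverage": "n"}
        )[["f", "m", "n"]].astype(float)
    else:
        df = pd.DataFrame(points, columns=["f", "m", "n"]).astype(float)
    return df


def fit_calibration(points) -> CalibrationModel:
    """Weighted least-squares line through (fraction, rate, coverage) points.

    ``points`` is a sequence of (f, m, n) tuples or a DataFrame with
    columns fraction/rate/coverage.  Weights are n / (m(1-m)) with the
    rate clamped away from 0 and 1 so zero-mutation points stay finite.
    Sampling noise around a clean background can push the fitted line
    marginally outside the physical region; the intercept is floored at
    zero and the slope capped so predicted rates stay within [0, 1].
    """
    df = _as_points(points)
    if df["f"].nunique() < 2:
        raise ValueError("need at least two distinct fractions to fit a line")
    if ((df["m"] < 0) | (df["m"] > 1)).any():
        raise ValueError("observed rates must lie in [0, 1]")
    if (df["n"] <= 0).any():
        raise ValueError("coverages must be positive")
    m_clamped = df["m"].clip(lower=0.5 / df["n"], upper=1 - 0.5 / df["n"])
    w = df["n"] / (m_clamped * (1 - m_clamped))
    X = sm.add_constant(df["f"].to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        # a saturated two-point fit has zero residual df
        res = sm.WLS(df["m"].to_numpy(), X, weights=w.to_numpy()).fit()
    b, a = res.params
    # the binomial weights are known variances, so the parameter
    # covariance must not be rescaled by the few-df residual estimate
    C = res.cov_params(scale=1.0)
    resid = df["m"].to_numpy() - res.fittedvalues
    b = float(max(b, 0.0))
    return CalibrationModel(
        slope=float(min(a, 1.0 - b)),
        intercept=b,
        se_slope=float(np.sqrt(C[1, 1])),
        se_intercept=float(np.sqrt(C[0, 0])),
        cov_slope_intercept=float(C[0, 1]),
        residual_sd=float(np.sqrt(np.mean(resid**2))) if len(df) > 2 else 0.0,
        r_squared=float(res.rsquared),
        n_points=len(df),
    )


def invert(model: CalibrationModel, m: float) -> tuple[float, bool]:
    """Deduce the modification fraction behind an observed mutation rate.

    Returns (f_hat clamped to [0, 1], clamp flag).
    """
    raw = (m - model.intercept) / model.slope
    clamped = raw < 0 or raw > 1
    return float(min(1.0, max(0.0, raw))), clamped


def fraction_ci(
    model: CalibrationModel,
    rec: pd.Series | tuple[int, int],
    level: float = 0.95,
) -> tuple[float, float]:
    """Wilson binomial CI on the rate, propagated through the inverse line."""
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if isinstance(rec, tuple):
        n_t, cov = rec
    else:
        n_t, cov = int(rec["n_T"]), int(rec["coverage"])
    if cov <= 0:
        raise ValueError("CI undefined at zero coverage")
    lo_m, hi_m = proportion_confint(n_t, cov, alpha=1 - level, method="wilson")
    lo, _ = invert(model, float(lo_m))
    hi, _ = invert(model, float(hi_m))
    # the Wilson bounds at k=0 / k=n are exactly 0 / 1; clear float residue
    if n_t == 0:
        lo = 0.0
    if n_t == cov:
        hi = 1.0
    return lo, hi


def fraction_se(model: CalibrationModel, m: float, coverage: int) -> float:
    """Delta-method standard error of an inverted fraction estimate.

    Combines the site's binomial rate variance with the calibration
    parameter covariance: Var(f_hat) = [m(1-m)/n + Var(b) + f^2 Var(a)
    + 2 f Cov(a, b)] / a^2.
    """
    f_hat, _ = invert(model, m)
    var = (
        m * (1 - m) / coverage
        + model.se_intercept**2
        + f_hat**2 * model.se_slope**2
        + 2 * f_hat * model.cov_slope_intercept
    )
    return float(np.sqrt(max(var, 0.0)) / model.slope)


@dataclass
class ContextReport:
    """Per-5-mer-context mutation rates plus dispersion summary."""

    per_context: pd.DataFrame
    grand_mean: float
    sd: float
    cv: float
    flagged: list[str] = field(default_factory=list)


def extract_context_counts(
    pileup_df: pd.DataFrame, design: SpikeInDesign, prefix: str = "spike_ctx_"
) -> pd.DataFrame:
    """Pull anchor-site counts of the context spike-ins out of a pileup table.

    Matches the transcript naming of :func:`f5cseq.simulate.spike_in_reference`
    (``spike_ctx_<context>``) and keeps only the modified-C anchor position.
    """
    from .simulate import _SPIKE_5P

    anchor_pos = len(_SPIKE_5P) + design.anchor
    sub = pileup_df[
        pileup_df["ref"].str.startswith(prefix) & (pileup_df["pos0"] == anchor_pos)
    ].copy()
    sub["context"] = sub["ref"].str.removeprefix(prefix)
    return sub[["context", "coverage", "n_T"]]


def context_dependence(
    spike_counts: pd.DataFrame,
    design: SpikeInDesign,
    z_threshold: float = 5.0,
) -> ContextReport:
    """Quantify sequence-context dependence of the mutation rate.

    ``spike_counts`` needs columns context, coverage, n_T — one row per
    design context, every one covered.  A context is flagged when its
    rate deviates from the grand mean by more than ``z_threshold``
    binomial standard errors.
    """
    expected = enumerate_contexts(design)
    have = set(spike_counts["context"])
    missing = sorted(set(expected) - have)
    if missing:
        raise ValueError(
            f"{len(missing)} design contexts missing or uncovered: "
            + ", ".join(missing[:8])
            + ("..." if len(missing) > 8 else "")
        )
    df = spike_counts.set_index("context").loc[expected].reset_index()
    if (df["coverage"] <= 0).any():
        bad = df.loc[df["coverage"] <= 0, "context"].tolist()
        raise ValueError(f"zero-coverage contexts: {bad}")
    df["rate"] = df["n_T"] / df["coverage"]
    grand = float(df["n_T"].sum() / df["coverage"].sum())
    sd = float(df["rate"].std(ddof=1))
    cv = sd / grand if grand > 0 else float("nan")
    se = np.sqrt(np.clip(grand * (1 - grand), 1e-12, None) / df["coverage"])
    df["z"] = (df["rate"] - grand) / se
    flagged = df.loc[df["z"].abs() > z_threshold, "context"].tolist()
    return ContextReport(
        per_context=df[["context", "coverage", "n_T", "rate", "z"]],
        grand_mean=grand,
        sd=sd,
        cv=cv,
        flagged=flagged,
    )
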