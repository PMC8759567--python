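"""Per-event two-group moderated differential analysis.

The model is the classical empirical-Bayes variance-shrinkage setup for
feature-wise two-group comparisons: each event g has an ordinary pooled
two-sample statistic (logFC = difference of group means on the common
[0, 100] scale, pooled variance s2_g on df_g degrees of freedom), the
event variances are assumed drawn from a scaled inverse chi-square prior
s0^2 * d0 / chisq(d0), and the posterior variance

    s2_post = (d0 * s0^2 + df * s2) / (d0 + df)

replaces s2 in the t statistic, which then has d0 + df degrees of freedom.
The prior (d0, s0^2) is estimated from all events by moment matching on
log s2 via the trigamma function.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from tadomics.aggregate import AggregatedTable
from tadomics.config import RunConfig

log = logging.getLogger(__name__)


@dataclass
class ModerationParams:
    """Empirical-Bayes prior: d0 degrees of freedom (may be inf), s0^2 variance."""

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive")
        if not (self.s0_2 > 0):
            raise ValueError("s0_2 must be positive")


def fit_two_group(
    values: pd.DataFrame | AggregatedTable,
    groups: pd.Series | dict,
) -> pd.DataFrame:
    """Ordinary per-event two-group statistics with pairwise NaN exclusion.

    ``groups`` maps sample id -> 0/1.  Returns a frame indexed like the
    value matrix with logFC (mean group1 - mean group0), AveExpr, pooled
    s2, df_resid, n0, n1 and an ``ok`` flag that is False for events with
    fewer than two observed samples in either group (those rows carry NaN
    statistics and are excluded downstream).
    """
    if isinstance(values, AggregatedTable):
        values = values.values
    groups = pd.Series(groups).dropna()
    g0 = [s for s in values.columns if groups.get(s) == 0]
    g1 = [s for s in values.columns if groups.get(s) == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(g0)} and {len(g1)}")

    x0 = values[g0].to_numpy(dtype=float)
    x1 = values[g1].to_numpy(dtype=float)
    n0 = (~np.isnan(x0)).sum(axis=1)
    n1 = (~np.isnan(x1)).sum(axis=1)
    ok = (n0 >= 2) & (n1 >= 2)

    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = np.nanmean(np.where(np.isnan(x0), np.nan, x0), axis=1)
        m1 = np.nanmean(np.where(np.isnan(x1), np.nan, x1), axis=1)
        ss0 = np.nansum((x0 - m0[:, None]) ** 2, axis=1)
        ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
        df_resid = n0 + n1 - 2
        s2 = np.where(ok, (ss0 + ss1) / np.maximum(df_resid, 1), np.nan)
        tot = np.nansum(np.concatenate([x0, x1], axis=1), axis=1)
        ave = tot / np.maximum(n0 + n1, 1)

    out = pd.DataFrame(
        {
            "logFC": np.where(ok, m1 - m0, np.nan),
            "AveExpr": np.where(ok, ave, np.nan),
            "s2": s2,
            "df_resid": np.where(ok, df_resid, 0).astype(int),
            "n0": n0,
            "n1": n1,
            "ok": ok,
        },
        index=values.index,
    )
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.info("%d events excluded (insufficient observed samples)", n_excluded)
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return y


def estimate_moderation(
    s2: np.ndarray | pd.Series, df: np.ndarray | pd.Series
) -> ModerationParams:
    """Moment estimator of the variance prior from all events.

    Works on e_g = log s2_g - digamma(df_g/2) + log(df_g/2), whose mean and
    excess dispersion identify (d0, s0^2): solve
    trigamma(d0/2) = mean[(e - mean(e))^2 * n/(n-1) - trigamma(df/2)]
    for d0 (inverse trigamma, Newton); a non-positive right-hand side means
    no excess dispersion, hence d0 = inf and s0^2 = exp(mean(e)).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    keep = np.isfinite(s2) & (df >= 1)
    if keep.sum() and not (s2[keep] > 0).any():
        raise ValueError("all event variances are zero; filter invariant events")
    if keep.sum() and (s2[keep] <= 0).any():
        n_zero = int((s2[keep] <= 0).sum())
        log.warning("%d events with zero variance excluded from prior fit", n_zero)
        keep &= s2 > 0
    s2, df = s2[keep], df[keep]
    n = s2.size
    if n < 10:
        raise ValueError(f"need >= 10 events with df >= 1, got {n}")

    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(
        np.mean((e - emean) ** 2 * n / (n - 1) - special.polygamma(1, df / 2.0))
    )
    if evar <= 0:
        return ModerationParams(d0=math.inf, s0_2=float(np.exp(emean)))
    half_d0 = _trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    s0_2 = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return ModerationParams(d0=d0, s0_2=s0_2)


def moderate(stats_df: pd.DataFrame, params: ModerationParams) -> pd.DataFrame:
    """Moderated t statistics and two-sided p-values from fitted stats.

    s2_post = (d0*s0^2 + df*s2)/(d0 + df) (= s0^2 at d0 = inf);
    t = logFC / sqrt(s2_post * (1/n0 + 1/n1)); p from t with d0 + df
    degrees of freedom (standard normal when infinite).
    """
    out = stats_df.copy()
    d0, s0_2 = params.d0, params.s0_2
    df = out["df_resid"].to_numpy(dtype=float)
    s2 = out["s2"].to_numpy(dtype=float)
    ok = out["ok"].to_numpy(dtype=bool)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    se2 = s2_post * (1.0 / out["n0"].to_numpy() + 1.0 / out["n1"].to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        t = out["logFC"].to_numpy() / np.sqrt(se2)
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), d0 + df)
    out["s2_post"] = np.where(ok, s2_post, np.nan)
    out["t_mod"] = np.where(ok, t, np.nan)
    out["p"] = np.where(ok, p, np.nan)
    return out


def bh_adjust(p: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    if mask.any():
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    return out


def evendiff_run(
    agg: AggregatedTable,
    meta: pd.DataFrame,
    contrast: str,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Full event-level differential analysis for one binary contrast.

    Fits per-event two-group statistics, estimates the variance prior,
    moderates, BH-adjusts, and flags events with adj_p < alpha_event and
    |logFC| >= lfc_min.  Writes ``<contrast>_evenDiff.txt`` (statistics +
    annotations + per-sample values) and appends to
    ``Summary_evenDiff.txt`` when ``out_dir`` is given.
    """
    config = config or RunConfig()
    if contrast not in meta.columns:
        raise ValueError(f"contrast {contrast!r} not in metadata")
    groups = meta[contrast].dropna()
    groups = groups[groups.index.isin(agg.sample_ids)]

    fitted = fit_two_group(agg.values, groups)
    ok = fitted["ok"]
    params = estimate_moderation(fitted.loc[ok, "s2"], fitted.loc[ok, "df_resid"])
    res = moderate(fitted, params)
    res["adj_p"] = bh_adjust(res["p"])
    res["significant"] = (
        ok
        & (res["adj_p"] < config.alpha_event)
        & (res["logFC"].abs() >= config.lfc_min)
    )
    res.attrs["moderation"] = params

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table = pd.concat(
            [
                agg.annotations,
                res[["logFC", "AveExpr", "t_mod", "p", "adj_p", "significant"]]
                .rename(columns={"t_mod": "t", "p": "P.Value",
                                 "adj_p": "adj.P.Val"}),
                agg.values,
            ],
            axis=1,
        )
        table.to_csv(out_dir / f"{contrast}_evenDiff.txt", sep="\t", index=False)
        summary_path = out_dir / "Summary_evenDiff.txt"
        header = not summary_path.exists()
        with open(summary_path, "a") as fh:
            if header:
                fh.write("contrast\tn_events_tested\tn_significant\n")
            fh.write(f"{contrast}\t{int(ok.sum())}\t{int(res['significant'].sum())}\n")
    return res
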