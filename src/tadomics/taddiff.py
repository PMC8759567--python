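"""TAD-level differential calls from event-level statistics.

A TAD is called significant when (i) it is enriched in significant events
relative to the genome-wide rate, by an upper-tail hypergeometric test on
(N = all TAD-assigned events, K = all significant TAD-assigned events,
n = events in this TAD, k = significant events in this TAD), and (ii) it
shows a phenotypic response in expression: the mean |logFC| over its
expression-source events ("activation") passes a threshold.  TADs without
expression events have activation 0 and can never be called.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from tadomics.aggregate import AggregatedTable
from tadomics.config import RunConfig
from tadomics.evendiff import bh_adjust, fit_two_group


def tad_hypergeom_test(N_total: int, K_sig_total: int, n_tad: int,
                       k_sig_tad: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k), X ~ Hypergeom(N, K, n)."""
    N, K, n, k = int(N_total), int(K_sig_total), int(n_tad), int(k_sig_tad)
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def tad_activation(logfc: pd.Series | np.ndarray,
                   is_expression: pd.Series | np.ndarray) -> float:
    """Mean |logFC| over expression-source events; 0 when there are none."""
    logfc = np.asarray(logfc, dtype=float)
    is_expression = np.asarray(is_expression, dtype=bool)
    sel = np.abs(logfc[is_expression])
    sel = sel[~np.isnan(sel)]
    return float(sel.mean()) if sel.size else 0.0


def taddiff_run(
    agg: AggregatedTable,
    event_stats: pd.DataFrame,
    contrast: str = "group",
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Aggregate event-level results into per-TAD statistics and calls.

    ``event_stats`` is the frame returned by :func:`evendiff_run` (indexed
    by event_id, with logFC/adj_p/significant).  Events without a TAD are
    excluded from both the universe N and the significant set K.  A BH
    column over the hypergeometric p-values is emitted for information;
    the default call uses the raw p, as the TAD criterion is a descriptive
    enrichment cut rather than a multiplicity-controlled test.
    """
    config = config or RunConfig()
    ann = agg.annotations
    assigned = ann["tad_id"] != ""
    joined = ann.loc[assigned, ["tad_id", "chrom", "tad_start", "tad_end",
                                "source"]].join(event_stats, how="left")
    joined = joined[joined["ok"].fillna(False).astype(bool)]
    joined["is_expression"] = joined["source"].map(agg.source_map) == "count"

    N = len(joined)
    K = int(joined["significant"].sum())

    rows = []
    for tad_id, grp in joined.groupby("tad_id", sort=True):
        n = len(grp)
        k = int(grp["significant"].sum())
        p = tad_hypergeom_test(N, K, n, k)
        activation = tad_activation(grp["logFC"], grp["is_expression"])
        rows.append({
            "tad_id": tad_id,
            "chrom": grp["chrom"].iloc[0],
            "start": int(grp["tad_start"].iloc[0]),
            "end": int(grp["tad_end"].iloc[0]),
            "n_events": n,
            "n_sig": k,
            "hyper_p": p,
            "activation": activation,
        })
    res = pd.DataFrame(rows)
    if res.empty:
        res = pd.DataFrame(columns=["tad_id", "chrom", "start", "end",
                                    "n_events", "n_sig", "hyper_p",
                                    "activation", "hyper_adj_p", "significant"])
        res["significant"] = res["significant"].astype(bool)
    else:
        res["hyper_adj_p"] = bh_adjust(res["hyper_p"])
        res["significant"] = (
            (res["hyper_p"] < config.alpha_tad)
            & (res["activation"] >= config.activation_min)
        )
        res = res.set_index("tad_id", drop=False)
        res.index.name = None

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / f"{contrast}_TADiff.txt"
        with open(path, "w") as fh:
            stat_cols = ["logFC", "AveExpr", "t_mod", "p", "adj_p", "significant"]
            fh.write("# one TAD line, then its events indented by 'event:'\n")
            fh.write("tad_id\tchrom\tstart\tend\tn_events\tn_sig\thyper_p\t"
                     "hyper_adj_p\tactivation\tsignificant\n")
            for _, row in res.sort_values("hyper_p").iterrows():
                fh.write("\t".join(str(row[c]) for c in
                                   ["tad_id", "chrom", "start", "end",
                                    "n_events", "n_sig", "hyper_p",
                                    "hyper_adj_p", "activation",
                                    "significant"]) + "\n")
                events = ann.index[(ann["tad_id"] == row["tad_id"])]
                block = pd.concat(
                    [ann.loc[events, ["event_id", "source", "gene_id",
                                      "gene_feature"]],
                     event_stats.reindex(events)[stat_cols],
                     agg.values.loc[events]],
                    axis=1,
                )
                for _, ev in block.iterrows():
                    fh.write("event:\t" + "\t".join(str(v) for v in ev) + "\n")
        summary_path = out_dir / "Summary_TADiff.txt"
        header = not summary_path.exists()
        with open(summary_path, "a") as fh:
            if header:
                fh.write("contrast\tn_TADs_tested\tn_significant\n")
            fh.write(f"{contrast}\t{len(res)}\t{int(res['significant'].sum())}\n")
    return res


def tad_sample_means(agg: AggregatedTable) -> pd.DataFrame:
    """TAD x sample matrix of per-TAD mean event values (NaN-excluded)."""
    assigned = agg.annotations["tad_id"] != ""
    if not assigned.any():
        raise ValueError("no TAD-assigned events")
    values = agg.values.loc[assigned]
    return values.groupby(agg.annotations.loc[assigned, "tad_id"]).mean()


def tad_abs_diff_means(
    agg: AggregatedTable, groups: pd.Series | dict
) -> pd.Series:
    """Per-TAD mean of |group1 mean - group0 mean| over its events."""
    fitted = fit_two_group(agg.values, groups)
    assigned = agg.annotations["tad_id"] != ""
    absfc = fitted["logFC"].abs()
    return absfc[assigned].groupby(
        agg.annotations.loc[assigned, "tad_id"]).mean()
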