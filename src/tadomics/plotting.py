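"""Visualisation of TADs of interest and enrichment results.

Every figure writes a machine-readable sidecar table (CSV) next to the
image with exactly the numbers plotted; tests assert on sidecars, never
on pixels.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from tadomics.aggregate import AggregatedTable


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".csv")


def plot_tad_dots(
    agg: AggregatedTable,
    tad_id: str,
    groups: pd.Series | dict,
    out_path: str | Path,
    mode: str = "values",
) -> Path:
    """Dot plot of one TAD's events split by group.

    ``mode="values"`` shows every sample value per event; ``mode="means"``
    shows the per-event group means joined by a line, with violins of the
    mean distributions.
    """
    out_path = Path(out_path)
    groups = pd.Series(groups).dropna()
    sel = agg.annotations["tad_id"] == tad_id
    if not sel.any():
        raise ValueError(f"no events in TAD {tad_id!r}")
    values = agg.values.loc[sel]
    g0 = [s for s in values.columns if groups.get(s) == 0]
    g1 = [s for s in values.columns if groups.get(s) == 1]

    fig, ax = plt.subplots(figsize=(max(6, 0.25 * len(values)), 4))
    x = np.arange(len(values))
    if mode == "values":
        rows = []
        for gi, (cols, color) in enumerate(((g0, "C0"), (g1, "C1"))):
            sub = values[cols]
            for off, (eid, row) in enumerate(sub.iterrows()):
                ax.scatter(np.full(len(cols), off + (gi - 0.5) * 0.3),
                           row.to_numpy(), s=8, color=color, alpha=0.6)
            for col in cols:
                for eid in sub.index:
                    rows.append({"event_id": eid, "sample_id": col,
                                 "group": gi, "value": sub.at[eid, col]})
        sidecar = pd.DataFrame(rows)
    elif mode == "means":
        m0 = values[g0].mean(axis=1)
        m1 = values[g1].mean(axis=1)
        ax.plot(x, m0, "o-", color="C0", label="group 0")
        ax.plot(x, m1, "o-", color="C1", label="group 1")
        for pos, series in ((-0.6, m0), (len(values) - 0.4, m1)):
            vp = ax.violinplot([series.dropna().to_numpy()], positions=[pos],
                               widths=0.8)
        ax.legend()
        sidecar = pd.DataFrame({"event_id": values.index,
                                "mean_group0": m0.to_numpy(),
                                "mean_group1": m1.to_numpy()})
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ax.set_xticks(x)
    ax.set_xticklabels(values.index, rotation=90, fontsize=6)
    ax.set_ylabel("scaled value")
    ax.set_title(f"{tad_id} ({int(sel.sum())} events)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    sidecar.to_csv(_sidecar(out_path), index=False)
    return out_path


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    lo, _, hi = span.replace(",", "").partition("-")
    if not chrom or not lo or not hi:
        raise ValueError(f"region {region!r} not of the form chrom:start-end")
    return chrom, int(lo), int(hi)


def plot_tad_track(
    agg: AggregatedTable,
    region: str,
    groups: pd.Series | dict,
    out_path: str | Path,
    mode: str = "group",
) -> Path:
    """Genomic-track plot: event position on x, value on y, for a region.

    ``mode="case"`` draws every sample, ``mode="group"`` the two group
    means, ``mode="difference"`` a single group-difference track.
    """
    out_path = Path(out_path)
    chrom, lo, hi = _parse_region(region)
    groups = pd.Series(groups).dropna()
    ann = agg.annotations
    sel = (ann["chrom"] == chrom) & (ann["start"] < hi) & (ann["end"] > lo)
    fig, ax = plt.subplots(figsize=(8, 4))
    if not sel.any():
        import warnings

        warnings.warn(f"no events in region {region}", stacklevel=2)
        sidecar = pd.DataFrame(columns=["event_id", "position", "series", "value"])
    else:
        values = agg.values.loc[sel.to_numpy()]
        pos = ann.loc[sel.to_numpy(), "start"].to_numpy()
        g0 = [s for s in values.columns if groups.get(s) == 0]
        g1 = [s for s in values.columns if groups.get(s) == 1]
        rows = []
        if mode == "case":
            for col in values.columns:
                ax.plot(pos, values[col], ".", ms=3, alpha=0.4)
                rows += [{"event_id": e, "position": p, "series": col,
                          "value": v}
                         for e, p, v in zip(values.index, pos, values[col])]
        elif mode == "group":
            for name, cols, color in (("group0", g0, "C0"), ("group1", g1, "C1")):
                m = values[cols].mean(axis=1)
                ax.plot(pos, m, "o", color=color, label=name)
                rows += [{"event_id": e, "position": p, "series": name,
                          "value": v}
                         for e, p, v in zip(values.index, pos, m)]
            ax.legend()
        elif mode == "difference":
            d = values[g1].mean(axis=1) - values[g0].mean(axis=1)
            ax.plot(pos, d, "o", color="C2")
            ax.axhline(0, color="grey", lw=0.5)
            rows += [{"event_id": e, "position": p, "series": "difference",
                      "value": v}
                     for e, p, v in zip(values.index, pos, d)]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        sidecar = pd.DataFrame(rows)
    ax.set_xlim(lo, hi)
    ax.set_xlabel(f"{chrom} position")
    ax.set_ylabel("scaled value")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    sidecar.to_csv(_sidecar(out_path), index=False)
    return out_path


def plot_enrichment_bars(
    results: pd.DataFrame,
    out_path: str | Path,
    top: int = 20,
    label_col: str | None = None,
) -> Path:
    """Horizontal bar plot of enrichment results, -log10 adjusted p."""
    out_path = Path(out_path)
    if results.empty:
        raise ValueError("no enrichment results to plot")
    if label_col is None:
        label_col = ("term_name" if "term_name" in results.columns
                     else "motif_id")
    df = results.sort_values("adj_p").head(top).copy()
    df["neg_log10_adj_p"] = -np.log10(df["adj_p"].clip(lower=1e-300))
    fig, ax = plt.subplots(figsize=(7, max(2, 0.35 * len(df))))
    ax.barh(df[label_col][::-1], df["neg_log10_adj_p"][::-1], color="C0")
    ax.set_xlabel("-log10 adjusted p")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    df[[label_col, "adj_p", "neg_log10_adj_p"]].to_csv(
        _sidecar(out_path), index=False)
    return out_path
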