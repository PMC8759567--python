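"""Shared fixtures: synthetic bundles, in-memory tables, brute-force oracles."""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from tadomics import (
    AggregatedTable,
    build_aggregated_table,
    generate_bundle,
    load_metadata,
    load_omics_dir,
    load_segments,
)
from tadomics.aggregate import ANNOTATION_COLUMNS


# ---------------------------------------------------------------------------
# independent oracles (hand-written, no scipy/statsmodels)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by exact pmf enumeration."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def bh_reference(p: np.ndarray) -> np.ndarray:
    """Naive BH: sort, p*m/rank, cumulative min from the end, unsort."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def naive_assign(events: pd.DataFrame, segments: pd.DataFrame) -> list[str]:
    """All-pairs max-overlap TAD assignment (ties: smallest tad_id)."""
    out = []
    for _, ev in events.iterrows():
        best_id, best_len = "", 0
        for _, seg in segments.iterrows():
            if seg["chrom"] != ev["chrom"]:
                continue
            ov = overlap_len(ev["start"], ev["end"], seg["start"], seg["end"])
            if ov > best_len or (ov == best_len and ov > 0
                                 and seg["tad_id"] < best_id):
                best_id, best_len = seg["tad_id"], ov
        out.append(best_id)
    return out


# ---------------------------------------------------------------------------
# in-memory table construction


def make_agg(
    values: pd.DataFrame,
    tad_ids: list[str] | None = None,
    sources: list[str] | None = None,
    source_map: dict[str, str] | None = None,
    chrom: str = "chr1",
) -> AggregatedTable:
    """Build a minimal AggregatedTable around a value matrix for unit tests."""
    n = len(values)
    ann = pd.DataFrame(
        {
            "chrom": chrom,
            "tad_id": tad_ids if tad_ids is not None else [""] * n,
            "tad_start": 0,
            "tad_end": 1_000_000,
            "event_id": list(values.index),
            "start": np.arange(n) * 100,
            "end": np.arange(n) * 100 + 2,
            "gene_id": "",
            "gene_feature": "intergenic",
            "source": sources if sources is not None else ["meth.tsv"] * n,
        },
        index=values.index,
    )[ANNOTATION_COLUMNS]
    return AggregatedTable(
        annotations=ann,
        values=values,
        source_map=source_map or {"meth.tsv": "freq", "expr.tsv": "count"},
    )


def toy_gtf(path: Path, genes: list[tuple]) -> Path:
    """Write a GTF from (gene_id, chrom, start0, end, strand, features) tuples.

    ``features`` is a list of (feature, start0, end); coordinates are 0-based
    half-open and converted to the GTF's 1-based closed dialect on write.
    """
    lines = []
    for gene_id, chrom, start0, end, strand, features in genes:
        attr = f'gene_id "{gene_id}"; transcript_id "{gene_id}.t1";'
        lines.append("\t".join(map(str, [
            chrom, "toy", "transcript", start0 + 1, end, ".", strand, ".", attr])))
        for feature, fs, fe in features:
            lines.append("\t".join(map(str, [
                chrom, "toy", feature, fs + 1, fe, ".", strand, ".", attr])))
    path.write_text("\n".join(lines) + "\n")
    return path


def run_bundle(bundle_dir: Path):
    """Load a generated bundle and build its aggregated table + metadata."""
    tables = load_omics_dir(bundle_dir / "freq", bundle_dir / "counts")
    segments = load_segments(bundle_dir / "tads.bed")
    agg = build_aggregated_table(tables, segments, bundle_dir / "genes.gtf")
    meta = load_metadata(bundle_dir / "meta.tsv")
    return agg, meta


# ---------------------------------------------------------------------------
# session-scoped bundles (generation is deterministic, sharing is safe)


@pytest.fixture(scope="session")
def small_planted_bundle(tmp_path_factory) -> Path:
    """50 TADs x 20 events, 3 planted with a 30-unit shift, 20/group."""
    path = tmp_path_factory.mktemp("bundle") / "planted"
    generate_bundle(path, n_tads=50, events_per_tad=20, n_samples=20,
                    n_planted_tads=3, effect=30.0, seed=7)
    return path


@pytest.fixture(scope="session")
def small_planted_run(small_planted_bundle):
    agg, meta = run_bundle(small_planted_bundle)
    return small_planted_bundle, agg, meta
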