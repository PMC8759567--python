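"""Data aggregation: load, harmonise, scale and annotate omics layers.

All interval arithmetic is done in 0-based half-open coordinates.  Omics
tables and the TAD BED are taken to be 0-based half-open already; GTF
coordinates (1-based closed) are converted on load.  Overlap means a shared
half-open intersection of length >= 1.  Strand is ignored for all overlap
work here; it matters only when the enrichment module extracts promoter
sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from tadomics.config import RunConfig, DEFAULT_CHROMOSOMES

log = logging.getLogger(__name__)

EVENT_COLUMNS = ["event_id", "chrom", "start", "end"]

#: columns of the integrated table ahead of the per-sample value columns
ANNOTATION_COLUMNS = [
    "chrom",
    "tad_id",
    "tad_start",
    "tad_end",
    "event_id",
    "start",
    "end",
    "gene_id",
    "gene_feature",
    "source",
]

# higher wins when one event touches several features of a gene
FEATURE_PRECEDENCE = {
    "cds": 5,
    "exon": 4,
    "threeUTR": 3,
    "fiveUTR": 3,
    "intron": 2,
    "promoter": 1,
}


@dataclass
class OmicsTable:
    """One input omics layer.

    ``events`` holds event_id/chrom/start/end (one row per event);
    ``values`` is indexed by event_id with one column per sample.  ``kind``
    is ``"freq"`` for data already on a 0-100 frequency scale (methylation
    beta x100, mutation VAF x100) and ``"count"`` for expression counts.
    """

    source: str
    kind: str
    events: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in ("freq", "count"):
            raise ValueError(f"kind must be 'freq' or 'count', got {self.kind!r}")
        if len(self.events) != len(self.values):
            raise ValueError("events and values row counts differ")
        if self.values.columns.duplicated().any():
            raise ValueError(f"{self.source}: duplicate sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path: str | Path) -> None:
        """Write back in the input dialect (ID, chrom, start, end, samples)."""
        out = pd.concat(
            [self.events.reset_index(drop=True),
             self.values.reset_index(drop=True)],
            axis=1,
        )
        out.to_csv(path, sep="\t", index=False)


@dataclass
class AggregatedTable:
    """The unified event x sample matrix on [0, 100] with annotations.

    ``annotations`` carries :data:`ANNOTATION_COLUMNS` (one row per event,
    indexed by event_id); ``values`` is the matrix with matching index.
    """

    annotations: pd.DataFrame
    values: pd.DataFrame
    source_map: dict[str, str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_events(self) -> int:
        return len(self.annotations)

    def frame(self) -> pd.DataFrame:
        """The full integrated table, annotation columns then sample columns."""
        return pd.concat([self.annotations, self.values], axis=1)

    def save(self, out_dir: str | Path, methnorm: bool = False) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        full = self.frame()
        no_tad = full.drop(columns=["tad_id", "tad_start", "tad_end"])
        no_tad.to_csv(out_dir / "integrated-table.csv", index=False)
        full.to_csv(out_dir / "integrated-tad-table.csv", index=False)
        if methnorm:
            full.to_csv(out_dir / "integrated-tad-table-methNorm.txt",
                        sep="\t", index=False)
        with open(out_dir / "summary.txt", "w") as fh:
            fh.write("source\tkind\tn_events\n")
            counts = self.annotations["source"].value_counts()
            for source, kind in sorted(self.source_map.items()):
                fh.write(f"{source}\t{kind}\t{int(counts.get(source, 0))}\n")

    @classmethod
    def load(cls, out_dir: str | Path) -> "AggregatedTable":
        out_dir = Path(out_dir)
        methnorm = out_dir / "integrated-tad-table-methNorm.txt"
        if methnorm.exists():
            full = pd.read_csv(methnorm, sep="\t", dtype={"chrom": str})
        else:
            full = pd.read_csv(out_dir / "integrated-tad-table.csv",
                               dtype={"chrom": str})
        for col in ("tad_id", "gene_id", "gene_feature"):
            full[col] = full[col].fillna("")
        annotations = full[ANNOTATION_COLUMNS].copy()
        annotations.index = pd.Index(annotations["event_id"], name="event_id")
        values = full.drop(columns=ANNOTATION_COLUMNS)
        values.index = annotations.index
        summary = pd.read_csv(out_dir / "summary.txt", sep="\t")
        source_map = dict(zip(summary["source"], summary["kind"]))
        return cls(annotations=annotations, values=values, source_map=source_map)


# ---------------------------------------------------------------------------
# loading


def load_omics_table(
    path: str | Path,
    kind: str,
    allowed_chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES,
) -> OmicsTable:
    """Read one tab-delimited omics table.

    Column 1 is a unique event ID, columns 2-4 chrom/start/end, the rest
    per-sample values.  Events on chromosomes outside ``allowed_chromosomes``
    are dropped (count logged).  Unparseable coordinates or duplicate event
    IDs are hard errors naming the file.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 5:
        raise ValueError(f"{path}: expected >= 5 columns, got {raw.shape[1]}")
    raw.columns = EVENT_COLUMNS + list(raw.columns[4:])
    for col in ("start", "end"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any() or coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna())[0]) + 2  # header is line 1
            raise ValueError(f"{path}: unparseable {col} at line {line}")
        raw[col] = coerced.astype(np.int64)
    if (raw["start"] > raw["end"]).any():
        line = int(np.flatnonzero(raw["start"] > raw["end"])[0]) + 2
        raise ValueError(f"{path}: start > end at line {line}")
    if raw["event_id"].duplicated().any():
        dup = raw.loc[raw["event_id"].duplicated(), "event_id"].iloc[0]
        raise ValueError(f"{path}: duplicate event id {dup!r}")

    keep = raw["chrom"].isin(allowed_chromosomes)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("%s: dropped %d events outside the allowed chromosomes",
                 path.name, n_dropped)
    raw = raw.loc[keep].reset_index(drop=True)

    events = raw[EVENT_COLUMNS].copy()
    values = raw.drop(columns=EVENT_COLUMNS).apply(pd.to_numeric)
    values.index = pd.Index(events["event_id"], name="event_id")
    return OmicsTable(source=path.name, kind=kind, events=events, values=values)


def load_omics_dir(
    freq_dir: str | Path,
    counts_dir: str | Path,
    allowed_chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES,
) -> list[OmicsTable]:
    """Load every table under the ``freq`` and ``counts`` folders."""
    tables: list[OmicsTable] = []
    for directory, kind in ((freq_dir, "freq"), (counts_dir, "count")):
        directory = Path(directory)
        if not directory.is_dir():
            continue
        for path in sorted(directory.iterdir()):
            if path.is_file():
                tables.append(load_omics_table(path, kind, allowed_chromosomes))
    if not tables:
        raise ValueError("no omics tables found")
    return tables


def load_segments(bed_path: str | Path) -> pd.DataFrame:
    """Read a BED3+ segment (TAD) file; column 4 is the segment name."""
    seg = pd.read_csv(bed_path, sep="\t", header=None, comment="#", dtype=str)
    if seg.shape[1] < 3:
        raise ValueError(f"{bed_path}: expected >= 3 BED columns")
    seg = seg.iloc[:, :4] if seg.shape[1] >= 4 else seg.assign(name=None)
    seg.columns = ["chrom", "start", "end", "tad_id"]
    seg["start"] = seg["start"].astype(np.int64)
    seg["end"] = seg["end"].astype(np.int64)
    if seg["tad_id"].isna().any():
        seg["tad_id"] = [f"TAD{i:05d}" for i in range(len(seg))]
    if (seg["start"] >= seg["end"]).any():
        raise ValueError(f"{bed_path}: segment with start >= end")
    if seg["tad_id"].duplicated().any():
        raise ValueError(f"{bed_path}: duplicate segment names")
    return seg[["tad_id", "chrom", "start", "end"]]


def load_metadata(path: str | Path, min_marker_n: int = 5) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id + binary contrast columns).

    Markers with fewer than ``min_marker_n`` positive samples and contrasts
    without at least two samples per group are dropped with a log message.
    """
    meta = pd.read_csv(path, sep="\t", dtype={0: str})
    meta = meta.rename(columns={meta.columns[0]: "sample_id"})
    meta = meta.set_index("sample_id")
    keep: list[str] = []
    for col in meta.columns:
        vals = pd.to_numeric(meta[col], errors="coerce")
        groups = vals.dropna().unique()
        if not set(groups) <= {0, 1}:
            log.warning("metadata column %r is not binary; dropped", col)
            continue
        n_pos = int((vals == 1).sum())
        n_neg = int((vals == 0).sum())
        if n_pos < min_marker_n:
            log.info("marker %r present in %d < %d samples; dropped",
                     col, n_pos, min_marker_n)
            continue
        if min(n_pos, n_neg) < 2:
            log.info("contrast %r lacks two samples per group; dropped", col)
            continue
        meta[col] = vals
        keep.append(col)
    return meta[keep]


# ---------------------------------------------------------------------------
# harmonisation and scaling


def harmonize_samples(
    tables: list[OmicsTable], mode: str = "intersect"
) -> list[OmicsTable]:
    """Align the sample columns of all layers.

    ``intersect`` restricts every table to the common sample set (hard error
    when empty); ``union`` keeps every sample and fills absent cells with
    NaN, which downstream statistics exclude pairwise.
    """
    if not tables:
        raise ValueError("no tables to harmonize")
    sets = [set(t.sample_ids) for t in tables]
    if mode == "intersect":
        common = set.intersection(*sets)
        if not common:
            raise ValueError("no samples shared by all omics layers")
        ordered = [s for s in tables[0].sample_ids if s in common]
        for t in tables[1:]:
            ordered += [s for s in t.sample_ids if s in common and s not in ordered]
        return [
            OmicsTable(t.source, t.kind, t.events, t.values[ordered].copy())
            for t in tables
        ]
    if mode == "union":
        ordered = []
        for t in tables:
            ordered += [s for s in t.sample_ids if s not in ordered]
        return [
            OmicsTable(t.source, t.kind, t.events,
                       t.values.reindex(columns=ordered))
            for t in tables
        ]
    raise ValueError(f"unknown sample mode {mode!r}")


def scale_counts(values: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Map non-negative counts onto [0, 100] by a per-sample log transform.

    Each column j becomes ``log1p(x) * 100 / max_i log1p(x_ij)``; an
    all-zero column stays zero.  log1p rather than a plain logarithm keeps
    zero counts (pervasive in expression data) finite and at 0.
    """
    arr = np.asarray(values, dtype=float)
    observed = ~np.isnan(arr)  # NaN marks a missing cell under union mode
    if not np.isfinite(arr[observed]).all():
        raise ValueError("counts must be finite")
    if (arr[observed] < 0).any():
        raise ValueError("counts must be non-negative")
    logged = np.log1p(arr)
    with np.errstate(invalid="ignore", divide="ignore"):
        colmax = (np.nanmax(np.where(observed, logged, np.nan), axis=0)
                  if logged.size else np.array([]))
        colmax = np.nan_to_num(colmax, nan=0.0)
    colmax = np.where(colmax > 0, colmax, np.inf)  # zero column -> stays 0
    # divide first: the column maximum maps to exactly 1.0 -> exactly 100
    out = (logged / colmax) * 100.0
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def scale_freq(
    values: pd.DataFrame | np.ndarray, beta_autoscale: bool = True
) -> pd.DataFrame | np.ndarray:
    """Bring frequency-scale data onto [0, 100].

    Data already on [0, 100] (mutation VAF x100, methylation beta x100) pass
    through; a layer whose maximum is <= 1 is treated as raw beta values and
    multiplied by 100 when ``beta_autoscale`` is on.  Stray values outside
    [0, 100] are clamped (logged).
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if beta_autoscale and finite.size and np.nanmax(finite) <= 1.0:
        arr = arr * 100.0
        log.info("freq layer auto-rescaled from beta [0,1] to [0,100]")
    n_clamped = int(((arr < 0) | (arr > 100)).sum())
    if n_clamped:
        log.warning("clamped %d freq values outside [0,100]", n_clamped)
    arr = np.clip(arr, 0.0, 100.0)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(arr, index=values.index, columns=values.columns)
    return arr


# ---------------------------------------------------------------------------
# annotation


def _parse_gtf(gtf_path: str | Path) -> pd.DataFrame:
    """Read a GTF and convert to 0-based half-open coordinates."""
    gtf = pd.read_csv(
        gtf_path, sep="\t", comment="#", header=None,
        names=["chrom", "src", "feature", "start", "end",
               "score", "strand", "frame", "attribute"],
        dtype={"chrom": str, "feature": str, "attribute": str},
    )
    gtf["gene_id"] = gtf["attribute"].str.extract(r'gene_id "([^"]+)"')
    gtf["start"] = gtf["start"].astype(np.int64) - 1
    gtf["end"] = gtf["end"].astype(np.int64)
    return gtf.dropna(subset=["gene_id"])


_GTF_FEATURE_MAP = {
    "cds": "cds",
    "exon": "exon",
    "three_prime_utr": "threeUTR",
    "3utr": "threeUTR",
    "three_prime_UTR": "threeUTR",
    "five_prime_utr": "fiveUTR",
    "5utr": "fiveUTR",
}


def gene_models(gtf_path: str | Path) -> pd.DataFrame:
    """Per-gene span, strand and TSS from a GTF (0-based half-open)."""
    gtf = _parse_gtf(gtf_path)
    span = gtf.groupby("gene_id").agg(
        chrom=("chrom", "first"),
        start=("start", "min"),
        end=("end", "max"),
        strand=("strand", "first"),
    )
    span["tss"] = np.where(span["strand"] == "-", span["end"] - 1, span["start"])
    return span.reset_index()


def _gene_feature_trees(
    gtf: pd.DataFrame,
    promoter_upstream: int = 1000,
    promoter_downstream: int = 200,
) -> dict[str, IntervalTree]:
    """Interval trees of (gene_id, feature) payloads, one per chromosome.

    The gene span itself is inserted with feature ``intron`` (lowest gene-body
    precedence), so any overlap not explained by a finer feature reads as
    intronic.  Promoter windows are added around the TSS.
    """
    trees: dict[str, IntervalTree] = {}

    def add(chrom: str, start: int, end: int, gene: str, feature: str) -> None:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end, (gene, feature))

    for (gene, chrom), grp in gtf.groupby(["gene_id", "chrom"], sort=False):
        strand = grp["strand"].iloc[0]
        gstart, gend = int(grp["start"].min()), int(grp["end"].max())
        add(chrom, gstart, gend, gene, "intron")
        if strand == "-":
            add(chrom, gend - promoter_downstream, gend + promoter_upstream,
                gene, "promoter")
        else:
            add(chrom, gstart - promoter_upstream, gstart + promoter_downstream,
                gene, "promoter")
        for _, row in grp.iterrows():
            feature = _GTF_FEATURE_MAP.get(row["feature"].lower())
            if feature:
                add(chrom, int(row["start"]), int(row["end"]), gene, feature)
    return trees


def annotate_genes(
    events: pd.DataFrame,
    gtf: str | Path,
    promoter_upstream: int = 1000,
    promoter_downstream: int = 200,
) -> pd.DataFrame:
    """Fill gene_id / gene_feature for every event by interval overlap.

    An event overlapping several features of one gene gets the
    highest-precedence feature (cds > exon > UTR > intron > promoter); an
    event overlapping several genes lists all their IDs joined with ";".
    Events touching nothing get gene_feature ``intergenic`` and an empty
    gene_id.
    """
    gtf_df = _parse_gtf(gtf)
    trees = _gene_feature_trees(gtf_df, promoter_upstream, promoter_downstream)
    known_chroms = set(gtf_df["chrom"].unique())

    out = events.copy()
    gene_ids: list[str] = []
    gene_features: list[str] = []
    unknown: set[str] = set()
    for chrom, start, end in zip(out["chrom"], out["start"], out["end"]):
        tree = trees.get(chrom)
        if tree is None:
            if chrom not in known_chroms:
                unknown.add(chrom)
            gene_ids.append("")
            gene_features.append("intergenic")
            continue
        per_gene: dict[str, int] = {}
        for iv in tree.overlap(int(start), int(end)):
            gene, feature = iv.data
            rank = FEATURE_PRECEDENCE[feature]
            if rank > per_gene.get(gene, 0):
                per_gene[gene] = rank
        if not per_gene:
            gene_ids.append("")
            gene_features.append("intergenic")
        else:
            best = max(per_gene.values())
            name = {v: k for k, v in FEATURE_PRECEDENCE.items()}[best]
            gene_ids.append(";".join(sorted(per_gene)))
            gene_features.append(name)
    if unknown:
        log.warning("chromosomes absent from the GTF: %s", sorted(unknown))
    out["gene_id"] = gene_ids
    out["gene_feature"] = gene_features
    return out


def assign_tads(events: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Assign every event to the segment (TAD) it overlaps.

    An event overlapping several segments goes to the one with maximal
    overlap length, ties broken by the lexicographically smallest tad_id;
    events with no overlap keep an empty tad_id (retained in the table,
    excluded from TAD-level statistics).
    """
    trees: dict[str, IntervalTree] = {}
    for _, seg in segments.iterrows():
        trees.setdefault(seg["chrom"], IntervalTree()).addi(
            int(seg["start"]), int(seg["end"]), seg["tad_id"])
    seg_coords = segments.set_index("tad_id")[["start", "end"]]

    out = events.copy()
    tad_ids: list[str] = []
    for chrom, start, end in zip(out["chrom"], out["start"], out["end"]):
        tree = trees.get(chrom)
        best_id = ""
        if tree is not None:
            best_len = 0
            for iv in tree.overlap(int(start), int(end)):
                ov = min(iv.end, int(end)) - max(iv.begin, int(start))
                if ov > best_len or (ov == best_len and ov > 0 and iv.data < best_id):
                    best_len, best_id = ov, iv.data
        tad_ids.append(best_id)
    out["tad_id"] = tad_ids
    out["tad_start"] = [
        int(seg_coords.at[t, "start"]) if t else -1 for t in tad_ids]
    out["tad_end"] = [
        int(seg_coords.at[t, "end"]) if t else -1 for t in tad_ids]
    return out


def reverse_methylation(
    agg: AggregatedTable,
    sources: list[str],
    features: tuple[str, ...] = ("promoter", "intergenic"),
) -> AggregatedTable:
    """Invert methylation values (100 - v) for selected feature classes.

    Low methylation at a regulatory site usually means an accessible,
    active locus; inverting makes high values mean "active" across layers.
    Only rows from the named freq sources whose gene_feature is listed are
    touched.  Applying the operation twice restores the input.
    """
    for src in sources:
        if src not in agg.source_map:
            raise ValueError(f"unknown source {src!r}")
        if agg.source_map[src] != "freq":
            raise ValueError(f"source {src!r} is not a freq layer")
    mask = (
        agg.annotations["source"].isin(sources)
        & agg.annotations["gene_feature"].isin(features)
    ).to_numpy()
    values = agg.values.copy()
    values.iloc[mask] = 100.0 - values.iloc[mask]
    return AggregatedTable(agg.annotations.copy(), values, dict(agg.source_map))


# ---------------------------------------------------------------------------
# assembly


def build_aggregated_table(
    tables: list[OmicsTable],
    segments: pd.DataFrame,
    gtf: str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> AggregatedTable:
    """Scale, annotate and concatenate all layers into one table.

    Sample columns are harmonised per ``config.sample_mode``, counts are
    log-scaled onto [0, 100], freq layers clamped/rescaled, every event is
    annotated with gene context and TAD, and the layers are stacked.  When
    ``out_dir`` is given the integrated-table/integrated-tad-table/summary
    files are written there.
    """
    config = config or RunConfig()
    if not tables:
        raise ValueError("no omics tables")
    ids = pd.concat([t.events["event_id"] for t in tables])
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"event id {dup!r} appears in more than one layer")

    tables = harmonize_samples(tables, config.sample_mode)
    blocks: list[pd.DataFrame] = []
    values: list[pd.DataFrame] = []
    source_map: dict[str, str] = {}
    for t in tables:
        source_map[t.source] = t.kind
        scaled = (scale_counts(t.values) if t.kind == "count"
                  else scale_freq(t.values, config.beta_autoscale))
        ann = annotate_genes(t.events, gtf,
                             config.promoter_upstream, config.promoter_downstream)
        ann = assign_tads(ann, segments)
        ann["source"] = t.source
        blocks.append(ann)
        values.append(scaled)

    annotations = pd.concat(blocks, ignore_index=True)[ANNOTATION_COLUMNS]
    annotations.index = pd.Index(annotations["event_id"], name="event_id")
    matrix = pd.concat(values)
    matrix.index = annotations.index
    agg = AggregatedTable(annotations=annotations, values=matrix,
                          source_map=source_map)
    if out_dir is not None:
        agg.save(out_dir)
    return agg
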