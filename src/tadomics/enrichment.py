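"""Local functional analysis: gene-set over-representation, motif
enrichment by PWM scanning, and the per-TAD term hypergeometric.

All tests run offline against user-supplied GMT gene sets, JASPAR-format
position weight matrices and an indexed genome FASTA; no web service is
involved.  The over-representation statistic is the upper-tail
hypergeometric, motif enrichment is a per-motif one-sided Fisher exact
test on sequences with/without a hit, and both are BH-corrected across
terms/motifs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from pyfaidx import Fasta
from scipy import stats

from tadomics.aggregate import AggregatedTable, gene_models
from tadomics.evendiff import bh_adjust

log = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities (4 x width)."""

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = None  # type: ignore[assignment]
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("PWM matrix must be 4 x width with width >= 1")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: PWM columns must sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x width log2-odds matrix after pseudocount renormalisation."""
        padded = self.matrix + self.pseudocount
        padded = padded / padded.sum(axis=0, keepdims=True)
        return np.log2(padded / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())


def load_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file: term_id -> (term_name, gene set)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line with < 3 fields: {line[:60]!r}")
        term_id, term_name = parts[0], parts[1]
        genes = frozenset(g for g in parts[2:] if g)
        if term_id in sets:
            raise ValueError(f"{path}: duplicate term {term_id!r}")
        sets[term_id] = (term_name, genes)
    return sets


def load_jaspar_pwms(path: str | Path, pseudocount: float = 0.01) -> list[PWM]:
    """Read JASPAR-format PFMs and normalise counts to probabilities."""
    pwms: list[PWM] = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            probs = counts / counts.sum(axis=0, keepdims=True)
            name = m.matrix_id or m.name
            pwms.append(PWM(motif_id=name, matrix=probs, pseudocount=pseudocount))
    return pwms


# ---------------------------------------------------------------------------
# over-representation


def ora_test(
    query_genes: set[str], term_genes: set[str], universe_genes: set[str]
) -> float:
    """Upper-tail hypergeometric over-representation p-value.

    N = |universe|, K = |term in universe|, n = |query in universe|,
    k = |query in term in universe|.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query_genes) & universe
    term = set(term_genes) & universe
    k = len(query & term)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(term), len(query)))


def ora_table(
    query_genes: set[str],
    gene_sets: dict[str, tuple[str, frozenset[str]]],
    universe_genes: set[str],
) -> pd.DataFrame:
    """ORA over a whole gene-set collection, BH-corrected across terms."""
    rows = []
    universe = set(universe_genes)
    query = set(query_genes) & universe
    for term_id, (term_name, genes) in gene_sets.items():
        term = set(genes) & universe
        k = len(query & term)
        p = ora_test(query, term, universe)
        rows.append({
            "term_id": term_id, "term_name": term_name,
            "K_term": len(term), "n_query": len(query), "k_overlap": k,
            "p": p,
            "genes": ";".join(sorted(query & term)),
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["adj_p"] = bh_adjust(out["p"])
        out = out.sort_values(["p", "term_id"]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# sequence extraction


def merge_intervals(
    intervals: list[tuple[str, int, int, str]]
) -> list[tuple[str, int, int, list[str]]]:
    """Union of half-open intervals per chromosome, carrying member ids."""
    merged: list[tuple[str, int, int, list[str]]] = []
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, name in intervals:
        by_chrom.setdefault(chrom, []).append((int(start), int(end), name))
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e, members = spans[0][0], spans[0][1], [spans[0][2]]
        for s, e, name in spans[1:]:
            if s < cur_e:  # strict: touching intervals do not merge
                cur_e = max(cur_e, e)
                members.append(name)
            else:
                merged.append((chrom, cur_s, cur_e, members))
                cur_s, cur_e, members = s, e, [name]
        merged.append((chrom, cur_s, cur_e, members))
    return merged


def extract_sequences(
    agg: AggregatedTable,
    genome_fasta: str | Path,
    gtf: str | Path | None = None,
    event_ids: list[str] | None = None,
    flank: int = 50,
    promoter_upstream: int = 1000,
    promoter_downstream: int = 200,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Extract genomic sequences for motif scanning of selected events.

    Point events (freq layers) are extended by ``flank`` bases on each
    side; expression events are replaced by the promoter window
    [TSS - promoter_upstream, TSS + promoter_downstream) of their annotated
    gene, on its strand.  Overlapping extended intervals on one chromosome
    are merged; one record is emitted per merged interval with the
    constituent event ids.  Intervals beyond contig ends are truncated
    with a warning.  Writes ``seq_perTADs.fasta`` and
    ``prepared sequences info.csv`` when ``out_dir`` is given.
    """
    fasta = Fasta(str(genome_fasta))
    ann = agg.annotations
    if event_ids is not None:
        ann = ann.loc[ann.index.intersection(event_ids)]
    tss_map: dict[str, tuple[str, int, str]] = {}
    if gtf is not None:
        gm = gene_models(gtf)
        tss_map = {
            r["gene_id"]: (r["chrom"], int(r["tss"]), r["strand"])
            for _, r in gm.iterrows()
        }

    intervals: list[tuple[str, int, int, str]] = []
    for event_id, row in ann.iterrows():
        kind = agg.source_map.get(row["source"], "freq")
        if kind == "count" and row["gene_id"]:
            gene = row["gene_id"].split(";")[0]
            if gene in tss_map:
                chrom, tss, strand = tss_map[gene]
                if strand == "-":
                    start, end = tss - promoter_downstream + 1, tss + promoter_upstream + 1
                else:
                    start, end = tss - promoter_upstream, tss + promoter_downstream
                intervals.append((chrom, start, end, event_id))
                continue
        intervals.append(
            (row["chrom"], int(row["start"]) - flank,
             int(row["end"]) + flank, event_id))

    records = []
    for chrom, start, end, members in merge_intervals(intervals):
        if chrom not in fasta:
            log.warning("chromosome %s absent from the genome FASTA", chrom)
            continue
        contig_len = len(fasta[chrom])
        t_start, t_end = max(0, start), min(end, contig_len)
        if (t_start, t_end) != (start, end):
            log.warning("interval %s:%d-%d truncated to contig bounds",
                        chrom, start, end)
        if t_end <= t_start:
            continue
        seq = fasta[chrom][t_start:t_end].seq.upper()
        rec_id = f"{chrom}:{t_start}-{t_end}"
        records.append({
            "record_id": rec_id, "chrom": chrom, "start": t_start,
            "end": t_end, "sequence": seq,
            "event_ids": ";".join(members),
        })
    out = pd.DataFrame(records)
    if out_dir is not None and not out.empty:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "seq_perTADs.fasta", "w") as fh:
            for _, rec in out.iterrows():
                fh.write(f">{rec['record_id']}\n{rec['sequence']}\n")
        out.drop(columns=["sequence"]).to_csv(
            out_dir / "prepared sequences info.csv", index=False)
    return out


# ---------------------------------------------------------------------------
# motif scanning


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _window_scores(seq: str, lod: np.ndarray) -> np.ndarray:
    """Log-odds score at every window start; NaN where a window contains N."""
    width = lod.shape[1]
    if len(seq) < width:
        return np.array([])
    idx = np.array([_BASE_INDEX.get(b, -1) for b in seq])
    n_win = len(seq) - width + 1
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for j in range(width):
        col = idx[j:j + n_win]
        bad = col < 0
        valid &= ~bad
        scores += np.where(bad, 0.0, lod[np.clip(col, 0, 3), j])
    return np.where(valid, scores, np.nan)


def pwm_scan(
    sequence: str, pwm: PWM, threshold: float | None = None
) -> tuple[float, list[tuple[int, str]]]:
    """Best log2-odds score of a PWM over both strands of a sequence.

    Returns ``(max_score, hits)`` where hits are (position, strand) pairs
    with score >= threshold.  Windows containing N are skipped; a sequence
    shorter than the motif yields ``(nan, [])``.
    """
    seq = sequence.upper()
    lod = pwm.log_odds()
    if len(seq) < pwm.width:
        log.warning("sequence shorter than motif %s; no score", pwm.motif_id)
        return float("nan"), []
    fwd = _window_scores(seq, lod)
    rev = _window_scores(seq.translate(_COMPLEMENT)[::-1], lod)
    # map reverse-strand window i back to forward coordinates
    rev = rev[::-1]
    best = np.nanmax(np.concatenate([fwd, rev])) if (
        np.isfinite(fwd).any() or np.isfinite(rev).any()) else float("nan")
    hits: list[tuple[int, str]] = []
    if threshold is not None:
        for i, s in enumerate(fwd):
            if np.isfinite(s) and s >= threshold:
                hits.append((i, "+"))
        for i, s in enumerate(rev):
            if np.isfinite(s) and s >= threshold:
                hits.append((i, "-"))
    return float(best), hits


def motif_enrichment(
    fg_seqs: list[str],
    bg_seqs: list[str],
    pwms: list[PWM],
    hit_fraction: float = 0.8,
) -> pd.DataFrame:
    """Per-motif one-sided Fisher exact enrichment of foreground sequences.

    A sequence counts as a hit when its best log-odds score reaches
    ``hit_fraction`` of the motif's maximum achievable score.  The 2x2
    table (hit / no hit x foreground / background) is tested one-sided
    for foreground enrichment; BH correction across motifs.
    """
    if not fg_seqs or not bg_seqs:
        raise ValueError("need at least one foreground and one background sequence")
    rows = []
    for pwm in pwms:
        threshold = hit_fraction * pwm.max_score()
        fg_hits = sum(
            1 for s in fg_seqs
            if (sc := pwm_scan(s, pwm)[0]) == sc and sc >= threshold)
        bg_hits = sum(
            1 for s in bg_seqs
            if (sc := pwm_scan(s, pwm)[0]) == sc and sc >= threshold)
        table = [[fg_hits, len(fg_seqs) - fg_hits],
                 [bg_hits, len(bg_seqs) - bg_hits]]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append({
            "motif_id": pwm.motif_id, "fg_hits": fg_hits,
            "fg_total": len(fg_seqs), "bg_hits": bg_hits,
            "bg_total": len(bg_seqs), "threshold": threshold, "p": float(p),
        })
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p"])
    return out.sort_values(["p", "motif_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# per-TAD term significance


def _split_genes(gene_id: str) -> list[str]:
    return [g for g in str(gene_id).split(";") if g]


def per_tad_term_test(
    enriched_terms: pd.DataFrame,
    agg: AggregatedTable,
    gene_sets: dict[str, tuple[str, frozenset[str]]],
    out_dir: str | Path | None = None,
    label: str = "terms",
) -> pd.DataFrame:
    """Hypergeometric significance of each TAD for each enriched term.

    The universe is the set of genes present in the aggregated table.  For
    a term with K genes in the universe and a TAD containing n universe
    genes, of which k belong to the term, p = P(X >= k) upper-tail; BH is
    applied within each term across TADs.  Writes the two grouped CSV
    views when ``out_dir`` is given.
    """
    ann = agg.annotations
    gene_tads: dict[str, set[str]] = {}
    for gid, tad in zip(ann["gene_id"], ann["tad_id"]):
        for g in _split_genes(gid):
            gene_tads.setdefault(g, set())
            if tad:
                gene_tads[g].add(tad)
    universe = set(gene_tads)
    if not universe:
        raise ValueError("no annotated genes in the aggregated table")
    tad_genes: dict[str, set[str]] = {}
    for g, tads in gene_tads.items():
        for t in tads:
            tad_genes.setdefault(t, set()).add(g)

    rows = []
    for term_id in enriched_terms["term_id"]:
        term_name, genes = gene_sets[term_id]
        term = set(genes) & universe
        for tad_id, genes_in_tad in sorted(tad_genes.items()):
            k = len(term & genes_in_tad)
            p = float(stats.hypergeom.sf(
                k - 1, len(universe), len(term), len(genes_in_tad)))
            rows.append({
                "term_id": term_id, "term_name": term_name, "tad_id": tad_id,
                "k_term_tad": k, "n_tad_genes": len(genes_in_tad),
                "K_term": len(term), "N_universe": len(universe), "p": p,
            })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["adj_p"] = np.nan
        for term_id, grp in out.groupby("term_id"):
            out.loc[grp.index, "adj_p"] = bh_adjust(grp["p"])
    if out_dir is not None and not out.empty:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        by_tad = out.sort_values(["tad_id", "p", "term_id"])
        by_tad.to_csv(out_dir / f"over-represented enriched {label}.csv",
                      index=False)
        by_term = out.sort_values(["term_id", "p", "tad_id"])
        by_term.to_csv(out_dir / f"enriched {label} in different TADs.csv",
                       index=False)
    return out
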