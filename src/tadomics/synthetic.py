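"""Synthetic multi-omics bundles with known planted truth.

The generator emulates the structure of a two-layer same-sample study —
one DNA-methylation frequency table (450K-like beta values x100) and one
RNA-seq count table — with events clustered inside non-overlapping TADs
on the autosomes, a toy gene annotation, and a binary sample contrast.
A chosen subset of TADs carries a planted between-group shift of a given
size on the common [0, 100] scale, inverted in sign for methylation to
mimic the usual inverse coupling between promoter methylation and
expression.  Everything is reproducible from a single seed.

Distributional choices (documented test scaffolding, not fitted to any
dataset): methylation betas per event from a bimodal Beta(2,5)/Beta(5,2)
mixture with per-sample Beta noise of heterogeneous precision; expression
counts negative binomial with dispersion 0.2 around log-normal per-event
means.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: ln(1 + c) span assumed when converting a [0,100]-scale shift into a
#: count multiplier; matches the typical column maximum of the generated
#: count layer so a planted shift of `effect` lands near `effect` after
#: log-scaling.
LOG_COUNT_SPAN = 10.0

# per-event methylation noise: variances from a scaled inverse chi-square
# prior so the empirical-Bayes model downstream is well specified
METH_VAR_PRIOR_DF = 10.0
METH_VAR_PRIOR_SCALE = 36.0  # units^2 on the 0-100 scale (sd ~ 6)

NB_DISPERSION = 0.2


@dataclass
class SyntheticTruth:
    """What was planted: which TADs/events carry the group shift."""

    planted_tads: list[str]
    planted_events: list[str]
    effect: float
    n_samples_per_group: int
    seed: int

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _layout_tads(rng: np.random.Generator, n_tads: int) -> pd.DataFrame:
    """Non-overlapping domains of 0.2-1.5 Mb cycled across chr1-chr22."""
    chroms = [f"chr{i}" for i in range(1, 23)]
    cursors = {c: 100_000 for c in chroms}
    rows = []
    for i in range(n_tads):
        chrom = chroms[i % len(chroms)]
        length = int(rng.integers(200_000, 1_500_000))
        gap = int(rng.integers(10_000, 100_000))
        start = cursors[chrom]
        end = start + length
        cursors[chrom] = end + gap
        rows.append({"tad_id": f"TAD{i:04d}", "chrom": chrom,
                     "start": start, "end": end})
    return pd.DataFrame(rows)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_bundle(
    out_dir: str | Path,
    n_tads: int = 200,
    events_per_tad: int = 20,
    expr_fraction: float = 0.25,
    n_samples: int = 20,
    n_planted_tads: int = 0,
    effect: float = 0.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Write a complete input bundle and return the planted truth.

    Produces ``freq/methylation.tsv``, ``counts/expression.tsv``,
    ``tads.bed``, ``genes.gtf``, ``meta.tsv`` and ``truth.json`` under
    ``out_dir``.  ``n_samples`` is per group (two groups).  The first
    ``n_planted_tads`` TADs receive a group-1 mean shift of ``effect``
    scale units on every event (negative for methylation).
    """
    if min(n_tads, events_per_tad, n_samples) <= 0 or effect < 0:
        raise ValueError("arguments must be positive and effect >= 0")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    (out_dir / "freq").mkdir(parents=True, exist_ok=True)
    (out_dir / "counts").mkdir(parents=True, exist_ok=True)

    tads = _layout_tads(rng, n_tads)
    planted = set(tads["tad_id"].iloc[:n_planted_tads])

    samples = [f"S{i:03d}" for i in range(2 * n_samples)]
    group = np.array([0] * n_samples + [1] * n_samples)

    n_expr = max(1, round(events_per_tad * expr_fraction))
    n_meth = events_per_tad - n_expr
    n_genes = max(1, events_per_tad // 3)

    gtf_lines: list[str] = []
    meth_rows: list[list] = []
    expr_rows: list[list] = []
    planted_events: list[str] = []
    cg_i = t_i = g_i = 0

    for _, tad in tads.iterrows():
        chrom, t_start, t_end = tad["chrom"], int(tad["start"]), int(tad["end"])
        tad_planted = tad["tad_id"] in planted
        span = t_end - t_start

        # toy genes tiling the domain, 2 exons each
        genes = []
        slot = span // n_genes
        for j in range(n_genes):
            g_start = t_start + j * slot + slot // 4
            g_len = min(max(5_000, slot // 3), 50_000)
            g_end = g_start + g_len
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{g_i:05d}"
            g_i += 1
            genes.append((gid, g_start, g_end, strand))
            attr = f'gene_id "{gid}"; transcript_id "{gid}.t1";'
            exon1 = (g_start, g_start + g_len // 3)
            exon2 = (g_end - g_len // 3, g_end)
            gtf_lines.append("\t".join(map(str, [
                chrom, "toy", "transcript", g_start + 1, g_end, ".",
                strand, ".", attr])))
            for es, ee in (exon1, exon2):
                gtf_lines.append("\t".join(map(str, [
                    chrom, "toy", "exon", es + 1, ee, ".", strand, ".", attr])))

        # expression events: one per gene, cycling
        for j in range(n_expr):
            gid, g_start, g_end, strand = genes[j % len(genes)]
            eid = f"t_{t_i:06d}"
            t_i += 1
            log_mu = rng.normal(4.0, 1.5)
            mu = np.full(2 * n_samples, np.exp(log_mu))
            if tad_planted and effect > 0:
                mu[group == 1] *= np.exp(effect * LOG_COUNT_SPAN / 100.0)
                planted_events.append(eid)
            counts = _nb_counts(rng, mu, NB_DISPERSION)
            expr_rows.append([eid, chrom, g_start, g_end] + counts.tolist())

        # methylation events: random positions within the domain
        for _ in range(n_meth):
            pos = int(rng.integers(t_start, t_end - 2))
            eid = f"cg{cg_i:06d}"
            cg_i += 1
            base = (rng.beta(2, 5) if rng.random() < 0.5 else rng.beta(5, 2))
            base = float(np.clip(base, 0.05, 0.95))
            mean_b = np.full(2 * n_samples, base)
            if tad_planted and effect > 0:
                shifted = np.clip(base - effect / 100.0, 0.02, 0.98)
                mean_b[group == 1] = shifted
                planted_events.append(eid)
            # per-event precision from the inverse chi-square variance prior
            var_units = (METH_VAR_PRIOR_SCALE * METH_VAR_PRIOR_DF
                         / rng.chisquare(METH_VAR_PRIOR_DF))
            var_beta = min(var_units / 100.0**2,
                           0.9 * np.min(mean_b * (1 - mean_b)))
            kappa = np.min(mean_b * (1 - mean_b)) / var_beta - 1.0
            betas = rng.beta(mean_b * kappa, (1 - mean_b) * kappa)
            vals = np.round(betas * 100.0, 4)
            meth_rows.append([eid, chrom, pos, pos + 2] + vals.tolist())

    header = ["event_id", "chrom", "start", "end"] + samples
    pd.DataFrame(meth_rows, columns=header).to_csv(
        out_dir / "freq" / "methylation.tsv", sep="\t", index=False)
    pd.DataFrame(expr_rows, columns=header).to_csv(
        out_dir / "counts" / "expression.tsv", sep="\t", index=False)
    tads[["chrom", "start", "end", "tad_id"]].to_csv(
        out_dir / "tads.bed", sep="\t", header=False, index=False)
    (out_dir / "genes.gtf").write_text("\n".join(gtf_lines) + "\n")
    meta = pd.DataFrame({"sample_id": samples, "group": group})
    meta.to_csv(out_dir / "meta.tsv", sep="\t", index=False)

    truth = SyntheticTruth(
        planted_tads=sorted(planted),
        planted_events=sorted(planted_events),
        effect=float(effect),
        n_samples_per_group=int(n_samples),
        seed=int(seed),
    )
    truth.save(out_dir / "truth.json")
    return truth


def score_recovery(
    truth: SyntheticTruth, tad_stats: pd.DataFrame
) -> tuple[float, int]:
    """(sensitivity, number of false TAD calls) against the planted truth."""
    called = set(tad_stats.loc[tad_stats["significant"], "tad_id"])
    planted = set(truth.planted_tads)
    if not planted:
        return 0.0, len(called)
    sensitivity = len(called & planted) / len(planted)
    return sensitivity, len(called - planted)
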