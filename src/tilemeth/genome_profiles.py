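"""Chromosome-scale and gene-scale methylation profiles.

Three views of the per-probe methylation signal: percent-methylated in
sliding windows along each chromosome (pericentromeric enrichment), metagene
profiles that map probes into a common upstream/body/downstream coordinate
system per gene class, and the CpG-dinucleotide density profile over the same
binning (gene-body methylation tracks CpG density inside genes but not in the
flanks).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segment_em import em_fit, posterior
from .synthetic_data import GeneModelSet, SyntheticGenome


def classify_probe_methylation(values: np.ndarray, threshold: float = 0.5,
                               seed: int = 0) -> np.ndarray:
    """Call each probe methylated from its log2(IP/input) value.

    The per-probe signal is bimodal (methylated vs unmethylated, with an
    intermediate shoulder); a 3-component Gaussian mixture is fit by EM and a
    probe is methylated when the total posterior of the components on the
    methylated side (means above the midpoint of the extreme component
    means) exceeds ``threshold``. Summing sides rather than taking only the
    top component keeps the call stable when two components share a mode.
    """
    x = np.asarray(values, dtype=float)
    model = em_fit(x, K=3, seed=seed)
    post = posterior(x, model)
    midpoint = (model.means[0] + model.means[-1]) / 2.0
    high_side = model.means > midpoint
    return post[:, high_side].sum(axis=1) > threshold


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

def window_methylation(probe_states: np.ndarray, probe_map: pd.DataFrame,
                       chrom_lengths: dict[str, int] | None = None,
                       window: int = 5_000_000, step: int = 1_000_000
                       ) -> pd.DataFrame:
    """Percent methylated probes in sliding windows per chromosome.

    Windows are anchored at the chromosome start and step by ``step``; the
    last partial window is retained. Windows containing no probes are flagged
    missing (NaN percent).
    """
    if step > window:
        import warnings
        warnings.warn("step exceeds window; windows will not overlap",
                      stacklevel=2)
    states = np.asarray(probe_states, dtype=bool)
    mid = (probe_map["start"].to_numpy() + probe_map["end"].to_numpy() - 1) / 2.0
    rows = []
    for chrom, sub_idx in probe_map.groupby("chrom").indices.items():
        m = mid[sub_idx]
        s = states[sub_idx]
        if chrom_lengths and chrom in chrom_lengths:
            chrom_end = chrom_lengths[chrom]
        else:
            chrom_end = int(probe_map["end"].to_numpy()[sub_idx].max())
        start = 0
        while start < chrom_end:
            end = min(start + window, chrom_end)
            inside = (m >= start) & (m < end)
            n = int(inside.sum())
            pct = 100.0 * s[inside].sum() / n if n else np.nan
            rows.append((chrom, start, end, pct, n))
            if start + window >= chrom_end:
                break
            start += step
    return pd.DataFrame(rows, columns=["chrom", "window_start", "window_end",
                                       "percent_methylated", "n_probes"])


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

def _metagene_bin(d_tss: float, d_tts: float, inside: bool, body_pos: float,
                  flank: int, n_bins: int) -> int | None:
    """Map a probe-gene geometry to a bin in [0, 3*n_bins)."""
    if inside:
        b = int(body_pos / 1000.0 * n_bins)
        return n_bins + min(b, n_bins - 1)
    if -flank <= d_tss < 0:
        b = int((d_tss + flank) / flank * n_bins)
        return min(b, n_bins - 1)
    if 0 < d_tts <= flank:
        b = int((d_tts - 1e-9) / flank * n_bins)
        return 2 * n_bins + min(b, n_bins - 1)
    return None


def metagene_profile(values: pd.Series, probe_map: pd.DataFrame,
                     genes: GeneModelSet, class_column: str = "gene_class",
                     flank: int = 1_000, n_bins: int = 20) -> pd.DataFrame:
    """Mean probe value per metagene bin, per gene class.

    Probe midpoints within ``flank`` of a gene (or inside it) map to 3*n_bins
    bins: upstream flank, gene body normalized to a 0-1000 scale, downstream
    flank, all oriented along the transcription strand. Every qualifying
    probe-gene pair contributes once; ``values`` is indexed by probe_id (for
    instance the b73_meth column of the estimates table).

    ``class_column`` may be any gene attribute (gene_class, expression,
    syntenic, subgenome) — each distinct value becomes one profile.
    """
    g = genes.genes
    if not len(g):
        raise ValueError("no gene models supplied")
    mid_all = (probe_map["start"].to_numpy()
               + probe_map["end"].to_numpy() - 1) / 2.0
    val = values.reindex(probe_map["probe_id"]).to_numpy(dtype=float)

    acc: dict[tuple[str, int], list[float]] = {}
    skipped = 0
    for row in g.itertuples(index=False):
        tss, tts = ((row.start, row.end - 1) if row.strand == "+"
                    else (row.end - 1, row.start))
        span = tts - tss if row.strand == "+" else tss - tts
        if span <= 0:
            skipped += 1
            continue
        cls = str(getattr(row, class_column))
        sel = np.flatnonzero(
            (probe_map["chrom"].to_numpy() == row.chrom)
            & (mid_all >= min(row.start, row.end) - flank)
            & (mid_all < max(row.start, row.end) + flank))
        for i in sel:
            mid = mid_all[i]
            if row.strand == "+":
                d_tss, d_tts = mid - tss, mid - tts
            else:
                d_tss, d_tts = tss - mid, tts - mid
            inside = row.start <= mid < row.end
            body_pos = 1000.0 * d_tss / span if inside else np.nan
            b = _metagene_bin(d_tss, d_tts, inside, body_pos, flank, n_bins)
            if b is not None and np.isfinite(val[i]):
                acc.setdefault((cls, b), []).append(val[i])
    if skipped:
        import warnings
        warnings.warn(f"skipped {skipped} gene(s) with degenerate span",
                      stacklevel=2)
    regions = (["upstream"] * n_bins + ["body"] * n_bins
               + ["downstream"] * n_bins)
    rows = []
    for cls in sorted({c for c, _ in acc}):
        for b in range(3 * n_bins):
            vals = acc.get((cls, b), [])
            rows.append((cls, b, regions[b],
                         float(np.mean(vals)) if vals else np.nan, len(vals)))
    return pd.DataFrame(rows, columns=["gene_class", "bin", "region",
                                       "mean_value", "n_probes"])


# ---------------------------------------------------------------------------
# CpG density
# ---------------------------------------------------------------------------

def _cpg_fraction(seq: str) -> float:
    if len(seq) < 2:
        return 0.0
    return seq.count("CG") / (len(seq) - 1)


def cpg_profile(genome: SyntheticGenome, genes: GeneModelSet,
                flank: int = 1_000, n_bins: int = 20) -> pd.DataFrame:
    """Per-bin CpG dinucleotide proportion, averaged over genes.

    Uses the same upstream/body/downstream binning as the metagene profile,
    computed on the transcription strand.
    """
    from .probe_annotation import reverse_complement

    sums = np.zeros(3 * n_bins)
    counts = np.zeros(3 * n_bins, dtype=int)
    for row in genes.genes.itertuples(index=False):
        chrom_seq = genome.sequence[row.chrom]
        lo = max(0, row.start - flank)
        hi = min(len(chrom_seq), row.end + flank)
        up = chrom_seq[lo:row.start]
        body = chrom_seq[row.start:row.end]
        down = chrom_seq[row.end:hi]
        if row.strand == "-":
            up, down = reverse_complement(down), reverse_complement(up)
            body = reverse_complement(body)
        for region_idx, seq in enumerate((up, body, down)):
            if len(seq) < 2:
                continue
            edges = np.linspace(0, len(seq), n_bins + 1).astype(int)
            for b in range(n_bins):
                chunk = seq[edges[b]:edges[b + 1]]
                if len(chunk) >= 2:
                    sums[region_idx * n_bins + b] += _cpg_fraction(chunk)
                    counts[region_idx * n_bins + b] += 1
    regions = (["upstream"] * n_bins + ["body"] * n_bins
               + ["downstream"] * n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"bin": np.arange(3 * n_bins), "region": regions,
                         "cpg_proportion": mean, "n_genes": counts})
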