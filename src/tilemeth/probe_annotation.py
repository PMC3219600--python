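"""Probe copy-number annotation, the probe filter cascade, and gene context.

The array targets the repeat-masked genome, but masking leaves multi-copy
sequence behind, and probe copy number inflates apparent methylation; the
genome-wide analyses therefore restrict to single-copy probes. This module
counts perfect (exact, both strands) and close (>=90% identity over >=90% of
the probe) genomic matches per probe, applies the documented probe filters in
order (chr9 density thinning, uniqueness, CGH floor), and assigns each probe
a gene context (exon/intron/UTR/intergenic with strand-oriented distances to
the transcription start and termination sites).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .synthetic_data import GeneModelSet, SyntheticGenome

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# match counting
# ---------------------------------------------------------------------------

def _exact_positions(seq: str, probe: str) -> list[int]:
    out, i = [], seq.find(probe)
    while i != -1:
        out.append(i)
        i = seq.find(probe, i + 1)
    return out


def _close_positions(seq: str, probe: str, max_edits: int,
                     kmer_index: dict[str, list[int]], k: int) -> set[int]:
    """Start positions with a fixed-start alignment within ``max_edits``.

    Candidate positions come from exact k-mer seeds (pigeonhole: a hit with
    <= max_edits edits contains an exact k-mer when len(probe) >= k *
    (max_edits + 1)); each candidate is verified with a prefix-mode edit
    distance (query consumed fully, target end free).
    """
    m = len(probe)
    candidates: set[int] = set()
    for off in range(0, m - k + 1):
        for gpos in kmer_index.get(probe[off:off + k], ()):
            p0 = gpos - off
            for p in range(p0 - max_edits, p0 + max_edits + 1):
                if 0 <= p <= len(seq) - (m - max_edits):
                    candidates.add(p)
    hits = set()
    for p in candidates:
        window = seq[p:p + m + max_edits]
        res = edlib.align(probe, window, mode="SHW", k=max_edits)
        if res["editDistance"] != -1:
            hits.add(p)
    return hits


def _cluster_count(positions: set[int], min_gap: int) -> int:
    """Number of distinct loci: maximal runs of nearby start positions."""
    if not positions:
        return 0
    pos = sorted(positions)
    return 1 + sum(1 for a, b in zip(pos[:-1], pos[1:]) if b - a > min_gap)


def count_matches(probe_sequences: dict[str, str] | pd.Series,
                  genome: SyntheticGenome,
                  identity_threshold: float = 0.90) -> pd.DataFrame:
    """Perfect and close match counts per probe over both genome strands.

    Perfect = exact substring occurrences. Close = distinct loci aligning
    with at most floor((1 - identity_threshold) * len) edits (fixed start,
    free end), counted after clustering nearby starts, minus the perfect
    loci. Probes with ambiguous bases are rejected.
    """
    if isinstance(probe_sequences, pd.Series):
        probe_sequences = probe_sequences.to_dict()
    for pid, s in probe_sequences.items():
        if len(s) < 20:
            raise ValueError(f"probe {pid} shorter than 20 nt")
        if set(s) - set("ACGT"):
            raise ValueError(f"ambiguous bases in probe {pid}")

    lengths = {len(s) for s in probe_sequences.values()}
    max_edits_global = max(int((1 - identity_threshold) * ln) for ln in lengths)
    min_len = min(lengths)
    k = max(8, min_len // (max_edits_global + 1))
    k = min(k, 12)

    strands: list[str] = []
    for name, _ in genome.chromosomes:
        strands.append(genome.sequence[name])
        strands.append(reverse_complement(genome.sequence[name]))

    kmer_indexes = []
    for seq in strands:
        idx: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            idx.setdefault(seq[i:i + k], []).append(i)
        kmer_indexes.append(idx)

    rows = []
    for pid, probe in probe_sequences.items():
        max_edits = int((1 - identity_threshold) * len(probe))
        perfect = 0
        close_loci = 0
        for seq, idx in zip(strands, kmer_indexes):
            exact = set(_exact_positions(seq, probe))
            perfect += _cluster_count(exact, len(probe) // 2)
            hits = _close_positions(seq, probe, max_edits, idx, k)
            nonexact = {p for p in hits
                        if min((abs(p - q) for q in exact), default=10**9)
                        > max_edits}
            close_loci += _cluster_count(nonexact, len(probe) // 2)
        rows.append((pid, perfect, close_loci))
    return pd.DataFrame(rows, columns=["probe_id", "perfect_match_count",
                                       "close_match_count"])


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

@dataclass
class FilterOptions:
    filters: tuple[str, ...] = ("chr9_thinning", "unique", "cgh")
    chr9_keep_every: int = 3
    unique_definition: str = "perfect_and_no_close"  # or "perfect_only"
    cgh_floor: float = -1.0


def apply_probe_filters(probe_map: pd.DataFrame, estimates: pd.DataFrame,
                        options: FilterOptions | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the probe filters in their documented order.

    1. chr9 thinning: keep every third chr9 probe (first, fourth, ...) so the
       dense chromosome matches the genome-wide spacing;
    2. unique: single perfect match (and, by default, no close matches);
    3. CGH floor: keep probes with cgh strictly greater than -1 (drops
       PAV / copy-loss probes whose Mo17 signal is unreliable).

    Returns the surviving probe_map rows and a provenance frame recording
    which filter removed each dropped probe.
    """
    options = options or FilterOptions()
    known = {"chr9_thinning", "unique", "cgh"}
    unknown = set(options.filters) - known
    if unknown:
        raise ValueError(f"unknown filter name(s): {sorted(unknown)}")
    current = probe_map.copy()
    removed = []

    est = estimates.set_index("probe_id") if "probe_id" in estimates else estimates
    for name in options.filters:
        if name == "chr9_thinning":
            is9 = (current["chrom"] == "chr9").to_numpy()
            ord9 = np.cumsum(is9) - 1
            keep = ~is9 | (ord9 % options.chr9_keep_every == 0)
        elif name == "unique":
            keep = (current["perfect_match_count"] == 1).to_numpy()
            if options.unique_definition == "perfect_and_no_close":
                keep &= (current["close_match_count"] == 0).to_numpy()
            elif options.unique_definition != "perfect_only":
                raise ValueError(
                    f"unknown unique_definition: {options.unique_definition!r}")
        elif name == "cgh":
            cgh = est.loc[current["probe_id"], "cgh"].to_numpy()
            keep = cgh > options.cgh_floor
        dropped = current.loc[~keep, "probe_id"]
        removed.append(pd.DataFrame({"probe_id": dropped, "filter": name}))
        current = current.loc[keep]
    provenance = (pd.concat(removed, ignore_index=True) if removed
                  else pd.DataFrame(columns=["probe_id", "filter"]))
    return current.reset_index(drop=True), provenance


# ---------------------------------------------------------------------------
# gene context
# ---------------------------------------------------------------------------

_CLASS_PRIORITY = {"FGS": 0}


def annotate_probe_context(probe_map: pd.DataFrame, genes: GeneModelSet,
                           flank: int = 1_000) -> pd.DataFrame:
    """Assign each probe a feature class and gene with oriented distances.

    The probe midpoint decides everything. A probe is assigned to the gene
    containing its midpoint, otherwise to the nearest gene whose TSS or TTS
    lies within ``flank`` bp; ties go to the smallest |TSS distance|, then
    FGS over rejected, then lexicographic gene id. Distances are oriented
    along the transcription strand (upstream of the TSS is negative).
    """
    g = genes.genes
    exons_by_gene = {gid: list(zip(sub["start"], sub["end"]))
                     for gid, sub in genes.exons.groupby("gene_id")}
    rows = []
    mid_all = (probe_map["start"].to_numpy()
               + probe_map["end"].to_numpy() - 1) / 2.0
    for (pid, chrom), mid in zip(
            probe_map[["probe_id", "chrom"]].itertuples(index=False), mid_all):
        sub = g[g["chrom"] == chrom]
        best = None  # (|d_tss|, class_priority, gene_id, row, d_tss, d_tts, inside)
        for row in sub.itertuples(index=False):
            if row.strand == "+":
                d_tss = mid - row.start
                d_tts = mid - (row.end - 1)
            else:
                d_tss = (row.end - 1) - mid
                d_tts = row.start - mid
            inside = row.start <= mid < row.end
            if inside or abs(d_tss) <= flank or abs(d_tts) <= flank:
                key = (0 if inside else 1, abs(d_tss),
                       _CLASS_PRIORITY.get(row.gene_class, 1), row.gene_id)
                if best is None or key < best[0]:
                    best = (key, row, d_tss, d_tts, inside)
        if best is None:
            rows.append((pid, "intergenic", None, np.nan, np.nan))
            continue
        _, row, d_tss, d_tts, inside = best
        if not inside:
            feature = "intergenic"
        else:
            in_exon = any(s <= mid < e
                          for s, e in exons_by_gene.get(row.gene_id, ()))
            if in_exon:
                in_cds = row.cds_start <= mid < row.cds_end
                feature = "exon" if in_cds else "UTR"
            else:
                feature = "intron"
        rows.append((pid, feature, row.gene_id, d_tss, d_tts))
    return pd.DataFrame(rows, columns=["probe_id", "feature", "gene_id",
                                       "distance_to_TSS", "distance_to_TTS"])
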