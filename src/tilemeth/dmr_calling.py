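"""Differential-methylation calls, DMR segments, and the IBD epiallele screen.

Two complementary routes discover methylation differences between the
inbreds: per-probe calls (q < 0.001 on the differential-methylation
contrast; sensitive to small regions) and segment calls (CBS segments of the
differential signal classified by a 3-component mixture; >= 3 probes, high
confidence). DMRs falling inside identical-by-descent (IBD) blocks — long
intervals with no structural variation and a >= 25-fold SNP depletion — are
candidate pure epialleles: methylation differences with no nearby genetic
difference to blame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .segment_em import Segment
from .synthetic_data import GeneModelSet


# ---------------------------------------------------------------------------
# probe-level calls
# ---------------------------------------------------------------------------

def call_variable_probes(estimates: pd.DataFrame,
                         q_threshold: float = 0.001) -> pd.DataFrame:
    """Probes with q strictly below threshold on the diff_meth contrast.

    Direction follows the sign of diff_meth (positive = B73 hypermethylated);
    an exactly-zero significant difference is flagged with direction
    ``unclassified``.
    """
    sig = estimates["q_diff_meth"].to_numpy() < q_threshold
    out = estimates.loc[sig, ["probe_id", "diff_meth", "q_diff_meth"]].copy()
    d = out["diff_meth"].to_numpy()
    out["direction"] = np.where(d > 0, "B73_hyper",
                                np.where(d < 0, "Mo17_hyper", "unclassified"))
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# segment-level DMRs
# ---------------------------------------------------------------------------

def call_dmr_segments(segments: list[Segment], probe_map: pd.DataFrame,
                      estimates: pd.DataFrame,
                      genes: GeneModelSet | None = None,
                      min_probes: int = 3,
                      probe_q_threshold: float = 0.0001,
                      gene_distance: int = 500,
                      ibd_intervals: pd.DataFrame | None = None
                      ) -> pd.DataFrame:
    """Turn classified segments into DMR records.

    DMRs are segments labeled in an extreme mixture component (class3 = B73
    hypermethylated, class1 = Mo17 hypermethylated) spanning at least
    ``min_probes`` probes. Each record carries the fraction of member probes
    independently significant at the stricter per-probe cutoff
    (q < ``probe_q_threshold``), overlapping gene ids, a within-500bp-of-FGS
    flag, and an IBD flag.

    ``segments`` must index into ``probe_map`` row order (the segmentation is
    run on estimates aligned to the probe map).
    """
    est = estimates.set_index("probe_id")
    q = est["q_diff_meth"].reindex(probe_map["probe_id"]).to_numpy()
    rows = []
    for k, seg in enumerate(segments):
        if seg.label not in ("class1", "class3") or seg.n_probes < min_probes:
            continue
        sub = probe_map.iloc[seg.start:seg.end]
        chrom = sub["chrom"].iloc[0]
        start = int(sub["start"].iloc[0])
        end = int(sub["end"].iloc[-1])
        direction = "B73_hyper" if seg.label == "class3" else "Mo17_hyper"
        qs = q[seg.start:seg.end]
        frac_sig = float(np.mean(qs < probe_q_threshold))
        fgs_ids: list[str] = []
        wgs_ids: list[str] = []
        near_fgs = False
        if genes is not None:
            g = genes.genes
            sub_g = g[g["chrom"] == chrom]
            overlap = sub_g[(sub_g["start"] < end) & (sub_g["end"] > start)]
            wgs_ids = sorted(overlap["gene_id"])
            fgs_ids = sorted(overlap.loc[overlap["gene_class"] == "FGS",
                                         "gene_id"])
            fgs = sub_g[sub_g["gene_class"] == "FGS"]
            near_fgs = bool(((fgs["start"] < end + gene_distance)
                             & (fgs["end"] > start - gene_distance)).any())
        ibd_flag = False
        if ibd_intervals is not None and len(ibd_intervals):
            ib = ibd_intervals[ibd_intervals["chrom"] == chrom]
            ibd_flag = bool(((ib["start"] < end) & (ib["end"] > start)).any())
        rows.append({"seg_index": k, "chrom": chrom, "start": start,
                     "end": end, "n_probes": seg.n_probes,
                     "seg_mean": seg.mean, "direction": direction,
                     "posterior": float(np.max(seg.posterior))
                     if seg.posterior is not None else np.nan,
                     "fraction_probes_q_significant": frac_sig,
                     "fgs_gene_ids": ",".join(fgs_ids),
                     "wgs_gene_ids": ",".join(wgs_ids),
                     "within_500bp_fgs": near_fgs,
                     "ibd_flag": ibd_flag,
                     "probe_first": seg.start, "probe_last": seg.end - 1})
    cols = ["seg_index", "chrom", "start", "end", "n_probes", "seg_mean",
            "direction", "posterior", "fraction_probes_q_significant",
            "fgs_gene_ids", "wgs_gene_ids", "within_500bp_fgs", "ibd_flag",
            "probe_first", "probe_last"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# summaries and enrichment
# ---------------------------------------------------------------------------

def chi_square_enrichment(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a 2 x K table."""
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(stat, dof))
    return stat, dof, p


def summarize_dmrs(dmrs: pd.DataFrame, genes: GeneModelSet | None = None,
                   enrichment_attrs: tuple[str, ...] = ("syntenic",
                                                        "subgenome",
                                                        "expression")
                   ) -> dict:
    """Length histogram, intergenic fraction, gene overlap, enrichment tests.

    Enrichment contrasts the gene-attribute composition of DMR-overlapped
    FGS genes against the full FGS background with a Pearson chi-square
    (no continuity correction).
    """
    if not len(dmrs):
        return {"n_dmrs": 0, "lengths": {}, "percent_intergenic": np.nan,
                "n_with_fgs": 0, "n_with_wgs": 0, "enrichment": {}}
    lengths = (dmrs["end"] - dmrs["start"]).to_numpy()
    summary = {
        "n_dmrs": int(len(dmrs)),
        "lengths": {
            "n_lt_5kb": int((lengths < 5_000).sum()),
            "n_lt_10kb": int((lengths < 10_000).sum()),
            "n_ge_10kb": int((lengths >= 10_000).sum()),
            "mean_bp": float(lengths.mean()),
        },
        "percent_intergenic": 100.0 * float((dmrs["wgs_gene_ids"] == "").mean()),
        "n_with_fgs": int((dmrs["fgs_gene_ids"] != "").sum()),
        "n_with_wgs": int((dmrs["wgs_gene_ids"] != "").sum()),
        "enrichment": {},
    }
    if genes is not None:
        fgs = genes.genes[genes.genes["gene_class"] == "FGS"]
        hit_ids = sorted({gid for ids in dmrs["fgs_gene_ids"]
                          for gid in ids.split(",") if gid})
        hit = fgs[fgs["gene_id"].isin(hit_ids)]
        for attr in enrichment_attrs:
            if not len(hit):
                continue
            cats = sorted(fgs[attr].astype(str).unique())
            obs = np.array([
                [int((hit[attr].astype(str) == c).sum()) for c in cats],
                [int((fgs[attr].astype(str) == c).sum()) for c in cats],
            ], dtype=float)
            keep = obs[1] > 0
            if keep.sum() < 2:
                continue
            stat, dof, p = chi_square_enrichment(obs[:, keep])
            summary["enrichment"][attr] = {"chi2": stat, "dof": dof, "p": p,
                                           "categories": list(
                                               np.array(cats)[keep])}
    return summary


# ---------------------------------------------------------------------------
# IBD screen
# ---------------------------------------------------------------------------

@dataclass
class IBDRegion:
    chrom: str
    start: int
    end: int
    snp_count: int
    fold_reduction: float
    infinite_fold: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def ibd_screen(snp_positions: dict[str, np.ndarray],
               chrom_lengths: dict[str, int],
               cgh_segments: pd.DataFrame | None,
               min_length: int, fold_threshold: float = 25.0,
               scan_step_fraction: float = 0.01) -> pd.DataFrame:
    """Find candidate identical-by-descent regions.

    Candidates are maximal runs >= ``min_length`` with no overlap with
    CNV/PAV segments and SNP density at most genome_density/fold_threshold,
    found by a sliding-window scan (window = min_length, step =
    ``scan_step_fraction`` * min_length) followed by merging of qualifying
    windows. ``cgh_segments`` needs chrom/start/end rows for structural
    variants (pass None for none). Fold reduction = genome-wide SNP rate /
    region SNP rate; a region with zero SNPs reports infinity and is flagged.
    """
    total_len = sum(chrom_lengths.values())
    total_snps = sum(len(v) for v in snp_positions.values())
    genome_rate = total_snps / total_len
    if genome_rate == 0:
        raise ValueError("no SNPs genome-wide; screen undefined")
    max_rate = genome_rate / fold_threshold
    step = max(1, int(min_length * scan_step_fraction))

    rows = []
    for chrom, length in chrom_lengths.items():
        pos = np.sort(np.asarray(snp_positions.get(chrom, []), dtype=int))
        blockers: list[tuple[int, int]] = []
        if cgh_segments is not None and len(cgh_segments):
            sub = cgh_segments[cgh_segments["chrom"] == chrom]
            blockers = sorted(zip(sub["start"].astype(int),
                                  sub["end"].astype(int)))
        # allowed intervals = complement of structural-variant segments
        allowed = []
        cursor = 0
        for bs, be in blockers:
            if bs > cursor:
                allowed.append((cursor, bs))
            cursor = max(cursor, be)
        if cursor < length:
            allowed.append((cursor, length))
        for a_s, a_e in allowed:
            if a_e - a_s < min_length:
                continue
            qual: list[tuple[int, int]] = []
            start = a_s
            while start + min_length <= a_e:
                end = start + min_length
                n = int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
                if n / min_length <= max_rate:
                    if qual and start <= qual[-1][1]:
                        qual[-1] = (qual[-1][0], end)
                    else:
                        qual.append((start, end))
                start += step
            # last, right-anchored window
            if a_e - min_length > a_s:
                start = a_e - min_length
                n = int(np.searchsorted(pos, a_e) - np.searchsorted(pos, start))
                if n / min_length <= max_rate:
                    if qual and start <= qual[-1][1]:
                        qual[-1] = (qual[-1][0], a_e)
                    else:
                        qual.append((start, a_e))
            for s, e in qual:
                # merged windows can overhang into dense flanks: trim the
                # denser edge inward until the whole region passes
                while e - s > min_length:
                    n = int(np.searchsorted(pos, e) - np.searchsorted(pos, s))
                    if n / (e - s) <= max_rate:
                        break
                    nl = int(np.searchsorted(pos, s + step)
                             - np.searchsorted(pos, s))
                    nr = int(np.searchsorted(pos, e)
                             - np.searchsorted(pos, e - step))
                    if nl >= nr:
                        s += step
                    else:
                        e -= step
                # snap edges outward to the nearest flanking SNP: adds no
                # SNPs (density can only fall), and recovers the depleted
                # region's SNP-free tails without diluting the fold statistic
                i_left = int(np.searchsorted(pos, s))
                s = int(pos[i_left - 1]) + 1 if i_left > 0 else a_s
                s = max(s, a_s)
                i_right = int(np.searchsorted(pos, e))
                e = int(pos[i_right]) if i_right < len(pos) else a_e
                e = min(e, a_e)
                n = int(np.searchsorted(pos, e) - np.searchsorted(pos, s))
                region_rate = n / (e - s)
                if region_rate > max_rate or (e - s) < min_length:
                    continue
                infinite = n == 0
                fold = np.inf if infinite else genome_rate / region_rate
                rows.append({"chrom": chrom, "start": int(s), "end": int(e),
                             "snp_count": n, "fold_reduction": fold,
                             "infinite_fold": infinite})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "snp_count",
                                       "fold_reduction", "infinite_fold"])


def overlay_variable_calls(regions: pd.DataFrame, probe_calls: pd.DataFrame,
                           probe_map: pd.DataFrame,
                           dmrs: pd.DataFrame) -> pd.DataFrame:
    """Count variable probes and DMR segments inside each candidate region.

    A probe counts if its midpoint falls in the region; a DMR counts if it
    overlaps the region.
    """
    pm = probe_map.set_index("probe_id")
    call_mid = ((pm.loc[probe_calls["probe_id"], "start"].to_numpy()
                 + pm.loc[probe_calls["probe_id"], "end"].to_numpy() - 1) / 2.0
                if len(probe_calls) else np.array([]))
    call_chrom = (pm.loc[probe_calls["probe_id"], "chrom"].to_numpy()
                  if len(probe_calls) else np.array([]))
    out = regions.copy()
    n_probes, n_segs = [], []
    for r in regions.itertuples(index=False):
        in_probe = ((call_chrom == r.chrom) & (call_mid >= r.start)
                    & (call_mid < r.end)).sum() if len(probe_calls) else 0
        if len(dmrs):
            in_seg = int(((dmrs["chrom"] == r.chrom)
                          & (dmrs["start"] < r.end)
                          & (dmrs["end"] > r.start)).sum())
        else:
            in_seg = 0
        n_probes.append(int(in_probe))
        n_segs.append(in_seg)
    out["variable_probe_count"] = n_probes
    out["variable_segment_count"] = n_segs
    return out
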