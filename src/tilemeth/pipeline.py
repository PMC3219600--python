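"""End-to-end orchestration: simulated arrays through DMR and CNV calls.

The stages mirror the study design: (1) simulate or load two-color array
intensities; (2) normalize and fit the per-probe contrasts with moderated
statistics; (3) thin the dense chromosome and drop multi-copy probes, then
run CBS + mixture classification on the CGH contrast to call CNV/PAV
segments; (4) additionally drop probes with CGH <= -1 and run CBS + mixture
classification on the differential-methylation contrast to call DMRs; (5)
call per-probe differences, screen for IBD regions, and score everything
against the simulation truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dmr_calling, linear_model, probe_annotation, segment_em
from . import synthetic_data as sd


@dataclass
class PipelineConfig:
    reference: sd.ReferenceConfig = field(default_factory=sd.ReferenceConfig)
    truth: sd.TruthConfig = field(default_factory=sd.TruthConfig)
    arrays: sd.ArrayConfig = field(default_factory=sd.ArrayConfig)
    normalize: bool = True
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 1000
    cbs_min_width: int = 2
    posterior_threshold: float = 0.95
    probe_q_threshold: float = 0.001
    segment_probe_q: float = 0.0001
    min_dmr_probes: int = 3
    ibd_fold_threshold: float = 25.0


@dataclass
class PipelineResult:
    genome: sd.SyntheticGenome
    probe_map: pd.DataFrame
    genes: sd.GeneModelSet
    truth: sd.TruthSet
    estimates: pd.DataFrame
    cgh_probe_map: pd.DataFrame          # after thinning + uniqueness
    meth_probe_map: pd.DataFrame         # after thinning + uniqueness + CGH
    cnv_segments: pd.DataFrame
    dmr_segments: pd.DataFrame
    probe_calls: pd.DataFrame
    ibd_regions: pd.DataFrame
    metrics: dict


def _segment_and_classify(values: np.ndarray, probe_map: pd.DataFrame,
                          config: PipelineConfig, seed: int,
                          stream: str) -> list[segment_em.Segment]:
    """Per-chromosome CBS, pooled mixture fit, posterior classification."""
    segments: list[segment_em.Segment] = []
    offset = 0
    for chrom in probe_map["chrom"].unique():
        idx = np.flatnonzero((probe_map["chrom"] == chrom).to_numpy())
        segs = segment_em.cbs_segment(values[idx], alpha=config.cbs_alpha,
                                      n_perm=config.cbs_n_perm,
                                      min_width=config.cbs_min_width,
                                      seed=seed)
        for s in segs:
            segments.append(segment_em.Segment(s.start + offset,
                                               s.end + offset, s.mean))
        offset += len(idx)
    means = np.array([s.mean for s in segments])
    model = segment_em.em_fit(means, K=3, seed=seed)
    return segment_em.classify_by_posterior(
        segments, model, threshold=config.posterior_threshold)


def _segments_to_frame(segments: list[segment_em.Segment],
                       probe_map: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for seg in segments:
        sub = probe_map.iloc[seg.start:seg.end]
        rows.append({"chrom": sub["chrom"].iloc[0],
                     "start": int(sub["start"].iloc[0]),
                     "end": int(sub["end"].iloc[-1]),
                     "n_probes": seg.n_probes, "seg_mean": seg.mean,
                     "label": seg.label,
                     "posterior": float(np.max(seg.posterior))
                     if seg.posterior is not None else np.nan,
                     "probe_first": seg.start, "probe_last": seg.end - 1})
    return pd.DataFrame(rows)


def _interval_recovery(truth_df: pd.DataFrame, called_df: pd.DataFrame,
                       truth_label_col: str | None = None,
                       called_label_col: str | None = None,
                       label_map: dict | None = None) -> dict:
    """Recall / exact-boundary fraction / label accuracy of interval calls."""
    n_truth = len(truth_df)
    if n_truth == 0:
        return {"recall": np.nan, "exact_fraction": np.nan,
                "label_accuracy": np.nan, "n_truth": 0,
                "n_called": int(len(called_df))}
    recovered = exact = correct_label = 0
    for t in truth_df.itertuples(index=False):
        hits = called_df[(called_df["chrom"] == t.chrom)
                         & (called_df["start"] < t.end)
                         & (called_df["end"] > t.start)]
        if not len(hits):
            continue
        recovered += 1
        if ((hits["start"] == t.start) & (hits["end"] == t.end)).any():
            exact += 1
        if truth_label_col and called_label_col:
            want = getattr(t, truth_label_col)
            if label_map:
                want = label_map[want]
            if (hits[called_label_col] == want).any():
                correct_label += 1
    return {"recall": recovered / n_truth,
            "exact_fraction": exact / n_truth,
            "label_accuracy": (correct_label / recovered if recovered
                               else np.nan),
            "n_truth": n_truth, "n_called": int(len(called_df))}


def run_pipeline(config: PipelineConfig | None = None,
                 seed: int = 0) -> PipelineResult:
    config = config or PipelineConfig()
    genome, probe_map, genes = sd.generate_reference(config.reference, seed)
    truth = sd.simulate_truth((genome, probe_map), config.truth, seed)
    table = sd.simulate_arrays(truth, (genome, probe_map), config.arrays, seed)

    if config.normalize:
        table = linear_model.normalize(table)
    estimates = linear_model.fit_and_moderate(table)

    est_ix = estimates.set_index("probe_id")

    # probe set A (thinning + uniqueness): CGH segmentation
    opts_a = probe_annotation.FilterOptions(filters=("chr9_thinning",
                                                     "unique"))
    map_a, _ = probe_annotation.apply_probe_filters(probe_map, estimates,
                                                    opts_a)
    cgh_a = est_ix.loc[map_a["probe_id"], "cgh"].to_numpy()
    cgh_segments = _segment_and_classify(cgh_a, map_a, config, seed, "cgh")
    cnv_frame = _segments_to_frame(cgh_segments, map_a)
    cnv_frame["cnv_class"] = cnv_frame["label"].map(
        {"class1": "M_lt_B_or_PAV", "class3": "M_gt_B"}).fillna("none")

    # probe set B (+ CGH floor): differential methylation
    opts_b = probe_annotation.FilterOptions()
    map_b, _ = probe_annotation.apply_probe_filters(probe_map, estimates,
                                                    opts_b)
    diff_b = est_ix.loc[map_b["probe_id"], "diff_meth"].to_numpy()
    diff_segments = _segment_and_classify(diff_b, map_b, config, seed, "diff")
    dmr_frame = dmr_calling.call_dmr_segments(
        diff_segments, map_b, estimates, genes=genes,
        min_probes=config.min_dmr_probes,
        probe_q_threshold=config.segment_probe_q,
        ibd_intervals=truth.ibd_intervals)

    est_b = estimates[estimates["probe_id"].isin(map_b["probe_id"])]
    probe_calls = dmr_calling.call_variable_probes(
        est_b, q_threshold=config.probe_q_threshold)

    chrom_lengths = dict(genome.chromosomes)
    structural = cnv_frame[cnv_frame["cnv_class"] != "none"]
    ibd_regions = dmr_calling.ibd_screen(
        truth.snp_positions, chrom_lengths, structural,
        min_length=config.truth.ibd_min_length,
        fold_threshold=config.ibd_fold_threshold)
    ibd_regions = dmr_calling.overlay_variable_calls(
        ibd_regions, probe_calls, probe_map, dmr_frame)

    cnv_called = structural.rename(columns={"cnv_class": "called_class"})
    metrics = {
        "dmr": _interval_recovery(truth.dmr_intervals, dmr_frame,
                                  "direction", "direction"),
        "cnv": _interval_recovery(truth.cnv_intervals, cnv_called,
                                  "cnv_class", "called_class"),
        "ibd": _interval_recovery(truth.ibd_intervals, ibd_regions),
        "n_probe_calls": int(len(probe_calls)),
    }
    return PipelineResult(genome=genome, probe_map=probe_map, genes=genes,
                          truth=truth, estimates=estimates,
                          cgh_probe_map=map_a, meth_probe_map=map_b,
                          cnv_segments=cnv_frame, dmr_segments=dmr_frame,
                          probe_calls=probe_calls, ibd_regions=ibd_regions,
                          metrics=metrics)
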