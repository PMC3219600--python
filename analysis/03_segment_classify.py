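"""Filter probes, segment the CGH and differential-methylation signals, and
classify segments with the 3-component mixture.

Follows the study's filter order: the dense chr9 design is thinned to every
third probe, multi-copy probes are dropped, and (for the methylation
comparison only) probes with CGH <= -1 are removed. CBS segments each
chromosome; segment means are fit with a 3-component Gaussian mixture and
segments with >0.95 posterior in an extreme component become CNV/PAV calls
(CGH signal) or hypermethylation calls (differential signal).

    python analysis/03_segment_classify.py --sim results/sim --out results
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from tilemeth import probe_annotation as pa
from tilemeth import segment_em as se


def segment_stat(values, probe_map, n_perm, seed):
    segments = []
    offset = 0
    for chrom in probe_map["chrom"].unique():
        idx = np.flatnonzero((probe_map["chrom"] == chrom).to_numpy())
        for s in se.cbs_segment(values[idx], n_perm=n_perm, seed=seed):
            segments.append(se.Segment(s.start + offset, s.end + offset,
                                       s.mean))
        offset += len(idx)
    model = se.em_fit(np.array([s.mean for s in segments]), K=3, seed=seed)
    return se.classify_by_posterior(segments, model), model


def to_frame(segments, probe_map):
    rows = []
    for s in segments:
        sub = probe_map.iloc[s.start:s.end]
        rows.append((sub["chrom"].iloc[0], int(sub["start"].iloc[0]),
                     int(sub["end"].iloc[-1]), s.label, s.mean, s.n_probes,
                     float(np.max(s.posterior)), s.start, s.end - 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label",
                                       "seg_mean", "n_probes", "posterior",
                                       "probe_first", "probe_last"])


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-perm", type=int, default=200,
                    help="permutations per CBS split test")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    probe_map = pd.read_csv(args.sim / "probes.tsv", sep="\t")
    est = pd.read_csv(args.out / "estimates.tsv", sep="\t")
    est_ix = est.set_index("probe_id")

    map_a, prov_a = pa.apply_probe_filters(
        probe_map, est, pa.FilterOptions(filters=("chr9_thinning", "unique")))
    print(f"CGH probe set: {len(map_a):,} of {len(probe_map):,} "
          f"(thinning + uniqueness)")
    cgh_segments, cgh_model = segment_stat(
        est_ix.loc[map_a["probe_id"], "cgh"].to_numpy(), map_a,
        args.n_perm, args.seed)
    cgh_frame = to_frame(cgh_segments, map_a)
    cgh_frame["cnv_class"] = cgh_frame["label"].map(
        {"class1": "M_lt_B_or_PAV", "class3": "M_gt_B"}).fillna("none")
    cgh_frame.to_csv(args.out / "cgh_segments.tsv", sep="\t", index=False)
    n_cnv = (cgh_frame["cnv_class"] != "none").sum()
    print(f"  {len(cgh_frame)} segments; {n_cnv} CNV/PAV calls; "
          f"mixture means {np.round(cgh_model.means, 2)}")

    map_b, prov_b = pa.apply_probe_filters(probe_map, est,
                                           pa.FilterOptions())
    print(f"methylation probe set: {len(map_b):,} (+ CGH > -1 filter)")
    diff_segments, diff_model = segment_stat(
        est_ix.loc[map_b["probe_id"], "diff_meth"].to_numpy(), map_b,
        args.n_perm, args.seed)
    diff_frame = to_frame(diff_segments, map_b)
    diff_frame.to_csv(args.out / "diff_segments.tsv", sep="\t", index=False)
    n_hyper = diff_frame["label"].isin(["class1", "class3"]).sum()
    print(f"  {len(diff_frame)} segments; {n_hyper} hypermethylation "
          f"candidates; mixture means {np.round(diff_model.means, 2)}")
    prov = pd.concat([prov_a.assign(stage="cgh"),
                      prov_b.assign(stage="methylation")])
    prov.to_csv(args.out / "filter_provenance.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
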