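"""qPCR validation and cis/trans inheritance mapping in the NIL panel.

Simulates methylation-dependent-digest qPCR for every (NIL, DMR) pair using
the true states from 01_simulate.py, calls per-line methylation states from
differential Cts, classifies each DMR as cis- or trans-controlled from the
introgression maps, and tallies the packaged published validation tables.

    python analysis/06_inheritance.py --sim results/sim --out results
"""

import argparse
from pathlib import Path

import pandas as pd

from tilemeth import inheritance_validation as iv
from tilemeth import synthetic_data as sd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--sigma-ct", type=float, default=0.25)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    truth_dmrs = pd.read_csv(args.sim / "truth_dmrs.tsv", sep="\t")
    nil_states = pd.read_csv(args.sim / "nil_true_states.tsv", sep="\t")
    nil_bed = pd.read_csv(args.sim / "nil_introgressions.bed", sep="\t",
                          names=["chrom", "start", "end", "nil_id",
                                 "recurrent"])
    nils = []
    for nil_id, g in nil_bed.groupby("nil_id"):
        nils.append(sd.NILPanel(
            nil_id=nil_id, recurrent_parent=g["recurrent"].iloc[0],
            introgression_intervals=list(zip(g["chrom"], g["start"],
                                             g["end"]))))
    qcfg = sd.QpcrConfig(sigma_ct=args.sigma_ct, delta_ct=5.0,
                         enzyme="MspJI")

    rows, qpcr_rows = [], []
    for dmr in truth_dmrs.itertuples(index=False):
        want = "trans" if dmr.control == "trans" else "cis"
        sub = nil_states[nil_states["dmr_id"] == dmr.dmr_id]
        calls = {}
        for r in sub.itertuples(index=False):
            meas = sd.simulate_qpcr({r.nil_id: bool(r.methylated)}, qcfg,
                                    seed=args.seed,
                                    assay_id=f"{dmr.dmr_id}:{r.nil_id}")
            qpcr_rows.append(meas)
            m = meas.iloc[0]
            calls[r.nil_id] = iv.call_state(m["mock_ct"], m["digest_ct"],
                                            genotype=r.nil_id,
                                            assay_id=dmr.dmr_id)
        parents = {"B73": "high" if dmr.direction == "B73_hyper" else "low",
                   "Mo17": "high" if dmr.direction == "Mo17_hyper" else "low"}
        got = iv.classify_cis_trans(
            (dmr.chrom, int(dmr.start), int(dmr.end)), calls, nils, parents)
        rows.append({"dmr_id": dmr.dmr_id, "true_control": dmr.control,
                     "called": got.label, "expected": want,
                     "donor_match": round(got.donor_match_fraction, 3),
                     "recurrent_match": round(got.recurrent_match_fraction,
                                              3),
                     "n_informative": got.n_informative,
                     "controls_expected": got.stability["expected"],
                     "controls_partial": got.stability["partial"],
                     "controls_switched": got.stability["switched"]})
    out = pd.DataFrame(rows)
    out.to_csv(args.out / "inheritance_calls.tsv", sep="\t", index=False)
    pd.concat(qpcr_rows, ignore_index=True).to_csv(
        args.out / "qpcr_measurements.csv", index=False)

    n_ok = (out["called"] == out["expected"]).sum()
    print(f"cis/trans classification: {n_ok}/{len(out)} correct at "
          f"sigma_ct={args.sigma_ct}")
    print(out["called"].value_counts().to_string())
    stab = out[["controls_expected", "controls_partial",
                "controls_switched"]].sum()
    total_controls = stab.sum()
    print(f"control-line stability: {stab['controls_expected']}"
          f"/{total_controls} expected state "
          f"({stab['controls_partial']} partial, "
          f"{stab['controls_switched']} switched)")

    tally = iv.tally_validation_table(iv.load_table5(), iv.load_table4())
    print("published validation table: "
          f"{tally['b73_direction']} B73-direction / "
          f"{tally['mo17_direction']} Mo17-direction assays, "
          f"{tally['confirmed']}/{tally['n_assays']} confirmed, "
          f"{tally['ibd']} in IBD regions, "
          f"{tally['cis']} cis / {tally['trans']} trans")
    t4 = iv.load_table4()
    print(f"published IBD table: {int(t4['variable_probes'].sum())} variable "
          f"probes and {int(t4['variable_segments'].sum())} DMRs inside "
          f"{len(t4)} IBD regions")


if __name__ == "__main__":
    main()
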