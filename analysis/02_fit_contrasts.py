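"""Normalize intensities and fit the per-probe methylation contrasts.

Reads the long-format intensity table written by 01_simulate.py, applies the
affine + generalized-log normalization, fits the four-factor linear model
per probe, and moderates the statistics by empirical Bayes with BH FDR
control. Writes one row per probe with the four contrasts (B73 methylation,
CGH, corrected Mo17 methylation, differential methylation) and their
moderated t / p / q values.

    python analysis/02_fit_contrasts.py --sim results/sim --out results
"""

import argparse
from pathlib import Path

import pandas as pd

from tilemeth import linear_model as lm


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = pd.read_csv(args.sim / "intensities.csv")
    table = lm.normalize(table)
    est = lm.fit_and_moderate(table)
    est.to_csv(args.out / "estimates.tsv", sep="\t", index=False)

    d0 = est["d0"].iloc[0]
    print(f"fitted {len(est):,} probes; residual df "
          f"{est['df_resid'].iloc[0]:.0f}, prior df "
          f"{'inf' if d0 == float('inf') else f'{d0:.1f}'}")
    for c in ("b73_meth", "cgh", "mo17_meth_corr", "diff_meth"):
        n_sig = int((est[f"q_{c}"] < 0.05).sum())
        print(f"  {c:15s} mean {est[c].mean():+.3f}  q<0.05: {n_sig:,}")
    print(f"-> {args.out / 'estimates.tsv'}")


if __name__ == "__main__":
    main()
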