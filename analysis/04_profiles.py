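"""Chromosome windows, metagene profiles by gene class, and CpG density.

Per-probe methylation states are called from the B73 log2(IP/input) signal
with the 3-component mixture, then summarized as percent-methylated in
sliding windows along each chromosome. Metagene profiles compare gene
classes (high-confidence vs rejected models, expression classes, syntenic
vs non-syntenic) on a common upstream/body/downstream coordinate, and the
CpG-dinucleotide profile is computed over the same bins.

    python analysis/04_profiles.py --sim results/sim --out results
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from tilemeth import genome_profiles as gp
from tilemeth import synthetic_data as sd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--window", type=int, default=100_000)
    ap.add_argument("--step", type=int, default=20_000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    probe_map = pd.read_csv(args.sim / "probes.tsv", sep="\t")
    est = pd.read_csv(args.out / "estimates.tsv", sep="\t")
    gene_attrs = pd.read_csv(args.sim / "gene_attributes.tsv", sep="\t")
    exons = []
    for rec in open(args.sim / "genes.gff3"):
        if rec.startswith("#"):
            continue
        f = rec.rstrip("\n").split("\t")
        if f[2] == "exon":
            gid = f[8].split("Parent=")[1].split(";")[0]
            exons.append((gid, int(f[3]) - 1, int(f[4])))
    genes = sd.GeneModelSet(
        genes=gene_attrs,
        exons=pd.DataFrame(exons, columns=["gene_id", "start", "end"]))
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(args.sim / "genome.fasta",
                                                  "fasta")}
    genome = sd.SyntheticGenome(
        chromosomes=[(c, len(s)) for c, s in seqs.items()], sequence=seqs,
        centromere_position={c: len(s) // 2 for c, s in seqs.items()})

    vals = est.set_index("probe_id")["b73_meth"]
    states = gp.classify_probe_methylation(
        vals.loc[probe_map["probe_id"]].to_numpy(), seed=args.seed)
    pct = 100.0 * states.mean()
    print(f"probe methylation calls: {pct:.1f}% methylated "
          f"({len(states):,} probes)")

    windows = gp.window_methylation(
        states, probe_map, dict(genome.chromosomes),
        window=args.window, step=args.step)
    windows.to_csv(args.out / "window_methylation.tsv", sep="\t",
                   index=False)
    print(f"windows: {len(windows)} of {args.window/1e3:.0f} kb "
          f"(step {args.step/1e3:.0f} kb); percent methylated "
          f"{windows['percent_methylated'].min():.0f}-"
          f"{windows['percent_methylated'].max():.0f}")

    g2 = gene_attrs.copy()
    g2["fgs_or_rejected"] = np.where(g2["gene_class"] == "FGS", "FGS",
                                     "rejected")
    frames = []
    for col in ("fgs_or_rejected", "expression", "syntenic", "subgenome"):
        prof = gp.metagene_profile(vals, probe_map,
                                   sd.GeneModelSet(g2, genes.exons),
                                   class_column=col)
        prof["attribute"] = col
        frames.append(prof)
    metagene = pd.concat(frames, ignore_index=True)
    metagene.to_csv(args.out / "metagene_profiles.tsv", sep="\t",
                    index=False)
    body = metagene[(metagene["attribute"] == "fgs_or_rejected")
                    & (metagene["region"] == "body")]
    means = body.groupby("gene_class")["mean_value"].mean()
    print("metagene body means: "
          + ", ".join(f"{k}={v:.2f}" for k, v in means.items()))

    cpg = gp.cpg_profile(genome, genes)
    cpg.to_csv(args.out / "cpg_profile.tsv", sep="\t", index=False)
    print(f"CpG body proportion mean "
          f"{cpg[cpg['region'] == 'body']['cpg_proportion'].mean():.4f}")


if __name__ == "__main__":
    main()
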