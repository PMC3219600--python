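"""Simulate the study's inputs: genome, probes, genes, truth, arrays.

Generates a desk-scale two-inbred methylation tiling-array experiment with
known ground truth and writes every external-format artifact the downstream
steps consume.

    python analysis/01_simulate.py --seed 1 --out results/sim
"""

import argparse
from pathlib import Path

from tilemeth import io
from tilemeth import synthetic_data as sd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    genome, probe_map, genes = sd.generate_reference(sd.ReferenceConfig(),
                                                     seed=args.seed)
    truth = sd.simulate_truth((genome, probe_map), sd.TruthConfig(),
                              seed=args.seed)
    table = sd.simulate_arrays(truth, (genome, probe_map), sd.ArrayConfig(),
                               seed=args.seed)
    nils, nil_states = sd.simulate_nil_panel(truth, (genome, probe_map),
                                             sd.NILConfig(), seed=args.seed)

    io.write_fasta(genome, args.out / "genome.fasta")
    io.write_probe_bed(probe_map, args.out / "probes.bed")
    io.write_probe_annotation(probe_map, args.out / "probes.tsv")
    io.write_gff3(genes, args.out / "genes.gff3")
    io.write_gene_attributes(genes, args.out / "gene_attributes.tsv")
    io.write_intensities(table, args.out / "intensities.csv")
    io.write_truth_tables(truth, args.out)
    io.write_nil_beds(nils, args.out / "nil_introgressions.bed")
    nil_states.to_csv(args.out / "nil_true_states.tsv", sep="\t", index=False)

    n9 = (probe_map["chrom"] == "chr9").sum()
    print(f"genome: {len(genome.chromosomes)} chromosomes, "
          f"{sum(l for _, l in genome.chromosomes):,} bp")
    print(f"probes: {len(probe_map):,} ({n9:,} on the dense chr9 design)")
    print(f"genes: {len(genes.genes)} "
          f"({(genes.genes['gene_class'] == 'FGS').sum()} FGS)")
    print(f"truth: {len(truth.dmr_intervals)} DMRs "
          f"({(truth.dmr_intervals['control'] == 'pure_epiallele').sum()} "
          f"pure epialleles), {len(truth.cnv_intervals)} CNV/PAV, "
          f"{len(truth.ibd_intervals)} IBD blocks")
    print(f"arrays: {table['sample_id'].nunique()} channels, "
          f"{len(table):,} measurements -> {args.out}")


if __name__ == "__main__":
    main()
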