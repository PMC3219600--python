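"""Plain-text writers for the pipeline's external formats.

Coordinates follow the usual conventions: BED is 0-based half-open, GFF3 is
1-based inclusive. Everything the pipeline exchanges is small enough to live
in uncompressed text.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import GeneModelSet, NILPanel, SyntheticGenome, TruthSet


def write_fasta(genome: SyntheticGenome, path: str | Path) -> None:
    records = [SeqRecord(Seq(genome.sequence[name]), id=name, description="")
               for name, _ in genome.chromosomes]
    SeqIO.write(records, str(path), "fasta")


def write_probe_bed(probe_map: pd.DataFrame, path: str | Path) -> None:
    probe_map[["chrom", "start", "end", "probe_id"]].to_csv(
        path, sep="\t", header=False, index=False)


def write_probe_annotation(probe_map: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in probe_map.columns if c != "sequence"]
    probe_map[cols].to_csv(path, sep="\t", index=False)


def write_gff3(genes: GeneModelSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        exons = genes.exons.groupby("gene_id")
        for g in genes.genes.itertuples(index=False):
            attrs = (f"ID={g.gene_id};gene_class={g.gene_class};"
                     f"syntenic={int(g.syntenic)};subgenome={g.subgenome};"
                     f"expression={g.expression}")
            fh.write(f"{g.chrom}\ttilemeth\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            if g.gene_id in exons.groups:
                for e in exons.get_group(g.gene_id).itertuples(index=False):
                    fh.write(f"{g.chrom}\ttilemeth\texon\t{e.start + 1}\t"
                             f"{e.end}\t.\t{g.strand}\t.\t"
                             f"Parent={g.gene_id}\n")


def write_gene_attributes(genes: GeneModelSet, path: str | Path) -> None:
    genes.genes.to_csv(path, sep="\t", index=False)


def write_intensities(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_truth_tables(truth: TruthSet, outdir: str | Path) -> None:
    outdir = Path(outdir)
    truth.probe_states.to_csv(outdir / "truth_probe_states.tsv", sep="\t",
                              index_label="probe_id")
    truth.dmr_intervals.to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False)
    truth.cnv_intervals.to_csv(outdir / "truth_cnvs.tsv", sep="\t", index=False)
    truth.ibd_intervals.to_csv(outdir / "truth_ibd.tsv", sep="\t", index=False)
    rows = [(c, int(p)) for c, pos in truth.snp_positions.items() for p in pos]
    pd.DataFrame(rows, columns=["chrom", "position"]).to_csv(
        outdir / "truth_snps.tsv", sep="\t", index=False)


def write_nil_beds(nils: list[NILPanel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for nil in nils:
            for chrom, s, e in nil.introgression_intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{nil.nil_id}\t"
                         f"{nil.recurrent_parent}\n")


def write_segments_bed(segments: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "direction", "seg_mean", "n_probes",
            "posterior"]
    segments[[c for c in cols if c in segments.columns]].to_csv(
        path, sep="\t", header=False, index=False)
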