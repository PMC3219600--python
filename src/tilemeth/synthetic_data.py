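"""Synthetic inputs for the comparative meDIP tiling-array pipeline.

This module emulates, at desk scale, the data a two-genotype methylation
tiling-array experiment produces: a repeat-masked reference genome tiled with
probes (~200 bp spacing genome-wide, denser on "chr9"), per-probe methylation
states for the two inbreds with implanted differentially methylated regions
(DMRs), copy-number / presence-absence variants (CNV/PAV), identical-by-descent
(IBD) haplotype blocks with depleted SNP density, two-color array intensities
with replicate/dye/array noise, near-isogenic-line (NIL) panels under cis or
trans methylation control, and methylation-dependent-digest qPCR Ct values.

Every generator takes an explicit integer seed and fans it out into named
substreams, so the whole truth set is reproducible bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

BASES = np.array(list("ACGT"))

METHYLATION_DEPENDENT_ENZYMES = frozenset({"MspJI", "FspEI"})
METHYLATION_SENSITIVE_ENZYMES = frozenset({"HpaII", "PstI"})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    """A small DNA genome with masked repeat intervals.

    ``chromosomes`` is an ordered list of (name, length); ``sequence`` maps
    names to A/C/G/T strings of exactly that length; repeat intervals are
    0-based half-open and are excluded from probe tiling (the array targets
    the repeat-masked, low-copy fraction of the genome).
    """

    chromosomes: list[tuple[str, int]]
    sequence: dict[str, str]
    centromere_position: dict[str, int]
    repeat_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            if len(self.sequence[name]) != length:
                raise ValueError(f"sequence length mismatch for {name}")


@dataclass
class GeneModelSet:
    """Gene models plus their exon structure.

    ``genes`` columns: gene_id, chrom, start, end (0-based half-open
    transcript span), strand, cds_start, cds_end, gene_class
    (FGS / rejected_low_confidence / rejected_transposon /
    rejected_pseudogene), syntenic (bool), subgenome (1/2), expression
    (none/Q1..Q4). ``exons`` columns: gene_id, start, end.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame


@dataclass
class TruthSet:
    """Ground truth behind one simulated experiment."""

    probe_states: pd.DataFrame          # index probe_id, bool columns B73 / Mo17
    dmr_intervals: pd.DataFrame         # chrom,start,end,direction,control,(controller_*)
    cnv_intervals: pd.DataFrame         # chrom,start,end,cnv_class
    ibd_intervals: pd.DataFrame         # chrom,start,end
    snp_positions: dict[str, np.ndarray]


@dataclass
class NILPanel:
    """One near-isogenic line: recurrent-parent background plus donor segments."""

    nil_id: str
    recurrent_parent: str               # B73 or Mo17
    introgression_intervals: list[tuple[str, int, int]]

    @property
    def donor(self) -> str:
        return "Mo17" if self.recurrent_parent == "B73" else "B73"

    def carries_donor(self, chrom: str, pos: float) -> bool:
        return any(c == chrom and s <= pos < e
                   for c, s, e in self.introgression_intervals)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ReferenceConfig:
    """Genome / array-design parameters.

    Chromosomes default to a few hundred kb (the real genome is ~2.3 Gb; the
    synthetic one is scaled down for desk runtime, with interval thresholds
    rescaled accordingly elsewhere). ``spacing`` is the genome-wide probe
    pitch; a chromosome named chr9 is tiled at ``chr9_spacing`` to emulate the
    dense design used to test resolution.
    """

    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 600_000), ("chr2", 400_000), ("chr9", 100_000))
    spacing: int = 200
    chr9_spacing: int = 56
    probe_length: int = 50
    gc_content: float = 0.46
    repeat_fraction: float = 0.2
    repeat_mean_length: int = 2_000
    n_exact_duplications: int = 1
    n_close_duplications: int = 1
    duplication_length: int = 5_000
    close_duplication_divergence: float = 0.03
    mean_bp_per_gene: int = 8_000
    gene_length_range: tuple[int, int] = (1_000, 6_000)
    max_exons: int = 5
    fgs_fraction: float = 0.4


@dataclass
class TruthConfig:
    dmr_count: int = 20
    cnv_count: int = 8
    ibd_count: int = 2
    fraction_methylated: float = 0.5    # ~50% of probes methylated genome-wide
    dmr_probe_range: tuple[int, int] = (3, 8)
    cnv_probe_range: tuple[int, int] = (5, 25)
    ibd_min_length: int = 100_000       # scaled stand-in for the 2 Mb rule
    # SNP rate is scaled up relative to the real inbred pair so that SNP
    # counts per (rescaled) IBD-length window keep the counting statistics
    # of the full-size genome; the screen depends on counts, not on per-bp
    # realism.
    snp_rate: float = 0.005             # background SNPs per bp
    ibd_snp_fold: int = 40              # within the observed 25-49x range
    control_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)  # cis/trans/pure
    controller_length: int = 5_000


@dataclass
class ArrayConfig:
    """Two-color array simulation: three biological replicates by default."""

    n_reps: int = 3
    mu_meth: float = 2.0                # log2 IP enrichment of a methylated probe
    ip_offset: float = 0.0              # IP-channel shift shared by all probes
    sigma: float = 0.3                  # per-measurement noise SD (log2)
    dye_effect: float = 0.3             # additive Cy5 offset
    array_effect: float = 0.2           # SD of per-array offsets
    baseline: float = 10.0              # log2 intensity of a single-copy probe
    pav_depth: float = -3.0             # Mo17 signal drop at M<B / PAV probes
    cnv_gain: float = 1.0               # Mo17 signal gain at M>B CNV probes


@dataclass
class NILConfig:
    n_nils: int = 20
    recurrent_b73_fraction: float = 0.8
    nils_per_dmr: tuple[int, int] = (2, 5)
    # donor segments stay a small fraction of the genome, mirroring real
    # NILs where >95% of the genome is the recurrent parent
    background_segments: tuple[int, int] = (0, 2)
    segment_length_range: tuple[int, int] = (8_000, 25_000)
    instability_rate: float = 0.0       # control NILs switch state at this rate


@dataclass
class QpcrConfig:
    baseline_ct: float = 20.0
    delta_ct: float = 5.0               # Ct shift from a fully digested template
    sigma_ct: float = 0.0
    enzyme: str = "MspJI"


# ---------------------------------------------------------------------------
# reference genome, probes, gene models
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p)


def _place_intervals(rng: np.random.Generator, chrom_len: int, n: int,
                     mean_len: int, occupied: list[tuple[int, int]],
                     max_tries: int = 200,
                     fixed_length: bool = False) -> list[tuple[int, int]]:
    """Place n non-overlapping intervals avoiding ``occupied``."""
    placed: list[tuple[int, int]] = []
    for _ in range(n):
        for _try in range(max_tries):
            length = (mean_len if fixed_length
                      else max(200, int(rng.exponential(mean_len))))
            if length >= chrom_len:
                continue
            start = int(rng.integers(0, chrom_len - length))
            iv = (start, start + length)
            if all(iv[1] <= s or iv[0] >= e for s, e in occupied + placed):
                placed.append(iv)
                break
    return sorted(placed)


def generate_reference(config: ReferenceConfig | None = None, seed: int = 0
                       ) -> tuple[SyntheticGenome, pd.DataFrame, GeneModelSet]:
    """Build a synthetic genome, its probe map, and gene models.

    Probes tile the non-repeat fraction at ``config.spacing`` (chr9 at the
    dense pitch). Each probe carries its true perfect/close match counts,
    known by construction from the implanted duplication blocks: an exact
    duplication gives its probes perfect_match_count = 2; a diverged (~97%
    identity) duplication gives close_match_count = 1.
    """
    config = config or ReferenceConfig()
    if not config.chromosomes:
        raise ValueError("at least one chromosome required")
    if config.spacing <= 0 or config.chr9_spacing <= 0:
        raise ValueError("spacing must be positive")
    for name, length in config.chromosomes:
        sp = config.chr9_spacing if name == "chr9" else config.spacing
        if sp >= length:
            raise ValueError("degenerate tiling: spacing >= chromosome length")

    rng = substream(seed, "reference")
    sequence_arrays: dict[str, np.ndarray] = {}
    repeat_intervals: dict[str, list[tuple[int, int]]] = {}
    centromeres: dict[str, int] = {}
    for name, length in config.chromosomes:
        seq = _random_sequence(rng, length, config.gc_content)
        n_rep = int(config.repeat_fraction * length / config.repeat_mean_length)
        reps = _place_intervals(rng, length, n_rep, config.repeat_mean_length, [])
        sequence_arrays[name] = seq
        repeat_intervals[name] = reps
        centromeres[name] = length // 2

    # duplication blocks: copy a source interval to a target elsewhere
    dup_truth: list[tuple[str, int, int, bool]] = []  # chrom,start,end,is_exact
    total_dups = config.n_exact_duplications + config.n_close_duplications
    chrom_names = [c for c, _ in config.chromosomes]
    for i in range(total_dups):
        exact = i < config.n_exact_duplications
        chrom = chrom_names[i % len(chrom_names)]
        length = config.duplication_length
        occupied = repeat_intervals[chrom] + [(s, e) for c, s, e, _ in dup_truth
                                              if c == chrom]
        spots = _place_intervals(rng, len(sequence_arrays[chrom]), 2,
                                 length, occupied, fixed_length=True)
        if len(spots) < 2:
            continue
        (src_s, src_e), (dst_s, dst_e) = spots
        block = sequence_arrays[chrom][src_s:src_e].copy()
        if not exact:
            n_mut = int(round(config.close_duplication_divergence * length))
            pos = rng.choice(length, size=n_mut, replace=False)
            for p in pos:
                choices = [b for b in "ACGT" if b != block[p]]
                block[p] = choices[int(rng.integers(0, 3))]
        sequence_arrays[chrom][dst_s:dst_e] = block
        dup_truth.append((chrom, src_s, src_e, exact))
        dup_truth.append((chrom, dst_s, dst_e, exact))

    genome = SyntheticGenome(
        chromosomes=list(config.chromosomes),
        sequence={c: "".join(a) for c, a in sequence_arrays.items()},
        centromere_position=centromeres,
        repeat_intervals=repeat_intervals,
    )

    # probe tiling over non-repeat sequence
    rows = []
    pid = 0
    for name, length in config.chromosomes:
        sp = config.chr9_spacing if name == "chr9" else config.spacing
        reps = repeat_intervals[name]
        pos = 0
        while pos + config.probe_length <= length:
            s, e = pos, pos + config.probe_length
            if not any(s < re and e > rs for rs, re in reps):
                perfect, close = 1, 0
                for c, ds, de, exact in dup_truth:
                    if c == name and s >= ds and e <= de:
                        if exact:
                            perfect = 2
                        else:
                            close = 1
                        break
                rows.append((f"P{pid:06d}", name, s, e,
                             genome.sequence[name][s:e], perfect, close))
                pid += 1
            pos += sp
    probe_map = pd.DataFrame(
        rows, columns=["probe_id", "chrom", "start", "end", "sequence",
                       "perfect_match_count", "close_match_count"])

    genes = _generate_gene_models(config, genome, rng)
    return genome, probe_map, genes


def _generate_gene_models(config: ReferenceConfig, genome: SyntheticGenome,
                          rng: np.random.Generator) -> GeneModelSet:
    gene_rows, exon_rows = [], []
    gid = 0
    rejected_classes = ["rejected_low_confidence", "rejected_transposon",
                        "rejected_pseudogene"]
    for name, length in genome.chromosomes:
        n_genes = max(1, length // config.mean_bp_per_gene)
        occupied = list(genome.repeat_intervals.get(name, []))
        lo, hi = config.gene_length_range
        for _ in range(n_genes):
            for _try in range(50):
                glen = int(rng.integers(lo, hi))
                if glen >= length:
                    continue
                start = int(rng.integers(0, length - glen))
                iv = (start, start + glen)
                if all(iv[1] <= s or iv[0] >= e for s, e in occupied):
                    occupied.append(iv)
                    break
            else:
                continue
            start, end = iv
            strand = "+" if rng.random() < 0.5 else "-"
            is_fgs = rng.random() < config.fgs_fraction
            gene_class = ("FGS" if is_fgs
                          else rejected_classes[int(rng.integers(0, 3))])
            syntenic = rng.random() < (0.7 if is_fgs else 0.2)
            subgenome = int(rng.integers(1, 3))
            if is_fgs:
                expression = ["none", "Q1", "Q2", "Q3", "Q4"][int(rng.integers(0, 5))]
            else:
                expression = "none"
            n_exons = int(rng.integers(1, config.max_exons + 1))
            # split span into exons separated by introns
            cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_exons - 2,
                                      replace=False)) if n_exons > 1 else np.array([])
            bounds = np.concatenate([[0], cuts, [glen]])
            gene_id = f"G{gid:05d}"
            for k in range(n_exons):
                es, ee = int(bounds[2 * k]), int(bounds[2 * k + 1])
                if ee > es:
                    exon_rows.append((gene_id, start + es, start + ee))
            utr5 = int(rng.integers(50, 300))
            utr3 = int(rng.integers(50, 300))
            if strand == "+":
                cds_start, cds_end = start + utr5, end - utr3
            else:
                cds_start, cds_end = start + utr3, end - utr5
            cds_start = min(cds_start, end - 1)
            cds_end = max(cds_end, cds_start + 1)
            gene_rows.append((gene_id, name, start, end, strand, cds_start,
                              cds_end, gene_class, syntenic, subgenome,
                              expression))
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=[
        "gene_id", "chrom", "start", "end", "strand", "cds_start", "cds_end",
        "gene_class", "syntenic", "subgenome", "expression"])
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "start", "end"])
    return GeneModelSet(genes=genes, exons=exons)


# ---------------------------------------------------------------------------
# truth simulation
# ---------------------------------------------------------------------------

def _pick_probe_run(rng: np.random.Generator, probe_map: pd.DataFrame,
                    n_probes: int, taken: np.ndarray,
                    chrom_subset: pd.DataFrame | None = None) -> np.ndarray | None:
    """Pick ``n_probes`` consecutive free probes (positional indices).

    Runs are restricted to single-copy probes: the analysis explicitly
    confines itself to unique probes, so implanted variants live on the
    analyzable fraction of the array.
    """
    pool = chrom_subset if chrom_subset is not None else probe_map
    unique_ok = ((probe_map["perfect_match_count"] == 1)
                 & (probe_map["close_match_count"] == 0)).to_numpy()
    for _try in range(200):
        chrom = rng.choice(pool["chrom"].unique())
        idx = np.flatnonzero((probe_map["chrom"] == chrom).to_numpy())
        if chrom_subset is not None:
            idx = np.intersect1d(idx, pool.index.to_numpy())
        if len(idx) < n_probes:
            continue
        # runs must be consecutive in the chromosome's probe order
        start = int(rng.integers(0, len(idx) - n_probes + 1))
        run = idx[start:start + n_probes]
        if np.any(np.diff(run) != 1):
            continue
        # require a 2-probe clear buffer on both sides: implanted intervals
        # separated by less than the segmentation's minimum arc width are
        # sub-resolution for the array design and would merge into one call
        lo = max(run[0] - 2, 0)
        hi = min(run[-1] + 3, len(taken))
        if np.any(taken[lo:hi]) or not np.all(unique_ok[run]):
            continue
        return run
    return None


def _mark_taken(taken: np.ndarray, run: np.ndarray) -> None:
    """Mark a run plus its 2-probe buffer as occupied."""
    taken[max(run[0] - 2, 0):min(run[-1] + 3, len(taken))] = True


def simulate_truth(reference: tuple[SyntheticGenome, pd.DataFrame],
                   params: TruthConfig | None = None, seed: int = 0) -> TruthSet:
    """Draw probe methylation states and implant DMRs, CNVs, IBD blocks, SNPs.

    Both genotypes start from a shared per-probe state drawn with
    ``fraction_methylated``; each DMR flips the state of one genotype over a
    run of >=3 consecutive probes. IBD blocks get a >=25-fold SNP depletion;
    pure-epiallele DMRs sit inside IBD blocks and have no SNP within 1 kb.
    """
    genome, probe_map = reference
    params = params or TruthConfig()
    if not 0 < params.fraction_methylated < 1:
        raise ValueError("fraction_methylated must be in (0, 1)")
    if params.dmr_probe_range[0] < 3:
        raise ValueError("DMRs must span at least 3 probes")
    chrom_len = dict(genome.chromosomes)
    max_chrom_probes = int(probe_map.groupby("chrom").size().max())
    if params.dmr_probe_range[1] > max_chrom_probes:
        raise ValueError("requested DMR wider than chromosome")

    rng = substream(seed, "truth")
    n = len(probe_map)
    base = rng.random(n) < params.fraction_methylated
    states = pd.DataFrame({"B73": base.copy(), "Mo17": base.copy()},
                          index=probe_map["probe_id"].to_numpy())
    taken = np.zeros(n, dtype=bool)

    # IBD intervals first (pure DMRs must live inside them)
    ibd_rows = []
    for _ in range(params.ibd_count):
        for _try in range(100):
            candidates = [c for c, ln in chrom_len.items()
                          if ln > 2 * params.ibd_min_length]
            if not candidates:
                raise ValueError("no chromosome long enough for an IBD block")
            chrom = candidates[int(rng.integers(0, len(candidates)))]
            length = int(params.ibd_min_length * (1 + 0.3 * rng.random()))
            start = int(rng.integers(0, chrom_len[chrom] - length))
            iv = (chrom, start, start + length)
            if all(c != chrom or e <= start or s >= start + length
                   for c, s, e in [(r[0], r[1], r[2]) for r in ibd_rows]):
                ibd_rows.append(iv)
                break
    ibd = pd.DataFrame(ibd_rows, columns=["chrom", "start", "end"])

    # control labels for DMRs
    n_cis = int(round(params.control_mix[0] * params.dmr_count))
    n_trans = int(round(params.control_mix[1] * params.dmr_count))
    n_pure = params.dmr_count - n_cis - n_trans
    if n_pure > 0 and len(ibd) == 0:
        raise ValueError("pure-epiallele DMRs require at least one IBD block")
    controls = ["cis"] * n_cis + ["trans"] * n_trans + ["pure_epiallele"] * n_pure

    dmr_rows = []
    lo, hi = params.dmr_probe_range
    mid = (probe_map["start"].to_numpy() + probe_map["end"].to_numpy()) / 2.0
    # balanced direction assignment: the study observed hundreds of DMRs in
    # each direction, and the mixture classifier needs both extreme classes
    # populated to anchor its components
    n_dmrs = len(controls)
    directions = np.array(["B73_hyper", "Mo17_hyper"] * (n_dmrs // 2 + 1))[:n_dmrs]
    rng.shuffle(directions)
    for d, control in enumerate(controls):
        n_probes = int(rng.integers(lo, hi + 1))
        if control == "pure_epiallele":
            mask = np.zeros(n, dtype=bool)
            for _, r in ibd.iterrows():
                mask |= ((probe_map["chrom"] == r["chrom"]).to_numpy()
                         & (mid >= r["start"]) & (mid < r["end"]))
            subset = probe_map[mask]
            run = _pick_probe_run(rng, probe_map, n_probes, taken, subset)
        else:
            run = _pick_probe_run(rng, probe_map, n_probes, taken)
        if run is None:
            raise ValueError("could not place DMR; genome too crowded")
        _mark_taken(taken, run)
        direction = str(directions[d])
        pid = probe_map["probe_id"].to_numpy()[run]
        if direction == "B73_hyper":
            states.loc[pid, "B73"] = True
            states.loc[pid, "Mo17"] = False
        else:
            states.loc[pid, "B73"] = False
            states.loc[pid, "Mo17"] = True
        chrom = probe_map["chrom"].iloc[run[0]]
        row = {"dmr_id": f"DMR{d:03d}", "chrom": chrom,
               "start": int(probe_map["start"].iloc[run[0]]),
               "end": int(probe_map["end"].iloc[run[-1]]),
               "direction": direction, "control": control,
               "probe_first": int(run[0]), "probe_last": int(run[-1]),
               "controller_chrom": None, "controller_start": np.nan,
               "controller_end": np.nan}
        dmr_rows.append(row)

    # second pass: trans controller loci, placed after all DMRs are known so
    # each controller stays unlinked — a different chromosome where possible
    # and never directly overlapping a DMR neighbourhood, so an introgression
    # covering a DMR can always be positioned to avoid the controller
    clearance = 5_000
    placed_controllers: list[tuple[str, int, int]] = []
    for row in dmr_rows:
        if row["control"] != "trans":
            continue
        others = [c for c in chrom_len if c != row["chrom"]] or [row["chrom"]]
        for _try in range(200):
            cchrom = others[int(rng.integers(0, len(others)))]
            cstart = int(rng.integers(0, chrom_len[cchrom]
                                      - params.controller_length))
            cend = cstart + params.controller_length
            clear_of_dmrs = all(r["chrom"] != cchrom
                                or cend <= r["start"] - clearance
                                or cstart >= r["end"] + clearance
                                for r in dmr_rows)
            clear_of_ctrls = all(c != cchrom
                                 or cend <= s - clearance
                                 or cstart >= e + clearance
                                 for c, s, e in placed_controllers)
            if clear_of_dmrs and clear_of_ctrls:
                break
        placed_controllers.append((cchrom, cstart, cend))
        row.update(controller_chrom=cchrom, controller_start=cstart,
                   controller_end=cend)
    dmr_cols = ["dmr_id", "chrom", "start", "end", "direction", "control",
                "probe_first", "probe_last", "controller_chrom",
                "controller_start", "controller_end"]
    dmrs = pd.DataFrame(dmr_rows, columns=dmr_cols)

    # CNV/PAV intervals: avoid DMR probes and IBD blocks (IBD = no structural
    # variation by definition)
    cnv_rows = []
    lo_c, hi_c = params.cnv_probe_range
    ibd_by_chrom = {c: list(zip(g["start"], g["end"]))
                    for c, g in ibd.groupby("chrom")} if len(ibd) else {}
    # both structural classes present (balanced), as in the real inbred pair
    cnv_classes = np.array(["M_gt_B", "M_lt_B_or_PAV"]
                           * (params.cnv_count // 2 + 1))[:params.cnv_count]
    rng.shuffle(cnv_classes)
    for k in range(params.cnv_count):
        for _try in range(200):
            n_probes = int(rng.integers(lo_c, hi_c + 1))
            run = _pick_probe_run(rng, probe_map, n_probes, taken)
            if run is None:
                break
            chrom = probe_map["chrom"].iloc[run[0]]
            s = int(probe_map["start"].iloc[run[0]])
            e = int(probe_map["end"].iloc[run[-1]])
            if any(s < ie and e > is_ for is_, ie in ibd_by_chrom.get(chrom, [])):
                continue
            _mark_taken(taken, run)
            cls = str(cnv_classes[k])
            cnv_rows.append({"cnv_id": f"CNV{k:03d}", "chrom": chrom,
                             "start": s, "end": e, "cnv_class": cls,
                             "probe_first": int(run[0]),
                             "probe_last": int(run[-1])})
            break
    cnvs = pd.DataFrame(cnv_rows, columns=["cnv_id", "chrom", "start", "end",
                                           "cnv_class", "probe_first",
                                           "probe_last"])

    # SNPs: Poisson background, depleted inside IBD, absent near pure DMRs
    snps: dict[str, np.ndarray] = {}
    for chrom, length in chrom_len.items():
        n_snps = rng.poisson(params.snp_rate * length)
        pos = np.sort(rng.integers(0, length, size=n_snps))
        keep = np.ones(len(pos), dtype=bool)
        for _, r in ibd[ibd["chrom"] == chrom].iterrows():
            inside = np.flatnonzero((pos >= r["start"]) & (pos < r["end"]))
            # fixed-count subsampling so the stated fold depletion holds as
            # an invariant of the truth set, not merely in expectation
            n_keep = max(1, int(round(len(inside) / params.ibd_snp_fold)))
            keep[inside] = False
            if len(inside):
                kept = rng.choice(inside, size=min(n_keep, len(inside)),
                                  replace=False)
                keep[kept] = True
        pure = dmrs[(dmrs["control"] == "pure_epiallele")
                    & (dmrs["chrom"] == chrom)]
        for _, r in pure.iterrows():
            keep &= ~((pos >= r["start"] - 1_000) & (pos < r["end"] + 1_000))
        snps[chrom] = pos[keep]

    return TruthSet(probe_states=states, dmr_intervals=dmrs,
                    cnv_intervals=cnvs, ibd_intervals=ibd, snp_positions=snps)


# ---------------------------------------------------------------------------
# array intensities
# ---------------------------------------------------------------------------

def simulate_arrays(truth: TruthSet, reference: tuple[SyntheticGenome, pd.DataFrame],
                    params: ArrayConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Simulate two-color array intensities on the log2 scale.

    Each (genotype, replicate) is one array carrying an IP channel (Cy5) and
    an input channel (Cy3). log2 intensity = baseline + copy-number term
    (both channels) + methylation term (IP only: +mu_meth for a methylated
    probe) + dye offset (Cy5) + per-array offset + N(0, sigma^2).
    """
    params = params or ArrayConfig()
    if params.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if params.sigma < 0:
        raise ValueError("sigma must be non-negative")
    _, probe_map = reference
    rng = substream(seed, "arrays")
    n = len(probe_map)

    # per-genotype copy term (B73 is the design reference)
    copy_term = {"B73": np.zeros(n), "Mo17": np.zeros(n)}
    for _, r in truth.cnv_intervals.iterrows():
        sl = slice(int(r["probe_first"]), int(r["probe_last"]) + 1)
        delta = params.cnv_gain if r["cnv_class"] == "M_gt_B" else params.pav_depth
        copy_term["Mo17"][sl] += delta

    meth = {g: truth.probe_states[g].to_numpy().astype(float)
            for g in ("B73", "Mo17")}

    frames = []
    probe_ids = probe_map["probe_id"].to_numpy()
    for g in ("B73", "Mo17"):
        for rep in range(1, params.n_reps + 1):
            array_id = f"{g}_r{rep}"
            arr_off = (rng.normal(0.0, params.array_effect)
                       if params.array_effect > 0 else 0.0)
            for channel, factor, dye in (("IP", f"{g}_IP", "Cy5"),
                                         ("input", f"{g}_input", "Cy3")):
                mu = params.baseline + copy_term[g] + arr_off
                if channel == "IP":
                    mu = mu + params.ip_offset + params.mu_meth * meth[g]
                    mu = mu + params.dye_effect
                noise = (rng.normal(0.0, params.sigma, size=n)
                         if params.sigma > 0 else 0.0)
                frames.append(pd.DataFrame({
                    "probe_id": probe_ids,
                    "sample_id": f"{factor}_r{rep}",
                    "factor": factor,
                    "replicate": rep,
                    "dye": dye,
                    "array": array_id,
                    "log2_intensity": mu + noise,
                }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# NIL panels
# ---------------------------------------------------------------------------

def _merge_intervals(ivs: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for c, s, e in sorted(ivs):
        if out and out[-1][0] == c and s <= out[-1][2]:
            out[-1] = (c, out[-1][1], max(out[-1][2], e))
        else:
            out.append((c, s, e))
    return out


def simulate_nil_panel(truth: TruthSet,
                       reference: tuple[SyntheticGenome, pd.DataFrame],
                       params: NILConfig | None = None, seed: int = 0
                       ) -> tuple[list[NILPanel], pd.DataFrame]:
    """Build NILs and their true methylation state at every DMR.

    Each DMR is guaranteed a handful of NILs with a donor introgression
    covering it (the informative genotypes). cis and pure-epiallele DMRs
    follow the local haplotype; trans DMRs follow the haplotype at their
    controller locus — so a NIL introgressed at the DMR but not the
    controller keeps the recurrent-parent state, and one introgressed at the
    controller only adopts the donor state. Control NILs (no introgression at
    the DMR) keep the recurrent-parent state, flipped at ``instability_rate``.
    """
    genome, _ = reference
    params = params or NILConfig()
    if params.n_nils < 1:
        raise ValueError("n_nils must be >= 1")
    rng = substream(seed, "nils")
    chrom_len = dict(genome.chromosomes)

    n_b73 = int(round(params.recurrent_b73_fraction * params.n_nils))
    recurrents = ["B73"] * n_b73 + ["Mo17"] * (params.n_nils - n_b73)
    segments: list[list[tuple[str, int, int]]] = [[] for _ in range(params.n_nils)]

    lo_len, hi_len = params.segment_length_range

    def random_segment(chrom: str, around: tuple[int, int] | None = None
                       ) -> tuple[str, int, int]:
        length = int(rng.integers(lo_len, hi_len))
        length = min(length, chrom_len[chrom] - 1)
        if around is not None:
            lo = max(0, around[1] - length)
            hi = min(chrom_len[chrom] - length, around[0])
            hi = max(hi, lo + 1)
            start = int(rng.integers(lo, hi))
        else:
            start = int(rng.integers(0, chrom_len[chrom] - length))
        return (chrom, start, start + length)

    dmrs = truth.dmr_intervals

    # Genotype selection discipline: a line chosen to probe a trans DMR must
    # not carry that DMR's controller (the study picked lines with
    # informative introgression configurations). ``forbidden`` records, per
    # NIL, the controller midpoints its future segments must avoid.
    forbidden: dict[int, list[tuple[str, float]]] = {}

    def allowed(i: int, seg: tuple[str, int, int]) -> bool:
        c, s, e = seg
        return all(cc != c or not (s <= m < e)
                   for cc, m in forbidden.get(i, ()))

    def covers(i: int, chrom: str, mid: float) -> bool:
        return any(c == chrom and s <= mid < e for c, s, e in segments[i])

    def add_segment(i: int, chrom: str,
                    around: tuple[int, int] | None) -> None:
        for _try in range(30):
            seg = random_segment(chrom, around)
            if allowed(i, seg):
                segments[i].append(seg)
                return

    # informative introgressions covering each DMR
    for _, dmr in dmrs.iterrows():
        k = int(rng.integers(params.nils_per_dmr[0], params.nils_per_dmr[1] + 1))
        is_trans = dmr["control"] == "trans"
        if is_trans:
            cchrom = dmr["controller_chrom"]
            cmid = (dmr["controller_start"] + dmr["controller_end"]) / 2.0
            candidates = [i for i in range(params.n_nils)
                          if not covers(i, cchrom, cmid)]
        else:
            candidates = list(range(params.n_nils))
        k = min(k, len(candidates))
        chosen = rng.choice(candidates, size=k, replace=False)
        if is_trans:
            for i in chosen:
                forbidden.setdefault(int(i), []).append((cchrom, cmid))
        for i in chosen:
            add_segment(int(i), dmr["chrom"],
                        (int(dmr["start"]), int(dmr["end"])))
        if is_trans:
            # one extra NIL introgressed at the controller locus only
            pool = [i for i in range(params.n_nils) if i not in chosen]
            if pool:
                i = pool[int(rng.integers(0, len(pool)))]
                add_segment(i, dmr["controller_chrom"],
                            (int(dmr["controller_start"]),
                             int(dmr["controller_end"])))

    # background segments
    chroms = list(chrom_len)
    for i in range(params.n_nils):
        for _ in range(int(rng.integers(params.background_segments[0],
                                        params.background_segments[1] + 1))):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            add_segment(i, chrom, None)

    nils = [NILPanel(nil_id=f"NIL{i:03d}", recurrent_parent=recurrents[i],
                     introgression_intervals=_merge_intervals(segments[i]))
            for i in range(params.n_nils)]

    # parental methylation state at each DMR (True = methylated)
    parent_state = {}
    for _, dmr in dmrs.iterrows():
        hyper = "B73" if dmr["direction"] == "B73_hyper" else "Mo17"
        parent_state[dmr["dmr_id"]] = {"B73": hyper == "B73",
                                       "Mo17": hyper == "Mo17"}

    rows = []
    for nil in nils:
        for _, dmr in dmrs.iterrows():
            mid = (dmr["start"] + dmr["end"]) / 2.0
            at_dmr = nil.carries_donor(dmr["chrom"], mid)
            local_hap = nil.donor if at_dmr else nil.recurrent_parent
            if dmr["control"] == "trans":
                cmid = (dmr["controller_start"] + dmr["controller_end"]) / 2.0
                at_ctrl = nil.carries_donor(dmr["controller_chrom"], cmid)
                deciding = nil.donor if at_ctrl else nil.recurrent_parent
            else:
                deciding = local_hap
            state = parent_state[dmr["dmr_id"]][deciding]
            if not at_dmr and params.instability_rate > 0:
                if rng.random() < params.instability_rate:
                    state = not state
            rows.append({"nil_id": nil.nil_id, "dmr_id": dmr["dmr_id"],
                         "introgressed_at_dmr": at_dmr,
                         "haplotype_at_dmr": local_hap,
                         "methylated": state})
    return nils, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(true_state_pair: dict[str, bool],
                  params: QpcrConfig | None = None, seed: int = 0,
                  assay_id: str = "assay") -> pd.DataFrame:
    """Simulate mock/digest Ct pairs for one assay across genotypes.

    Methylation-dependent enzymes (MspJI, FspEI) cut methylated template, so
    a methylated state raises the digest Ct by ``delta_ct`` over mock;
    methylation-sensitive enzymes (HpaII, PstI) cut unmethylated template, so
    the shift applies to the unmethylated state instead. Gaussian noise
    (``sigma_ct``) is added to every Ct independently.
    """
    params = params or QpcrConfig()
    if params.delta_ct <= 0:
        raise ValueError("delta_ct must be positive")
    enzyme = params.enzyme
    if enzyme in METHYLATION_DEPENDENT_ENZYMES:
        shift_if_methylated = True
    elif enzyme in METHYLATION_SENSITIVE_ENZYMES:
        shift_if_methylated = False
    else:
        raise ValueError(f"unknown enzyme: {enzyme!r}")
    rng = substream(seed, f"qpcr:{assay_id}:{enzyme}")
    rows = []
    for genotype, methylated in true_state_pair.items():
        mock = params.baseline_ct
        digest = params.baseline_ct
        if bool(methylated) == shift_if_methylated:
            digest += params.delta_ct
        if params.sigma_ct > 0:
            mock += rng.normal(0.0, params.sigma_ct)
            digest += rng.normal(0.0, params.sigma_ct)
        rows.append({"assay_id": assay_id, "genotype": genotype,
                     "enzyme": enzyme, "mock_ct": mock, "digest_ct": digest})
    return pd.DataFrame(rows)
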