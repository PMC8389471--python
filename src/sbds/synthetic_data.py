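"""Synthetic genomes, insertion cohorts, and RNA reads with ground truth.

The generator emulates the statistical structure the driver analysis
assumes, at desk scale:

* random genomes with a tunable GC fraction (controlling TA density) and
  uniformly placed, non-overlapping genes;
* per-genome insertion burdens drawn from a negative binomial whose
  default mean (1,320) and dispersion reproduce the heavy right tail of
  insertion counts in histologically normal SB-mobilized skin;
* uniform background targeting of TA sites, with a multiplicative rate
  elevation inside a donor-chromosome local-hopping window;
* subclonal read depths from a geometric distribution (mean 3) and
  clonal depths from a log-normal with median ten times the clonality
  cutoff, so planted clonal insertions sit far above the cutoff while
  normals keep (far) fewer than 1% of insertions above it;
* planted drivers: *activating* drivers receive sense-strand, clonal
  insertions clustered in a configurable 5' window of the gene;
  *inactivating* drivers receive clonal insertions on both strands
  across the gene body;
* optional RNA reads: background exon fragments plus motif-bearing
  fusion reads and fold-elevated expression for activated genes in
  carrier specimens.

Every simulation takes an explicit seed and emits a truth manifest
(planted sites, carriers, donor window, fusion reads) for recovery
testing. Chromosome sizes default to a scaled-down genome (5 x 1 Mb)
rather than a 2.5 Gb mammalian genome; burdens and rates are the
quantities of interest, not sequence realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .insertion_io import (
    GENE_COLUMNS,
    INSERTION_COLUMNS,
    GenomeModel,
    genome_model_from_arrays,
)

__all__ = [
    "GenomeConfig",
    "DriverSpec",
    "CohortConfig",
    "SimTruth",
    "simulate_genome_model",
    "simulate_cohort",
    "simulate_rna_reads",
    "write_fasta",
    "write_gene_bed",
]


@dataclass
class GenomeConfig:
    """Shape of the simulated genome."""

    n_chroms: int = 5
    chrom_length: int = 1_000_000
    gc_fraction: float = 0.42  # mouse-like base composition
    n_genes: int = 200
    gene_length: int = 10_000


@dataclass
class DriverSpec:
    """A planted driver gene."""

    gene_id: str
    mechanism: str  # activating | inactivating
    carrier_fraction: float = 0.7
    window: tuple[float, float] = (0.2, 0.4)  # activating cluster, relative coords
    sites_per_carrier: int = 1


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort."""

    n_tumors: int = 60
    n_normals: int = 32
    burden_mean: float = 1320.0  # normal-skin mean insertion events
    burden_dispersion: float = 3.5  # NB shape; reproduces the 1-3,857 range
    subclonal_depth_mean: float = 3.0  # geometric, support >= 1
    clonal_depth_cutoff: int = 300
    clonal_depth_sigma: float = 0.5  # log-normal sigma; median = 10 x cutoff
    tumor_clonal_background_fraction: float = 0.02  # passenger clonal expansions
    drivers: list[DriverSpec] = field(default_factory=list)
    donor_chrom: str | None = None
    donor_window: tuple[int, int] | None = None
    donor_fold: float = 10.0


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated tables."""

    drivers: list[dict] = field(default_factory=list)
    donor_chrom: str | None = None
    donor_window: tuple[int, int] | None = None
    fusion_reads: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    draw = bases[rng.choice(4, size=length, p=p)]
    return draw.tobytes().decode("ascii")


def simulate_genome_model(
    config: GenomeConfig, seed: int
) -> tuple[dict[str, str], pd.DataFrame, GenomeModel]:
    """Random genome + non-overlapping gene annotation + TA-site model.

    Deterministic for a fixed (config, seed). Raises when the requested
    genes cannot be placed without overlap.
    """
    rng = np.random.default_rng(seed)
    sequences = {
        f"chr{i + 1}": _random_sequence(rng, config.chrom_length, config.gc_fraction)
        for i in range(config.n_chroms)
    }
    total_len = config.n_chroms * config.chrom_length
    if config.n_genes * config.gene_length > 0.8 * total_len:
        raise ValueError("genes do not fit in the genome without crowding")
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chroms)
    rows = []
    for ci, idxs in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        n = len(idxs)
        if n == 0:
            continue
        # deterministic even spacing jittered within each slot keeps genes
        # non-overlapping without rejection sampling
        slot = config.chrom_length // max(n, 1)
        if slot <= config.gene_length:
            raise ValueError("genes do not fit on chromosome without overlap")
        jitter = rng.integers(0, slot - config.gene_length, size=n)
        for j, gi in enumerate(idxs):
            start = j * slot + int(jitter[j]) + 1
            end = start + config.gene_length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"g{gi:04d}", chrom, start, end, strand))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "gene_strand"]
    )
    model = genome_model_from_arrays(sequences, genes)
    if model.total_ta == 0:
        raise ValueError(
            "genome contains no TA sites (GC fraction too high); "
            "insertion statistics are undefined"
        )
    return sequences, model.genes[GENE_COLUMNS[:-1]].copy(), model


def _sample_burdens(
    rng: np.random.Generator, n: int, mean: float, dispersion: float
) -> np.ndarray:
    # negative binomial via gamma-Poisson mixture
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=n)
    return np.maximum(rng.poisson(lam), 1)


def _subclonal_depths(rng: np.random.Generator, n: int, mean: float) -> np.ndarray:
    return rng.geometric(1.0 / mean, size=n)


def _clonal_depths(
    rng: np.random.Generator, n: int, cutoff: int, sigma: float
) -> np.ndarray:
    median = 10.0 * cutoff
    return np.maximum(
        np.round(rng.lognormal(np.log(median), sigma, size=n)).astype(np.int64), 1
    )


def _site_weights(
    model: GenomeModel, cfg: CohortConfig
) -> tuple[list[str], np.ndarray, dict[str, np.ndarray | None]]:
    """Per-chromosome selection probabilities and (optional) cumulative
    within-chromosome TA-site weights for the donor local-hopping window."""
    chroms = list(model.ta_index)
    cum_weights: dict[str, np.ndarray | None] = {}
    totals = []
    for c in chroms:
        idx = model.ta_index[c]
        if (
            cfg.donor_chrom == c
            and cfg.donor_window is not None
            and cfg.donor_fold > 1
        ):
            lo, hi = cfg.donor_window
            w = np.ones(len(idx))
            w[(idx >= lo) & (idx <= hi)] = cfg.donor_fold
            cum_weights[c] = np.cumsum(w)
            totals.append(w.sum())
        else:
            cum_weights[c] = None
            totals.append(float(len(idx)))
    totals = np.array(totals)
    return chroms, totals / totals.sum(), cum_weights


def simulate_cohort(
    config: CohortConfig, model: GenomeModel, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate tumor and normal insertion tables plus the truth manifest.

    Background insertions target TA sites uniformly (donor window
    elevated multiplicatively); normals receive only subclonal depths;
    tumors additionally receive a small clonal passenger fraction and,
    in carrier specimens, the planted driver insertions at clonal
    depths.
    """
    rng = np.random.default_rng(seed)
    chroms, chrom_p, cum_weights = _site_weights(model, config)
    genes = model.genes.set_index("gene_id")

    def _background(specimen: str, n_sites: int, clonal_frac: float) -> pd.DataFrame:
        chosen_chrom = rng.choice(len(chroms), size=n_sites, p=chrom_p)
        clonal = rng.random(n_sites) < clonal_frac
        depth = _subclonal_depths(rng, n_sites, config.subclonal_depth_mean)
        if clonal.any():
            depth[clonal] = _clonal_depths(
                rng, int(clonal.sum()), config.clonal_depth_cutoff,
                config.clonal_depth_sigma,
            )
        pos = np.empty(n_sites, dtype=np.int64)
        for ci in np.unique(chosen_chrom):
            m = chosen_chrom == ci
            c = chroms[ci]
            idx = model.ta_index[c]
            cw = cum_weights[c]
            if cw is None:
                sel = rng.integers(0, len(idx), size=int(m.sum()))
            else:
                u = rng.random(int(m.sum())) * cw[-1]
                sel = np.searchsorted(cw, u, side="right")
            pos[m] = idx[sel]
        return pd.DataFrame(
            {
                "specimen_id": specimen,
                "chrom": np.array(chroms, dtype=object)[chosen_chrom],
                "pos": pos,
                "strand": np.where(rng.random(n_sites) < 0.5, "+", "-"),
                "read_count": depth.astype(np.int64),
            }
        )

    truth = SimTruth(
        donor_chrom=config.donor_chrom, donor_window=config.donor_window
    )
    tumor_frames: list[pd.DataFrame] = []
    normal_frames: list[pd.DataFrame] = []
    planted_rows: list[tuple] = []

    tumor_ids = [f"T{i + 1:03d}" for i in range(config.n_tumors)]
    normal_ids = [f"N{i + 1:03d}" for i in range(config.n_normals)]

    burdens_t = _sample_burdens(
        rng, config.n_tumors, config.burden_mean, config.burden_dispersion
    )
    burdens_n = _sample_burdens(
        rng, config.n_normals, config.burden_mean, config.burden_dispersion
    )
    for sid, b in zip(tumor_ids, burdens_t):
        tumor_frames.append(
            _background(sid, int(b), config.tumor_clonal_background_fraction)
        )
    for sid, b in zip(normal_ids, burdens_n):
        normal_frames.append(_background(sid, int(b), 0.0))

    for spec in config.drivers:
        if spec.gene_id not in genes.index:
            raise ValueError(f"planted driver {spec.gene_id!r} not in annotation")
        g = genes.loc[spec.gene_id]
        n_carriers = int(round(spec.carrier_fraction * config.n_tumors))
        carriers = list(rng.choice(tumor_ids, size=n_carriers, replace=False))
        gene_ta = model.ta_index[g.chrom]
        in_gene = gene_ta[(gene_ta >= g.start) & (gene_ta <= g.end)]
        if in_gene.size == 0:
            raise ValueError(f"gene {spec.gene_id!r} has no TA sites")
        planted = []
        for sid in carriers:
            depths = _clonal_depths(
                rng, spec.sites_per_carrier, config.clonal_depth_cutoff,
                config.clonal_depth_sigma,
            )
            for d in depths:
                if spec.mechanism == "activating":
                    lo = g.start + spec.window[0] * (g.end - g.start)
                    hi = g.start + spec.window[1] * (g.end - g.start)
                    if g.gene_strand == "-":
                        lo, hi = (
                            g.end - spec.window[1] * (g.end - g.start),
                            g.end - spec.window[0] * (g.end - g.start),
                        )
                    pool = in_gene[(in_gene >= lo) & (in_gene <= hi)]
                    if pool.size == 0:
                        pool = in_gene
                    strand = g.gene_strand  # sense
                else:
                    pool = in_gene
                    strand = "+" if rng.random() < 0.5 else "-"
                pos = int(pool[rng.integers(0, pool.size)])
                planted_rows.append((sid, g.chrom, pos, strand, int(d)))
                planted.append(
                    {"specimen_id": sid, "chrom": g.chrom, "pos": pos,
                     "strand": strand, "read_count": int(d)}
                )
        truth.drivers.append(
            {
                "gene_id": spec.gene_id,
                "mechanism": spec.mechanism,
                "carriers": sorted(carriers),
                "sites": planted,
            }
        )

    if planted_rows:
        tumor_frames.append(pd.DataFrame(planted_rows, columns=INSERTION_COLUMNS))
    tumors = (
        pd.concat(tumor_frames, ignore_index=True)
        if tumor_frames
        else pd.DataFrame(columns=INSERTION_COLUMNS)
    )
    normals = (
        pd.concat(normal_frames, ignore_index=True)
        if normal_frames
        else pd.DataFrame(columns=INSERTION_COLUMNS)
    )
    return tumors, normals, truth


DEFAULT_SD_MOTIF = "GTAAGTATCCGTCGACGATG"
DEFAULT_SA_MOTIF = "CATCGTCAGGTTTCTCTACG"


def simulate_rna_reads(
    transcriptome: dict[str, list[str]],
    truth: SimTruth,
    carriers_expression_fold: float = 150.0,
    n_background_reads: int = 450,
    n_fusion_reads_per_driver: int = 10,
    read_length: int = 60,
    k: int = 20,
    specimens: list[str] | None = None,
    motifs: dict[str, str] | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame, SimTruth]:
    """Emit RNA reads, an expression matrix, and the fusion manifest.

    Background reads are exact exon substrings (motif-free decoys).
    For every activating planted driver, carrier specimens emit
    ``n_fusion_reads_per_driver`` sense splice-donor fusion reads
    (motif + the first ``read_length - len(motif)`` bases of the planted
    junction exon); inactivating drivers emit splice-acceptor fusions.
    The expression matrix gives activated genes
    ``carriers_expression_fold`` times the baseline in carriers, exactly
    (noise-free construction). The returned truth object has its
    ``fusion_reads`` manifest filled in.
    """
    rng = np.random.default_rng(seed)
    if motifs is None:
        motifs = {
            "splice_donor": DEFAULT_SD_MOTIF,
            "splice_acceptor": DEFAULT_SA_MOTIF,
        }
    for name, motif in motifs.items():
        if read_length < len(motif) + k:
            raise ValueError(
                f"read_length {read_length} too short for motif {name!r} + k={k}"
            )
    genes = list(transcriptome)
    reads: list[tuple[str, str]] = []
    for i in range(n_background_reads):
        gene = genes[rng.integers(0, len(genes))]
        exons = transcriptome[gene]
        seq = exons[rng.integers(0, len(exons))]
        if len(seq) <= read_length:
            frag = seq
        else:
            at = rng.integers(0, len(seq) - read_length)
            frag = seq[at:at + read_length]
        reads.append((f"bg{i:05d}", frag))

    specimens = specimens or sorted(
        {c for d in truth.drivers for c in d["carriers"]}
    )
    n_read = 0
    for d in truth.drivers:
        gene = d["gene_id"]
        if gene not in transcriptome:
            continue
        exons = transcriptome[gene]
        junction_exon = min(1, len(exons) - 1)
        for _ in range(n_fusion_reads_per_driver):
            if d["mechanism"] == "activating":
                motif = motifs["splice_donor"]
                flank = exons[junction_exon][: read_length - len(motif)]
                seq = motif + flank
                element = "splice_donor"
            else:
                motif = motifs["splice_acceptor"]
                flank = exons[junction_exon][-(read_length - len(motif)):]
                seq = flank + motif
                element = "splice_acceptor"
            rid = f"fus{n_read:05d}"
            n_read += 1
            reads.append((rid, seq))
            truth.fusion_reads.append(
                {
                    "read_id": rid,
                    "gene_id": gene,
                    "element": element,
                    "junction_exon": junction_exon,
                    "orientation": "sense",
                }
            )

    baseline = 10.0
    expr = pd.DataFrame(
        baseline, index=pd.Index(specimens, name="specimen_id"), columns=genes
    )
    for d in truth.drivers:
        if d["mechanism"] != "activating" or d["gene_id"] not in expr.columns:
            continue
        carriers = [c for c in d["carriers"] if c in expr.index]
        expr.loc[carriers, d["gene_id"]] = baseline * carriers_expression_fold
    return reads, expr, truth


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_gene_bed(genes: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"] - 1,
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["gene_strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
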