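"""Candidate cancer driver statistics for SB insertional mutagenesis.

The null model: insertions land uniformly over the TA dinucleotides of
the genome. For a partition of the genome (donor chromosome vs the rest,
tested separately because SB local-hopping elevates the donor rate), the
background rate is

    lambda = (qualifying insertions in partition) / (TA sites in partition)

and a gene with t_g TA sites has expectation mu_g = lambda * t_g. The
per-gene p-value is the Poisson upper tail P(X >= k_g | mu_g) for the
observed k_g insertion sites. Driver tiers differ in the insertions they
consider and the multiple-testing control:

* discovery   — all insertions, Benjamini-Hochberg FDR, q < 0.5
* progression — all insertions, Holm FWER, adjusted p < 0.05
* trunk       — clonal insertions only (depth strictly above the cutoff,
                default 300 reads), Holm FWER, adjusted p < 0.05

A driver must additionally recur in at least ``min_tumors`` specimens
(default 3). The donor local-hopping window is detected from the data
(Poisson scan over fixed-width bins against the non-donor rate) and its
genes are censored from the tested set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .insertion_io import GenomeModel

__all__ = [
    "DriverConfig",
    "DonorWindow",
    "donor_hotspot_region",
    "gene_insertion_stats",
    "call_drivers",
    "classify_orientation",
    "ExclusivityResult",
    "mutual_exclusivity_test",
]


@dataclass
class DriverConfig:
    """Configuration of a driver-calling run."""

    mode: str = "discovery"  # discovery | progression | trunk
    min_tumors: int = 3
    depth_cutoff: int = 300  # trunk mode: qualifying depth, strict '>'
    discovery_q_max: float = 0.5
    fwer_alpha: float = 0.05
    fwer_method: str = "holm"  # or "bonferroni"
    donor_chrom: str | None = None
    donor_exclusion: tuple[int, int] | None = None  # (start, end) bp on donor
    upstream_pad: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("discovery", "progression", "trunk"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.min_tumors < 1:
            raise ValueError("min_tumors must be >= 1")
        for name in ("discovery_q_max", "fwer_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class DonorWindow:
    """Local-hopping window on the donor chromosome."""

    chrom: str
    start: int | None  # 1-based inclusive; None when no elevated window
    end: int | None
    excluded_genes: list[str] = field(default_factory=list)
    bin_edges: np.ndarray | None = None
    fold_over_background: np.ndarray | None = None

    @property
    def empty(self) -> bool:
        return self.start is None


def donor_hotspot_region(
    table: pd.DataFrame,
    model: GenomeModel,
    donor_chrom: str,
    bin_bp: int = 1_000_000,
    alpha: float = 0.05,
) -> DonorWindow:
    """Detect the donor-chromosome local-hopping window.

    The donor chromosome is scanned in fixed ``bin_bp`` bins. Each bin's
    insertion count is tested against a Poisson expectation lambda0 * TA,
    where lambda0 is the insertions-per-TA rate over all non-donor
    chromosomes. Bins significant after Bonferroni correction (upper tail
    p * n_bins < alpha) are elevated; the reported window is the longest
    run of contiguous elevated bins (leftmost on ties). Genes overlapping
    the window are listed for censoring.
    """
    if donor_chrom not in model.chrom_lengths:
        raise ValueError(f"donor chromosome {donor_chrom!r} not in genome model")
    if not (table["chrom"] == donor_chrom).any():
        raise ValueError(f"no insertions on donor chromosome {donor_chrom!r}")

    length = model.chrom_lengths[donor_chrom]
    edges = np.arange(0, length + bin_bp, bin_bp, dtype=np.int64)
    edges[-1] = max(edges[-1], length)
    n_bins = len(edges) - 1

    donor_pos = table.loc[table["chrom"] == donor_chrom, "pos"].to_numpy()
    counts, _ = np.histogram(donor_pos, bins=edges + 0.5)  # pos in (e_i, e_{i+1}]
    ta_idx = model.ta_index.get(donor_chrom, np.empty(0, dtype=np.int64))
    ta_per_bin = np.diff(np.searchsorted(ta_idx, edges, side="right"))

    off_mask = table["chrom"] != donor_chrom
    off_ins = int(off_mask.sum())
    off_ta = sum(
        len(v) for c, v in model.ta_index.items() if c != donor_chrom
    )
    if off_ta == 0 or off_ins == 0:
        raise ValueError("no non-donor background to estimate the hopping rate")
    lam0 = off_ins / off_ta

    mu = lam0 * ta_per_bin
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(ta_per_bin > 0, counts / np.maximum(ta_per_bin, 1), 0.0)
        fold = rate / lam0
    pvals = np.where(mu > 0, stats.poisson.sf(counts - 1, np.maximum(mu, 1e-300)), 1.0)
    sig = np.minimum(pvals * n_bins, 1.0) < alpha

    best_len, best_start = 0, -1
    i = 0
    while i < n_bins:
        if sig[i]:
            j = i
            while j + 1 < n_bins and sig[j + 1]:
                j += 1
            if j - i + 1 > best_len:
                best_len, best_start = j - i + 1, i
            i = j + 1
        else:
            i += 1

    if best_len == 0:
        return DonorWindow(donor_chrom, None, None, [], edges, fold)

    start = int(edges[best_start]) + 1
    end = int(edges[best_start + best_len])
    genes = model.genes
    mask = (
        (genes["chrom"] == donor_chrom)
        & (genes["start"] <= end)
        & (genes["end"] >= start)
    )
    return DonorWindow(
        donor_chrom, start, end, sorted(genes.loc[mask, "gene_id"]), edges, fold
    )


def _qualifying(annotated: pd.DataFrame, config: DriverConfig) -> pd.DataFrame:
    if config.mode == "trunk":
        return annotated[annotated["read_count"] > config.depth_cutoff]
    return annotated


def _excluded_gene_ids(model: GenomeModel, config: DriverConfig) -> set[str]:
    if config.donor_chrom is None or config.donor_exclusion is None:
        return set()
    start, end = config.donor_exclusion
    g = model.genes
    mask = (
        (g["chrom"] == config.donor_chrom)
        & (g["start"] <= end)
        & (g["end"] >= start)
    )
    return set(g.loc[mask, "gene_id"])


def gene_insertion_stats(
    annotated: pd.DataFrame, model: GenomeModel, config: DriverConfig
) -> pd.DataFrame:
    """Per-gene insertion counts and background expectations.

    Returns one row per (non-censored) gene with k_g (qualifying
    insertion sites in the gene), n_tumors_g (specimens contributing at
    least one), t_g (TA sites), expected_mu, and the background
    partition ('donor' / 'non-donor', or 'all' without a donor
    chromosome). Genes with zero insertions are included with k_g = 0.
    """
    qual = _qualifying(annotated, config)
    excluded = _excluded_gene_ids(model, config)

    genes = model.genes[~model.genes["gene_id"].isin(excluded)].copy()
    donor = config.donor_chrom
    if donor is None:
        genes["chrom_partition"] = "all"
    else:
        genes["chrom_partition"] = np.where(
            genes["chrom"] == donor, "donor", "non-donor"
        )

    # partition background: unique qualifying sites / TA sites, genome-wide
    sites = qual.drop_duplicates(["specimen_id", "chrom", "pos"])
    ta_per_chrom = {c: len(v) for c, v in model.ta_index.items()}
    if donor is None:
        part_ins = {"all": len(sites)}
        part_ta = {"all": sum(ta_per_chrom.values())}
    else:
        on_donor = sites["chrom"] == donor
        part_ins = {
            "donor": int(on_donor.sum()),
            "non-donor": int((~on_donor).sum()),
        }
        part_ta = {
            "donor": ta_per_chrom.get(donor, 0),
            "non-donor": sum(v for c, v in ta_per_chrom.items() if c != donor),
        }

    genic = qual[qual["gene_id"].notna() & ~qual["gene_id"].isin(excluded)]
    k = genic.groupby("gene_id").size()
    n_tum = genic.groupby("gene_id")["specimen_id"].nunique()

    out = genes.copy()
    out["k_g"] = out["gene_id"].map(k).fillna(0).astype(int)
    out["n_tumors_g"] = out["gene_id"].map(n_tum).fillna(0).astype(int)
    lam = out["chrom_partition"].map(
        lambda p: part_ins[p] / part_ta[p] if part_ta[p] > 0 else np.nan
    )
    out["expected_mu"] = lam * out["ta_count"]
    return out[
        [
            "gene_id", "chrom", "chrom_partition", "k_g", "n_tumors_g",
            "ta_count", "expected_mu",
        ]
    ].rename(columns={"ta_count": "t_g"}).reset_index(drop=True)


def call_drivers(stats_df: pd.DataFrame, config: DriverConfig) -> pd.DataFrame:
    """Call drivers from per-gene stats with partition-wise adjustment.

    p = Poisson upper tail P(X >= k_g | expected_mu); genes with t_g = 0
    receive p = 1 (untestable under the TA null). Discovery mode adjusts
    with Benjamini-Hochberg within each partition (significant iff
    q < discovery_q_max); progression/trunk use Holm (or Bonferroni via
    config) at fwer_alpha. The recurrence filter n_tumors_g >= min_tumors
    is applied after adjustment. Partitions are merged, deduplicating
    genes by keeping the smaller adjusted p; the result is sorted by
    (adj_p, -k_g, gene_id).
    """
    if stats_df.empty:
        return pd.DataFrame(
            columns=[
                "gene_id", "chrom", "chrom_partition", "mode", "k_g",
                "n_tumors_g", "t_g", "expected_mu", "p_value", "adj_p",
                "significant",
            ]
        )
    df = stats_df.copy()
    mu = df["expected_mu"].to_numpy(dtype=float)
    k = df["k_g"].to_numpy(dtype=np.int64)
    p = np.ones(len(df))
    testable = (df["t_g"].to_numpy() > 0) & np.isfinite(mu)
    p[testable] = stats.poisson.sf(k[testable] - 1, mu[testable])
    p = np.clip(p, 0.0, 1.0)
    df["p_value"] = p
    df["mode"] = config.mode

    method = "fdr_bh" if config.mode == "discovery" else config.fwer_method
    threshold = (
        config.discovery_q_max if config.mode == "discovery" else config.fwer_alpha
    )
    adj = np.ones(len(df))
    for _, idx in df.groupby("chrom_partition").groups.items():
        loc = df.index.get_indexer(idx)
        adj[loc] = multipletests(p[loc], method=method)[1]
    df["adj_p"] = adj
    df["significant"] = (df["adj_p"] < threshold) & (
        df["n_tumors_g"] >= config.min_tumors
    )

    df = df.sort_values("adj_p").drop_duplicates("gene_id", keep="first")
    df = df.sort_values(
        ["adj_p", "k_g", "gene_id"], ascending=[True, False, True], kind="mergesort"
    )
    cols = [
        "gene_id", "chrom", "chrom_partition", "mode", "k_g", "n_tumors_g",
        "t_g", "expected_mu", "p_value", "adj_p", "significant",
    ]
    return df[cols].reset_index(drop=True)


def classify_orientation(
    gene_insertions: pd.DataFrame,
    min_sites: int = 3,
    orientation_alpha: float = 0.05,
    cluster_iqr: float = 0.5,
) -> str:
    """Classify a driver's insertion pattern.

    Activating drivers show a significant sense-strand excess (two-sided
    exact binomial test against 0.5) together with positional clustering
    (IQR of the relative position along the gene < ``cluster_iqr``), the
    promoter-fusion pattern that truncates and activates oncogenes.
    Dispersed insertions (IQR >= cluster_iqr) or a significant antisense
    excess indicate gene inactivation; anything else (including fewer
    than ``min_sites`` insertions) is indeterminate.
    """
    genic = gene_insertions[
        gene_insertions["relative_orientation"].isin(["sense", "antisense"])
    ]
    n = len(genic)
    if n < min_sites:
        return "indeterminate"
    n_sense = int((genic["relative_orientation"] == "sense").sum())
    p_orient = stats.binomtest(n_sense, n, 0.5).pvalue
    sig = p_orient < orientation_alpha
    sense_excess = sig and n_sense * 2 > n
    antisense_excess = sig and n_sense * 2 < n
    relpos = genic["relative_position"].to_numpy(dtype=float)
    iqr = float(np.percentile(relpos, 75) - np.percentile(relpos, 25))
    # strict boundary up to float epsilon: an IQR at the threshold is dispersed
    clustered = iqr < cluster_iqr - 1e-9
    if sense_excess and clustered:
        return "activating"
    if antisense_excess or not clustered:
        return "inactivating"
    return "indeterminate"


# ---------------------------------------------------------------------------
# mutual exclusivity


@njit(cache=True)
def _swap_chain(mat, per_sample, ia, ib, out, seed):
    """Checkerboard-swap Markov chain; records the (ia, ib) column overlap."""
    np.random.seed(seed)
    n_rows, n_cols = mat.shape
    for t in range(out.shape[0]):
        for _ in range(per_sample):
            r1 = np.random.randint(0, n_rows)
            r2 = np.random.randint(0, n_rows)
            c1 = np.random.randint(0, n_cols)
            c2 = np.random.randint(0, n_cols)
            a = mat[r1, c1]
            if (
                a != mat[r1, c2]
                and a == mat[r2, c2]
                and mat[r1, c2] == mat[r2, c1]
            ):
                mat[r1, c1] = 1 - a
                mat[r2, c2] = 1 - a
                mat[r1, c2] = a
                mat[r2, c1] = a
        ov = 0
        for r in range(n_rows):
            ov += mat[r, ia] * mat[r, ib]
        out[t] = ov
    return out


@dataclass(frozen=True)
class ExclusivityResult:
    """Outcome of a pairwise mutual-exclusivity permutation test."""

    gene_a: str
    gene_b: str
    observed_overlap: int
    p_value: float
    combined_carrier_fraction: float
    n_perm: int
    null_mean_overlap: float
    degenerate: bool


def mutual_exclusivity_test(
    alterations: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    n_perm: int = 10_000,
    seed: int | None = None,
    null: str = "swap",
) -> ExclusivityResult:
    """Test whether two genes are altered in fewer common specimens than
    expected.

    ``alterations`` is a binary specimen x gene matrix. The statistic is
    the number of specimens altered in both genes; small values indicate
    exclusivity and the p-value is the lower tail
    p = (1 + #{null overlap <= observed}) / (1 + n_perm).

    Two null models:

    * ``"swap"`` — checkerboard swaps over the whole matrix, preserving
      per-specimen alteration burdens (row sums) and per-gene frequencies
      (column sums); 10 x (number of ones) swaps between recorded
      matrices. Appropriate when the matrix carries the cohort's full
      alteration landscape.
    * ``"permute"`` — each gene's carrier set is independently permuted
      across specimens (column sums preserved); the overlap null is then
      exactly hypergeometric. Appropriate for an isolated pair.

    Degenerate margins (a gene altered in no or all specimens) yield a
    flagged result with p = NaN.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    mat = alterations.astype(bool)
    n = len(mat)
    ca, cb = int(mat[gene_a].sum()), int(mat[gene_b].sum())
    observed = int((mat[gene_a] & mat[gene_b]).sum())
    carrier = float((mat[gene_a] | mat[gene_b]).mean())
    if ca in (0, n) or cb in (0, n):
        return ExclusivityResult(
            gene_a, gene_b, observed, np.nan, carrier, n_perm, np.nan, True
        )
    rng = np.random.default_rng(seed)
    if null == "permute":
        hits = 0
        total = 0.0
        for _ in range(n_perm):
            pa = rng.permutation(n) < ca
            pb = rng.permutation(n) < cb
            ov = int(np.sum(pa & pb))
            hits += ov <= observed
            total += ov
        p = (1 + hits) / (1 + n_perm)
        return ExclusivityResult(
            gene_a, gene_b, observed, p, carrier, n_perm, total / n_perm, False
        )
    if null != "swap":
        raise ValueError(f"unknown null {null!r}")
    arr = mat.to_numpy(dtype=np.int8).copy()
    n_ones = int(arr.sum())
    per_sample = 10 * n_ones
    ia = int(mat.columns.get_loc(gene_a))
    ib = int(mat.columns.get_loc(gene_b))
    out = np.zeros(n_perm, dtype=np.int64)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    _swap_chain(arr, per_sample, ia, ib, out, kernel_seed)
    hits = int(np.sum(out <= observed))
    p = (1 + hits) / (1 + n_perm)
    return ExclusivityResult(
        gene_a, gene_b, observed, p, carrier, n_perm, float(out.mean()), False
    )
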