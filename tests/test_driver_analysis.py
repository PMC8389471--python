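"""Driver statistics: Poisson null, multiplicity control, donor window,
orientation classes, and mutual exclusivity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, poisson

from sbds import (
    DriverConfig,
    assign_insertions_to_genes,
    call_drivers,
    classify_orientation,
    collapse_to_sites,
    donor_hotspot_region,
    gene_insertion_stats,
    genome_model_from_arrays,
    mutual_exclusivity_test,
)
from sbds.insertion_io import INSERTION_COLUMNS


# --- independent oracles (tests/oracles.py) --------------------------------

from oracles import bh_oracle, holm_oracle, poisson_upper_tail_oracle


# --- Poisson tail / adjustments vs oracles ---------------------------------

def test_poisson_tail_example_mu1_k5():
    # P(X >= 5 | mu = 1) = 1 - e^{-1}(1 + 1 + 1/2 + 1/6 + 1/24)
    oracle = poisson_upper_tail_oracle(5, 1.0)
    assert oracle == pytest.approx(3.6598468273437131e-03, rel=1e-10)
    assert abs(float(poisson.sf(4, 1.0)) - oracle) < 1e-12


def test_poisson_tail_matches_summation_oracle_on_grid():
    rng = np.random.default_rng(5)
    mus = rng.uniform(0.05, 30.0, size=100)
    ks = rng.integers(0, 60, size=100)
    for mu, k in zip(mus, ks):
        assert abs(float(poisson.sf(k - 1, mu)) - poisson_upper_tail_oracle(int(k), float(mu))) < 1e-12


def test_bh_and_holm_match_brute_force_oracles():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(9)
    for n in (1, 2, 10, 100):
        p = rng.uniform(0, 1, size=n)
        p[: n // 3] = rng.uniform(0, 0.01, size=n // 3)  # some small values
        assert np.max(np.abs(multipletests(p, method="fdr_bh")[1] - bh_oracle(p))) < 1e-12
        assert np.max(np.abs(multipletests(p, method="holm")[1] - holm_oracle(p))) < 1e-12


# --- gene stats ------------------------------------------------------------

def _annotate(table, model):
    return assign_insertions_to_genes(collapse_to_sites(table), model)


def test_expected_mu_arithmetic(tiny_model):
    # 4 qualifying sites genome-wide, 5 TA total; plusG has 2 TA
    t = pd.DataFrame(
        [
            ("s1", "chrA", 3, "+", 10),
            ("s1", "chrA", 11, "+", 10),
            ("s2", "chrA", 7, "-", 10),
            ("s2", "chrB", 4, "+", 10),
        ],
        columns=INSERTION_COLUMNS,
    )
    stats = gene_insertion_stats(_annotate(t, tiny_model), tiny_model, DriverConfig())
    row = stats.set_index("gene_id").loc["plusG"]
    assert row["expected_mu"] == pytest.approx(4 / 5 * 2)
    assert row["k_g"] == 2
    assert row["n_tumors_g"] == 2


def test_zero_insertion_gene_gets_p_one(tiny_model):
    t = pd.DataFrame([("s1", "chrB", 4, "+", 1)], columns=INSERTION_COLUMNS)
    stats = gene_insertion_stats(_annotate(t, tiny_model), tiny_model, DriverConfig())
    res = call_drivers(stats, DriverConfig()).set_index("gene_id")
    assert res.loc["plusG", "k_g"] == 0
    assert res.loc["plusG", "p_value"] == 1.0
    assert not res["significant"].any()
    assert (stats.set_index("gene_id")["expected_mu"] > 0).all()


def test_gene_tallies_match_brute_force(sim_model, sim_cohort):
    tumors, _, _ = sim_cohort
    table = collapse_to_sites(tumors)
    ann = assign_insertions_to_genes(table, sim_model)
    cfg = DriverConfig(mode="trunk", depth_cutoff=300)
    stats = gene_insertion_stats(ann, sim_model, cfg).set_index("gene_id")
    genes = sim_model.genes
    for g in genes.itertuples():
        sub = table[
            (table["chrom"] == g.chrom)
            & (table["pos"] >= g.start)
            & (table["pos"] <= g.end)
            & (table["read_count"] > 300)
        ]
        assert stats.loc[g.gene_id, "k_g"] == len(sub)
        assert stats.loc[g.gene_id, "n_tumors_g"] == sub["specimen_id"].nunique()


def test_recurrence_filter_applies_after_adjustment():
    stats = pd.DataFrame(
        {
            "gene_id": ["a", "b"],
            "chrom": ["chr1", "chr1"],
            "chrom_partition": ["all", "all"],
            "k_g": [30, 30],
            "n_tumors_g": [5, 2],  # b fails the >= 3 tumors filter
            "t_g": [10, 10],
            "expected_mu": [1.0, 1.0],
        }
    )
    res = call_drivers(stats, DriverConfig(mode="trunk")).set_index("gene_id")
    assert bool(res.loc["a", "significant"])
    assert not bool(res.loc["b", "significant"])
    # identical statistics -> identical adjusted p; only recurrence differs
    assert res.loc["a", "adj_p"] == res.loc["b", "adj_p"]


# --- donor window ----------------------------------------------------------

def _uniform_table(rng, model, n, chrom_p=None):
    chroms = list(model.ta_index)
    p = chrom_p or [len(model.ta_index[c]) for c in chroms]
    p = np.asarray(p, dtype=float) / np.sum(p)
    rows = []
    for ci in rng.choice(len(chroms), size=n, p=p):
        c = chroms[ci]
        idx = model.ta_index[c]
        rows.append(("s1", c, int(idx[rng.integers(0, len(idx))]), "+", 1))
    return pd.DataFrame(rows, columns=INSERTION_COLUMNS)


def test_uniform_insertions_yield_empty_window(sim_model):
    rng = np.random.default_rng(17)
    t = _uniform_table(rng, sim_model, 3000)
    win = donor_hotspot_region(t, sim_model, "chr1", bin_bp=10_000)
    assert win.empty
    assert win.excluded_genes == []


def test_synthetic_spike_recovered_exactly(sim_model):
    # 10x elevation confined to bins 5-8 (0-based) of twenty 10 kb bins
    rng = np.random.default_rng(31)
    t = _uniform_table(rng, sim_model, 4000)
    idx = sim_model.ta_index["chr1"]
    lo, hi = 50_001, 90_000  # bins 5, 6, 7, 8
    spike_sites = idx[(idx >= lo) & (idx <= hi)]
    extra = pd.DataFrame(
        [
            ("s1", "chr1", int(spike_sites[rng.integers(0, len(spike_sites))]), "+", 1)
            for _ in range(2000)
        ],
        columns=INSERTION_COLUMNS,
    )
    win = donor_hotspot_region(
        pd.concat([t, extra], ignore_index=True), sim_model, "chr1", bin_bp=10_000
    )
    assert (win.start, win.end) == (50_001, 90_000)
    genes = sim_model.genes
    expect = set(
        genes.loc[
            (genes["chrom"] == "chr1")
            & (genes["start"] <= win.end)
            & (genes["end"] >= win.start),
            "gene_id",
        ]
    )
    assert set(win.excluded_genes) == expect


def test_donor_chrom_absent_from_data_raises(sim_model):
    t = pd.DataFrame([("s1", "chr2", 11, "+", 1)], columns=INSERTION_COLUMNS)
    with pytest.raises(ValueError, match="chr1"):
        donor_hotspot_region(t, sim_model, "chr1")


# --- orientation classification --------------------------------------------

def _gene_insertions(orients, relpos):
    return pd.DataFrame(
        {
            "relative_orientation": orients,
            "relative_position": relpos,
        }
    )


def test_clustered_sense_insertions_are_activating():
    # two-sided exact binomial p for 10/10 sense = 2 * (1/2)^10
    ins = _gene_insertions(["sense"] * 10, np.linspace(0.30, 0.35, 10))
    assert classify_orientation(ins) == "activating"
    from scipy.stats import binomtest

    assert binomtest(10, 10, 0.5).pvalue == pytest.approx(2 * 0.5**10)


def test_dispersed_unbiased_insertions_are_inactivating():
    # uniform spread over the gene body: IQR = 0.5, the dispersion boundary
    ins = _gene_insertions(
        ["sense"] * 5 + ["antisense"] * 5, np.linspace(0.0, 1.0, 10)
    )
    assert classify_orientation(ins) == "inactivating"


def test_antisense_excess_is_inactivating_even_when_clustered():
    ins = _gene_insertions(["antisense"] * 12, np.linspace(0.4, 0.45, 12))
    assert classify_orientation(ins) == "inactivating"


def test_below_min_sites_is_indeterminate():
    ins = _gene_insertions(["sense", "sense"], [0.3, 0.31])
    assert classify_orientation(ins, min_sites=3) == "indeterminate"


# --- mutual exclusivity ----------------------------------------------------

def _pair_matrix(rng, n=24, n_decoys=40, ca=12, cb=12, overlap=3):
    mat = pd.DataFrame(
        rng.random((n, n_decoys)) < 0.4,
        index=[f"s{i}" for i in range(n)],
        columns=[f"d{i}" for i in range(n_decoys)],
    )
    a = np.zeros(n, bool)
    a[:ca] = True
    b = np.zeros(n, bool)
    b[ca - overlap : ca - overlap + cb] = True
    mat["ga"], mat["gb"] = a, b
    return mat


def test_permutation_null_matches_hypergeometric_enumeration():
    rng = np.random.default_rng(2)
    mat = _pair_matrix(rng)
    res = mutual_exclusivity_test(mat, "ga", "gb", n_perm=10_000, seed=4, null="permute")
    p_oracle = float(hypergeom.cdf(res.observed_overlap, 24, 12, 12))
    mc_sd = math.sqrt(p_oracle * (1 - p_oracle) / 10_000)
    assert abs(res.p_value - p_oracle) < 3 * mc_sd + 2e-4
    assert res.observed_overlap == 3


def test_swap_null_preserves_margins_and_mixes():
    rng = np.random.default_rng(3)
    mat = _pair_matrix(rng)
    res = mutual_exclusivity_test(mat, "ga", "gb", n_perm=1_000, seed=8, null="swap")
    # null overlap must move off the observed value (the chain mixes)
    assert res.null_mean_overlap > res.observed_overlap
    assert 0 < res.p_value < 1


def test_degenerate_margin_is_flagged():
    rng = np.random.default_rng(4)
    mat = _pair_matrix(rng)
    mat["gb"] = False
    res = mutual_exclusivity_test(mat, "ga", "gb", n_perm=1_000, seed=1)
    assert res.degenerate
    assert np.isnan(res.p_value)


def test_reports_combined_carrier_fraction():
    rng = np.random.default_rng(6)
    mat = _pair_matrix(rng, overlap=0)
    res = mutual_exclusivity_test(mat, "ga", "gb", n_perm=1_000, seed=2, null="permute")
    assert res.combined_carrier_fraction == pytest.approx(1.0)
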