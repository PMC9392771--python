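"""UTR filtering, seed-site scanning and regulon enrichment."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from diffstab import (
    RegulonEnrichmentModel,
    build_site_matrix,
    enrichment_glm,
    filter_single_utr_genes,
    regulon_activity,
    scan_sites,
    simulate_regulon,
)
from diffstab.regulon import RegulonError, SiteMatrix


# ---------------------------------------------------------------------------
# single-UTR filter

def test_single_utr_filter_rules():
    ann = pd.DataFrame({
        "gene_id":       ["a", "a", "a", "b", "b", "c"],
        "isoform_id":    ["a1", "a2", "a3", "b1", "b2", "c1"],
        "utr_id":        ["uA", "uA", "uA", "uB1", "uB2", "uC"],
        "utr_exon_count": [1, 1, 1, 1, 1, 2],
    })
    keep = filter_single_utr_genes(ann)
    assert keep == {"a"}  # b: two UTRs; c: multi-exon UTR


def test_single_utr_filter_rejects_malformed():
    with pytest.raises(RegulonError):
        filter_single_utr_genes(pd.DataFrame())


# ---------------------------------------------------------------------------
# seed-site scanning

def test_scan_single_match_and_window_boundary():
    site = "ACGTACGT"
    seq = "T" * 9 + site + "T" * 50
    assert scan_sites(seq, site) == 1  # starts at 1-based position 10
    # a site starting beyond the 2000-nt window does not count
    far = "T" * 2000 + site
    assert scan_sites(far, site) == 0
    # last permissible start: 1-based 1993 (site ends exactly at 2000)
    edge = "T" * 1992 + site + "T" * 100
    assert scan_sites(edge, site) == 1
    over = "T" * 1993 + site + "T" * 100
    assert scan_sites(over, site) == 0


def test_scan_overlapping_matches_counted():
    assert scan_sites("AAAAAAAAAA", "AAAAAAAA") == 3


def test_scan_normalizes_u_and_validates():
    assert scan_sites("ACGUACGUACGU", "ACGUACGU") == 2  # RNA input, overlap at 5
    with pytest.raises(RegulonError):
        scan_sites("ACGT", "ACGTACG")  # wrong length
    with pytest.raises(RegulonError):
        scan_sites("ACGT" * 10, "ACGTNCGT")  # ambiguity code


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(20, 200))
def test_scan_matches_regex_enumeration(seed, length):
    r = np.random.default_rng(seed)
    seq = "".join(r.choice(list("ACGT"), size=length))
    site = "".join(r.choice(list("ACG"), size=8))  # low-entropy to force hits
    window = 100
    expected = len(re.findall(f"(?={site})", seq[:window]))
    assert scan_sites(seq, site, max_downstream=window) == expected


# ---------------------------------------------------------------------------
# site-matrix assembly

def test_site_matrix_assembly_and_totals():
    utrs = {"g1": "AAAAAAAAA" + "CCGGCCGG", "g2": "CCGGCCGG" + "T" * 20}
    factors = pd.DataFrame({
        "factor_id": ["A", "B"],
        "site_sequence": ["AAAAAAAA", "CCGGCCGG"],
    })
    sm_ = build_site_matrix(utrs=utrs, factor_sites=factors)
    assert sm_.counts.loc["g1", "A"] == 2  # overlapping poly-A matches
    assert sm_.counts.loc["g1", "B"] == 1
    assert sm_.counts.loc["g2", "A"] == 0
    np.testing.assert_array_equal(sm_.totals.to_numpy(),
                                  sm_.counts.sum(axis=1).to_numpy())


def test_site_matrix_drops_all_zero_factor():
    pre = pd.DataFrame({"A": [2, 1], "B": [0, 0]},
                       index=pd.Index(["g1", "g2"], name="gene_id"))
    sm_ = build_site_matrix(precomputed=pre)
    assert list(sm_.counts.columns) == ["A"]


def test_site_matrix_binarize_collapses_multiplicity():
    pre = pd.DataFrame({"A": [3, 0], "B": [1, 2]},
                       index=pd.Index(["g1", "g2"], name="gene_id"))
    sm_ = build_site_matrix(precomputed=pre, binarize=True)
    np.testing.assert_array_equal(sm_.counts.to_numpy(), [[1, 1], [0, 1]])
    np.testing.assert_array_equal(sm_.totals.to_numpy(), [2, 1])


# ---------------------------------------------------------------------------
# enrichment GLM

def test_enrichment_null_proportions():
    status = np.array([-1, 0, 1] * 200)
    totals = np.full(600, 50)
    succ = np.full(600, 5)  # identical share in every class
    coef, se, p = enrichment_glm(succ, totals, status)
    assert abs(coef) < 1e-6 and p > 0.99


def test_enrichment_recovers_closed_form_log_odds():
    """Odds 0.10 at status 0 vs 0.20 at status +1 gives slope log 2."""
    status = np.repeat([0, 1], 500)
    totals = np.full(1000, 4000)
    odds = np.where(status == 0, 0.10, 0.20)
    pi = odds / (1 + odds)
    succ = np.rint(totals * pi).astype(int)
    coef, se, p = enrichment_glm(succ, totals, status)
    assert coef == pytest.approx(np.log(2.0), abs=0.01)


def test_enrichment_degenerate_inputs():
    with pytest.raises(RegulonError):
        enrichment_glm([1, 2], [5, 5], [1, 1])  # single status level
    coef, se, p = enrichment_glm([0, 0], [5, 5], [0, 1])  # all-zero successes
    assert not np.isfinite(se)


def test_fisher_collapse_sign_concordance(rng):
    """On two-level status the GLM slope sign equals the 2x2 log-odds sign."""
    for _ in range(25):
        status = rng.integers(0, 2, size=300)
        totals = rng.poisson(20, size=300) + 1
        pi = np.where(status == 1, rng.uniform(0.05, 0.3), rng.uniform(0.05, 0.3))
        succ = rng.binomial(totals, pi)
        if succ.sum() == 0 or ((totals - succ).sum() == 0):
            continue
        coef, se, p = enrichment_glm(succ, totals, status)
        hi = status == 1
        tab = np.array([[succ[hi].sum(), (totals - succ)[hi].sum()],
                        [succ[~hi].sum(), (totals - succ)[~hi].sum()]])
        if 0 in tab:
            continue
        log_or = np.log(tab[0, 0] * tab[1, 1] / (tab[0, 1] * tab[1, 0]))
        if abs(log_or) < 1e-8 or not np.isfinite(coef):
            continue
        assert np.sign(coef) == np.sign(log_or)


def test_regulon_activity_sign_convention():
    assert regulon_activity(-0.4, "destabilizer") == pytest.approx(0.4)
    assert regulon_activity(-0.4, "stabilizer") == pytest.approx(-0.4)
    assert regulon_activity(0.0, "stabilizer") == 0.0
    assert regulon_activity(0.0, "destabilizer") == 0.0
    with pytest.raises(RegulonError):
        regulon_activity(0.3, "unknown")


# ---------------------------------------------------------------------------
# simulation + model round trip

def test_simulated_enrichment_recovered():
    counts, status, truth = simulate_regulon(2000, n_factors=5,
                                             focal_odds_ratio=2.0, seed=3)
    totals = counts.sum(axis=1)
    coef, se, p = enrichment_glm(counts[:, 0], totals, status)
    assert coef == pytest.approx(np.log(2.0), abs=3 * se)
    assert p < 0.01


def test_regulon_model_table_and_activity():
    counts, status, _ = simulate_regulon(800, n_factors=4, focal_odds_ratio=2.0,
                                         seed=5)
    genes = [f"g{i}" for i in range(800)]
    sm_ = SiteMatrix(
        counts=pd.DataFrame(counts, index=genes,
                            columns=["focal", "f1", "f2", "f3"]),
        totals=pd.Series(counts.sum(axis=1), index=genes),
    )
    res = RegulonEnrichmentModel(sm_, pd.Series(status, index=genes),
                                 directions={"focal": "stabilizer"}).fit()
    t = res.table.set_index("factor_id")
    assert t.loc["focal", "qvalue"] < 0.05
    assert t.loc["focal", "activity"] == pytest.approx(t.loc["focal", "coefficient"])
    assert np.isnan(t.loc["f1", "activity"])  # unknown direction


def test_single_status_level_simulation_errors_in_glm():
    counts, status, _ = simulate_regulon(200, n_factors=3,
                                         status_proportions=(0.0, 1.0, 0.0),
                                         seed=7)
    with pytest.raises(RegulonError):
        enrichment_glm(counts[:, 0], counts.sum(axis=1), status)
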