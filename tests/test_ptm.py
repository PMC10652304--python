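"""Percent-change-per-site quantification and its aggregations."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_evidence
from redoxsens.ptm import (
    NEW_SITE,
    correlate,
    grand_sum,
    lfq_log2_table,
    modification_ptm_change,
    overlay_lfq,
    protein_ptm_change,
    ptm_change_table,
    sign_census,
    site_percent_change,
)

PAIR = ("vehicle", "treated")


@pytest.mark.parametrize(
    "vehicle, treated, expected",
    [
        ([10, 10], [5, 5], -50.0),
        ([8], [8], 0.0),
        ([100], [150], 50.0),
        ([2, 4], [6, 6], 100.0),  # means 3 -> 6
    ],
)
def test_site_percent_change(vehicle, treated, expected):
    assert site_percent_change(vehicle, treated) == pytest.approx(expected)


def test_site_percent_change_degenerate_cases():
    assert site_percent_change([0], [7]) is NEW_SITE
    assert site_percent_change([0, 0], [0]) is None
    # pseudocount turns a new site into a finite change
    assert site_percent_change([0], [7], pseudocount=0.5) == pytest.approx(1400.0)


def _two_site_evidence():
    rows = []
    for rep in (1, 2):
        rows += [
            ("prot1", 10, "HNE", "vehicle", rep, 10.0),
            ("prot1", 10, "HNE", "treated", rep, 5.0),   # -50%
            ("prot1", 33, "4-ONE", "vehicle", rep, 8.0),
            ("prot1", 33, "4-ONE", "treated", rep, 8.0),  # 0%
        ]
    return make_evidence(rows)


def test_protein_ptm_change_averages_sites():
    entry = protein_ptm_change(_two_site_evidence(), "prot1", PAIR)
    assert entry.pct_change_per_site == pytest.approx(-25.0)
    assert entry.n_sites == 2
    assert entry.net_sign == -1


def test_protein_ptm_change_unchanged_and_missing():
    ev = make_evidence([("p", 1, "HNE", "vehicle", 1, 5.0), ("p", 1, "HNE", "treated", 1, 5.0)])
    entry = protein_ptm_change(ev, "p", PAIR)
    assert entry.pct_change_per_site == 0.0 and entry.net_sign == 0
    absent = protein_ptm_change(ev, "ghost", PAIR)
    assert absent.insufficient and np.isnan(absent.pct_change_per_site)


def test_modification_ptm_change_pools_proteins():
    rows = []
    for prot in ("a", "b"):
        rows += [
            (prot, 1, "4-ONE", "vehicle", 1, 100.0),
            (prot, 1, "4-ONE", "treated", 1, 53.0),  # -47%
        ]
    entry = modification_ptm_change(make_evidence(rows), "4-ONE", PAIR)
    assert entry.pct_change_per_site == pytest.approx(-47.0)
    missing = modification_ptm_change(make_evidence(rows), "G-H1", PAIR)
    assert missing.insufficient


def test_new_site_excluded_from_average_by_default():
    rows = [
        ("p", 1, "HNE", "vehicle", 1, 10.0),
        ("p", 1, "HNE", "treated", 1, 5.0),  # -50%
        ("p", 2, "HNE", "vehicle", 1, 0.0),
        ("p", 2, "HNE", "treated", 1, 9.0),  # new site, excluded
    ]
    entry = protein_ptm_change(make_evidence(rows), "p", PAIR)
    assert entry.pct_change_per_site == pytest.approx(-50.0)
    assert entry.n_sites == 1


def test_scale_invariance_of_site_change():
    base = site_percent_change([3, 5], [2, 2])
    scaled = site_percent_change([30, 50], [20, 20])
    assert base == pytest.approx(scaled)


def test_grand_sum_and_signs():
    table = pd.DataFrame({"pct_change_per_site": [-10.0, -5.0, 3.0]})
    assert grand_sum(table) == pytest.approx(-12.0)
    with pytest.raises(ValueError):
        grand_sum(pd.DataFrame({"pct_change_per_site": []}))


def test_grand_sum_consistent_across_groupings():
    """Protein-wise and modification-wise sums agree when every protein/mod
    pairing is one site (zero noise)."""
    rows = []
    for i, (prot, mod, change) in enumerate(
        [("a", "HNE", -20.0), ("b", "4-ONE", 40.0), ("c", "G-H1", -5.0)]
    ):
        rows += [
            (prot, 1, mod, "vehicle", 1, 100.0),
            (prot, 1, mod, "treated", 1, 100.0 * (1 + change / 100)),
        ]
    ev = make_evidence(rows)
    by_prot = ptm_change_table(ev, PAIR, by="protein_id")
    by_mod = ptm_change_table(ev, PAIR, by="modification")
    assert grand_sum(by_prot) == pytest.approx(grand_sum(by_mod))
    assert grand_sum(by_prot) == pytest.approx(15.0)


def test_sign_census():
    assert sign_census([-1e-9, 2], zero_tolerance=1e-6) == (0, 1, 1)
    assert sign_census([0.0, 0.0, 0.0]) == (0, 0, 3)
    assert sign_census([-5, -1, 2, np.nan]) == (2, 1, 1)


def test_overlay_lfq_outer_join():
    ptm = pd.DataFrame({"pct_change_per_site": [-10.0]}, index=pd.Index(["a"], name="protein_id"))
    lfq = pd.DataFrame({"log2_ratio": [1.0, 2.0]}, index=pd.Index(["a", "b"], name="protein_id"))
    joined = overlay_lfq(ptm, lfq)
    assert set(joined.index) == {"a", "b"}
    assert np.isnan(joined.loc["b", "pct_change_per_site"])
    disjoint = overlay_lfq(
        ptm, pd.DataFrame({"log2_ratio": [3.0]}, index=pd.Index(["z"], name="protein_id"))
    )
    assert len(disjoint) == 2 and disjoint.isna().sum().sum() == 2


def test_lfq_log2_ratio_zero_noise():
    rows = []
    for rep in (1, 2):
        rows += [
            ("p", "vehicle", rep, 1000.0),
            ("p", "treated", rep, 2000.0),  # fold 2 -> log2 ratio 1
            ("q", "vehicle", rep, 500.0),
            ("q", "treated", rep, 500.0),  # fold 1 -> 0
        ]
    lfq = pd.DataFrame(rows, columns=["protein_id", "condition", "replicate", "intensity"])
    table = lfq_log2_table(lfq, PAIR)
    assert table.loc["p", "log2_ratio"] == pytest.approx(1.0)
    assert table.loc["q", "log2_ratio"] == pytest.approx(0.0)


def test_correlate_perfect_line_and_guards():
    x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    res = correlate(x, 2 * x + 1, n_boot=50, seed=0)
    assert res.pearson_r == pytest.approx(1.0)
    assert res.slope == pytest.approx(2.0) and res.intercept == pytest.approx(1.0)
    assert res.ci_low <= res.slope <= res.ci_high
    with pytest.raises(ValueError):
        correlate([1, 2], [3, 4], n_boot=10, seed=0)
    with pytest.raises(ValueError):
        correlate([1, 1, 1], [1, 2, 3], n_boot=10, seed=0)


def test_correlate_independent_normals_near_zero():
    rng = np.random.default_rng(0)
    hits = 0
    for trial in range(40):
        x, y = rng.standard_normal(1000), rng.standard_normal(1000)
        if abs(correlate(x, y, n_boot=10, seed=trial).pearson_r) < 0.1:
            hits += 1
    assert hits >= 38  # |r| < 0.1 in at least 95% of runs


def test_bootstrap_slope_coverage():
    """The 95% bootstrap band on the slope covers the true slope in roughly
    95% of repeated draws from a bivariate normal with rho = -0.2."""
    rho, n, runs = -0.2, 200, 120
    cov = np.array([[1.0, rho], [rho, 1.0]])
    covered = 0
    rng = np.random.default_rng(2024)
    for trial in range(runs):
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        res = correlate(xy[:, 0], xy[:, 1], n_boot=300, seed=trial)
        if res.ci_low <= rho <= res.ci_high:  # true slope = rho here
            covered += 1
    assert 0.88 <= covered / runs <= 1.0
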