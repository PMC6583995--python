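"""TMM normalisation, common-dispersion estimation, the conditional NB exact
test, BH adjustment and DE calling."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mctomics.de import (
    DEConfig,
    ExactTestDE,
    bh_adjust,
    call_de,
    equalize_libraries,
    effective_library_sizes,
    estimate_common_dispersion,
    nb_exact_test,
    norm_factors,
)
from conftest import simulate_nb_counts


# ---------------------------------------------------------------------------
# TMM factors
# ---------------------------------------------------------------------------

def test_norm_factors_identical_columns_are_unit():
    col = np.arange(1, 21)
    counts = pd.DataFrame({f"s{j}": col for j in range(4)})
    f = norm_factors(counts)
    assert np.allclose(f, 1.0)


def test_norm_factors_equalise_doubled_library():
    """One sample = 2x another: after scaling by factor x library size, the
    effective library sizes are equal (composition is identical)."""
    col = np.array([50, 80, 120, 40, 60, 90, 200, 30, 70, 110])
    counts = pd.DataFrame({"a": col, "b": 2 * col})
    eff = effective_library_sizes(counts)
    assert eff["a"] * 2 == pytest.approx(eff["b"], rel=1e-9)


def test_norm_factors_geometric_mean_is_one():
    counts, _ = simulate_nb_counts(300, (3, 3), phi=0.2, seed=11,
                                   lib_factors=[0.5, 1, 1, 1, 2, 1.5])
    f = norm_factors(counts)
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)


def test_norm_factors_reject_all_zero_sample():
    counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
    with pytest.raises(ValueError, match="b"):
        norm_factors(counts)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_norm_factors_match_edgeR(tmp_path):
    """Independent oracle: edgeR's calcNormFactors on the same matrix."""
    rng = np.random.default_rng(3)
    mu = rng.lognormal(4, 1.5, 500)
    y = rng.poisson(
        mu[:, None] * rng.uniform(0.5, 2, 6)[None, :] * np.exp(rng.normal(0, 0.3, (500, 6)))
    )
    path = tmp_path / "counts.tsv"
    pd.DataFrame(y).to_csv(path, sep="\t", index=False, header=False)
    script = (
        "suppressMessages(library(edgeR));"
        f"y <- as.matrix(read.delim('{path}', header=FALSE));"
        "f <- calcNormFactors(DGEList(counts=y))$samples$norm.factors;"
        "cat(sprintf('%.8f', f), sep=' ')"
    )
    try:
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300,
        )
    except (subprocess.TimeoutExpired, OSError):
        pytest.skip("Rscript/edgeR unavailable")
    if out.returncode != 0:
        pytest.skip(f"edgeR not importable: {out.stderr[-200:]}")
    ref = np.array([float(v) for v in out.stdout.split()])
    ours = norm_factors(pd.DataFrame(y, columns=[f"s{j}" for j in range(6)])).to_numpy()
    assert np.allclose(ours, ref, atol=1e-6)


# ---------------------------------------------------------------------------
# common dispersion
# ---------------------------------------------------------------------------

def test_dispersion_poisson_data_estimates_near_zero():
    counts, groups = simulate_nb_counts(2000, (4, 11), phi=0.0, seed=21)
    assert estimate_common_dispersion(counts, groups) <= 0.01


def test_dispersion_recovers_planted_value():
    counts, groups = simulate_nb_counts(2000, (4, 11), phi=0.2, seed=22)
    est = estimate_common_dispersion(counts, groups)
    assert est == pytest.approx(0.2, abs=0.05)


def test_dispersion_approx_invariant_to_count_doubling():
    counts, groups = simulate_nb_counts(1000, (4, 11), phi=0.15, seed=23)
    e1 = estimate_common_dispersion(counts, groups)
    e2 = estimate_common_dispersion(counts * 2, groups)
    assert e2 == pytest.approx(e1, rel=0.15)


def test_dispersion_requires_two_per_group():
    counts, _ = simulate_nb_counts(50, (1, 5), phi=0.1, seed=1)
    with pytest.raises(ValueError, match="fewer than 2"):
        estimate_common_dispersion(counts, np.array(["A"] + ["B"] * 5))


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def test_exact_test_symmetric_identical_totals_give_p_one():
    # equal library sizes and equal group totals under symmetric group sizes
    counts = pd.DataFrame(
        {"a1": [10, 10], "a2": [20, 0], "b1": [15, 5], "b2": [15, 5]}
    )
    groups = np.array(["A", "A", "B", "B"])
    factors = pd.Series(1.0, index=counts.columns)
    p = nb_exact_test(counts, groups, phi=0.1, factors=factors)
    assert np.allclose(p, 1.0)


def test_exact_test_label_swap_symmetry():
    counts, groups = simulate_nb_counts(100, (4, 11), phi=0.1, seed=31)
    p1 = nb_exact_test(counts, groups, phi=0.1)
    swapped = np.where(groups == "A", "B", "A")
    p2 = nb_exact_test(counts, swapped, phi=0.1)
    assert np.allclose(p1, p2, atol=1e-12)


def test_exact_test_null_p_uniform():
    """No planted effect: empirical p distribution approximately uniform."""
    counts, groups = simulate_nb_counts(2000, (4, 11), phi=0.1, seed=42)
    phi = estimate_common_dispersion(counts, groups)
    p = nb_exact_test(counts, groups, phi)
    ks = stats.kstest(p, "uniform").statistic
    assert ks < 0.05


def test_exact_test_rejects_more_than_two_groups():
    counts, _ = simulate_nb_counts(10, (2, 4), phi=0.1, seed=1)
    with pytest.raises(ValueError, match="two groups"):
        nb_exact_test(counts, np.array(["A", "B", "C", "A", "B", "C"]), 0.1)

    with pytest.raises(ValueError, match=">= 0"):
        nb_exact_test(counts, np.array(["A"] * 2 + ["B"] * 4), -0.5)


# ---------------------------------------------------------------------------
# BH adjustment and calling
# ---------------------------------------------------------------------------

def test_bh_single_p_unchanged():
    assert bh_adjust([0.03]) == pytest.approx([0.03])


def test_bh_matches_hand_stepup():
    # step-up: p_(i) * m / i with cumulative minimum from the largest rank
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
    assert np.allclose(bh_adjust([0.001, 0.02, 0.9]), [0.003, 0.03, 0.9])


def test_bh_adjusted_at_least_raw():
    rng = np.random.default_rng(9)
    p = rng.uniform(size=200)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@pytest.mark.parametrize(
    "fdr,logfc,expected",
    [(0.05, 2.0, "up"), (0.06, 5.0, "none"), (0.01, -2.5, "down"),
     (0.05, -2.0, "down"), (0.04, 1.99, "none")],
)
def test_call_de_inclusive_thresholds(fdr, logfc, expected):
    table = pd.DataFrame({"logFC": [logfc], "FDR": [fdr]})
    assert call_de(table, DEConfig()).loc[0, "call"] == expected


# ---------------------------------------------------------------------------
# model-level properties
# ---------------------------------------------------------------------------

def test_fdr_controlled_under_null():
    """All-null replicates: proportion of called genes <= nominal 0.05."""
    called = 0
    total = 0
    for rep in range(20):
        counts, groups = simulate_nb_counts(400, (4, 11), phi=0.1, seed=1000 + rep)
        res = ExactTestDE(counts, groups, baseline="B").fit()
        called += res.n_up + res.n_down
        total += len(res.table)
    assert called / total <= 0.05


def test_power_on_strong_planted_effects():
    """Planted |log2FC| = 4 at phi = 0.1, n = 4 vs 11: most are recovered."""
    counts, groups = simulate_nb_counts(
        2000, (4, 11), phi=0.1, seed=77, n_de=100, log2fc=4.0
    )
    res = ExactTestDE(counts, groups, baseline="B").fit()
    planted = res.table.index[:100]
    frac = (res.table.loc[planted, "call"] == "up").mean()
    assert frac >= 0.70


def test_logfc_sign_convention_up_in_comparison_group():
    counts, groups = simulate_nb_counts(
        500, (4, 11), phi=0.05, seed=78, n_de=20, log2fc=3.0
    )
    res = ExactTestDE(counts, groups, baseline="B").fit()  # comparison = A (first 4)
    assert (res.table.iloc[:20]["logFC"] > 0).all()
    # and the estimated effect is close to the planted one
    assert res.table.iloc[:20]["logFC"].mean() == pytest.approx(3.0, abs=0.5)


def test_model_fit_deterministic_and_summary(tmp_path):
    counts, groups = simulate_nb_counts(200, (4, 11), phi=0.1, seed=79, n_de=10, log2fc=4.0)
    r1 = ExactTestDE(counts, groups, baseline="B").fit()
    r2 = ExactTestDE(counts, groups, baseline="B").fit()
    pd.testing.assert_frame_equal(r1.table, r2.table)
    text = r1.summary()
    assert "dispersion" in text and "A vs B" in text
    out = tmp_path / "de.tsv"
    r1.to_tsv(out)
    back = pd.read_csv(out, sep="\t", index_col="gene")
    assert back.shape[0] == 200


def test_equalized_libraries_share_target_size():
    """After scaling, every sample's *effective* library size equals the
    geometric-mean target."""
    counts, _ = simulate_nb_counts(300, (3, 3), phi=0.1, seed=80,
                                   lib_factors=[0.4, 1, 1, 1, 1, 2.5])
    f = norm_factors(counts)
    eff = counts.sum(axis=0) * f
    pseudo = equalize_libraries(counts, eff)
    target = np.exp(np.mean(np.log(eff)))
    assert np.allclose(pseudo.sum(axis=0) * f, target, rtol=1e-12)
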