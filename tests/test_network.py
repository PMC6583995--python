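"""Co-expression network: connectivity, adjacency, TOM (with brute-force
oracle), module detection, eigengenes and module-trait correlation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mctomics.network import (
    UNASSIGNED,
    CoexpressionNetwork,
    NetworkConfig,
    adjacency,
    connectivity,
    correlation_pvalue,
    detect_modules,
    module_eigengene,
    module_trait_correlation,
    select_top_connected,
    tom,
)


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Independent triple-loop evaluation of the topological overlap."""
    n = a.shape[0]
    k = a.sum(axis=1)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return out


def planted_block_expression(block_sizes, n_noise, n_samples, loading, seed):
    """Expression with latent-factor blocks; returns (DataFrame, true labels)."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b, size in enumerate(block_sizes):
        f = rng.standard_normal(n_samples)
        for _ in range(size):
            rows.append(loading * f + rng.standard_normal(n_samples))
            labels.append(f"block{b}")
    for _ in range(n_noise):
        rows.append(rng.standard_normal(n_samples))
        labels.append("noise")
    expr = pd.DataFrame(
        rows, index=[f"g{i:03d}" for i in range(len(rows))],
        columns=[f"s{j:02d}" for j in range(n_samples)],
    )
    return expr, np.array(labels)


# ---------------------------------------------------------------------------
# connectivity and adjacency
# ---------------------------------------------------------------------------

def test_connectivity_perfectly_correlated_genes():
    x = np.arange(10, dtype=float)
    expr = pd.DataFrame([x, 2 * x + 1, -3 * x], index=list("abc"))
    k = connectivity(expr, beta=11)
    assert np.allclose(k, 2.0)  # |cor| = 1 between all pairs


def test_connectivity_orthogonal_gene_near_zero():
    rng = np.random.default_rng(0)
    n = 2000  # large sample count so chance correlation is tiny
    x = rng.standard_normal(n)
    expr = pd.DataFrame([x, x * 1.0, rng.standard_normal(n)], index=list("abc"))
    k = connectivity(expr, beta=11)
    assert k["c"] < 1e-6


def test_connectivity_matches_bruteforce_sum():
    rng = np.random.default_rng(4)
    expr = pd.DataFrame(rng.normal(size=(5, 12)), index=[f"g{i}" for i in range(5)])
    cor = np.corrcoef(expr.to_numpy())
    beta = 11.0
    expected = [
        sum(abs(cor[i, j]) ** beta for j in range(5) if j != i) for i in range(5)
    ]
    assert np.allclose(connectivity(expr, beta=beta), expected, atol=1e-10)
    raw_expected = [sum(abs(cor[i, j]) for j in range(5) if j != i) for i in range(5)]
    assert np.allclose(connectivity(expr, mode="raw"), raw_expected, atol=1e-10)


def test_select_top_connected_rules():
    k = pd.Series([3.0, 1.0, 2.0, 2.0], index=list("abcd"))
    assert select_top_connected(k, 4) == list("abcd")  # identity at full size
    assert select_top_connected(k, 2) == ["a", "c"]  # ties by input order
    tied = pd.Series([1.0, 1.0, 1.0], index=list("xyz"))
    assert select_top_connected(tied, 2) == ["x", "y"]
    sorted_oracle = list(k.sort_values(ascending=False, kind="stable").index[:3])
    assert set(select_top_connected(k, 3)) == set(sorted_oracle)


def test_adjacency_values_and_validation():
    cor = np.array([[1.0, 0.5, -0.5], [0.5, 1.0, 1.0], [-0.5, 1.0, 1.0]])
    a = adjacency(cor, beta=11)
    assert a[0, 1] == pytest.approx(2.0 ** -11)
    assert a[0, 2] == pytest.approx(2.0 ** -11)  # unsigned: |-0.5| = |0.5|
    assert a[1, 2] == pytest.approx(1.0)
    assert np.all(np.diag(a) == 0)
    with pytest.raises(ValueError, match="symmetric"):
        adjacency(np.array([[1.0, 0.2], [0.5, 1.0]]))


# ---------------------------------------------------------------------------
# TOM
# ---------------------------------------------------------------------------

def test_tom_complete_graph_is_all_ones():
    n = 6
    a = np.ones((n, n)) - np.eye(n)
    assert np.allclose(tom(a), 1.0)


def test_tom_three_node_hand_example():
    a = np.full((3, 3), 0.5) - 0.5 * np.eye(3)
    t = tom(a)
    assert t[0, 1] == pytest.approx((0.25 + 0.5) / (1 + 1 - 0.5))


def test_tom_matches_bruteforce_on_random_matrices():
    rng = np.random.default_rng(8)
    for _ in range(3):
        c = rng.uniform(-1, 1, (30, 30))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        a = adjacency(c, beta=6)
        assert np.allclose(tom(a), tom_bruteforce(a), atol=1e-10)


def test_tom_stays_in_unit_interval():
    rng = np.random.default_rng(9)
    for beta in (3, 6, 11):
        c = rng.uniform(-1, 1, (25, 25))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        t = tom(adjacency(c, beta=beta))
        assert t.min() >= 0.0 and t.max() <= 1.0


def test_tom_rejects_bad_adjacency():
    with pytest.raises(ValueError, match="diagonal"):
        tom(np.ones((3, 3)))
    with pytest.raises(ValueError, match="symmetric"):
        tom(np.array([[0.0, 0.1], [0.4, 0.0]]))


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def _partition_from_expression(expr, config):
    from mctomics.network import adjacency, correlation_matrix, tom

    a = adjacency(correlation_matrix(expr), beta=config.beta)
    return detect_modules(1.0 - tom(a), list(expr.index), config)


def test_detect_modules_recovers_three_planted_blocks():
    expr, truth = planted_block_expression([40, 40, 40], 0, 30, loading=3.0, seed=12)
    cfg = NetworkConfig(beta=6, min_module_size=30)
    part = _partition_from_expression(expr, cfg)
    assert len(part.module_names) == 3
    ari = adjusted_rand_score(truth, part.labels.to_numpy())
    assert ari >= 0.9


def test_small_block_falls_into_unassigned():
    expr, truth = planted_block_expression([40, 20], 40, 30, loading=3.0, seed=13)
    cfg = NetworkConfig(beta=6, min_module_size=30)
    part = _partition_from_expression(expr, cfg)
    small = part.labels[truth == "block1"]
    assert (small == UNASSIGNED).all()


def test_detect_modules_deterministic():
    expr, _ = planted_block_expression([35, 35], 20, 20, loading=2.0, seed=14)
    cfg = NetworkConfig(beta=6, min_module_size=30)
    p1 = _partition_from_expression(expr, cfg)
    p2 = _partition_from_expression(expr, cfg)
    pd.testing.assert_series_equal(p1.labels, p2.labels)


def test_detect_modules_too_few_genes_warns():
    with pytest.warns(UserWarning, match="no modules"):
        part = detect_modules(np.zeros((5, 5)), [f"g{i}" for i in range(5)],
                              NetworkConfig(min_module_size=30))
    assert (part.labels == UNASSIGNED).all()


def test_module_labels_are_size_ranked():
    expr, truth = planted_block_expression([60, 35], 0, 25, loading=3.0, seed=15)
    part = _partition_from_expression(expr, NetworkConfig(beta=6, min_module_size=30))
    sizes = part.sizes
    assert sizes["M1"] >= sizes["M2"]


# ---------------------------------------------------------------------------
# eigengenes
# ---------------------------------------------------------------------------

def test_eigengene_of_identical_profiles():
    rng = np.random.default_rng(16)
    base = rng.standard_normal(12)
    expr = pd.DataFrame([base, 2 * base + 5, 0.5 * base - 1],
                        index=list("abc"), columns=[f"s{j}" for j in range(12)])
    eig, ve = module_eigengene(expr, list("abc"))
    assert ve == pytest.approx(1.0)
    assert abs(np.corrcoef(eig, base)[0, 1]) == pytest.approx(1.0)
    assert np.linalg.norm(eig) == pytest.approx(1.0)


def test_eigengene_variance_explained_beats_random_directions():
    rng = np.random.default_rng(17)
    expr = pd.DataFrame(rng.normal(size=(20, 10)),
                        index=[f"g{i}" for i in range(20)])
    eig, ve = module_eigengene(expr, list(expr.index))
    z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1, ddof=1)).T.to_numpy()
    total = np.sum(z ** 2)
    for _ in range(100):
        v = rng.standard_normal(10)
        v /= np.linalg.norm(v)
        assert np.sum((z @ v) ** 2) / total <= ve + 1e-12


def test_eigengene_orientation_invariant_to_global_sign_flip():
    rng = np.random.default_rng(18)
    f = rng.standard_normal(10)
    expr = pd.DataFrame([f + 0.1 * rng.standard_normal(10) for _ in range(8)],
                        index=[f"g{i}" for i in range(8)])
    eig1, _ = module_eigengene(expr, list(expr.index))
    eig2, _ = module_eigengene(-expr, list(expr.index))
    # orientation rule: mean correlation with members >= 0 in both cases
    assert np.corrcoef(eig1, f)[0, 1] > 0.9
    assert np.corrcoef(eig2, -f)[0, 1] > 0.9


# ---------------------------------------------------------------------------
# module-trait correlation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("r,expected_p", [(0.51, 0.05), (0.45, 0.09), (-0.45, 0.09)])
def test_correlation_pvalue_reference_pairs(r, expected_p):
    """The correlation t-test at n = 15 reproduces the reference (r, p)
    pairs to 2 decimal places."""
    assert round(correlation_pvalue(r, 15), 2) == expected_p


def test_trait_correlation_exact_trait_gives_r_one():
    trait = pd.Series([3.0, 5, 6, 9, 11, 4, 8, 7, 10, 5.5],
                      index=[f"s{j}" for j in range(10)])
    eig = pd.DataFrame([trait.to_numpy()], index=["M1"], columns=trait.index)
    mt = module_trait_correlation(eig, trait)
    assert mt.loc[0, "r"] == pytest.approx(1.0)
    assert mt.loc[0, "p"] < 1e-9
    assert bool(mt.loc[0, "significant"])


def test_trait_correlation_threshold_is_strict():
    # r chosen so p is just above 0.1 at n=15
    rng = np.random.default_rng(20)
    x = rng.standard_normal(15)
    trait = pd.Series(np.arange(15.0), index=[f"s{j}" for j in range(15)])
    eig = pd.DataFrame([x], index=["M1"], columns=trait.index)
    mt = module_trait_correlation(eig, trait, p_threshold=0.1)
    assert bool(mt.loc[0, "significant"]) == (mt.loc[0, "p"] < 0.1)


def test_trait_correlation_rejects_constant_trait():
    eig = pd.DataFrame(np.random.default_rng(0).normal(size=(1, 6)),
                       index=["M1"], columns=[f"s{j}" for j in range(6)])
    with pytest.raises(ValueError, match="constant"):
        module_trait_correlation(eig, pd.Series(2.0, index=eig.columns))


# ---------------------------------------------------------------------------
# model-level
# ---------------------------------------------------------------------------

def test_network_model_end_to_end_and_deterministic():
    expr, truth = planted_block_expression([45, 40], 40, 15, loading=3.0, seed=21)
    cfg = NetworkConfig(beta=6, n_top_genes=100, min_module_size=30)
    r1 = CoexpressionNetwork(expr, cfg).fit()
    r2 = CoexpressionNetwork(expr, cfg).fit()
    pd.testing.assert_series_equal(r1.partition.labels, r2.partition.labels)
    pd.testing.assert_frame_equal(r1.eigengenes, r2.eigengenes)
    assert r1.n_modules >= 2
    assert "modules detected" in r1.summary()


def test_network_screens_zero_variance_genes():
    rng = np.random.default_rng(22)
    expr = pd.DataFrame(rng.normal(size=(10, 8)), index=[f"g{i}" for i in range(10)])
    expr.loc["g0"] = 5.0  # constant gene
    k = connectivity(expr, beta=6)
    assert "g0" not in k.index
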