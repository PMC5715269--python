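"""Cohort and connectome generators: moments, invariants, planted effects."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

import wmnet as w


def test_cohort_deterministic_byte_identical():
    spec = w.CohortSpec(seed=7)
    a = w.generate_cohort(spec).to_csv(sep="\t", index=False)
    b = w.generate_cohort(spec).to_csv(sep="\t", index=False)
    assert a == b
    c = w.generate_cohort(w.CohortSpec(seed=8)).to_csv(sep="\t", index=False)
    assert a != c


def test_cohort_score_invariants():
    table = w.generate_cohort(w.CohortSpec(n_is=50, n_nis=50, seed=1))
    is_tab = table[table["group"] == "IS"]
    nis_tab = table[table["group"] == "NIS"]
    assert (is_tab["insomnia"] >= 1).all()
    assert (nis_tab["insomnia"] == 0).all()
    for col in ("hamd", "hamd_adj", "hama", "hama_adj", "insomnia"):
        assert (table[col] >= 0).all()
    assert (table["hamd_adj"] <= table["hamd"]).all()
    assert (table["hama_adj"] <= table["hama"]).all()
    assert len(table) == 100


def test_cohort_moments_match_defaults_at_large_n():
    """IS age sample mean within 2 SE of 38.00, SD within 5% of 11.85."""
    table = w.generate_cohort(w.CohortSpec(n_is=3000, n_nis=62, seed=7))
    age = table.loc[table["group"] == "IS", "age"]
    se = 11.85 / np.sqrt(3000)
    assert abs(age.mean() - 38.00) <= 2 * se
    assert abs(age.std(ddof=1) - 11.85) / 11.85 <= 0.05
    ins = table.loc[table["group"] == "IS", "insomnia"]
    assert abs(ins.mean() - 1.70) <= 0.1
    assert abs(ins.std(ddof=1) - 0.92) <= 0.1


def test_cohort_bad_sizes_name_field():
    with pytest.raises(ValueError, match="n_is"):
        w.CohortSpec(n_is=1)
    with pytest.raises(ValueError, match="n_nis"):
        w.CohortSpec(n_nis=0)


def test_connectome_weight_invariants(small_cohort):
    table, conns = small_cohort
    assert set(conns) == set(table["id"])
    for conn in conns.values():
        assert np.array_equal(conn.weights, conn.weights.T)
        assert np.all(np.diag(conn.weights) == 0)
        assert conn.weights.min() >= 0 and conn.weights.max() <= 1


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_connectomes_90pct_connected_at_min_sparsity(seed):
    table = w.generate_cohort(w.CohortSpec(n_is=3, n_nis=3, seed=seed))
    conns = w.generate_connectomes(
        table, n_nodes=90, effects=w.EffectSpec.insomnia_default(), seed=seed
    )
    for conn in conns.values():
        g = w.sparsity_threshold(conn, 0.10)
        _, labels = connected_components(csr_matrix(g.adjacency))
        assert np.bincount(labels).max() >= 0.9 * g.n_nodes


def test_connectomes_deterministic(small_cohort):
    table, conns = small_cohort
    again = w.generate_connectomes(table, n_nodes=30, seed=12)
    for sid in conns:
        assert np.array_equal(conns[sid].weights, again[sid].weights)


def test_effect_node_out_of_range_rejected():
    table = w.generate_cohort(w.CohortSpec(n_is=2, n_nis=2, seed=0))
    eff = w.EffectSpec(nodal=(w.NodalEffect(99, "degree", 1, 0.5),))
    with pytest.raises(ValueError, match="out of range"):
        w.generate_connectomes(table, n_nodes=20, effects=eff, seed=0)
    with pytest.raises(ValueError, match="unknown nodal metric"):
        w.NodalEffect(1, "pagerank", 1, 0.5)


def test_null_effects_leave_groups_exchangeable():
    """With no planted effects the IS/NIS Eglo AUCs come from one
    distribution: a permutation test should not reject strongly."""
    ps = []
    for seed in range(6):
        table = w.generate_cohort(w.CohortSpec(n_is=8, n_nis=8, seed=seed))
        conns = w.generate_connectomes(table, n_nodes=24, seed=seed + 100)
        auc = [
            float(
                w.metric_curves(
                    conns[sid], include_nodal=False, include_small_world=False
                )["Eglo"].auc
            )
            for sid in table["id"]
        ]
        res = w.permutation_group_test(
            np.array(auc) - np.mean(auc),
            (table["group"] == "IS").to_numpy(),
            n_perm=199,
            seed=seed,
        )
        ps.append(res.p)
    assert min(ps) > 0.005  # no extreme rejection across 6 null replicates


def test_planted_nodal_effects_enriched_in_planted_nodes():
    """Significant nodal-degree contrasts concentrate on planted nodes."""
    planted = (10, 40, 70)
    eff = w.EffectSpec(
        nodal=tuple(w.NodalEffect(n, "degree", +1, 0.5) for n in planted)
    )
    n_nodes = 90
    grid = np.round(np.linspace(0.10, 0.20, 6), 10)
    hit_planted = hit_other = 0
    n_planted = n_other = 0
    for seed in range(3):
        table = w.generate_cohort(w.CohortSpec(n_is=15, n_nis=15, seed=seed))
        conns = w.generate_connectomes(table, n_nodes=n_nodes, effects=eff, seed=seed)
        deg_auc = np.vstack(
            [
                w.metric_curves(
                    conns[sid], grid, include_nodal=True, include_small_world=False
                )["degree"].auc
                for sid in table["id"]
            ]
        )
        covs = w.covariate_matrix(table)
        is1 = (table["group"] == "IS").to_numpy()
        for node in range(n_nodes):
            res = w.permutation_group_test(
                deg_auc[:, node], is1, n_perm=199, seed=node, covariates=covs
            )
            sig = res.p < 0.05
            if node + 1 in planted:
                n_planted += 1
                hit_planted += sig
            else:
                n_other += 1
                hit_other += sig
    rate_planted = hit_planted / n_planted
    rate_other = max(hit_other / n_other, 1e-6)
    assert rate_planted >= 0.5
    assert rate_planted / rate_other >= 5.0


def test_cohort_io_roundtrip(tmp_path, small_cohort):
    table, conns = small_cohort
    path = tmp_path / "subjects.tsv"
    w.cohort.write_cohort(table, path)
    back = w.cohort.read_cohort(path)
    assert list(back.columns) == list(table.columns)
    assert back["id"].tolist() == table["id"].tolist()
    w.cohort.save_connectomes(conns, tmp_path / "conn")
    first = table["id"].iloc[0]
    m = w.network.read_connectome_matrix(tmp_path / "conn" / f"{first}.mat.txt")
    assert np.allclose(m, conns[first].weights, atol=1e-7)
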