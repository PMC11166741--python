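import dataclasses

import numpy as np
import pytest
import scipy.sparse as sp

from surfage.synthetic_cortex import (
    FeatureParams,
    SimulationConfig,
    make_icosphere,
    mesh_adjacency,
    simulate_cohort,
    simulate_outcomes,
    vertices_per_hemisphere,
)


@pytest.mark.parametrize("level", range(5))
@pytest.mark.parametrize("hemispheres", [1, 2])
def test_icosphere_counts_and_euler(level, hemispheres):
    """Vertex/face/edge counts follow the icosphere closed forms and each
    hemisphere has Euler characteristic 2."""
    mesh = make_icosphere(level, hemispheres)
    v = 10 * 4**level + 2
    f = 20 * 4**level
    e = 30 * 4**level
    assert mesh.n_vertices == hemispheres * v
    assert mesh.n_faces == hemispheres * f
    adj = mesh_adjacency(mesh)
    assert adj.nnz == hemispheres * e * 2
    assert v - e + f == 2
    # adjacency is symmetric, binary, zero-diagonal
    assert (adj != adj.T).nnz == 0
    assert set(np.unique(adj.data)) == {1.0}
    assert adj.diagonal().sum() == 0


def test_hemispheres_share_no_edges(ico2):
    adj = mesh_adjacency(ico2).tocoo()
    h = ico2.hemisphere_label
    assert np.all(h[adj.row] == h[adj.col])
    # leftmost component is labeled left
    left = ico2.coordinates[h == 0]
    right = ico2.coordinates[h == 1]
    assert left[:, 0].mean() < right[:, 0].mean()


@pytest.mark.parametrize("level", [1, 2, 3])
def test_parent_first_vertex_ordering(level):
    """Level L-1 vertices occupy the first indices of the level-L sphere,
    at identical unit positions, per hemisphere."""
    fine = make_icosphere(level, 2)
    coarse = make_icosphere(level - 1, 2)
    fu, cu = fine.unit_positions(), coarse.unit_positions()
    n = vertices_per_hemisphere(level - 1)
    for fsl, csl in zip(fine.hemisphere_slices(), coarse.hemisphere_slices()):
        assert np.allclose(fu[fsl][:n], cu[csl], atol=1e-9)


def test_icosphere_guards():
    with pytest.raises(ValueError, match="resource guard"):
        make_icosphere(8)
    with pytest.raises(ValueError):
        make_icosphere(2, hemispheres=3)
    with pytest.raises(ValueError):
        make_icosphere(-1)


def test_model_resolution_vertex_count(ico3):
    assert ico3.n_vertices == 1284


def test_simulation_reproducible_and_seed_sensitive():
    cfg = SimulationConfig(n_subjects=10, mesh_level=1, seed=5)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg)
    assert np.array_equal(a.feature_array(), b.feature_array())
    assert a.metadata().equals(b.metadata())
    c = simulate_cohort(cfg.with_(seed=6))
    assert not np.array_equal(a.feature_array()[: c.n_scans], c.feature_array()[: a.n_scans])


def test_noiseless_flat_slope_is_exactly_linear():
    """With no noise, no site/clinical effects and a flat slope, the feature
    difference between a subject's two scans is slope * delta PMA exactly."""
    cfg = SimulationConfig(
        n_subjects=5,
        mesh_level=1,
        repeat_scan_fraction=1.0,
        flag_effect_weeks={},
        subject_shift_sd=0.0,
        features={
            "thickness": FeatureParams(1.2, 0.0, 0.04, 0.0, 0.0),
            "sulcal_depth": FeatureParams(2.0, 0.0, 0.35, 0.0, 0.0),
            "gmwm_ratio": FeatureParams(1.1, 0.0, -0.012, 0.0, 0.0),
        },
        site_effects={
            k: dataclasses.replace(v, location=(0.0, 0.0, 0.0), scale=1.0)
            for k, v in SimulationConfig().site_effects.items()
        },
        seed=3,
    )
    cohort = simulate_cohort(cfg)
    meta = cohort.metadata()
    slopes = np.array([0.04, 0.35, -0.012])
    for sid in meta["subject_id"].unique():
        rows = np.flatnonzero(meta["subject_id"] == sid)
        assert len(rows) == 2
        dpma = meta.loc[rows[1], "pma_scan"] - meta.loc[rows[0], "pma_scan"]
        diff = cohort.feature_maps[rows[1]].values - cohort.feature_maps[rows[0]].values
        assert np.allclose(diff, slopes * dpma, atol=1e-9)


def test_mean_sulcal_depth_slope_recovered_by_ols():
    """OLS of cohort-mean sulcal depth on PMA recovers the configured
    developmental slope within 3 SE."""
    cfg = SimulationConfig(n_subjects=500, mesh_level=2, seed=11)
    cohort = simulate_cohort(cfg)
    meta = cohort.metadata()
    y = cohort.feature_array()[:, :, 1].mean(axis=1)
    x = meta["pma_scan"].to_numpy()
    design = np.column_stack([np.ones_like(x), x])
    coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sigma2 = resid @ resid / (len(y) - 2)
    se = np.sqrt(sigma2 * np.linalg.inv(design.T @ design)[1, 1])
    assert abs(coef[1] - 0.35) < 3 * se


def test_ga_birth_matches_configured_distribution():
    cfg = SimulationConfig(n_subjects=500, mesh_level=0, seed=2)
    meta = simulate_cohort(cfg).metadata()
    ga = meta.groupby("subject_id")["ga_birth"].first()
    assert abs(ga.mean() - 28.2) < 3 * 1.9 / np.sqrt(len(ga))


class TestOutcomes:
    def _cohort(self, cfg):
        cohort = simulate_cohort(cfg)
        table = simulate_outcomes(cohort.records, cfg)
        shifts = cohort.metadata().groupby("subject_id")["true_maturation_shift"].first()
        table = table.set_index("subject_id")
        return table, shifts.loc[table.index]

    def test_null_loading_gives_independent_scores(self):
        cfg = SimulationConfig(
            n_subjects=400, mesh_level=0, outcome_fraction=1.0,
            outcomes={"cognitive": (103.0, 0.0, 13.0)}, seed=7,
        )
        table, shifts = self._cohort(cfg)
        r = np.corrcoef(table["cognitive"], -shifts)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(table))

    def test_deterministic_limit_correlates_perfectly(self):
        cfg = SimulationConfig(
            n_subjects=100, mesh_level=0, outcome_fraction=1.0,
            outcomes={"cognitive": (103.0, 9.0, 1e-9)}, seed=8,
        )
        table, shifts = self._cohort(cfg)
        r = np.corrcoef(table["cognitive"], -shifts)[0, 1]
        assert r > 0.999

    def test_default_outcome_mean(self):
        cfg = SimulationConfig(n_subjects=600, mesh_level=0, outcome_fraction=1.0, seed=9)
        table, _ = self._cohort(cfg)
        se = 15.45 / np.sqrt(len(table))
        assert abs(table["cognitive"].mean() - 103.0) < 3 * se


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(site_probs={"a": 0.5, "b": 0.6})
    with pytest.raises(ValueError):
        SimulationConfig(flag_prevalence={"x": 1.5})
    with pytest.raises(ValueError):
        SimulationConfig(repeat_scan_fraction=-0.1)
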