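"""Pseudotime association, smoothing, module detection and transfer."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from nephroniche import simulate as sim
from nephroniche import trajectory as tj


class TestGamAssociation:
    def test_constant_gene_flat_p(self):
        expr = pd.DataFrame({f"c{i}": [1.0] for i in range(50)}, index=["g"])
        t = np.linspace(0, 1, 50)
        fit = tj.gam_association(expr, t)
        assert fit.table.loc["g", "F"] == 0.0
        assert fit.table.loc["g", "p"] == 1.0

    def test_linear_df_matches_closed_form_regression_f(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 1, 80))
        expr = pd.DataFrame(
            rng.normal(0, 1, (20, 80)) + np.outer(rng.normal(0, 1, 20), t),
            columns=[f"c{i}" for i in range(80)])
        fit = tj.gam_association(expr, t, spline_df=1)
        # closed-form simple linear regression F = r^2 (n-2) / (1 - r^2)
        for g in expr.index:
            y = expr.loc[g].to_numpy()
            r = np.corrcoef(t, y)[0, 1]
            F = r ** 2 * (80 - 2) / (1 - r ** 2)
            assert fit.table.loc[g, "F"] == pytest.approx(F, abs=1e-10)

    def test_power_on_planted_sigmoid_genes(self, traj_draw):
        expr, pt, truth = traj_draw
        fit = tj.gam_association(expr, pt)
        planted = [g for g, m in truth.gene_module.items() if m != "null"]
        assert (fit.table.loc[planted, "q"] < 0.05).mean() >= 0.9

    def test_type_one_error_on_null_genes(self):
        cfg = sim.TrajectoryConfig(seed=9, genes_per_module=5,
                                   n_null_genes=200)
        expr, pt, truth = sim.simulate_trajectory(cfg)
        fit = tj.gam_association(expr, pt)
        nulls = [g for g, m in truth.gene_module.items() if m == "null"]
        assert (fit.table.loc[nulls, "p"] < 0.05).mean() <= 1.5 * 0.05


class TestSmoothing:
    def test_constant_gene_unchanged(self):
        expr = pd.DataFrame(np.ones((1, 40)),
                            columns=[f"c{i}" for i in range(40)])
        sm, _ = tj.smooth_expression(expr, np.linspace(0, 1, 40))
        assert np.allclose(sm.to_numpy(), 1.0)

    def test_step_function_midpoint(self):
        n = 100
        t = np.linspace(0, 1, n)
        expr = pd.DataFrame([(t > 0.5).astype(float)],
                            columns=[f"c{i}" for i in range(n)], index=["g"])
        sm, ts = tj.smooth_expression(expr, t, window_frac=0.2)
        y = sm.loc["g"].to_numpy()
        assert (np.diff(y) >= -1e-12).all()          # monotone ramp
        mid = y[np.argmin(np.abs(ts.to_numpy() - 0.5))]
        assert mid == pytest.approx(0.5, abs=0.08)

    def test_noise_variance_reduced_by_window(self):
        rng = np.random.default_rng(1)
        n, w_frac = 2000, 0.05
        expr = pd.DataFrame([rng.normal(0, 1, n)],
                            columns=[f"c{i}" for i in range(n)], index=["g"])
        sm, _ = tj.smooth_expression(expr, np.linspace(0, 1, n),
                                     window_frac=w_frac)
        w = max(5, int(np.ceil(w_frac * n)))
        var = sm.loc["g"].to_numpy()[w:-w].var()
        assert var == pytest.approx(1.0 / w, rel=0.35)

    def test_window_clamped_with_warning(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(1, 10)),
                            columns=[f"c{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="clamp"):
            sm, _ = tj.smooth_expression(expr, np.linspace(0, 1, 10),
                                         window_frac=2.0)
        assert sm.shape == expr.shape


class TestDetectModules:
    def test_planted_modules_recovered(self, traj_draw):
        expr, pt, truth = traj_draw
        sm, _ = tj.smooth_expression(expr, pt)
        det = tj.detect_modules(sm)
        truth_labels = pd.Series(truth.gene_module).loc[det.gene_modules.index]
        assert adjusted_rand_score(truth_labels, det.gene_modules) >= 0.7
        n_modules = det.gene_modules[det.gene_modules != "grey"].nunique()
        assert n_modules == 3

    def test_duplication_invariance(self, traj_draw):
        expr, pt, truth = traj_draw
        sm, _ = tj.smooth_expression(expr, pt)
        det1 = tj.detect_modules(sm)
        doubled = pd.concat([sm, sm.rename(index=lambda g: g + "_dup")])
        det2 = tj.detect_modules(doubled)
        m1 = det1.gene_modules
        m2 = det2.gene_modules
        base = m2.loc[m1.index]
        dup = m2.loc[[g + "_dup" for g in m1.index]]
        assert (base.to_numpy() == dup.to_numpy()).all()
        assert adjusted_rand_score(m1, base) >= 0.95

    def test_oversized_min_module_all_grey_or_error(self, traj_draw):
        expr, pt, _ = traj_draw
        sm, _ = tj.smooth_expression(expr, pt)
        with pytest.raises(ValueError):
            tj.detect_modules(sm, min_module_size=10 ** 4)
        det = tj.detect_modules(sm, min_module_size=120)
        assert (det.gene_modules == "grey").all()


class TestAssignCells:
    def test_planted_segments_recovered(self, traj_draw):
        expr, pt, truth = traj_draw
        sm, _ = tj.smooth_expression(expr, pt)
        det = tj.detect_modules(sm)
        cells = tj.assign_cells_to_modules(sm, det.gene_modules, seed=0)
        gm = det.gene_modules
        truth_g = pd.Series(truth.gene_module)
        program_of = {m: truth_g.loc[gm.index[gm == m]].mode()[0]
                      for m in gm.unique() if m != "grey"}
        mapped = cells.map(lambda m: program_of.get(m, "unassigned"))
        truth_c = pd.Series(truth.cell_module).loc[cells.index]
        assert (mapped == truth_c).mean() >= 0.8

    def test_label_contract(self, traj_draw):
        expr, pt, _ = traj_draw
        sm, _ = tj.smooth_expression(expr, pt)
        det = tj.detect_modules(sm)
        cells = tj.assign_cells_to_modules(sm, det.gene_modules, seed=0)
        allowed = set(det.gene_modules.unique()) - {"grey"} | {"unassigned"}
        assert set(cells.unique()) <= allowed
        assert len(cells) == sm.shape[1]

    def test_single_module_assigns_everything(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 200)
        x = np.vstack([t + rng.normal(0, 0.1, 200) for _ in range(25)])
        sm = pd.DataFrame(x, index=[f"g{i}" for i in range(25)],
                          columns=[f"c{i}" for i in range(200)])
        gm = pd.Series("M1", index=sm.index)
        cells = tj.assign_cells_to_modules(sm, gm, seed=0)
        assert (cells == "M1").all()


class TestTransfer:
    def test_coincident_point_k1(self):
        ref = np.array([[0.0, 0.0], [5.0, 5.0]])
        out = tj.transfer_modules(ref, np.array(["a", "b"]),
                                  np.array([[5.0, 5.0]]), k=1)
        assert out[0] == "b"

    def test_separated_blobs_zero_errors(self):
        rng = np.random.default_rng(0)
        ref = np.vstack([rng.normal(0, 0.5, (100, 2)),
                         rng.normal(10, 0.5, (100, 2))])
        labels = np.array(["lo"] * 100 + ["hi"] * 100)
        qry = np.vstack([rng.normal(0, 0.3, (30, 2)),
                         rng.normal(10, 0.3, (30, 2))])
        out = tj.transfer_modules(ref, labels, qry, k=15)
        assert (out == np.array(["lo"] * 30 + ["hi"] * 30)).all()

    def test_majority_matches_bruteforce_vote(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(0, 1, (120, 3))
        labels = rng.choice(["a", "b", "c"], 120)
        qry = rng.normal(0, 1, (50, 3))
        k = 7
        out = tj.transfer_modules(ref, labels, qry, k=k)
        from scipy.spatial.distance import cdist
        d = cdist(qry, ref)
        for i in range(50):
            nbr = np.argsort(d[i], kind="stable")[:k]
            votes = pd.Series(labels[nbr]).value_counts()
            top = votes[votes == votes.iloc[0]].index
            expected = labels[nbr[0]] if len(top) > 1 else top[0]
            assert out[i] == expected

    def test_k_clamped_with_warning(self):
        ref = np.zeros((3, 2))
        with pytest.warns(UserWarning, match="clamp"):
            tj.transfer_modules(ref, np.array(["a", "a", "b"]),
                                np.ones((2, 2)), k=10)
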