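"""Moderated-statistic oracles, selection rules, and null calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beprog.diffexp import (
    calibrate_null,
    fit_moderated,
    fit_moderated_values,
    select_candidates,
)
from beprog.simulate import DatasetSpec, SimulationConfig, generate_meta_cohort
from beprog.types import DEResult, EBayesParams, ValidationError

from conftest import tiny_matrix


def _equal_variance_matrix(n_genes=50, seed=0):
    """Every gene shares the same residuals, so sample variances coincide."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=6)
    rows = []
    for _ in range(n_genes):
        row = base.copy()
        row[:3] += rng.normal()  # gene-specific effect
        row += rng.normal()  # gene-specific baseline
        rows.append(row)
    return pd.DataFrame(
        rows,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(6)],
    )


class TestFitModerated:
    def test_identical_group_means_give_zero(self):
        m = tiny_matrix(
            np.array([[1.0, 2.0, 1.0, 2.0], [5.0, 6.0, 5.0, 6.0]]),
            ["P-BE", "P-BE", "nonP-BE", "nonP-BE"],
        )
        de, _ = fit_moderated(m)
        np.testing.assert_allclose(de.table["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(de.table["t_mod"], 0.0, atol=1e-12)

    def test_equal_variances_collapse_to_ordinary_t(self):
        """With identical per-gene variances the moderated t IS the pooled t."""
        vals = _equal_variance_matrix()
        de, params = fit_moderated_values(vals, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        t_ord = np.array(
            [
                stats.ttest_ind(vals.iloc[g, :3], vals.iloc[g, 3:]).statistic
                for g in range(len(vals))
            ]
        )
        assert params.d0 == np.inf
        np.testing.assert_allclose(de.table["t_mod"].to_numpy(), t_ord, atol=1e-9)

    def test_finite_d0_brackets_between_oracles(self):
        """Shrinkage: each t_mod lies between the per-gene t and the
        complete-pooling t computed at the prior variance."""
        rng = np.random.default_rng(3)
        sd = rng.uniform(0.3, 3.0, size=50)
        vals = pd.DataFrame(
            rng.normal(size=(50, 6)) * sd[:, None],
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(6)],
        )
        de, params = fit_moderated_values(vals, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert np.isfinite(params.d0)
        v = 1 / 3 + 1 / 3
        a = vals.iloc[:, :3].to_numpy()
        b = vals.iloc[:, 3:].to_numpy()
        lfc = a.mean(axis=1) - b.mean(axis=1)
        s2 = (
            ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            + ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        ) / 4
        t_gene = lfc / np.sqrt(s2 * v)
        t_pool = lfc / np.sqrt(params.s0_sq * v)
        t_mod = de.table["t_mod"].to_numpy()
        lo = np.minimum(np.abs(t_gene), np.abs(t_pool)) - 1e-9
        hi = np.maximum(np.abs(t_gene), np.abs(t_pool)) + 1e-9
        assert np.all((np.abs(t_mod) >= lo) & (np.abs(t_mod) <= hi))

    def test_lods_strictly_increasing_in_abs_t(self):
        rng = np.random.default_rng(4)
        vals = pd.DataFrame(
            rng.normal(size=(200, 8)),
            index=[f"g{i}" for i in range(200)],
            columns=[f"s{j}" for j in range(8)],
        )
        vals.iloc[:10, :4] += 3.0  # a few changed genes so v0 is estimated
        de, _ = fit_moderated_values(vals, [f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 8)])
        t = de.table["t_mod"].abs().to_numpy()
        lods = de.table["lods"].to_numpy()
        order = np.argsort(t)
        assert np.all(np.diff(lods[order]) > -1e-12)
        big = np.abs(np.diff(t[order])) > 1e-6
        assert np.all(np.diff(lods[order])[big] > 0)

    def test_small_group_rejected(self):
        m = tiny_matrix(np.ones((3, 3)), ["P-BE", "nonP-BE", "nonP-BE"])
        with pytest.raises(ValidationError, match="2 samples"):
            fit_moderated(m)

    def test_zero_variance_flagged_not_dropped(self):
        rng = np.random.default_rng(5)
        vals = pd.DataFrame(
            rng.normal(size=(20, 6)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(6)],
        )
        vals.iloc[0] = 7.0  # constant gene
        de, _ = fit_moderated_values(vals, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert de.table["zero_variance"].iloc[0]
        assert len(de.table) == 20

    def test_type_i_error_controlled_on_null(self):
        cfg = SimulationConfig(
            n_genes=2000,
            datasets=[DatasetSpec("D1", "P-BE", 8), DatasetSpec("D2", "nonP-BE", 25)],
            batch_shift_sd=0.0,
            seed=21,
        )
        matrices, _, _ = generate_meta_cohort(cfg)
        vals = pd.concat([m.values for m in matrices], axis=1)
        de, _ = fit_moderated_values(
            vals, matrices[0].sample_ids, matrices[1].sample_ids
        )
        frac = float((de.table["p"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07


class TestSelectCandidates:
    @pytest.fixture()
    def de(self):
        table = pd.DataFrame(
            {
                "log2fc": [1.1, 0.1, 0.5, 0.58, -0.9],
                "mean_expr": 5.0,
                "t_mod": [8.0, -0.5, 7.0, 5.5, -6.0],
                "df_total": 10.0,
                "p": [1e-6, 0.6, 1e-5, 1e-4, 1e-5],
                "p_adj": [5e-6, 0.6, 2.5e-5, 2e-4, 2.5e-5],
                "lods": [5.84, -2.7, 10.0, 5.0, 6.5],
            },
            index=["TWIST1", "MAPKAPK2", "gFC", "gEDGE", "gDOWN"],
        )
        return DEResult(table, EBayesParams(d0=4.0, s0_sq=0.05))

    def test_strong_up_gene_selected(self, de):
        assert "TWIST1" in select_candidates(de).genes

    def test_negative_lods_rejected(self, de):
        assert "MAPKAPK2" not in select_candidates(de).genes

    def test_fold_change_gate(self, de):
        assert "gFC" not in select_candidates(de).genes

    def test_inclusive_bounds(self, de):
        assert "gEDGE" in select_candidates(de).genes

    def test_up_only_flag_drops_downregulated(self, de):
        sel = select_candidates(de, up_only=True)
        assert "gDOWN" not in sel.genes
        assert "gDOWN" in select_candidates(de).genes

    def test_ordered_by_descending_lods(self, de):
        sel = select_candidates(de)
        lods = [de.table.at[g, "lods"] for g in sel.genes]
        assert lods == sorted(lods, reverse=True)


class TestCalibrateNull:
    def test_null_split_passes_at_lods_5(self):
        """20 seeded null replicates: the conservative cutoff is clean in >= 95%."""
        clean = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_genes=2000,
                datasets=[DatasetSpec("D", "EA", 16)],
                batch_shift_sd=0.0,
                seed=seed,
            )
            (m,), _, _ = generate_meta_cohort(cfg)
            a = m.subset_samples(m.sample_ids[:8])
            b = m.subset_samples(m.sample_ids[8:])
            rep = calibrate_null(a, b, lods_min=5.0)
            if rep["n_above"] == 0:
                clean += 1
            assert rep["max_lods"] == rep["max_lods"]  # finite
        assert clean >= 19

    def test_unnormalized_shift_is_flagged(self):
        """A +3 mean shift on one half without normalization trips the cutoff,
        demonstrating why calibration precedes threshold use."""
        cfg = SimulationConfig(
            n_genes=500, datasets=[DatasetSpec("D", "EA", 16)], batch_shift_sd=0.0, seed=1
        )
        (m,), _, _ = generate_meta_cohort(cfg)
        even = m.subset_samples(m.sample_ids[0::2])
        odd = m.subset_samples(m.sample_ids[1::2])
        odd.values.iloc[:, :] = odd.values.to_numpy() + 3.0
        rep = calibrate_null(even, odd, lods_min=5.0)
        assert rep["n_above"] > 0

    def test_mismatched_gene_sets_rejected(self):
        m1 = tiny_matrix(np.ones((2, 2)), ["EA", "EA"], prefix="a")
        m2 = tiny_matrix(np.ones((3, 2)), ["EA", "EA"], prefix="b")
        with pytest.raises(ValidationError, match="gene set"):
            calibrate_null(m1, m2)
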