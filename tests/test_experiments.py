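"""Replicate batches, grids, persistence summaries, variance diagnostics."""

import numpy as np
import pandas as pd
import pytest

from plastisim import (
    PersistenceSummary,
    ScenarioGrid,
    SimulationConfig,
    persistence_summary,
    run_grid,
    run_replicate,
    run_scenario,
    variance_diagnostics,
)
from plastisim.experiments import CELL_SEED_STRIDE


def base_cfg(**kw):
    d = dict(K=500, psi=1.0, t_max=30, seed=0)
    d.update(kw)
    return SimulationConfig.from_values(**d)


class TestPersistenceSummary:
    def test_all_persisted(self):
        s = PersistenceSummary(n_reps=100, n_persisted=100)
        assert s.p == 1.0 and s.se == 0.0

    def test_half_persisted(self):
        s = PersistenceSummary(n_reps=100, n_persisted=50)
        assert s.p == 0.5
        assert s.se == pytest.approx(0.05)

    def test_nine_of_ten(self):
        s = PersistenceSummary(n_reps=10, n_persisted=9)
        assert s.p == pytest.approx(0.9)
        assert s.se == pytest.approx(0.0949, abs=1e-4)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            persistence_summary([])

    def test_counts_actual_records(self):
        recs = run_scenario(base_cfg(t_max=5), 4)
        s = persistence_summary(recs)
        assert s.n_reps == 4 and s.n_persisted == 4

    def test_wilson_interval_contains_p(self):
        s = PersistenceSummary(n_reps=20, n_persisted=19)
        lo, hi = s.wilson_interval()
        assert lo < s.p <= hi <= 1.0 + 1e-12


class TestScenarioGrid:
    def test_single_cell(self):
        grid = ScenarioGrid(base=base_cfg(t_max=5), axes={"eta": [0.0]}, n_reps=1)
        table = run_grid(grid)
        assert len(table) == 1
        assert table["p"].iloc[0] == 1.0

    def test_cartesian_product_size(self):
        grid = ScenarioGrid(
            base=base_cfg(t_max=2),
            axes={"eta": [0.0, 0.01], "alpha": [-0.4, 0.0, 0.4], "plasticity": ["none", "linear"]},
            n_reps=1,
        )
        table = run_grid(grid)
        assert len(table) == 12
        assert set(table["plasticity"]) == {"none", "linear"}

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError):
            ScenarioGrid(base=base_cfg(), axes={"kappa": [1]})

    def test_cells_seeded_locally_and_order_independent(self):
        grid = ScenarioGrid(
            base=base_cfg(t_max=10), axes={"eta": [0.0, 0.5]}, n_reps=3
        )
        table = run_grid(grid)
        # cell 1 recomputed standalone must match its grid row
        cfg1 = grid.cell_config({"eta": 0.5})
        recs = run_scenario(cfg1, 3, seed_offset=CELL_SEED_STRIDE * 1)
        s = persistence_summary(recs)
        assert table["n_persisted"].iloc[1] == s.n_persisted
        cfg0 = grid.cell_config({"eta": 0.0})
        s0 = persistence_summary(run_scenario(cfg0, 3, seed_offset=0))
        assert table["n_persisted"].iloc[0] == s0.n_persisted

    def test_persistence_declines_with_rate_of_change(self):
        # rapid change kills low-fecundity, non-plastic populations
        grid = ScenarioGrid(
            base=SimulationConfig.from_values(K=1000, psi=0.5, t_max=250, seed=0),
            axes={"eta": [0.0, 0.04]},
            n_reps=20,
        )
        table = run_grid(grid)
        p0 = table.loc[table["eta"] == 0.0, "p"].iloc[0]
        p4 = table.loc[table["eta"] == 0.04, "p"].iloc[0]
        assert p0 > p4

    def test_disjoint_seed_blocks_agree_within_binomial_error(self):
        cfg = SimulationConfig.from_values(
            K=1000, psi=0.5, eta=0.04, plasticity="linear", t_max=250, seed=0
        )
        s1 = persistence_summary(run_scenario(cfg, 20, seed_offset=0))
        s2 = persistence_summary(run_scenario(cfg, 20, seed_offset=10_000))
        combined_se = np.sqrt(s1.se**2 + s2.se**2)
        assert abs(s1.p - s2.p) <= 3 * max(combined_se, 0.05)


class TestVarianceDiagnostics:
    def test_linear_mode_ratio_is_one(self):
        rec = run_replicate(base_cfg(plasticity="linear", eta=0.02), 0)
        d = variance_diagnostics(rec)
        np.testing.assert_allclose(d["ratio_var"], 1.0, atol=1e-9)
        assert not d["degenerate"].any()

    def test_random_mode_heritability(self):
        # h^2 = Var(a) / (Var(a) + VE) ~ 0.2 / 1.2 at initialization
        rec = run_replicate(
            SimulationConfig.from_values(K=1000, psi=1.0, plasticity="random", t_max=20, seed=4), 0
        )
        d = variance_diagnostics(rec)
        assert d["h2"].mean() == pytest.approx(0.2 / 1.2, abs=0.02)

    def test_limited_plasticity_canalizes_locally_adapted_cohorts(self):
        rec = run_replicate(
            SimulationConfig.from_values(K=1000, psi=1.0, plasticity="sinusoidal", t_max=20, seed=4), 0
        )
        d = variance_diagnostics(rec)
        assert d["ratio_var"].median() < 1.0

    def test_degenerate_denominators_flagged(self):
        rec = run_replicate(base_cfg(VG=0.0, mu=0.0, t_max=5), 0)
        d = variance_diagnostics(rec)
        assert d["degenerate"].all()
        assert d["ratio_var"].isna().all()

    def test_empty_record_rejected(self):
        import pandas as pd

        from plastisim import ReplicateRecord

        rec = ReplicateRecord(persisted=False, extinction_generation=1, series=pd.DataFrame())
        with pytest.raises(ValueError):
            variance_diagnostics(rec)
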