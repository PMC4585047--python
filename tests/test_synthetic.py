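"""Generator: latent networks, PSD repair, copula counts, fixture round trips."""

import numpy as np
import pandas as pd
import pytest

from fosnet.errors import GenerationError, ParseError, SpecificationError
from fosnet.io import read_sample_table
from fosnet.synthetic import (
    REGIONS,
    GeneratorConfig,
    HubSpec,
    attenuated_correlation,
    build_latent_correlation,
    flat_cell_means,
    repair_psd,
    simulate_counts,
    study_config,
    write_fixture,
)


class TestBuildLatentCorrelation:
    def test_independence_gives_identity(self):
        c, delta = build_latent_correlation(3, 0.0)
        assert np.array_equal(c, np.eye(3))
        assert delta == 0.0

    def test_hub_entries_set_by_construction(self):
        c, delta = build_latent_correlation(3, 0.0, HubSpec(0, (1, 2), 0.7))
        assert c[0, 1] == c[0, 2] == pytest.approx(0.7)
        assert c[1, 2] == 0.0
        assert np.array_equal(c, c.T)
        assert np.array_equal(np.diag(c), np.ones(3))
        # this star is just inside the PSD cone (min eig = 1 - 0.7*sqrt(2))
        assert delta == 0.0

    def test_strong_hub_star_needs_visible_psd_repair(self):
        # raw target: base 0.2 with a 3-partner hub at 0.8 — eigendecomposition
        # shows it lies outside the PSD cone, so the default repair cap trips
        raw = np.full((17, 17), 0.2)
        np.fill_diagonal(raw, 1.0)
        for p in (1, 2, 3):
            raw[0, p] = raw[p, 0] = 0.8
        assert np.linalg.eigvalsh(raw).min() < -1e-6
        with pytest.raises(GenerationError):
            build_latent_correlation(17, 0.2, HubSpec(0, (1, 2, 3), 0.8))
        c, delta = build_latent_correlation(
            17, 0.2, HubSpec(0, (1, 2, 3), 0.8), max_repair=0.5
        )
        assert np.linalg.eigvalsh(c).min() >= -1e-10
        assert 0.05 < delta < 0.5

    def test_invalid_specifications_rejected(self):
        with pytest.raises(SpecificationError):
            build_latent_correlation(1, 0.0)
        with pytest.raises(SpecificationError):
            build_latent_correlation(3, 1.0)
        with pytest.raises(SpecificationError):
            build_latent_correlation(3, 0.0, HubSpec(0, (3,), 0.5))
        with pytest.raises(SpecificationError):
            build_latent_correlation(3, 0.0, HubSpec(0, (0, 1), 0.5))


def test_repair_psd_leaves_psd_input_untouched():
    c = np.array([[1.0, 0.3], [0.3, 1.0]])
    out, delta = repair_psd(c)
    assert np.array_equal(out, c)
    assert delta == 0.0


def _simple_config(n_per_cell=5, dispersion=0.3, seed=0, regions=("A", "B", "C"), base_r=0.0):
    corr, _ = build_latent_correlation(len(regions), base_r)
    return GeneratorConfig(
        region_names=regions,
        n_per_cell=n_per_cell,
        cell_means=flat_cell_means(regions, 60.0),
        dispersion=dispersion,
        latent_corr={"MA": corr, "SAL": corr},
        seed=seed,
    )


class TestSimulateCounts:
    def test_zero_dispersion_counts_equal_cell_means(self):
        cfg = _simple_config(dispersion=0.0)
        table = simulate_counts(cfg)
        assert len(table) == 4 * cfg.n_per_cell
        assert (table[list(cfg.region_names)] == 60.0).all().all()

    def test_same_seed_is_byte_identical(self):
        a = simulate_counts(_simple_config(seed=11)).to_csv(index=False)
        b = simulate_counts(_simple_config(seed=11)).to_csv(index=False)
        c = simulate_counts(_simple_config(seed=12)).to_csv(index=False)
        assert a == b
        assert a != c

    def test_counts_nonnegative_and_shape(self):
        table = simulate_counts(study_config(seed=3))
        assert len(table) == 40
        assert (table[list(REGIONS)] >= 0).all().all()
        assert table["treatment"].value_counts().to_dict() == {"MA": 20, "SAL": 20}

    def test_realized_moments_match_configured(self):
        # means to ~2% and correlations to ±0.05 at a moderate sample size
        cfg = _simple_config(n_per_cell=2000, dispersion=0.3, base_r=0.5, seed=21)
        table = simulate_counts(cfg)
        x = table[list(cfg.region_names)].to_numpy()
        assert np.abs(x.mean(axis=0) / 60.0 - 1.0).max() < 0.02
        target = attenuated_correlation(0.5, 0.3, 0.3)
        c = np.corrcoef(x.T)
        off = c[~np.eye(3, dtype=bool)]
        assert np.abs(off - target).max() < 0.05

    def test_hub_group_exceeds_control_on_hub_edges(self):
        cfg = study_config(n_per_cell=500, base_r=0.2, hub_r=0.7, seed=5)
        table = simulate_counts(cfg)
        idx = {r: i for i, r in enumerate(REGIONS)}
        ma = np.corrcoef(table[table.treatment == "MA"][list(REGIONS)].to_numpy().T)
        sal = np.corrcoef(table[table.treatment == "SAL"][list(REGIONS)].to_numpy().T)
        for partner in ("PVN", "BLA", "MEA"):
            assert ma[idx["VMH"], idx[partner]] > sal[idx["VMH"], idx[partner]]


def test_attenuation_formula_matches_monte_carlo():
    # independent large-sample oracle: simulate the bivariate lognormal directly
    rho, cv = 0.6, 0.4
    rng = np.random.default_rng(42)
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=100_000)
    sigma = np.sqrt(np.log1p(cv * cv))
    x = np.exp(sigma * z)  # common scale factor cancels in the correlation
    mc = np.corrcoef(x.T)[0, 1]
    assert attenuated_correlation(rho, cv, cv) == pytest.approx(mc, abs=0.01)


class TestWriteFixture:
    def test_roundtrip_equals_input(self, tmp_path):
        table = simulate_counts(_simple_config(seed=2))
        path = tmp_path / "t.csv"
        write_fixture(table, path)
        back = read_sample_table(path)
        pd.testing.assert_frame_equal(back, table)

    def test_empty_table_is_error_not_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        with pytest.raises(ParseError):
            write_fixture(pd.DataFrame(columns=["animal_id", "treatment", "phase", "A"]), path)
        assert not path.exists()

    def test_line_count_header_plus_rows(self, tmp_path):
        table = simulate_counts(study_config(seed=1))
        path = tmp_path / "t.csv"
        write_fixture(table, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 41
        assert lines[0].split(",")[:3] == ["animal_id", "treatment", "phase"]
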