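"""Generator correctness: closed forms, determinism, protein tables, round trips."""

import numpy as np
import pytest

from syntroflux.catalog import Assembly
from syntroflux.fit import proteomics_prior
from syntroflux.measurements import cumulative_table
from syntroflux.synthetic import (
    ConfigError,
    GeneratorConfig,
    PRESET_EXTENTS,
    preset_config,
    round_trip_check,
    simulate_culture,
    simulate_proteins,
)


def _config(label, extents, **kw):
    return GeneratorConfig(assembly=Assembly.from_label(label),
                           true_extents=extents, **kw)


class TestSimulateCulture:
    def test_zero_extents_stay_at_baseline(self, catalog):
        cfg = _config("Rc&Mc", {}, noise_cv=0.0)
        sim = simulate_culture(cfg, catalog)
        for s in sim.true_series:
            assert all(v == 0.0 for v in s.cumulative.values())
        aqueous = [r for r in sim.readings
                   if catalog.metabolite(r.analyte).phase == "aqueous"]
        assert all(r.value == 0.0 for r in aqueous)

    def test_closed_form_methane_and_acetate(self, catalog):
        # acetogenesis 0.05/day and acetoclastic 0.04/day for 7 days:
        # CH4 = 0.28, acetate = 2*0.35 - 0.28 = 0.42
        cfg = _config("Rc&Mc", {"hydrogenic_acetogenesis": 0.35,
                                "acetoclastic_methanogenesis": 0.28},
                      noise_cv=0.0)
        sim = simulate_culture(cfg, catalog)
        finals = {s.analyte: s.final for s in sim.true_series}
        assert finals["CH4"] == pytest.approx(0.28)
        assert finals["acetate"] == pytest.approx(0.42)

    def test_seeded_determinism_bitwise(self, catalog):
        cfg = preset_config("Rc&Mc&Mh&Dv", seed=17, noise_cv=0.05)
        a = simulate_culture(cfg, catalog)
        b = simulate_culture(cfg, catalog)
        assert [r.value for r in a.readings] == [r.value for r in b.readings]

    def test_different_seeds_differ(self, catalog):
        a = simulate_culture(preset_config("Rc&Mc", seed=1, noise_cv=0.05), catalog)
        b = simulate_culture(preset_config("Rc&Mc", seed=2, noise_cv=0.05), catalog)
        assert [r.value for r in a.readings] != [r.value for r in b.readings]

    def test_extent_for_inactive_species_rejected(self, catalog):
        cfg = _config("Rc", {"acetoclastic_methanogenesis": 0.1})
        with pytest.raises(ConfigError, match="inactive"):
            simulate_culture(cfg, catalog)

    def test_bookkeeping_inverts_exactly_at_zero_noise(self, catalog):
        # cumulative-production correction applied to generated readings
        # reproduces the true series to machine precision
        for label in PRESET_EXTENTS:
            cfg = preset_config(label, noise_cv=0.0, n_replicates=1)
            sim = simulate_culture(cfg, catalog)
            cum = cumulative_table(sim.readings, catalog)
            truth = {s.analyte: s for s in sim.true_series}
            for (_, _, analyte), grp in cum.groupby(
                ["culture", "replicate", "analyte"]
            ):
                for _, row in grp.iterrows():
                    expect = truth[analyte].cumulative[int(row["day"])]
                    assert row["mmol"] == pytest.approx(expect, abs=1e-12), label

    def test_generated_series_conserve_carbon_and_electrons(self, catalog):
        # products' carbon equals glucose-equivalent carbon consumed (6 per
        # unit fermentation extent); electrons likewise (24 per unit)
        cfg = preset_config("Rc&Mc&Mh&Dv", noise_cv=0.0)
        sim = simulate_culture(cfg, catalog)
        finals = {s.analyte: s.final for s in sim.true_series}
        carbon = sum(finals[a] * catalog.metabolite(a).carbon for a in finals)
        electrons = sum(finals[a] * catalog.metabolite(a).gamma for a in finals)
        glc = sum(sim.true_extents[r] for r in
                  ["lactate_fermentation", "hydrogenic_acetogenesis",
                   "mixed_acid_fermentation"])
        assert carbon == pytest.approx(6 * glc, abs=1e-9)
        assert electrons == pytest.approx(24 * glc, abs=1e-9)


class TestSimulateProteins:
    def test_zero_extents_leave_markers_at_background(self, catalog):
        cfg = _config("Rc&Mc", {}, protein_noise_cv=0.0)
        table, mapping = simulate_proteins(cfg, catalog)
        markers = [p for p in table.index if p in mapping]
        assert all(table.loc[p].iloc[0] == 0.0 for p in markers)

    def test_marker_ratio_tracks_extent_ratio(self, catalog):
        cfg = _config("Rc", {"lactate_fermentation": 0.4,
                             "hydrogenic_acetogenesis": 0.1},
                      protein_noise_cv=0.0)
        table, mapping = simulate_proteins(cfg, catalog)
        col = table.iloc[:, 0]
        lf = np.mean([col[p] for p, r in mapping.items()
                      if r == "lactate_fermentation"])
        ha = np.mean([col[p] for p, r in mapping.items()
                      if r == "hydrogenic_acetogenesis"])
        assert lf / ha == pytest.approx(4.0)

    def test_per_species_columns_sum_to_one(self, catalog):
        cfg = preset_config("Rc&Mc&Mh&Dv", seed=5)
        table, _ = simulate_proteins(cfg, catalog)
        col = table.iloc[:, 0]
        for sp in ["Rc", "Mc", "Mh", "Dv"]:
            total = col[[p for p in col.index if p.startswith(sp + "|")]].sum()
            assert total == pytest.approx(1.0)

    def test_prior_positively_correlates_with_true_extents(self, catalog):
        cfg = preset_config("Rc&Mc", seed=3, protein_noise_cv=0.02)
        table, mapping = simulate_proteins(cfg, catalog)
        prior = proteomics_prior(table, mapping, catalog, "Rc&Mc")
        true = PRESET_EXTENTS["Rc&Mc"]
        rids = sorted(true)
        r = np.corrcoef([true[r] for r in rids],
                        [prior.extents[r] for r in rids])[0, 1]
        assert r > 0


class TestRoundTrip:
    def test_noise_free_recovery_identifiable_assemblies(self, catalog):
        for label in ["Rc", "Rc&Mc", "Rc&Mh", "Rc&Mc&Mh"]:
            rep = round_trip_check(preset_config(label, noise_cv=0.0), catalog)
            assert rep.max_relative_error <= 1e-6, label
            assert rep.r_squared == pytest.approx(1.0)
            assert rep.nrmse == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_assemblies_fit_data_exactly_despite_nonunique_extents(
        self, catalog
    ):
        # with Dv present, acetogenesis == lactate fermentation + 2x lactate
        # oxidation over every metabolite, so extents are non-unique; the
        # fitted productions must still match the data exactly
        for label in ["Rc&Dv", "Rc&Mh&Dv", "Rc&Mc&Dv", "Rc&Mc&Mh&Dv"]:
            rep = round_trip_check(preset_config(label, noise_cv=0.0), catalog)
            assert rep.r_squared == pytest.approx(1.0), label
            assert rep.nrmse == pytest.approx(0.0, abs=1e-9), label

    def test_noise_widens_error_but_stays_bounded(self, catalog):
        errors = []
        for seed in range(1, 51):
            rep = round_trip_check(
                preset_config("Rc&Mc", seed=seed, noise_cv=0.05), catalog
            )
            errors += list(rep.relative_errors.values())
        assert np.median(errors) <= 0.10
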