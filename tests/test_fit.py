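"""Extent estimation: oracle equivalence, recovery, priors, fit quality."""

import numpy as np
import pandas as pd
import pytest

from syntroflux.catalog import Assembly, active_reactions, build_matrix
from syntroflux.fit import (
    DEFAULT_ANALYTES,
    PriorActivity,
    bootstrap_extents,
    fit_culture,
    fit_extents,
    goodness_of_fit,
    proteomics_prior,
)

ANALYTES = list(DEFAULT_ANALYTES)


def _active(catalog, label):
    assembly = Assembly.from_label(label)
    reactions = active_reactions(assembly, catalog)
    rids = [r.id for r in reactions]
    S = build_matrix(reactions, ANALYTES, strict=False)
    return S, rids


FULL_RANK_LABELS = ["Rc", "Rc&Mc", "Rc&Mh", "Rc&Mc&Mh"]


class TestFitExtents:
    def test_zero_target_gives_zero_extents(self, catalog):
        S, rids = _active(catalog, "Rc&Mc")
        res = fit_extents(S, np.zeros(len(ANALYTES)), rids, ANALYTES)
        assert all(v == 0 for v in res.extents.values())

    def test_two_methanogen_recovery_vs_flat_grid(self, catalog, grid_oracle):
        # flat 1e-3 grid over [0, 0.5]^2 is feasible for the 2-reaction case
        rxns = [catalog.reaction("acetoclastic_methanogenesis"),
                catalog.reaction("hydrogenotrophic_methanogenesis")]
        rids = [r.id for r in rxns]
        S = build_matrix(rxns, ANALYTES, strict=False)
        true = np.array([0.3, 0.1])
        y = S @ true
        res = fit_extents(S, y, rids, ANALYTES, weights=np.ones(len(ANALYTES)))
        est = np.array([res.extents[r] for r in rids])
        assert np.allclose(est, true, atol=1e-6)
        # genuinely exhaustive flat grid at 1e-3
        axes = np.arange(0.0, 0.5 + 1e-9, 1e-3)
        g1, g2 = np.meshgrid(axes, axes, indexing="ij")
        pts = np.stack([g1.ravel(), g2.ravel()], axis=1)
        sse = ((S @ pts.T - y[:, None]) ** 2).sum(axis=0)
        best = pts[np.argmin(sse)]
        assert np.allclose(est, best, atol=1e-3)

    @pytest.mark.parametrize("label", FULL_RANK_LABELS)
    def test_oracle_equivalence_per_assembly(self, catalog, grid_oracle, label):
        # solver matches the zoomed exhaustive grid on seeded random targets
        S, rids = _active(catalog, label)
        rng = np.random.default_rng(42)
        w = np.ones(len(ANALYTES))
        for _ in range(20):
            true = rng.uniform(0.0, 0.5, size=len(rids))
            y = S @ true
            res = fit_extents(S, y, rids, ANALYTES, weights=w)
            est = np.array([res.extents[r] for r in rids])
            best, best_sse = grid_oracle(S, y, weights=w, lo=0.0, hi=0.5)
            assert np.abs(est - best).max() <= 2e-3
            sse_est = float(((S @ est - y) ** 2).sum())
            assert sse_est <= best_sse + 1e-9

    def test_rank_deficient_objective_matches_oracle(self, catalog, grid_oracle):
        # with Dv present the catalogue is rank-deficient: extents are not
        # unique, but the solver must still reach the oracle's objective
        S, rids = _active(catalog, "Rc&Dv")
        rng = np.random.default_rng(7)
        w = np.ones(len(ANALYTES))
        for _ in range(5):
            true = rng.uniform(0.0, 0.5, size=len(rids))
            y = S @ true
            res = fit_extents(S, y, rids, ANALYTES, weights=w)
            assert res.warnings  # rank deficiency is surfaced, not hidden
            est = np.array([res.extents[r] for r in rids])
            _, best_sse = grid_oracle(S, y, weights=w, lo=0.0, hi=0.5)
            assert float(((S @ est - y) ** 2).sum()) <= best_sse + 1e-9

    @pytest.mark.parametrize("label", FULL_RANK_LABELS)
    def test_noise_free_recovery_full_rank(self, catalog, label):
        S, rids = _active(catalog, label)
        rng = np.random.default_rng(11)
        for _ in range(10):
            true = rng.uniform(0.0, 1.0, size=len(rids))
            res = fit_extents(S, S @ true, rids, ANALYTES)
            est = np.array([res.extents[r] for r in rids])
            assert np.abs(est - true).max() <= 1e-6

    def test_noisy_recovery_median_error_below_ten_percent(self, catalog):
        S, rids = _active(catalog, "Rc&Mc&Mh")
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            true = rng.uniform(0.1, 1.0, size=len(rids))
            y = (S @ true) * (1 + 0.05 * rng.standard_normal(len(ANALYTES)))
            res = fit_extents(S, y, rids, ANALYTES)
            est = np.array([res.extents[r] for r in rids])
            errors += list(np.abs(est - true) / true)
        assert np.median(errors) <= 0.10

    def test_lambda_moves_extents_monotonically_toward_prior(self, catalog):
        S, rids = _active(catalog, "Rc&Mc")
        rng = np.random.default_rng(3)
        true = rng.uniform(0.2, 0.6, size=len(rids))
        y = S @ true
        prior = PriorActivity({r: 0.1 for r in rids}, "uniform")
        a = prior.vector(rids)
        dists = []
        for lam in [0.0, 0.01, 0.1, 1.0, 10.0, 100.0]:
            res = fit_extents(S, y, rids, ANALYTES, prior=prior, lambda_=lam)
            est = np.array([res.extents[r] for r in rids])
            dists.append(np.linalg.norm(est - a))
        assert all(d2 <= d1 + 1e-9 for d1, d2 in zip(dists, dists[1:]))

    def test_fitted_productions_conserve_carbon_and_electrons(self, catalog):
        # net production implied by any extent vector balances against the
        # glucose-equivalent consumed, because every reaction balances
        mets = catalog.metabolite_ids
        S_all = build_matrix(list(catalog.reactions.values()), mets)
        carbon = np.array([catalog.metabolite(m).carbon for m in mets])
        gamma = np.array([catalog.metabolite(m).gamma for m in mets])
        rng = np.random.default_rng(5)
        for _ in range(10):
            xi = rng.uniform(0, 1, size=S_all.shape[1])
            net = S_all @ xi
            assert abs(carbon @ net) < 1e-12
            assert abs(gamma @ net) < 1e-12


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        r2, nrmse = goodness_of_fit([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert r2 == 1.0 and nrmse == 0.0

    def test_single_analyte_worked_example(self):
        # SSres=1, SStot=5 -> R2=0.8; RMSE=0.5 over range 3 -> 0.1667
        r2, nrmse = goodness_of_fit([0, 1, 2, 3], [0.5, 1.5, 1.5, 2.5])
        assert r2 == pytest.approx(0.8)
        assert nrmse == pytest.approx(1 / 6, abs=1e-4)

    def test_zero_variance_reports_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            r2, _ = goodness_of_fit([1.0, 1.0, 1.0], [1.0, 1.1, 0.9])
        assert np.isnan(r2)


class TestProteomicsPrior:
    def _table(self, values, culture="Rc&Mc"):
        return pd.DataFrame({culture: pd.Series(values)})

    def test_all_zero_abundances_give_zero_prior(self, catalog):
        table = self._table({"p1": 0.0, "p2": 0.0})
        mapping = {"p1": "hydrogenic_acetogenesis", "p2": "acetoclastic_methanogenesis"}
        prior = proteomics_prior(table, mapping, catalog, "Rc&Mc")
        assert all(v == 0 for v in prior.extents.values())

    def test_atp_yield_ratio_before_rescaling(self, catalog):
        # equal marker abundance, ATP yields 4 (acetogenesis) vs 1 (lactate
        # oxidation) -> 4:1 prior ratio
        table = self._table({"p1": 0.2, "p2": 0.2}, culture="Rc&Dv")
        mapping = {"p1": "hydrogenic_acetogenesis", "p2": "hydrogenic_lactate_oxidation"}
        prior = proteomics_prior(table, mapping, catalog, "Rc&Dv")
        ratio = (prior.extents["hydrogenic_acetogenesis"]
                 / prior.extents["hydrogenic_lactate_oxidation"])
        assert ratio == pytest.approx(4.0)

    def test_scale_invariance_of_rescaled_prior(self, catalog):
        values = {"p1": 0.1, "p2": 0.3, "p3": 0.05}
        mapping = {"p1": "hydrogenic_acetogenesis", "p2": "acetoclastic_methanogenesis",
                   "p3": "lactate_fermentation"}
        p1 = proteomics_prior(self._table(values), mapping, catalog, "Rc&Mc")
        scaled = {k: 7.3 * v for k, v in values.items()}
        p2 = proteomics_prior(self._table(scaled), mapping, catalog, "Rc&Mc")
        for rid in p1.extents:
            assert p1.extents[rid] == pytest.approx(p2.extents[rid])

    def test_unmapped_reaction_gets_mean_prior(self, catalog):
        table = self._table({"p1": 0.2})
        mapping = {"p1": "hydrogenic_acetogenesis"}
        prior = proteomics_prior(table, mapping, catalog, "Rc&Mc")
        mapped = prior.extents["hydrogenic_acetogenesis"]
        assert prior.extents["lactate_fermentation"] == pytest.approx(mapped)

    def test_missing_culture_is_key_error(self, catalog):
        with pytest.raises(KeyError):
            proteomics_prior(self._table({"p1": 1.0}), {}, catalog, "Rc&Mh")


class TestBootstrap:
    def test_identical_replicates_give_zero_sd(self, catalog):
        S, rids = _active(catalog, "Rc&Mc")
        true = np.array([0.35, 0.42, 0.10, 0.32])
        y = S @ true
        mean, sd = bootstrap_extents(S, [y, y.copy()], rids, ANALYTES,
                                     n_boot=50, seed=1)
        single = fit_extents(S, y, rids, ANALYTES)
        for rid in rids:
            assert sd[rid] == pytest.approx(0.0, abs=1e-12)
            assert mean[rid] == pytest.approx(single.extents[rid], abs=1e-9)

    def test_deterministic_given_seed(self, catalog):
        S, rids = _active(catalog, "Rc&Mh")
        rng = np.random.default_rng(0)
        ys = [S @ rng.uniform(0.1, 0.5, len(rids)) for _ in range(3)]
        a = bootstrap_extents(S, ys, rids, ANALYTES, n_boot=100, seed=9)
        b = bootstrap_extents(S, ys, rids, ANALYTES, n_boot=100, seed=9)
        assert a == b

    def test_too_few_draws_rejected(self, catalog):
        S, rids = _active(catalog, "Rc")
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_extents(S, [np.zeros(6)] * 2, rids, ANALYTES, n_boot=1)


class TestFitCulture:
    def _cum_table(self, catalog, label, extents, days=7, reps=2):
        assembly = Assembly.from_label(label)
        reactions = active_reactions(assembly, catalog)
        rids = [r.id for r in reactions]
        S = build_matrix(reactions, ANALYTES, strict=False)
        xi = np.array([extents.get(r, 0.0) for r in rids])
        rows = []
        for rep in range(reps):
            for d in range(days + 1):
                net = S @ xi * (d / days)
                for a, v in zip(ANALYTES, net):
                    rows.append({"culture": label, "replicate": f"r{rep+1}",
                                 "analyte": a, "day": d, "mmol": v})
        return pd.DataFrame(rows)

    def test_endpoint_and_trajectory_agree_noise_free(self, catalog):
        true = {"lactate_fermentation": 0.35, "hydrogenic_acetogenesis": 0.42,
                "mixed_acid_fermentation": 0.10, "acetoclastic_methanogenesis": 0.32}
        cum = self._cum_table(catalog, "Rc&Mc", true)
        for mode in ("endpoint", "trajectory"):
            fit = fit_culture(cum, Assembly.from_label("Rc&Mc"), catalog, mode=mode)
            for rid, v in true.items():
                assert fit.mean_extents[rid] == pytest.approx(v, abs=1e-8), mode
            assert fit.r_squared == pytest.approx(1.0)
            assert fit.nrmse == pytest.approx(0.0, abs=1e-9)
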