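"""K_D estimation: per-residue fits, hotspot rule, site averages, two-site."""
import dataclasses

import numpy as np
import pytest

from cspfit import (CSPProfile, InsufficientDataError, NonBindingError,
                    SingleSiteParams, TwoSiteParams, build_profiles,
                    fit_single_residue, fit_site_average, fit_two_site,
                    format_report, report, select_hotspots, simulate_titration,
                    site_mean_curve)
from cspfit.fitting import SingleSiteFit
from cspfit.simulate import (SCHEDULE_RECOMBINANT, SCHEDULE_SYNTHETIC,
                             SimulationSpec)

from conftest import noiseless


def _profiles_and_series(spec):
    series, truth = simulate_titration(spec)
    return build_profiles(series), series, truth


def _make_profiles(values):
    """CSPProfiles with a single meaningful (final) point per residue."""
    return [CSPProfile(residue_id=rid, delta_delta=np.array([0.0, v]),
                       flags=("observed", "observed"))
            for rid, v in values.items()]


class TestSelectHotspots:
    def test_mean_plus_sd_rule_on_toy_vector(self):
        profiles = _make_profiles({1: 0.01, 2: 0.02, 3: 0.03, 4: 0.10})
        sel = select_hotspots(profiles, point=1)
        assert sel.mean == pytest.approx(0.04)
        assert sel.sd == pytest.approx(0.040825, abs=1e-6)
        assert sel.threshold == pytest.approx(0.080825, abs=1e-6)
        assert sel.threshold == sel.mean + sel.sd
        assert sel.selected == (4,)

    def test_degenerate_tie_selects_everyone(self):
        profiles = _make_profiles({1: 0.05, 2: 0.05, 3: 0.05})
        sel = select_hotspots(profiles, point=1)
        assert sel.sd == pytest.approx(0.0, abs=1e-15)
        assert sel.selected == (1, 2, 3)

    def test_too_few_residues(self):
        with pytest.raises(InsufficientDataError):
            select_hotspots(_make_profiles({1: 0.05, 2: 0.02}), point=1)

    def test_input_order_invariance(self):
        vals = {1: 0.01, 2: 0.02, 3: 0.03, 4: 0.10, 5: 0.07}
        a = select_hotspots(_make_profiles(vals), point=1)
        b = select_hotspots(list(reversed(_make_profiles(vals))), point=1)
        assert a == b

    def test_residue_range_and_intermediate_exclusion(self):
        from cspfit import ExchangeCall
        vals = {1: 0.01, 2: 0.02, 3: 0.03, 4: 0.10, 5: 5.0}
        calls = [ExchangeCall(5, "intermediate", "peak absent")]
        sel = select_hotspots(_make_profiles(vals), point=1,
                              residue_range=(1, 5), exchange_calls=calls)
        assert 5 in sel.intermediate
        assert sel.selected == (4,)  # 5 excluded from statistics entirely


class TestFitSingleResidue:
    def test_noiseless_recovery_on_recombinant_schedule(self, fixtures):
        spec = noiseless(fixtures["ww4_smad7_recombinant"])
        profiles, series, truth = _profiles_and_series(spec)
        binder = next(p for p in profiles
                      if truth["amplitudes_ppm"][p.residue_id] > 0)
        fit = fit_single_residue(binder, series)
        assert fit.converged
        assert fit.kd == pytest.approx(0.237, rel=1e-6)
        assert fit.ddmax == pytest.approx(
            truth["amplitudes_ppm"][binder.residue_id], rel=1e-6)

    def test_flat_profile_is_non_binding(self):
        prof = CSPProfile(1, np.zeros(10), ("observed",) * 10)
        spec = SimulationSpec(label="x", model="single",
                              true_params=SingleSiteParams(0.2, 0.1, 0.08),
                              ratios=SCHEDULE_RECOMBINANT, noise_sd=0.0)
        series, _ = simulate_titration(spec)
        with pytest.raises(NonBindingError):
            fit_single_residue(prof, series)

    def test_three_points_insufficient(self):
        prof = CSPProfile(1, np.array([0.0, 0.05, 0.08]), ("observed",) * 3)
        spec = SimulationSpec(label="x", model="single",
                              true_params=SingleSiteParams(0.2, 0.1, 0.08),
                              ratios=(0.0, 1.0, 2.0), noise_sd=0.0)
        series, _ = simulate_titration(spec)
        with pytest.raises(InsufficientDataError):
            fit_single_residue(prof, series)

    def test_missing_points_excluded_not_imputed(self, fixtures):
        spec = noiseless(fixtures["ww4_smad7_recombinant"])
        profiles, series, truth = _profiles_and_series(spec)
        binder = next(p for p in profiles
                      if truth["amplitudes_ppm"][p.residue_id] > 0)
        dd = binder.delta_delta.copy()
        dd[4] = np.nan
        flags = tuple("missing" if i == 4 else f
                      for i, f in enumerate(binder.flags))
        gappy = CSPProfile(binder.residue_id, dd, flags)
        fit = fit_single_residue(gappy, series)
        assert fit.n_points == 9
        assert fit.kd == pytest.approx(0.237, rel=1e-6)


class TestFitSiteAverage:
    def test_single_residue_selection_equals_direct_fit(self, fixtures):
        spec = noiseless(fixtures["ww4_smad7_recombinant"])
        profiles, series, truth = _profiles_and_series(spec)
        rid = max(truth["amplitudes_ppm"], key=truth["amplitudes_ppm"].get)
        from cspfit.fitting import HotspotSelection
        sel = HotspotSelection("one", (rid,), 0.0, 0.0, 0.0, 9)
        by_id = {p.residue_id: p for p in profiles}
        fa = fit_site_average(sel, profiles, series, mode="curve-average")
        fr = fit_single_residue(by_id[rid], series)
        assert fa.kd == pytest.approx(fr.kd, rel=1e-9)

    def test_modes_agree_when_residues_share_kd(self, fixtures):
        spec = noiseless(fixtures["ww4_smad7_recombinant"])
        profiles, series, _ = _profiles_and_series(spec)
        sel = select_hotspots(profiles)
        fc = fit_site_average(sel, profiles, series, mode="curve-average")
        fk = fit_site_average(sel, profiles, series, mode="kd-average")
        assert fc.kd == pytest.approx(fk.kd, rel=1e-6)
        assert fc.kd == pytest.approx(0.237, rel=1e-5)

    def test_modes_disagree_for_heterogeneous_kd(self):
        # same residues, two true K_d's 10x apart: curve-averaging fits one
        # effective curve, kd-averaging averages the two constants
        base = dict(label="x", model="single", ratios=SCHEDULE_RECOMBINANT,
                    n_residues=6, binder_fraction=1.0, noise_sd=0.0,
                    ddmax_range=(0.15, 0.15))
        s1, _ = simulate_titration(SimulationSpec(
            true_params=SingleSiteParams(0.05, 0.15, 0.08), seed=3, **base))
        s2, _ = simulate_titration(SimulationSpec(
            true_params=SingleSiteParams(0.5, 0.15, 0.08), seed=3, **base))
        # splice: residues 1-6 from the tight sim, 7-12 relabelled from loose
        from cspfit.peaks import Peak, TitrationPoint, TitrationSeries
        points = []
        for pt1, pt2 in zip(s1.points, s2.points):
            peaks = dict(pt1.peaks)
            for rid, pk in pt2.peaks.items():
                peaks[rid + 6] = Peak(rid + 6, pk.residue_name, pk.delta_h,
                                      pk.delta_n, pk.height)
            points.append(TitrationPoint(pt1.index, pt1.ratio, pt1.protein_conc,
                                         pt1.ligand_conc, peaks))
        series = TitrationSeries(points=points, label="mixed")
        profiles = build_profiles(series)
        from cspfit.fitting import HotspotSelection
        sel = HotspotSelection("mixed", tuple(range(1, 13)), 0, 0, 0, 9)
        fc = fit_site_average(sel, profiles, series, mode="curve-average")
        fk = fit_site_average(sel, profiles, series, mode="kd-average")
        assert fk.kd == pytest.approx((0.05 + 0.5) / 2, rel=1e-3)
        assert abs(fc.kd - fk.kd) / fk.kd > 0.10  # genuinely different answers


class TestFitTwoSite:
    def test_noiseless_joint_recovery(self, tandem_series):
        series, truth = tandem_series
        profiles = build_profiles(series)
        from cspfit import classify_series
        calls = classify_series(series, profiles)
        sel1 = select_hotspots(profiles, residue_range=tuple(truth["site1_range"]),
                               exchange_calls=calls, site_label="WW3")
        sel2 = select_hotspots(profiles, residue_range=tuple(truth["site2_range"]),
                               exchange_calls=calls, site_label="WW4")
        fit = fit_two_site(site_mean_curve(sel1, profiles),
                           site_mean_curve(sel2, profiles), series, mode="joint")
        assert fit.converged
        assert fit.k1 == pytest.approx(truth["k1_mM"], rel=1e-4)
        assert fit.k2 == pytest.approx(truth["k2_mM"], rel=1e-4)
        assert fit.k1 < fit.k2

    def test_identical_sites_summed_matches_single_site_reduction(self):
        # two identical sites at p == one site at a = 2p with ddmax = 2*delta
        tp = TwoSiteParams(k1=0.15, k2=0.15, d1=0.08, d2=0.08, p=0.08)
        spec = SimulationSpec(label="eq", model="two-site", true_params=tp,
                              ratios=SCHEDULE_RECOMBINANT, n_residues=12,
                              binder_fraction=1.0, ddmax_range=(0.08, 0.08),
                              noise_sd=0.0, seed=9)
        series, truth = simulate_titration(spec)
        profiles = build_profiles(series)
        from cspfit.fitting import HotspotSelection
        sel1 = HotspotSelection("s1", tuple(range(1, 7)), 0, 0, 0, 9)
        sel2 = HotspotSelection("s2", tuple(range(7, 13)), 0, 0, 0, 9)
        with pytest.warns(UserWarning, match="amplitude heuristic"):
            fit = fit_two_site(site_mean_curve(sel1, profiles),
                               site_mean_curve(sel2, profiles), series,
                               mode="summed")
        # the summed curve equals the single-site isotherm at a = 2p
        from cspfit.fitting import _fit_single_curve
        ysum = site_mean_curve(sel1, profiles) + site_mean_curve(sel2, profiles)
        single = _fit_single_curve(series.ligand_concs / (2 * tp.p), ysum,
                                   np.full(len(ysum), 2 * tp.p), (), "red")
        assert single.kd == pytest.approx(0.15, rel=1e-5)
        assert single.ddmax == pytest.approx(2 * 0.08, rel=1e-5)
        assert fit.residual_rms < 1e-8

    def test_zero_amplitude_site_is_flagged_unidentifiable(self, fixtures):
        spec = dataclasses.replace(noiseless(fixtures["ww34_smad7_tandem"]),
                                   intermediate_residues=())
        series, truth = simulate_titration(spec)
        profiles = build_profiles(series)
        sel1 = select_hotspots(profiles, residue_range=tuple(truth["site1_range"]))
        y1 = site_mean_curve(sel1, profiles)
        y2 = np.zeros_like(y1)  # silent second site: K2 cannot be determined
        fit = fit_two_site(y1, y2, series, mode="joint")
        assert fit.d2 == pytest.approx(0.0, abs=1e-6)
        assert not np.isfinite(fit.k2_sd) or fit.k2_sd > 1e3
        assert any("non-identifiable" in m for m in fit.messages)

    def test_too_few_points(self, fixtures):
        spec = noiseless(fixtures["ww4_smad7_synthetic"])  # 7 points
        series, _ = simulate_titration(spec)
        y = np.linspace(0, 0.1, 5)
        short = dataclasses.replace(spec, ratios=spec.ratios[:5])
        series5, _ = simulate_titration(short)
        with pytest.raises(InsufficientDataError):
            fit_two_site(y, y, series5, mode="joint")


class TestJointVersusSummed:
    def test_joint_mode_at_least_as_accurate_as_summed(self, fixtures):
        # the summed curve discards which site produced which response; the
        # joint fit keeps site identity, so over seeded noisy replicates its
        # median K error must not be worse
        import warnings as w
        from cspfit import classify_series
        spec = fixtures["ww34_smad7_tandem"]
        ej, es = [], []
        for rep in range(40):
            series, truth = simulate_titration(spec, seed=50_000 + rep)
            profiles = build_profiles(series)
            calls = classify_series(series, profiles)
            sel1 = select_hotspots(profiles, residue_range=tuple(truth["site1_range"]),
                                   exchange_calls=calls)
            sel2 = select_hotspots(profiles, residue_range=tuple(truth["site2_range"]),
                                   exchange_calls=calls)
            y1 = site_mean_curve(sel1, profiles)
            y2 = site_mean_curve(sel2, profiles)
            fj = fit_two_site(y1, y2, series, mode="joint")
            with w.catch_warnings():
                w.simplefilter("ignore")
                fs = fit_two_site(y1, y2, series, mode="summed")
            for f, acc in ((fj, ej), (fs, es)):
                acc.append(abs(f.k1 - truth["k1_mM"]) / truth["k1_mM"])
                acc.append(abs(f.k2 - truth["k2_mM"]) / truth["k2_mM"])
        assert np.median(ej) <= np.median(es)


class TestReport:
    def test_micromolar_rendering(self):
        f = SingleSiteFit(residue_ids=(1, 2), kd=0.237, kd_sd=0.0157,
                          ddmax=0.15, ddmax_sd=0.01, n_points=10,
                          converged=True, residual_rms=0.001)
        text = format_report(report(fits=[f]))
        assert "237 ± 15.7 µM" in text

    def test_millimolar_rendering_and_nonconvergence(self):
        f = SingleSiteFit(residue_ids=(1,), kd=1.19, kd_sd=0.21,
                          ddmax=0.15, ddmax_sd=0.01, n_points=7,
                          converged=False, residual_rms=0.001)
        text = format_report(report(fits=[f]))
        assert "1.19 ± 0.21 mM" in text
        assert "NOT CONVERGED" in text

    def test_empty_exchange_section_omitted(self):
        f = SingleSiteFit((1,), 0.2, 0.01, 0.1, 0.01, 10, True, 0.001)
        text = format_report(report(fits=[f], calls=[]))
        assert "Exchange regimes" not in text
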