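"""FOCE-I objective, fitting, model comparison, selection, bootstrap, GOF."""

import math

import numpy as np
import pandas as pd
import pytest

import pippk as pk
from pippk import estimation as est
from pippk.model import CRCL_REF, CovariateEffect

from conftest import TABLE2_THETA


def single_subject_dataset(y_times, y_vals, weight=20.0, crcl=143.0):
    rows = [{"ID": 1, "TIME": 0.0, "AMT": 1700.0, "DUR": 0.5, "EVID": 1, "MDV": 1,
             "DV": np.nan, "OCC": "intra", "WT": weight, "CRCL": crcl}]
    for t, y in zip(y_times, y_vals):
        rows.append({"ID": 1, "TIME": t, "AMT": np.nan, "DUR": np.nan, "EVID": 0,
                     "MDV": 0, "DV": y, "OCC": "intra", "WT": weight, "CRCL": crcl})
    return pk.PKDataset(pd.DataFrame(rows))


class TestOFV:
    def test_zero_omega_reduces_to_weighted_least_squares_deviance(self, final_model):
        """With no random effects the FOCE objective is the proportional-error
        WLS deviance sum_j [(y-f)^2/(sigma^2 f^2) + ln(sigma^2 f^2) + ln 2pi]."""
        times = np.array([0.75, 1.5, 2.5, 4.0])
        spec = pk.ModelSpec(theta=final_model.theta,
                            covariate_effects=final_model.covariate_effects,
                            random=pk.RandomEffectSpec(sigma2_prop=0.1))
        cov = pk.SubjectCovariates(weight=20.0, crcl=143.0)
        f = pk.conc_profile(pk.typical_params(spec, cov),
                            [pk.DoseEvent(0, 1700, 0.5)], times)
        y = f * np.array([1.1, 0.9, 1.2, 0.95])
        ds = single_subject_dataset(times, y)
        v = 0.1 * f**2
        expected = np.sum((y - f) ** 2 / v + np.log(v) + math.log(2 * math.pi))
        assert pk.ofv(ds, spec) == pytest.approx(expected, abs=1e-8)

    def test_invariant_to_subject_ordering(self, final_model, study_dataset):
        df = study_dataset.df
        ids = df["ID"].drop_duplicates().to_list()
        rng = np.random.default_rng(0)
        perm = rng.permutation(ids)
        shuffled = pd.concat([df[df["ID"] == i] for i in perm], ignore_index=True)
        assert pk.ofv(pk.PKDataset(shuffled), final_model) == pytest.approx(
            pk.ofv(study_dataset, final_model), abs=1e-8)

    def test_observation_free_subject_leaves_ofv_unchanged(self, final_model, study_dataset):
        extra = study_dataset.df[study_dataset.df["EVID"] == 1].head(3).copy()
        extra["ID"] = 99_999
        augmented = pk.PKDataset(pd.concat([study_dataset.df, extra], ignore_index=True))
        assert pk.ofv(augmented, final_model) == pytest.approx(
            pk.ofv(study_dataset, final_model), abs=1e-8)

    def test_truth_beats_perturbed_parameters(self, no_iov_model):
        """On rich simulated data the OFV at the generating parameters is lower
        than at 2x-perturbed parameters in nearly every replicate."""
        perturbed = pk.ModelSpec(
            theta=pk.StructuralParams(2 * no_iov_model.theta.cl, no_iov_model.theta.v1 / 2,
                                      no_iov_model.theta.q, no_iov_model.theta.v2),
            covariate_effects=no_iov_model.covariate_effects,
            random=no_iov_model.random)
        wins = 0
        for s in range(20):
            ds = pk.rich_study(no_iov_model, n_subjects=12, n_samples=8, seed=300 + s)
            wins += pk.ofv(ds, no_iov_model) < pk.ofv(ds, perturbed)
        assert wins >= 19


class TestFit:
    def test_noise_free_rich_data_recovers_fixed_effects(self, no_iov_model):
        truth = pk.ModelSpec(theta=no_iov_model.theta,
                             covariate_effects=no_iov_model.covariate_effects,
                             random=pk.RandomEffectSpec(sigma2_prop=0.02**2))
        ds = pk.rich_study(truth, n_subjects=20, n_samples=12, seed=21)
        res = pk.fit(ds, truth)
        for name in ("cl", "v1", "q", "v2"):
            assert res.estimates[name] == pytest.approx(TABLE2_THETA[name], rel=0.05)

    def test_refit_from_solution_is_a_fixed_point(self, no_iov_model):
        ds = pk.rich_study(no_iov_model, n_subjects=15, n_samples=8, seed=22)
        first = pk.fit(ds, no_iov_model)
        second = pk.fit(ds, first.spec)
        assert abs(second.ofv - first.ofv) < 0.01

    def test_shrinkage_decreases_with_sampling_richness(self, no_iov_model):
        shr = []
        for n_samples in (2, 5, 10):
            ds = pk.rich_study(no_iov_model, n_subjects=30, n_samples=n_samples, seed=23)
            res = pk.fit(ds, no_iov_model)
            shr.append(np.mean([res.shrinkage["eta_cl"], res.shrinkage["eta_v1"]]))
        assert shr[0] > shr[1] > shr[2]


class TestAIC:
    @staticmethod
    def _fake_fit(ofv, n_params, fp="x"):
        return est.FitResult(spec=None, ofv=ofv, n_params=n_params, ebes=pd.DataFrame(),
                             shrinkage={}, convergence=True, fingerprint=fp)

    def test_tie_broken_by_fewer_parameters(self):
        a, b = self._fake_fit(100.0, 5), self._fake_fit(100.0 - 2.0, 6)
        # dOFV = 2 exactly: same AIC; the 5-parameter model ranks first
        ranking = pk.compare_aic([b, a])
        assert ranking[0][0] == 1

    def test_useless_parameter_increases_aic(self):
        base, bigger = self._fake_fit(100.0, 5), self._fake_fit(98.5, 6)
        ranking = pk.compare_aic([base, bigger])
        assert ranking[0][0] == 0  # dOFV 1.5 < 2 does not pay for the extra df

    def test_mismatched_datasets_rejected(self):
        with pytest.raises(ValueError):
            pk.compare_aic([self._fake_fit(1, 1, "a"), self._fake_fit(1, 1, "b")])

    def test_two_compartment_beats_one_on_biphasic_data(self, no_iov_model):
        # pronounced distribution phase: large Q and V2 relative to the defaults
        truth = pk.ModelSpec(
            theta=pk.StructuralParams(7.1, 10.0, 12.0, 25.0),
            covariate_effects=no_iov_model.covariate_effects,
            random=pk.RandomEffectSpec(omega2={"cl": 0.04}, sigma2_prop=0.01))
        ds = pk.rich_study(truth, n_subjects=25, n_samples=12, seed=24)
        two = pk.fit(ds, truth)
        one_init = pk.ModelSpec(
            theta=pk.StructuralParams(7.1, 30.0, 1e-4, 1.0),
            covariate_effects=truth.covariate_effects, random=truth.random)
        one = pk.fit(ds, one_init, fix_theta=("q", "v2"))
        ranking = pk.compare_aic([one, two])
        assert ranking[0][0] == 1


class TestStepwise:
    def test_exact_gate_values_are_not_crossed(self, monkeypatch):
        """dOFV of exactly 3.84 must not enter; a backward rise of exactly
        6.63 must not retain."""
        cand = CovariateEffect("cl", "crcl", "power-continuous", 0.3, CRCL_REF)
        fm = pk.load_final_model()
        base_spec = pk.ModelSpec(theta=fm.theta,
                                 covariate_effects=tuple(pk.allometric_effects()),
                                 random=fm.random)

        # base/candidate OFVs chosen so the drop is the float 3.84 exactly
        ofvs = {0: 3.84, 1: 0.0}

        def fake_fit(dataset, spec, maxiter=None, fix_theta=()):
            key = len([e for e in spec.covariate_effects if not e.fixed])
            return est.FitResult(spec=spec, ofv=ofvs[key], n_params=1,
                                 ebes=pd.DataFrame(), shrinkage={}, convergence=True)

        monkeypatch.setattr(est, "fit", fake_fit)
        res = est.stepwise_covariates(None, base_spec, [cand])
        assert res.retained == []
        assert res.forward_path[0][2] is False

        # now a forward drop of 6.63 (enters) whose backward rise is exactly
        # 6.63 -> strict backward gate removes it
        ofvs[0], ofvs[1] = 6.63, 0.0
        res = est.stepwise_covariates(None, base_spec, [cand])
        assert res.retained == [] and len(res.backward_removed) == 1

    def test_failing_candidate_is_skipped_with_warning(self, monkeypatch):
        cand = CovariateEffect("cl", "crcl", "power-continuous", 0.3, CRCL_REF)

        def fake_fit(dataset, spec, maxiter=None, fix_theta=()):
            if any(not e.fixed for e in spec.covariate_effects):
                raise RuntimeError("no convergence")
            return est.FitResult(spec=spec, ofv=50.0, n_params=1,
                                 ebes=pd.DataFrame(), shrinkage={}, convergence=True)

        monkeypatch.setattr(est, "fit", fake_fit)
        fm = pk.load_final_model()
        base_spec = pk.ModelSpec(theta=fm.theta,
                                 covariate_effects=tuple(pk.allometric_effects()),
                                 random=fm.random)
        with pytest.warns(UserWarning, match="skipped"):
            res = est.stepwise_covariates(None, base_spec, [cand])
        assert res.retained == []


class TestBootstrap:
    def test_single_replicate_reproducible_under_seed(self, no_iov_model):
        ds = pk.rich_study(no_iov_model, n_subjects=8, n_samples=6, seed=26)
        a = pk.bootstrap(ds, no_iov_model, n=1, seed=5)
        b = pk.bootstrap(ds, no_iov_model, n=1, seed=5)
        pd.testing.assert_frame_equal(a.estimates, b.estimates)
        assert a.n_failed == 0

    def test_interval_covers_truth_on_small_study(self, no_iov_model):
        ds = pk.rich_study(no_iov_model, n_subjects=20, n_samples=8, seed=27)
        res = pk.bootstrap(ds, no_iov_model, n=30, seed=6)
        row = res.summary.set_index("parameter").loc["cl"]
        assert row["ci_lower"] <= 7.1 <= row["ci_upper"]
        assert row["ci_lower"] <= row["median"] <= row["ci_upper"]


class TestGOF:
    def test_iwres_standardized_on_self_simulated_data(self, no_iov_model):
        ds = pk.rich_study(no_iov_model, n_subjects=40, n_samples=8, seed=28)
        res = pk.fit(ds, no_iov_model)
        table = pk.gof(res, ds)
        assert abs(table["IWRES"].mean()) < 0.15
        assert table["IWRES"].std() == pytest.approx(1.0, abs=0.2)
        assert {"PRED", "IPRED", "IWRES", "PWRES"} <= set(table.columns)

    def test_empty_observations_give_empty_table(self, no_iov_model):
        df = pd.DataFrame([{"ID": 1, "TIME": 0.0, "AMT": 500.0, "DUR": 0.5,
                            "EVID": 1, "MDV": 1, "DV": np.nan, "OCC": "intra",
                            "WT": 20.0, "CRCL": 143.0}])
        fr = est.FitResult(spec=no_iov_model, ofv=0.0, n_params=0,
                           ebes=pd.DataFrame(columns=["ID", *est.ETA_LABELS]),
                           shrinkage={}, convergence=True)
        table = pk.gof(fr, pk.PKDataset(df))
        assert len(table) == 0


class TestVPC:
    def test_constant_prediction_makes_correction_identity(self, no_iov_model):
        """All observations at the same time-after-dose and design: the
        bin-median prediction equals each row prediction, so pc is a no-op."""
        times = np.array([1.0])
        rows = []
        for sid in range(12):
            rows.append({"ID": sid, "TIME": 0.0, "AMT": 1700.0, "DUR": 0.5, "EVID": 1,
                         "MDV": 1, "DV": np.nan, "OCC": "intra", "WT": 20.0, "CRCL": 143.0})
            rows.append({"ID": sid, "TIME": 1.0, "AMT": np.nan, "DUR": np.nan, "EVID": 0,
                         "MDV": 0, "DV": 50.0 + sid, "OCC": "intra", "WT": 20.0,
                         "CRCL": 143.0})
        ds = pk.PKDataset(pd.DataFrame(rows))
        fr = est.FitResult(spec=no_iov_model, ofv=0.0, n_params=0, ebes=pd.DataFrame(),
                           shrinkage={}, convergence=True)
        v = pk.pcvpc(ds, fr, n_sim=20, bins=3, seed=0)
        obs_dv = np.array([50.0 + s for s in range(12)])
        assert v.observed["p50"].iloc[0] == pytest.approx(np.median(obs_dv))

    def test_percentile_ordering_within_bins(self, final_model, study_dataset):
        fr = est.FitResult(spec=final_model, ofv=0.0, n_params=0, ebes=pd.DataFrame(),
                           shrinkage={}, convergence=True)
        v = pk.pcvpc(study_dataset, fr, n_sim=30, bins=6, seed=2)
        assert np.all(v.observed["p5"] <= v.observed["p50"])
        assert np.all(v.observed["p50"] <= v.observed["p95"])
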