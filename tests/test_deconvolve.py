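import numpy as np
import pandas as pd
import pytest

import woundtraj as wt


def _profiles(n_marker=60, n_background=40, n_types=3, seed=0, labels=None):
    """Full cell-type TPM profiles (each column sums to 1e6) + signature.

    The signature handed to the estimator covers only the marker genes; the
    background genes carry the "other" tissue profile, so mixtures built from
    these profiles are genuine TPM columns.
    """
    rng = np.random.default_rng(seed)
    labels = labels or [f"type{j}" for j in range(n_types)]
    genes = [f"G{i}" for i in range(n_marker + n_background)]
    full = pd.DataFrame(rng.lognormal(0.0, 0.5,
                                      (len(genes), len(labels) + 1)),
                        index=genes, columns=labels + ["other"])
    block = n_marker // len(labels)
    for j in range(len(labels)):
        full.iloc[j * block:(j + 1) * block, j] *= 2000
    full.iloc[n_marker:, len(labels)] *= 500  # background: "other" tissue
    full = full * (1e6 / full.sum(axis=0))
    sig = wt.SignatureMatrix(values=full.iloc[:n_marker][labels].copy())
    return sig, full


def _signature(n_genes=60, n_types=3, seed=0, labels=None):
    sig, _ = _profiles(n_marker=n_genes, n_types=n_types, seed=seed,
                       labels=labels)
    return sig


def _mix(full_profiles, weights):
    """TPM column for a mixture; the leftover mass goes to "other"."""
    w = np.asarray(weights, dtype=float)
    w_full = np.append(w, 1.0 - w.sum())
    return pd.Series(full_profiles.to_numpy() @ w_full,
                     index=full_profiles.index)


class TestExactRecovery:
    def test_noiseless_two_type_mixture(self):
        sig, full = _profiles(n_types=2)
        tpm = pd.DataFrame({"s": _mix(full, [0.3, 0.7])})
        res = wt.estimate_proportions(tpm, sig)
        assert res.proportions.loc["s", "type0"] == pytest.approx(0.3, abs=1e-6)
        assert res.proportions.loc["s", "type1"] == pytest.approx(0.7, abs=1e-6)
        assert res.other_fraction["s"] == pytest.approx(0.0, abs=1e-6)

    def test_interior_simplex_point_with_other(self):
        sig, full = _profiles(n_types=3)
        w = [0.2, 0.3, 0.1]  # other = 0.4
        tpm = pd.DataFrame({"s": _mix(full, w)})
        res = wt.estimate_proportions(tpm, sig)
        # the "other" profile leaks a little mass onto marker genes, so
        # recovery is close but not exact
        np.testing.assert_allclose(res.proportions.loc["s"], w, atol=5e-3)
        assert res.other_fraction["s"] == pytest.approx(0.4, abs=5e-3)

    def test_pure_noise_sample_attributed_to_other(self):
        sig, full = _profiles(n_types=3, seed=1)
        tpm = pd.DataFrame({"s": _mix(full, [0.0, 0.0, 0.0])})
        res = wt.estimate_proportions(tpm, sig)
        assert res.proportions.loc["s"].sum() < 0.01
        assert res.other_fraction["s"] > 0.99


class TestInvariants:
    def test_proportions_and_other_sum_to_one(self, cohort, cohort_tpm):
        res = wt.estimate_proportions(cohort_tpm, cohort.signature)
        total = res.proportions.sum(axis=1) + res.other_fraction
        np.testing.assert_allclose(total, 1.0, atol=1e-9)
        assert (res.proportions.to_numpy() >= 0).all()

    def test_sample_scale_invariance(self):
        sig, full = _profiles(n_types=2, seed=3)
        tpm = pd.DataFrame({"s": _mix(full, [0.25, 0.35])})
        res1 = wt.estimate_proportions(tpm, sig)
        res2 = wt.estimate_proportions(tpm * 17.3, sig)
        pd.testing.assert_frame_equal(res1.proportions, res2.proportions)

    def test_cell_type_relabeling_equivariance(self):
        sig, full = _profiles(n_types=3, seed=4)
        tpm = pd.DataFrame({"s": _mix(full, [0.1, 0.2, 0.3])})
        res = wt.estimate_proportions(tpm, sig)
        perm = ["type2", "type0", "type1"]
        sig_perm = wt.SignatureMatrix(values=sig.values[perm])
        res_perm = wt.estimate_proportions(tpm, sig_perm)
        np.testing.assert_allclose(res_perm.proportions[["type0", "type1",
                                                         "type2"]],
                                   res.proportions, atol=1e-9)

    def test_residual_non_increasing_with_more_types(self):
        sig3 = _signature(n_types=3, seed=5)
        rng = np.random.default_rng(6)
        tpm = pd.DataFrame({"s": rng.lognormal(3, 1, 60)},
                           index=sig3.values.index)
        sig2 = wt.SignatureMatrix(values=sig3.values[["type0", "type1"]])
        r2 = wt.estimate_proportions(tpm, sig2).residual_norm["s"]
        r3 = wt.estimate_proportions(tpm, sig3).residual_norm["s"]
        assert r3 <= r2 + 1e-12

    def test_collinear_signature_rejected(self):
        base = _signature(n_types=2, seed=7)
        vals = base.values.copy()
        vals["dup"] = vals["type0"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            wt.estimate_proportions(
                pd.DataFrame({"s": vals["type0"]}, index=vals.index),
                wt.SignatureMatrix(values=vals))

    def test_disjoint_gene_spaces_rejected(self):
        sig = _signature(n_types=2, seed=8)
        tpm = pd.DataFrame({"s": [1.0]}, index=["ZZZ"])
        with pytest.raises(ValueError, match="shared"):
            wt.estimate_proportions(tpm, sig)


class TestNoisyRecovery:
    def test_rmse_under_multiplicative_noise(self):
        """100 samples, 10 cell types, 50 markers/type, 5% lognormal noise."""
        rng = np.random.default_rng(42)
        n_types, markers = 10, 50
        labels = [f"ct{j}" for j in range(n_types)]
        sig, full = _profiles(n_marker=n_types * markers, n_background=200,
                              n_types=n_types, seed=42, labels=labels)
        truth = rng.dirichlet(np.ones(n_types) * 2.0, size=100) * 0.6
        w_full = np.hstack([truth, 1.0 - truth.sum(axis=1, keepdims=True)])
        mixed = full.to_numpy() @ w_full.T
        noisy = mixed * np.exp(rng.normal(0.0, 0.05, mixed.shape))
        tpm = pd.DataFrame(noisy, index=full.index,
                           columns=[f"s{i}" for i in range(100)])
        res = wt.estimate_proportions(tpm, sig)
        rmse = float(np.sqrt(np.mean(
            (res.proportions.to_numpy() - truth) ** 2)))
        assert rmse < 0.05

    def test_cohort_ground_truth_recovery(self, cohort, cohort_tpm):
        res = wt.estimate_proportions(cohort_tpm, cohort.signature)
        truth = cohort.truth.true_proportions[list(wt.CELL_TYPES)]
        rmse = float(np.sqrt(np.mean(
            (res.proportions.to_numpy() - truth.to_numpy()) ** 2)))
        assert rmse < 0.05


class TestM1M2Ratio:
    def _result(self, p1, p2):
        props = pd.DataFrame({"Macrophages M1": p1, "Macrophages M2": p2},
                             index=[f"s{i}" for i in range(len(p1))])
        return wt.DeconvolutionResult(
            proportions=props,
            other_fraction=1 - props.sum(axis=1),
            residual_norm=pd.Series(0.0, index=props.index))

    def test_basic_ratio(self):
        res = self._result([0.1, 0.05, 0.05], [0.05, 0.05, 0.1])
        ratio = wt.m1_m2_ratio(res)
        np.testing.assert_allclose(ratio, [2.0, 1.0, 0.5])

    def test_zero_m2_recorded_missing(self):
        res = self._result([0.1], [0.0])
        with pytest.warns(UserWarning, match="M1/M2"):
            ratio = wt.m1_m2_ratio(res)
        assert ratio.isna().all()

    def test_missing_macrophage_label_rejected(self):
        props = pd.DataFrame({"B cells": [0.1]}, index=["s"])
        res = wt.DeconvolutionResult(
            proportions=props, other_fraction=pd.Series([0.9], index=["s"]),
            residual_norm=pd.Series([0.0], index=["s"]))
        with pytest.raises(ValueError, match="M1"):
            wt.m1_m2_ratio(res)
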