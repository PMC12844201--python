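"""Generator contracts: design enumeration, logistic curves, planted omics."""

import numpy as np
import pandas as pd
import pytest

from omigrow import (
    generate_design,
    generate_growth_curves,
    generate_omics,
    logistic_od,
)
from omigrow.errors import InputError, InvalidDesignError, InvalidTruthError


class TestDesign:
    def test_fourteen_unique_conditions_full_factorial(self):
        design = generate_design(14, seed=0)
        ids = [c.condition_id for c in design]
        assert len(ids) == 14 and len(set(ids)) == 14
        by_oxygen = {"aerobic": 0, "anaerobic": 0}
        for c in design:
            by_oxygen[c.oxygen] += 1
        assert by_oxygen == {"aerobic": 7, "anaerobic": 7}
        # acetate control and p-coumarate grow without co-feeding
        assert all(
            not c.acetate_supplemented
            for c in design
            if c.substrate in ("acetate", "p-coumarate")
        )

    def test_two_conditions_split_half_gives_one_each(self):
        design = generate_design(2, oxygen_split=0.5, seed=0)
        assert sorted(c.oxygen for c in design) == ["aerobic", "anaerobic"]

    def test_both_levels_present_for_interior_split(self):
        design = generate_design(5, oxygen_split=0.05, seed=0)
        assert {c.oxygen for c in design} == {"aerobic", "anaerobic"}

    def test_deterministic_for_fixed_seed(self):
        assert generate_design(9, seed=3) == generate_design(9, seed=3)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_conditions=1), dict(substrates=()), dict(oxygen_split=1.5)],
    )
    def test_invalid_design_rejected(self, kwargs):
        with pytest.raises(InvalidDesignError):
            generate_design(**{"n_conditions": 4, **kwargs})


class TestGrowthCurves:
    def _params(self, design, K=1.0, r=0.3, od0=0.05):
        return {c.condition_id: (K, r, od0) for c in design}

    def test_noiseless_curves_lie_on_logistic(self):
        design = generate_design(2, seed=0)
        t = np.arange(0.0, 25.0, 2.0)
        table = generate_growth_curves(
            design, self._params(design), noise_sd=0.0, timepoints=t, seed=0
        )
        sub = table[(table.condition_id == design[0].condition_id) & (table.replicate == 1)]
        assert np.allclose(sub.od660.to_numpy(), logistic_od(t, 1.0, 0.3, 0.05), atol=1e-12)
        # at t=0 the curve starts at OD0; replicates are identical without noise
        assert sub.od660.iloc[0] == pytest.approx(0.05)
        wide = table.pivot_table(index="replicate", columns="time_h", values="od660")
        assert np.ptp(wide.to_numpy(), axis=0).max() == 0.0

    def test_logistic_midpoint_and_asymptote(self):
        # OD reaches K/2 at t = ln((K-OD0)/OD0)/r, here ln(9)/0.5
        assert logistic_od(np.log(9.0) / 0.5, 1.0, 0.5, 0.1) == pytest.approx(0.5, abs=1e-12)
        assert logistic_od(1e3, 1.0, 0.5, 0.1) == pytest.approx(1.0, abs=1e-6)

    def test_replicates_differ_under_noise(self):
        design = generate_design(2, seed=0)
        table = generate_growth_curves(design, self._params(design), noise_sd=0.02, seed=0)
        wide = table[table.condition_id == design[0].condition_id].pivot(
            index="replicate", columns="time_h", values="od660"
        )
        assert np.ptp(wide.to_numpy(), axis=0).max() > 0.0

    def test_bad_inputs_rejected(self):
        design = generate_design(2, seed=0)
        with pytest.raises(InputError):
            generate_growth_curves(
                design, self._params(design), timepoints=[0.0, 2.0, 1.0], seed=0
            )
        with pytest.raises(InputError):
            generate_growth_curves(design, self._params(design, K=0.01, od0=0.05), seed=0)
        with pytest.raises(InputError):
            generate_growth_curves(design, {}, seed=0)


class TestOmics:
    def test_proteomics_feature_means_are_100(self, small_omics):
        _, prot, _, _ = small_omics
        assert np.allclose(prot.values().mean(axis=0), 100.0, atol=1e-9)

    def test_all_abundances_non_negative(self, small_omics):
        trans, prot, _, _ = small_omics
        assert (trans.values() >= 0).all() and (prot.values() >= 0).all()

    def test_perfect_coupling_gives_correlation_one(self):
        design = generate_design(6, seed=2)
        trans, prot, _, _ = generate_omics(
            design, n_features=10, n_planted=2, coupling=1.0, noise_sd=0.0, seed=2
        )
        T, P = trans.values(), prot.values()
        for j in range(10):
            assert np.corrcoef(T[:, j], P[:, j])[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_log_scale_coupling_is_exact(self):
        design = generate_design(12, seed=5)
        trans, prot, _, _ = generate_omics(
            design, n_features=15, n_planted=3, coupling=0.6, noise_sd=0.0, seed=5
        )
        T, P = np.log(trans.values()), np.log(prot.values())
        for j in range(15):
            assert np.corrcoef(T[:, j], P[:, j])[0, 1] == pytest.approx(0.6, abs=1e-9)

    def test_same_seed_bit_identical(self):
        design = generate_design(8, seed=4)
        a = generate_omics(design, n_features=30, n_planted=3, seed=4)
        b = generate_omics(design, n_features=30, n_planted=3, seed=4)
        assert a[0].data.equals(b[0].data) and a[1].data.equals(b[1].data)
        assert a[2].equals(b[2])
        assert a[3].planted_features == b[3].planted_features

    def test_planted_separation_by_correlation_noiseless(self):
        design = generate_design(14, seed=1)
        _, prot, rates, truth = generate_omics(
            design, n_features=200, n_planted=8, coupling=0.8, noise_sd=0.0, seed=1
        )
        P, y = prot.values(), rates.to_numpy()
        corr = np.abs(np.corrcoef(P.T, y)[-1, :-1])
        planted = np.isin(prot.feature_ids, truth.planted_features)
        assert corr[planted].min() > corr[~planted].max()
        # and a fortiori above the null 95th percentile
        assert corr[planted].min() > np.quantile(corr[~planted], 0.95)

    def test_growth_function_record_reproduces_rates(self):
        design = generate_design(10, seed=9)
        _, prot, rates, truth = generate_omics(
            design, n_features=25, n_planted=5, noise_sd=0.0, seed=9
        )
        gf = truth.growth_function
        total = np.full(len(design), gf["baseline_rate"])
        for pid, w in gf["weights"].items():
            a = prot.data[pid].to_numpy()
            total += w * a / (a + gf["half_saturation"][pid])
        assert np.allclose(total, rates.to_numpy(), atol=1e-12)

    def test_linear_growth_model_closed_form(self):
        design = generate_design(8, seed=3)
        _, prot, rates, truth = generate_omics(
            design, n_features=12, n_planted=2, noise_sd=0.0, seed=3,
            growth_model="linear", effect_sizes=[0.03, 0.05],
        )
        expected = 0.05 + sum(
            w * prot.data[pid].to_numpy() / 100.0
            for pid, w in truth.layer_effects.items()
        )
        assert np.allclose(expected, rates.to_numpy(), atol=1e-12)

    def test_oxygen_shift_mean_difference_on_transcripts(self):
        design = generate_design(14, seed=6)
        trans, _, _, truth = generate_omics(
            design, n_features=60, n_planted=4, oxygen_shift=400.0, noise_sd=0.0,
            seed=6, n_oxygen_shifted=6,
        )
        assert len(truth.oxygen_shifted_features) == 6
        assert not set(truth.oxygen_shifted_features) & set(truth.planted_features)
        aer = [c.condition_id for c in design if c.oxygen == "aerobic"]
        ana = [c.condition_id for c in design if c.oxygen == "anaerobic"]
        for pid in truth.oxygen_shifted_features:
            gene = pid.replace("RPA", "rpa")
            diff = trans.data.loc[aer, gene].mean() - trans.data.loc[ana, gene].mean()
            assert diff == pytest.approx(400.0, abs=1e-9)

    def test_invalid_truth_and_inputs_rejected(self, design14):
        with pytest.raises(InvalidTruthError):
            generate_omics(design14, n_features=5, n_planted=5, seed=0)
        with pytest.raises(InputError):
            generate_omics(design14, n_features=10, n_planted=2, coupling=1.3, seed=0)
        with pytest.raises(InvalidTruthError):
            generate_omics(
                design14, n_features=10, n_planted=2, effect_sizes=[0.1], seed=0
            )
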