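"""Shift-analysis tests: CSP mapping, sign determination from SQ/MQ peak
positions, excited-state reconstruction and state-model discrimination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cpmgdisp import ExperimentGeometry, TwoStateParams
from cpmgdisp.dispersion_fit import FitResult
from cpmgdisp.shift_analysis import (
    ShiftTable,
    apparent_shift_mq_c_ppm,
    apparent_shift_sq_ppm,
    compare_state_models,
    csp,
    csp_between,
    determine_sign,
    determine_sign_two_field,
    flag_perturbed,
    reconstruct_excited_shifts,
)
from cpmgdisp.synthetic_data import generate_shift_scenario, generate_sign_inputs

GEOM = ExperimentGeometry("MQ_HC", 800.0, 0.025, (100.0,))


def make_fit(dw_h, dw_c, errors=None):
    """Minimal FitResult carrying per-residue shift differences."""
    residues = list(dw_c)
    return FitResult(
        kex=1200.0,
        p_b=0.1,
        dw_h=dw_h,
        dw_c=dw_c,
        r2_0={},
        errors=errors or {},
        chi2=1.0,
        n_data=100,
        n_params=4,
        chi2_by_residue={},
    )


class TestCsp:
    @pytest.mark.parametrize(
        "dh, dc, expected",
        [
            (0.0, 0.0, 0.0),
            (0.03, 0.2, np.sqrt(0.0009 + 0.0025)),  # 0.0583 ppm
            (0.1, 0.0, 0.1),
            (0.0, 0.4, 0.1),
        ],
    )
    def test_known_values(self, dh, dc, expected):
        assert csp(dh, dc) == pytest.approx(expected, abs=1e-6)

    @given(
        dh=st.floats(-1, 1),
        dc=st.floats(-4, 4),
        dh2=st.floats(-1, 1),
        dc2=st.floats(-4, 4),
    )
    @settings(max_examples=100, derandomize=True)
    def test_norm_properties(self, dh, dc, dh2, dc2):
        assert csp(-dh, dc) == pytest.approx(csp(dh, dc))
        assert csp(dh, -dc) == pytest.approx(csp(dh, dc))
        assert csp(dh + dh2, dc + dc2) <= csp(dh, dc) + csp(dh2, dc2) + 1e-12

    def test_flag_perturbed_construction(self):
        vals = pd.Series(
            [0.08] * 8 + [0.01] * 16,
            index=[f"I{i}" for i in range(24)],
        )
        big = [f"I{i}" for i in range(8)]
        assert sorted(flag_perturbed(vals, mode="mean")) == sorted(big)
        assert sorted(flag_perturbed(vals, mode="fixed", cutoff=0.04)) == sorted(big)

    def test_flag_perturbed_edge_cases(self):
        equal = pd.Series([0.05] * 6, index=[f"I{i}" for i in range(6)])
        assert flag_perturbed(equal, mode="mean") == []
        outlier = pd.Series([0.01, 0.01, 0.01, 0.5], index=list("ABCD"))
        assert flag_perturbed(outlier, mode="mean") == ["D"]

    def test_csp_between_tables(self):
        a = ShiftTable.from_records("ATP", [("I75", 0.80, 12.5, 0.004, 0.02)])
        b = ShiftTable.from_records("ADP", [("I75", 0.83, 12.3, 0.004, 0.02)])
        out = csp_between(a, b)
        assert out.loc["I75", "csp_ppm"] == pytest.approx(csp(0.03, -0.2))


class TestSignDetermination:
    def test_zero_dw_undetermined(self):
        params = TwoStateParams(kex=1200.0, p_b=0.1, dw_h=0.0, dw_c=0.0)
        sign = determine_sign((0.8, 12.5), (0.8, 12.5), params, GEOM, 0.002)
        assert sign == 0

    @pytest.mark.parametrize("true_sign", [+1, -1])
    def test_oracle_generated_inputs(self, true_sign):
        # dw_h matters: the SQ/MQ position difference grows with the 1H
        # shift difference, and ~0.15 ppm puts it well above position noise
        params = TwoStateParams(kex=1200.0, p_b=0.1, dw_h=0.15, dw_c=true_sign * 1.2)
        inputs = generate_sign_inputs(params, GEOM, seed=5, position_sigma=(0.0005, 0.001))
        fitted = TwoStateParams(kex=1200.0, p_b=0.1, dw_h=0.15, dw_c=abs(params.dw_c))
        sign = determine_sign(inputs["sq"], inputs["mq"], fitted, GEOM, 0.002)
        assert sign == true_sign

    def test_antisymmetry_over_parameter_sweep(self):
        """Flipping the generating dw_c flips the verdict across a seeded
        sweep of exchange regimes (noiseless oracle positions)."""
        rng = np.random.default_rng(42)
        for _ in range(12):
            kex = rng.uniform(400, 2500)
            p_b = rng.uniform(0.02, 0.15)
            dw_c = rng.uniform(0.6, 2.5)
            dw_h = rng.uniform(-0.1, 0.1)
            fitted = TwoStateParams(kex=kex, p_b=p_b, dw_h=dw_h, dw_c=dw_c)
            verdicts = []
            for sgn in (+1, -1):
                truth = TwoStateParams(kex=kex, p_b=p_b, dw_h=dw_h, dw_c=sgn * dw_c)
                inputs = generate_sign_inputs(truth, GEOM, seed=1, position_sigma=(0.0, 0.0))
                verdicts.append(
                    determine_sign(inputs["sq_true"], inputs["mq_true"], fitted, GEOM, 1e-6)
                )
            assert verdicts[0] == -verdicts[1] != 0

    def test_noise_dominated_case_undetermined(self):
        params = TwoStateParams(kex=1200.0, p_b=0.1, dw_h=0.0, dw_c=1.2)
        inputs = generate_sign_inputs(params, GEOM, seed=9, position_sigma=(0.001, 0.005))
        # claimed position uncertainty far above the predicted displacement
        sign = determine_sign(inputs["sq"], inputs["mq"], params, GEOM, 0.5)
        assert sign == 0

    def test_two_field_variant_antisymmetric(self):
        params = TwoStateParams(kex=1200.0, p_b=0.1, dw_c=1.2)
        d600 = apparent_shift_sq_ppm(1.2, "C13", 600.0, 1200.0, 0.1)
        d800 = apparent_shift_sq_ppm(1.2, "C13", 800.0, 1200.0, 0.1)
        peak_low = (0.8, 12.5 + d600)
        peak_high = (0.8, 12.5 + d800)
        assert determine_sign_two_field(peak_low, peak_high, params, 600.0, 800.0, 1e-6) == 1
        flipped_low = (0.8, 12.5 - d600)
        flipped_high = (0.8, 12.5 - d800)
        assert determine_sign_two_field(flipped_low, flipped_high, params, 600.0, 800.0, 1e-6) == -1

    def test_fast_exchange_limits(self):
        """In fast exchange the SQ line sits at the population average."""
        shift = apparent_shift_sq_ppm(1.0, "C13", 800.0, 50000.0, 0.1)
        assert shift == pytest.approx(0.1, rel=0.05)
        mq = apparent_shift_mq_c_ppm(0.0, 1.0, 800.0, 50000.0, 0.1)
        assert mq == pytest.approx(shift, rel=1e-6)


class TestReconstruction:
    def test_zero_dw_and_plain_arithmetic(self):
        ground = ShiftTable.from_records(
            "ATP",
            [("I75", 0.80, 13.5, 0.004, 0.02), ("I64", 0.55, 11.0, 0.004, 0.02)],
        )
        fit = make_fit({"I75": 0.0, "I64": 0.0}, {"I75": 0.8, "I64": 0.0})
        out = reconstruct_excited_shifts(ground, fit, {"I75": +1, "I64": +1})
        assert out.data.loc["I75", "delta_c_ppm"] == pytest.approx(14.3)
        assert out.data.loc["I64", "delta_c_ppm"] == pytest.approx(11.0)
        assert not out.data.ambiguous.any()

    def test_undetermined_sign_yields_two_candidates(self):
        ground = ShiftTable.from_records("ATP", [("I75", 0.80, 13.5, 0.004, 0.02)])
        fit = make_fit({"I75": 0.05}, {"I75": 0.8})
        out = reconstruct_excited_shifts(ground, fit, {"I75": 0})
        assert sorted(out.data.index) == ["I75(+)", "I75(-)"]
        assert out.data.ambiguous.all()
        assert out.data.loc["I75(+)", "delta_c_ppm"] == pytest.approx(14.3)
        assert out.data.loc["I75(-)", "delta_c_ppm"] == pytest.approx(12.7)

    def test_missing_residue_rejected(self):
        ground = ShiftTable.from_records("ATP", [("I64", 0.55, 11.0, 0.004, 0.02)])
        fit = make_fit({"I75": 0.0}, {"I75": 0.8})
        with pytest.raises(KeyError, match="I75"):
            reconstruct_excited_shifts(ground, fit, {"I75": +1})

    def test_round_trip_against_generator_truth(self):
        """Ground + signed |dw| reproduces the generator's excited table."""
        rng = np.random.default_rng(3)
        records_g, records_e, dw_h, dw_c, signs = [], [], {}, {}, {}
        for i in range(8):
            res = f"I{i + 10}"
            dh, dc = rng.uniform(0.3, 1.0), rng.uniform(9, 15)
            ddh = rng.uniform(-0.1, 0.1)
            ddc = rng.choice([-1, 1]) * rng.uniform(0.5, 2.0)
            records_g.append((res, dh, dc, 0.004, 0.02))
            records_e.append((res, dh + ddh, dc + ddc, 0.004, 0.02))
            signs[res] = int(np.sign(ddc))
            dw_c[res] = abs(ddc)
            dw_h[res] = ddh * signs[res]  # relative sign as fitted
        ground = ShiftTable.from_records("ATP", records_g)
        expected = ShiftTable.from_records("ATP*", records_e)
        fit = make_fit(dw_h, dw_c)
        out = reconstruct_excited_shifts(ground, fit, signs)
        pd.testing.assert_frame_equal(
            out.data[["delta_h_ppm", "delta_c_ppm"]].sort_index(),
            expected.data[["delta_h_ppm", "delta_c_ppm"]].sort_index(),
            check_exact=False,
            atol=1e-12,
        )


class TestStateModels:
    @pytest.mark.parametrize(
        "hypothesis, expected",
        [
            ("two_state", "2-state"),
            ("three_state", "3-state"),
            ("four_state", "4-state"),
        ],
    )
    def test_constructed_hypotheses_recovered(self, hypothesis, expected):
        tables, excluded = generate_shift_scenario(hypothesis, separation=10.0, seed=4)
        verdict = compare_state_models(tables, excluded)
        assert verdict.verdict == expected

    def test_zero_separation_indistinguishable(self):
        tables, excluded = generate_shift_scenario(
            "four_state", separation=0.0, seed=4, n_excluded=0, sigma_h=0.0, sigma_c=0.0
        )
        verdict = compare_state_models(tables, excluded)
        assert verdict.verdict == "indistinguishable"

    def test_all_excluded_gives_insufficient_evidence(self):
        tables, _ = generate_shift_scenario("four_state", separation=10.0, seed=4)
        everything = tables["ATP"].residues
        verdict = compare_state_models(tables, everything)
        assert verdict.verdict == "insufficient evidence"

    def test_verdict_stable_under_permutation_and_extra_exclusions(self):
        tables, excluded = generate_shift_scenario("three_state", separation=10.0, seed=8)
        base = compare_state_models(tables, excluded).verdict
        shuffled = {
            k: ShiftTable(t.state_label, t.data.sample(frac=1.0, random_state=1))
            for k, t in tables.items()
        }
        assert compare_state_models(shuffled, excluded).verdict == base
        # excluding residues that are not evidence anyway must not matter
        more = list(excluded) + ["Z999"]
        assert compare_state_models(tables, more).verdict == base

    def test_excluded_residues_never_count(self):
        tables, excluded = generate_shift_scenario("two_state", separation=10.0, seed=4)
        verdict = compare_state_models(tables, excluded)
        flagged = verdict.table[verdict.table.excluded]
        assert set(flagged.residue) <= set(excluded)
        informative = verdict.table[~verdict.table.excluded]
        assert not informative[informative.pair == "ADP vs ATP*"].off_diagonal.any()

    def test_missing_table_rejected(self):
        tables, excluded = generate_shift_scenario("two_state", separation=10.0, seed=4)
        tables.pop("ADP*")
        with pytest.raises(ValueError, match="ADP"):
            compare_state_models(tables, excluded)
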