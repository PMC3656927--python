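"""Normalization anchoring, five-bin classification, and profile recovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cycleplate.cellcycle import (
    BIN_EDGES,
    DnaReference,
    ReliabilityError,
    classify_cells,
    count_cells,
    estimate_reference,
    normalize_well,
    peak_centers_log2,
    profile_plate,
)
from cycleplate.simulate import (
    REFERENCE_SCALE,
    NoiseModel,
    PhenotypeState,
    UNTREATED_MIXTURE,
    sample_population,
)


class TestEstimateReference:
    def test_recovers_generative_scale(self, control_sample):
        ref = estimate_reference(control_sample["dna_int"].to_numpy())
        assert ref.log2_center_2n == pytest.approx(np.log2(REFERENCE_SCALE), abs=0.05)

    def test_noiseless_pure_g1_exact(self, noiseless):
        cells = sample_population(((PhenotypeState("G1"), 1.0),), 500, noiseless)
        ref = estimate_reference(cells["dna_int"].to_numpy())
        assert ref.log2_center_2n == np.log2(REFERENCE_SCALE)

    def test_too_few_cells_rejected(self, noiseless):
        cells = sample_population(((PhenotypeState("G1"), 1.0),), 100, noiseless)
        with pytest.raises(ReliabilityError):
            estimate_reference(cells["dna_int"].to_numpy())

    def test_bimodal_ambiguity_takes_lower_mode_with_warning(self):
        noise = NoiseModel(dna_cv=0.06, rng_seed=2)
        mix = ((PhenotypeState("G1"), 0.5), (PhenotypeState("G2M"), 0.5))
        cells = sample_population(mix, 4000, noise, rng=np.random.default_rng(2))
        with pytest.warns(UserWarning, match="lower mode"):
            ref = estimate_reference(cells["dna_int"].to_numpy())
        assert ref.log2_center_2n == pytest.approx(np.log2(REFERENCE_SCALE), abs=0.05)


class TestNormalizeWell:
    def test_control_like_well_mode_at_one(self, control_sample):
        ref = estimate_reference(control_sample["dna_int"].to_numpy())
        noise = NoiseModel(rng_seed=77)
        well = sample_population(UNTREATED_MIXTURE, 2000, noise,
                                 rng=np.random.default_rng(77))
        norm = normalize_well(well["dna_int"].to_numpy(), ref)
        assert not norm.used_fallback
        centers = peak_centers_log2(norm.values, min_height=0.5)
        assert centers[0] == pytest.approx(0.0, abs=0.02)  # 2N mode at content 1

    def test_pure_4n_well_falls_back_and_sits_at_two(self, control_sample):
        """A fully arrested well has no in-window 2N peak; the pooled anchor
        leaves its 4N population at normalized content 2."""
        ref = estimate_reference(control_sample["dna_int"].to_numpy())
        noise = NoiseModel(dna_cv=0.06, rng_seed=5)
        well = sample_population(((PhenotypeState("G2M"), 1.0),), 2000, noise,
                                 rng=np.random.default_rng(5))
        norm = normalize_well(well["dna_int"].to_numpy(), ref)
        assert norm.used_fallback
        centers = peak_centers_log2(norm.values, min_height=0.5)
        assert 2.0 ** centers[-1] == pytest.approx(2.0, abs=0.1)

    def test_staining_drift_recentered(self, control_sample):
        """A 10 % per-well staining drift is corrected by the per-well peak."""
        ref = estimate_reference(control_sample["dna_int"].to_numpy())
        noise = NoiseModel(rng_seed=11)
        well = sample_population(UNTREATED_MIXTURE, 2000, noise,
                                 rng=np.random.default_rng(11))
        drifted = well["dna_int"].to_numpy() * 1.10
        norm = normalize_well(drifted, ref)
        assert not norm.used_fallback
        centers = peak_centers_log2(norm.values, min_height=0.5)
        assert 2.0 ** centers[0] == pytest.approx(1.00, abs=0.02)

    def test_empty_well_flagged(self, control_sample):
        ref = estimate_reference(control_sample["dna_int"].to_numpy())
        norm = normalize_well([], ref)
        assert norm.values.size == 0 and not norm.reliable

    @given(scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, scale, control_sample):
        """Multiplying all intensities by a constant changes nothing."""
        ints = control_sample["dna_int"].to_numpy()
        ref_a = estimate_reference(ints)
        ref_b = estimate_reference(ints * scale)
        a = normalize_well(ints[:500], ref_a)
        b = normalize_well(ints[:500] * scale, ref_b)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9, atol=1e-9)


class TestClassifyCells:
    @pytest.mark.parametrize(
        "value,bin_name",
        [
            (0.5, "subG1"), (0.74, "subG1"),
            (0.75, "2N"), (1.0, "2N"), (1.24, "2N"),
            (1.25, "S"), (1.5, "S"),
            (1.75, "4N"), (2.0, "4N"), (2.49, "4N"),
            (2.5, "gt4N"), (3.0, "gt4N"), (8.0, "gt4N"),
        ],
    )
    def test_bin_membership_half_open_intervals(self, value, bin_name):
        prof = classify_cells([value], min_cells=1)
        assert prof.fractions[bin_name] == 1.0

    def test_equal_representatives_give_uniform_fractions(self):
        prof = classify_cells([0.5, 1.0, 1.5, 2.0, 3.0], min_cells=1)
        assert all(f == pytest.approx(0.2) for f in prof.fractions.values())

    def test_fractions_sum_to_one(self, five_state_mixture, default_noise):
        cells = sample_population(five_state_mixture, 777, default_noise)
        prof = classify_cells(cells["true_dna_content"].to_numpy())
        assert sum(prof.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            classify_cells([1.0, -0.5])

    def test_low_count_flagged_unreliable(self):
        prof = classify_cells([1.0] * 20, min_cells=50)
        assert not prof.reliable and prof.n_cells == 20

    def test_log2_scale_convention(self):
        """On the log2 convention the thresholds act on 1 + log2(content)."""
        # content 1.5 -> 1 + log2(1.5) = 1.585 -> S on log2 scale
        prof = classify_cells([1.5], min_cells=1, scale="log2")
        assert prof.fractions["S"] == 1.0
        # content 2 -> exactly 2 on both scales -> 4N
        prof = classify_cells([2.0], min_cells=1, scale="log2")
        assert prof.fractions["4N"] == 1.0


class TestRecovery:
    def test_mixture_fractions_recovered_within_3_points(self, five_state_mixture):
        """Simulated wells of 2000 cells recover content-binned truth to ±3 pp."""
        worst = 0.0
        for seed in range(10):
            noise = NoiseModel(rng_seed=seed)
            ctrl = sample_population(UNTREATED_MIXTURE, 3000, noise,
                                     rng=np.random.default_rng(1000 + seed))
            ref = estimate_reference(ctrl["dna_int"].to_numpy())
            cells = sample_population(five_state_mixture, 2000, noise,
                                      rng=np.random.default_rng(seed))
            norm = normalize_well(cells["dna_int"].to_numpy(), ref)
            prof = classify_cells(norm.values)
            truth = classify_cells(cells["true_dna_content"].to_numpy())
            worst = max(
                worst,
                max(abs(prof.fractions[k] - truth.fractions[k]) for k in prof.fractions),
            )
        assert worst < 0.03

    def test_peak_spacing_2n_4n_8n(self, control_sample):
        """2N/4N/8N populations sit one log2 unit apart after normalization."""
        ref = estimate_reference(control_sample["dna_int"].to_numpy())
        noise = NoiseModel(rng_seed=5)
        mix = (
            (PhenotypeState("G1"), 0.4),
            (PhenotypeState("G2M"), 0.35),
            (PhenotypeState("endoredup", endoredup_high_fraction=0.0), 0.25),
        )
        cells = sample_population(mix, 4500, noise, rng=np.random.default_rng(2))
        norm = normalize_well(cells["dna_int"].to_numpy(), ref)
        centers = peak_centers_log2(norm.values)
        assert centers.size == 3
        np.testing.assert_allclose(np.diff(centers), 1.0, atol=0.05)


class TestCountCells:
    def test_percent_of_control(self):
        out = count_cells({"A01": 100, "A02": 100, "B01": 50, "B02": 0},
                          control_wells=["A01", "A02"])
        pct = out.set_index("well")["pct_of_control"]
        assert pct["A01"] == 100.0 and pct["B01"] == 50.0 and pct["B02"] == 0.0

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            count_cells({"A01": 0, "A02": 0, "B01": 5}, control_wells=["A01", "A02"])

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            count_cells({"A01": 10}, control_wells=["A01"])


class TestProfilePlate:
    def test_inhibition_scenario_percent_of_control(self):
        """80 % count inhibition reads out near 20 % of control."""
        noise = NoiseModel(rng_seed=8)
        rng_c = np.random.default_rng(3000)
        tables = []
        for i, w in enumerate(["C01", "C02", "C03"]):
            tables.append(sample_population(UNTREATED_MIXTURE, 1000, noise,
                                            rng=np.random.default_rng(100 + i), well=w))
        tables.append(sample_population(UNTREATED_MIXTURE, 200, noise,
                                        rng=rng_c, well="D01"))
        import pandas as pd

        cells = pd.concat(tables, ignore_index=True)
        out = profile_plate(cells, control_wells=["C01", "C02", "C03"])
        row = out.set_index("well").loc["D01"]
        assert row["pct_of_control"] == pytest.approx(20.0, abs=2.0)
        assert abs(out.set_index("well").loc["C01", "f_2N"] - 0.60) < 0.05
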