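"""Generator calibration, determinism and measurement-model oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from ctmon.ddpcr_quant import QuantConfig, poisson_concentration, quantify_sample
from ctmon.io import droplet_counts_from_frame
from ctmon.synthetic_cohort import (
    CohortConfig,
    Mutation,
    SimPatient,
    simulate_cohort,
    simulate_droplet_counts,
    simulate_ngs_reads,
    tumour_burden_trajectory,
)


def make_patient(rates, responder=False, size0=100.0):
    return SimPatient(
        patient_id="p1",
        sequenced=True,
        detectable=True,
        responder=responder,
        mutations=[
            Mutation(gene="TP53", label=f"m{i}", cds="c.1A>G", protein="p.M1V",
                     amplicon_id="AMP_010", baseline_af_percent=2.5,
                     baseline_copies_per_ml=100.0, kinetic_rate=r)
            for i, r in enumerate(rates)
        ],
        kinetic_rate=rates[0] if rates else 0.0,
        tumour_size_baseline_mm=size0,
        os_days=300.0,
        plasma_volume_ml=1.5,
        cfdna_background_per_ml=5000.0,
    )


class TestDeterminism:
    def test_same_seed_identical_output(self, tmp_path):
        cfg = CohortConfig(n_patients=6, seed=3)
        a = simulate_cohort(cfg)
        b = simulate_cohort(CohortConfig(n_patients=6, seed=3))
        for name in ("variants", "droplets", "timeline", "imaging", "truth",
                     "true_concentrations"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
        pa = a.write(tmp_path / "a")
        pb = b.write(tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes()

    def test_different_seed_differs(self):
        a = simulate_cohort(CohortConfig(n_patients=6, seed=3))
        b = simulate_cohort(CohortConfig(n_patients=6, seed=4))
        assert not a.truth.equals(b.truth)

    def test_patient_streams_stable_under_cohort_growth(self):
        # child RNG streams are keyed by patient id, so adding patients
        # does not change earlier patients' data
        small = simulate_cohort(CohortConfig(n_patients=4, seed=9))
        large = simulate_cohort(CohortConfig(n_patients=8, seed=9))
        pd.testing.assert_frame_equal(
            small.truth, large.truth[large.truth.patient_id.isin(small.truth.patient_id)]
            .reset_index(drop=True),
        )


class TestKinetics:
    def test_forced_growth_is_strictly_increasing(self):
        cfg = CohortConfig(
            n_patients=8, seed=5, responder_fraction=0.0,
            growth_rate_range_nonresponder=(0.05, 0.08), day_noise_sd=0.0,
            p_sequencing_success=1.0, p_detectable=1.0,
        )
        cohort = simulate_cohort(cfg)
        for (pid, assay), grp in cohort.true_concentrations.groupby(["patient_id", "assay_id"]):
            c = grp.sort_values("day")["true_copies_per_ml"].to_numpy()
            assert (np.diff(c) > 0).all()

    def test_calibration_against_target_distribution(self):
        # at n=500 the generated per-patient mutation-count median is 2,
        # the baseline AF median sits in [2.0, 3.0]% and gene fractions
        # track the configured weights within 0.05
        cfg = CohortConfig(n_patients=500, seed=17)
        cohort = simulate_cohort(cfg)
        counts = cohort.truth[cohort.truth.detectable].n_mutations
        assert counts.median() == 2
        assert counts.between(1, 5).all()

        af = np.array([m.baseline_af_percent for p in cohort.patients for m in p.mutations])
        assert 2.0 <= np.median(af) <= 3.0
        assert af.min() >= cfg.af_bounds[0] and af.max() <= cfg.af_bounds[1]

        genes = pd.Series([m.gene for p in cohort.patients for m in p.mutations])
        frac = genes.value_counts(normalize=True)
        assert abs(frac.get("TP53", 0) - 20 / 41) < 0.05
        assert abs(frac.get("KRAS", 0) - 13 / 41) < 0.05


class TestTumourTrajectory:
    def test_zero_rate_constant(self):
        p = make_patient([1e-12])
        assert tumour_burden_trajectory(p, 100.0) == pytest.approx(100.0)

    def test_responder_non_increasing(self):
        p = make_patient([-0.05], responder=True)
        sizes = [tumour_burden_trajectory(p, t) for t in (0, 30, 60, 90)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_power_law_exponent(self):
        # with exponent 1/3, an 8-fold burden gives a 2-fold size
        rate = 0.05
        t = math.log(8) / rate
        p = make_patient([rate])
        assert tumour_burden_trajectory(p, t, exponent=1 / 3) == pytest.approx(200.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            tumour_burden_trajectory(make_patient([0.01]), -1.0)


class TestDropletSimulation:
    def test_zero_concentration_no_positives(self):
        rng = np.random.default_rng(0)
        w = simulate_droplet_counts(0.0, 20000, 0.00085, 0.0, rng)
        assert w.mut_positive == 0 and w.double_positive == 0

    def test_saturation_at_huge_concentration(self):
        rng = np.random.default_rng(0)
        w = simulate_droplet_counts(1e9, 20000, 0.00085, 0.0, rng)
        assert w.mut_channel_positive == 20000

    def test_mean_positive_fraction_closed_form(self):
        # c=60 copies/µL, v=0.85 nL: E[positive fraction] = 1-exp(-0.051)
        rng = np.random.default_rng(12)
        n, reps = 20000, 1000
        p_true = -math.expm1(-60.0 * 0.00085)
        fracs = [
            simulate_droplet_counts(60.0, n, 0.00085, 0.0, rng).mut_channel_positive / n
            for _ in range(reps)
        ]
        se = math.sqrt(p_true * (1 - p_true) / n / reps)
        assert np.mean(fracs) == pytest.approx(p_true, abs=3 * se)

    def test_poisson_round_trip_within_two_percent(self):
        # mean concentration estimate over simulated wells recovers the
        # truth for occupancies up to c·v = 0.5
        rng = np.random.default_rng(23)
        for c in (10.0, 200.0, 0.5 / 0.00085):
            est = [
                poisson_concentration(
                    simulate_droplet_counts(c, 20000, 0.00085, 0.0, rng).mut_channel_positive,
                    20000,
                )
                for _ in range(300)
            ]
            assert np.mean(est) == pytest.approx(c, rel=0.02)


class TestNgsReads:
    def test_extremes(self):
        rng = np.random.default_rng(1)
        assert simulate_ngs_reads(0.0, 1000, rng) == (0, 1000)
        assert simulate_ngs_reads(1.0, 1000, rng) == (1000, 1000)

    def test_binomial_mean(self):
        rng = np.random.default_rng(2)
        draws = [simulate_ngs_reads(0.025, 4000, rng)[0] for _ in range(1000)]
        se = math.sqrt(4000 * 0.025 * 0.975) / math.sqrt(1000)
        assert np.mean(draws) == pytest.approx(100.0, abs=3 * se)

    def test_invalid_inputs(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            simulate_ngs_reads(1.5, 100, rng)
        with pytest.raises(ValueError):
            simulate_ngs_reads(0.5, 0, rng)


class TestSchedulesAndConfig:
    def test_first_imaging_in_window_then_regular(self):
        cohort = simulate_cohort(CohortConfig(n_patients=20, seed=21))
        for pid, grp in cohort.imaging.groupby("patient_id"):
            days = grp.sort_values("day")["day"].to_numpy()
            assert 63.0 <= days[0] <= 77.0
            for a, b in zip(days, days[1:]):
                assert b - a == pytest.approx(84.0, abs=0.11)

    def test_sample_days_monthly_from_baseline(self):
        cohort = simulate_cohort(CohortConfig(n_patients=10, seed=21))
        for pid, grp in cohort.timeline.groupby("patient_id"):
            days = grp.sort_values("day")["day"].to_numpy()
            assert days[0] == 0.0
            assert np.allclose(np.diff(days), 28.0)

    def test_plasma_volume_bounds(self):
        cohort = simulate_cohort(CohortConfig(n_patients=10, seed=2))
        vols = cohort.timeline.plasma_volume_ml
        assert vols.between(1.0, 2.0).all()

    def test_invalid_probability_vector_rejected(self):
        cfg = CohortConfig(mutations_per_patient_weights=(0.5, 0.5, 0.5, 0, 0))
        with pytest.raises(ValueError):
            simulate_cohort(cfg)

    def test_invalid_rate_ranges_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(CohortConfig(growth_rate_range_nonresponder=(-0.1, 0.1)))


class TestEndToEndQuantification:
    def test_baseline_quantification_tracks_truth(self, small_cohort):
        # quantifying the generated baseline wells recovers the generated
        # baseline concentrations within droplet-counting noise
        plasma = dict(zip(small_cohort.timeline.sample_id,
                          small_cohort.timeline.plasma_volume_ml))
        truth = small_cohort.true_concentrations
        base = truth[truth.day == 0.0]
        rel_errors = []
        for sid, grp in small_cohort.droplets.groupby("sample_id"):
            sub = base[base.sample_id == sid]
            if sub.empty:
                continue
            cfg = QuantConfig(plasma_volume_ml=float(plasma[sid]))
            res = quantify_sample(droplet_counts_from_frame(grp), cfg)
            for r in sub.itertuples():
                est = res[r.assay_id].copies_per_ml_plasma
                if r.true_copies_per_ml > 50:
                    rel_errors.append(abs(est - r.true_copies_per_ml) / r.true_copies_per_ml)
        assert rel_errors and np.median(rel_errors) < 0.25
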