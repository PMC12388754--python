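"""Stage performance metrics, the packaged train table, degree of fouling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import foulfit as ff
from foulfit.exceptions import ValidationError
from foulfit.stages import StageAssay, StageSpec

# hand-recomputed derived columns (VCF, ACF, R%, PF) from the measured
# feed/retentate values of the packaged seven-stage laccase train
EXPECTED = {
    "MF": (16.67, 4.78, 29, 1.37),
    "UF 1000": (10.44, 2.04, 20, 1.49),
    "UF 500": (28.33, 0.80, 3, 1.79),
    "UF 300": (26.67, 0.89, 3, 0.89),
    "UF 100": (24.33, 4.98, 20, 6.97),
    "UF 50": (23.00, 5.34, 23, 3.20),
    "UF 10": (21.33, 5.65, 26, 4.04),
}

positive = st.floats(0.01, 1e3, allow_nan=False, allow_infinity=False)


class TestSpecificActivity:
    def test_full_precision_values(self):
        assert ff.specific_activity(StageAssay(500, 0.217, 0.08)) == (
            pytest.approx(2.7125)
        )
        assert ff.specific_activity(StageAssay(15, 0.473, 0.05)) == (
            pytest.approx(9.46)
        )

    def test_zero_activity_gives_zero(self):
        assert ff.specific_activity(StageAssay(10, 0.0, 0.5)) == 0.0

    def test_nonpositive_protein_rejected(self):
        with pytest.raises(ValidationError):
            StageAssay(10, 0.1, 0.0)


class TestStagePerformance:
    def test_microfiltration_stage_values(self):
        summary = ff.stage_performance(
            StageAssay(500, 0.217, 0.08), StageAssay(30, 1.038, 0.28)
        )
        assert round(summary.vcf, 2) == 16.67
        assert round(summary.acf, 2) == 4.78
        assert round(100 * summary.recovery) == 29
        assert round(summary.pf, 2) == 1.37

    def test_identity_stream(self):
        a = StageAssay(100, 0.5, 0.1)
        summary = ff.stage_performance(a, a)
        assert summary.vcf == 1.0
        assert summary.acf == 1.0
        assert summary.pf == 1.0
        assert summary.diluted

    @given(v0=positive, vr=positive, l0=positive, lr=positive,
           p0=positive, pr=positive)
    def test_algebraic_identities(self, v0, vr, l0, lr, p0, pr):
        s = ff.stage_performance(StageAssay(v0, l0, p0), StageAssay(vr, lr, pr))
        assert s.recovery == s.acf / s.vcf
        assert s.pf == s.acf * (p0 / pr)
        # PF equals the specific-activity ratio up to float rounding
        assert s.pf == pytest.approx(s.sa_retentate / s.sa_feed, rel=1e-12)

    def test_full_train_reproduction(self):
        table = ff.performance_table(ff.laccase_train_table())
        for _, row in table.iterrows():
            vcf, acf, r, pf = EXPECTED[row["stage"]]
            assert round(row["VCF"], 2) == pytest.approx(vcf)
            assert round(row["ACF"], 2) == pytest.approx(acf)
            assert round(row["R_pct"]) == r
            assert round(row["PF"], 2) == pytest.approx(pf)


class TestTrainTable:
    def test_seven_stages(self):
        table = ff.laccase_train_table()
        assert len(table) == 7

    def test_spot_values(self):
        table = ff.laccase_train_table()
        assert table[0].feed.volume == 500
        assert table[0].feed.lac == 0.217
        assert table[0].feed.pro == 0.08
        assert table[0].retentate.lac == 1.038
        assert table[4].label == "UF 100"
        assert table[4].retentate.lac == 0.473

    def test_feeds_chain_from_permeates(self):
        table = ff.laccase_train_table()
        assert table[1].feed.label == "MF permeate"
        assert table[6].feed.label == "UF 50 permeate"


class TestSimulateTrain:
    FEED = StageAssay(500, 0.2, 0.08, label="extract")

    def test_total_rejection_empties_permeate(self):
        spec = StageSpec("S1", retentate_fraction=0.1, rejection_lac=1.0,
                         rejection_pro=0.5)
        stage = ff.simulate_train(self.FEED, [spec])[0]
        assert stage.permeate.lac == 0.0
        assert stage.retentate.total_activity == pytest.approx(
            self.FEED.total_activity
        )

    def test_free_passage_preserves_concentration(self):
        spec = StageSpec("S1", retentate_fraction=0.3, rejection_lac=0.0,
                         rejection_pro=0.0)
        stage = ff.simulate_train(self.FEED, [spec])[0]
        assert stage.retentate.lac == pytest.approx(self.FEED.lac)
        assert stage.permeate.lac == pytest.approx(self.FEED.lac)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_audit(self, seed):
        rng = np.random.default_rng(seed)
        specs = [
            StageSpec(f"S{i}", retentate_fraction=rng.uniform(0.05, 0.4),
                      rejection_lac=rng.uniform(0, 1),
                      rejection_pro=rng.uniform(0, 1),
                      loss=rng.uniform(0, 0.2))
            for i in range(4)
        ]
        stages = ff.simulate_train(self.FEED, specs)
        for stage, spec in zip(stages, specs):
            total_in = stage.feed.total_activity * (1 - spec.loss)
            total_out = stage.retentate.total_activity + stage.permeate.total_activity
            assert total_out == pytest.approx(total_in, rel=1e-12)
            assert stage.retentate.volume + stage.permeate.volume == (
                pytest.approx(stage.feed.volume, rel=1e-12)
            )

    def test_permeate_chains_to_next_feed(self):
        specs = [StageSpec(f"S{i}", 0.2, 0.5, 0.5) for i in range(3)]
        stages = ff.simulate_train(self.FEED, specs)
        for prev, nxt in zip(stages, stages[1:]):
            assert nxt.feed == prev.permeate

    def test_infeasible_loss_rejected(self):
        spec = StageSpec("S1", retentate_fraction=0.05, rejection_lac=0.0,
                         rejection_pro=0.0, loss=0.5)
        with pytest.raises(ValidationError, match="infeasible"):
            ff.simulate_train(self.FEED, [spec])

    def test_noisy_reporting_is_seeded(self):
        specs = [StageSpec("S1", 0.2, 0.5, 0.5)]
        a = ff.simulate_train(self.FEED, specs, noise_cv=0.05, seed=1)
        b = ff.simulate_train(self.FEED, specs, noise_cv=0.05, seed=1)
        assert a[0].retentate.lac == b[0].retentate.lac


class TestVmax:
    def test_direct_evaluation(self):
        assert ff.vmax(0.181) == pytest.approx(abs(math.log(0.4)) / 0.181, rel=1e-12)
        assert ff.vmax(0.181) == pytest.approx(5.0624, abs=2e-4)

    def test_inverse_proportionality(self):
        assert ff.vmax(0.2) == pytest.approx(2 * ff.vmax(0.4), rel=1e-12)

    def test_fraction_close_to_one_gives_tiny_vmax(self):
        assert ff.vmax(0.1, residual_fraction=1 - 1e-9) < 1e-7

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 2.0])
    def test_out_of_range_fraction_rejected(self, bad):
        with pytest.raises(ValidationError):
            ff.vmax(0.1, residual_fraction=bad)


class TestFoulingDegree:
    def test_truncation_at_residual_gives_unit_ratio(self):
        # run the intermediate law exactly until J/Jo = 0.4: the collected
        # volume then equals Vmax by construction of the law
        jo, ki = 400.0, 0.02
        t_end = (1 / 0.4 - 1) / (ki * jo)  # J(t_end)/Jo = 0.4
        grid = np.linspace(t_end / 200, t_end, 200)
        series = ff.simulate_deadend(
            ff.BlockingParams("intermediate", Jo=jo, K=ki), grid
        )
        fd = ff.fouling_degree(series, ki, residual_fraction=0.4)
        assert fd.ratio == pytest.approx(1.0, rel=1e-3)
        assert fd.non_exhaustive

    def test_ceiling_boundary_flagged(self):
        s = ff.series_from_flux([0.5, 1.0, 1.5], [100.0, 90.0, 80.0])
        ki = abs(math.log(0.4)) / (s.v[-1] / 1.10)
        fd = ff.fouling_degree(s, ki)
        assert fd.at_ceiling
        assert fd.non_exhaustive

    def test_exhaustive_use_detected(self):
        s = ff.series_from_flux([0.5, 1.0, 1.5], [100.0, 90.0, 80.0])
        ki = abs(math.log(0.4)) / (s.v[-1] / 2.0)  # collected = 2× critical
        assert not ff.fouling_degree(s, ki).non_exhaustive
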