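"""NTC normalization, cluster fitting, confidence rules and sample QC."""

import math

import pytest

from pgxforge.errors import (
    ConfigurationError,
    DegenerateControlError,
    NoSignalError,
    UsageError,
)
from pgxforge.genotype import (
    AMBIGUOUS_POSITION,
    FAM_HOM,
    HET,
    LOW_INTENSITY,
    NO_CALL,
    VIC_HOM,
    AssayClusterModel,
    FluorescenceReading,
    GenotypeCall,
    PlateRun,
    call_genotype,
    call_plate,
    cluster_assay,
    normalize_plate,
    qc_sample,
)


def _reading(sample, vic, fam, role="sample", assay="A1", **kw):
    return FluorescenceReading(sample_id=sample, assay_id=assay,
                               raw_vic=vic, raw_fam=fam, well_role=role, **kw)


def _norm(sample, vic, fam, role="sample", assay="A1"):
    return FluorescenceReading(sample_id=sample, assay_id=assay, raw_vic=vic,
                               raw_fam=fam, well_role=role,
                               norm_vic=vic, norm_fam=fam)


@pytest.fixture
def simple_model():
    return AssayClusterModel(
        assay_id="A1",
        centroids={VIC_HOM: (4.0, 1.3), HET: (3.2, 3.2), FAM_HOM: (1.3, 4.0)},
        ntc_centroid=(1.0, 1.0),
    )


class TestNormalize:
    def test_ntc_wells_map_to_unit_baseline(self):
        run = PlateRun("R", (
            _reading("NTC1", 100.0, 80.0, role="NTC"),
            _reading("NTC2", 100.0, 80.0, role="NTC"),
            _reading("S1", 200.0, 160.0),
        ))
        out = normalize_plate(run)
        ntc = [r for r in out.readings if r.well_role == "NTC"][0]
        assert ntc.norm_vic == pytest.approx(1.0)
        assert ntc.norm_fam == pytest.approx(1.0)

    def test_twice_ntc_normalizes_to_two(self):
        run = PlateRun("R", (
            _reading("NTC1", 100.0, 50.0, role="NTC"),
            _reading("S1", 200.0, 100.0),
        ))
        sample = [r for r in normalize_plate(run).readings
                  if r.well_role == "sample"][0]
        assert (sample.norm_vic, sample.norm_fam) == pytest.approx((2.0, 2.0))

    def test_missing_ntc_is_a_configuration_error(self):
        run = PlateRun("R", (_reading("S1", 1.0, 1.0),))
        with pytest.raises(ConfigurationError):
            normalize_plate(run)

    def test_zero_ntc_intensity_is_degenerate(self):
        run = PlateRun("R", (_reading("NTC1", 0.0, 10.0, role="NTC"),))
        with pytest.raises(DegenerateControlError):
            normalize_plate(run)


class TestClusterAssay:
    def _controls(self):
        return [
            _norm("NTC1", 1.0, 1.0, role="NTC"),
            _norm("V", 4.0, 1.3, role="VIC_CTRL"),
            _norm("H", 3.2, 3.2, role="VICFAM_CTRL"),
            _norm("F", 1.3, 4.0, role="FAM_CTRL"),
        ]

    def test_three_cluster_labels_by_angle(self):
        pts = self._controls() + [
            _norm("S1", 4.1, 1.2), _norm("S2", 3.1, 3.3), _norm("S3", 1.2, 3.9),
        ]
        model = cluster_assay(pts, seed=0)
        assert set(model.centroids) == {VIC_HOM, HET, FAM_HOM}
        assert model.centroids[VIC_HOM][0] > model.centroids[FAM_HOM][0]
        assert model.centroids[FAM_HOM][1] > model.centroids[VIC_HOM][1]

    def test_two_control_types_emit_two_labels(self):
        pts = [
            _norm("NTC1", 1.0, 1.0, role="NTC"),
            _norm("V", 4.0, 1.3, role="VIC_CTRL"),
            _norm("H", 3.2, 3.2, role="VICFAM_CTRL"),
            _norm("S1", 4.1, 1.25), _norm("S2", 3.9, 1.35),
        ]
        model = cluster_assay(pts, seed=0)
        assert set(model.centroids) == {VIC_HOM, HET}

    def test_duplicating_every_point_leaves_model_unchanged(self):
        pts = self._controls() + [_norm("S1", 4.1, 1.2), _norm("S2", 3.1, 3.3)]
        m1 = cluster_assay(pts, seed=3)
        m2 = cluster_assay(pts + pts, seed=3)
        for label in m1.centroids:
            assert m1.centroids[label] == pytest.approx(m2.centroids[label])

    def test_collapsed_readings_raise_no_signal(self):
        pts = [_norm("NTC1", 1.0, 1.0, role="NTC"),
               _norm("V", 1.0, 1.0, role="VIC_CTRL"),
               _norm("S1", 1.0, 1.0)]
        with pytest.raises(NoSignalError):
            cluster_assay(pts, seed=0)

    def test_unnormalized_readings_rejected(self):
        with pytest.raises(UsageError, match="not normalized"):
            cluster_assay([_reading("V", 4.0, 1.3, role="VIC_CTRL")], seed=0)


class TestCallGenotype:
    def test_point_on_centroid_has_full_confidence(self, simple_model, clinical_panel):
        assay = clinical_panel.assays[0]
        model = AssayClusterModel(assay_id=assay.assay_id,
                                  centroids=simple_model.centroids,
                                  ntc_centroid=(1.0, 1.0))
        r = _norm("S1", 4.0, 1.3, assay=assay.assay_id)
        call = call_genotype(r, model, assay)
        assert call.call == VIC_HOM
        assert call.confidence == pytest.approx(1.0)
        assert call.base_genotype == assay.vic_allele * 2

    def test_midpoint_between_het_and_homozygote_is_ambiguous(self, simple_model,
                                                              clinical_panel):
        assay = clinical_panel.assays[0]
        model = AssayClusterModel(assay_id=assay.assay_id,
                                  centroids=simple_model.centroids,
                                  ntc_centroid=(1.0, 1.0))
        mid = tuple((a + b) / 2 for a, b in
                    zip(model.centroids[HET], model.centroids[VIC_HOM]))
        call = call_genotype(_norm("S1", *mid, assay=assay.assay_id), model, assay)
        assert call.call == NO_CALL
        assert call.no_call_reason == AMBIGUOUS_POSITION
        assert call.confidence == pytest.approx(0.5)

    def test_low_intensity_floor_overrides_cluster_pattern(self, simple_model,
                                                           clinical_panel):
        assay = clinical_panel.assays[0]
        model = AssayClusterModel(assay_id=assay.assay_id,
                                  centroids=simple_model.centroids,
                                  ntc_centroid=(1.0, 1.0))
        call = call_genotype(_norm("S1", 1.15, 1.18, assay=assay.assay_id),
                             model, assay)
        assert call.call == NO_CALL
        assert call.no_call_reason == LOW_INTENSITY

    def test_one_bright_channel_clears_the_floor(self, simple_model, clinical_panel):
        # homozygotes have one dim channel; only both-dim wells are no-called
        assay = clinical_panel.assays[0]
        model = AssayClusterModel(assay_id=assay.assay_id,
                                  centroids=simple_model.centroids,
                                  ntc_centroid=(1.0, 1.0))
        call = call_genotype(_norm("S1", 4.0, 1.05, assay=assay.assay_id),
                             model, assay)
        assert call.call == VIC_HOM

    def test_model_assay_mismatch_is_a_lookup_error(self, simple_model,
                                                    clinical_panel):
        assay = clinical_panel.assays[0]
        with pytest.raises(UsageError):
            call_genotype(_norm("S1", 4.0, 1.3, assay="OTHER"),
                          simple_model, assay)


class TestSampleQc:
    def _calls(self, n_auto, n_nc, sample="S1"):
        calls = [
            GenotypeCall(sample, f"A{i}", VIC_HOM, "AA", 1.0)
            for i in range(n_auto)
        ]
        calls += [
            GenotypeCall(sample, f"N{i}", NO_CALL, "NN", 0.0, LOW_INTENSITY)
            for i in range(n_nc)
        ]
        return calls

    def test_clean_sample_attains_the_50_percent_ceiling(self):
        qc = qc_sample(self._calls(48, 0))
        assert qc.initial_call_rate == pytest.approx(0.5)
        assert not qc.poor_amplifier

    def test_four_no_calls_sit_exactly_on_the_threshold_and_do_not_flag(self):
        qc = qc_sample(self._calls(44, 4))
        assert qc.initial_call_rate == pytest.approx(44 / 96)
        assert not qc.poor_amplifier  # 45.83% is not strictly below 45.83%

    def test_ten_no_calls_flag_a_poor_amplifier(self):
        qc = qc_sample(self._calls(38, 10))
        assert qc.initial_call_rate == pytest.approx(38 / 96, abs=1e-4)
        assert qc.poor_amplifier


class TestCallPlate:
    def _plate(self, order=1):
        readings = []
        for assay in ("A1", "A2"):
            readings += [
                _reading("NTC1", 100.0, 100.0, role="NTC", assay=assay),
                _reading("V", 400.0, 130.0, role="VIC_CTRL", assay=assay),
                _reading("H", 320.0, 320.0, role="VICFAM_CTRL", assay=assay),
                _reading("F", 130.0, 400.0, role="FAM_CTRL", assay=assay),
                _reading("S1", 410.0, 125.0, assay=assay),
                _reading("S2", 315.0, 325.0, assay=assay),
            ]
        return PlateRun("R", tuple(readings[::order]))

    @pytest.fixture
    def two_assay_panel(self):
        from pgxforge.panel import PanelDef, SnpAssayDef
        return PanelDef(name="mini", assays=(
            SnpAssayDef("A1", "rs1", "G1", "A", "G"),
            SnpAssayDef("A2", "rs2", "G1", "C", "T"),
        ))

    def test_every_sample_well_gets_exactly_one_call(self, two_assay_panel):
        calls, qc = call_plate(self._plate(), two_assay_panel, seed=0)
        assert len(calls) == 4  # 2 samples x 2 assays
        assert {(c.sample_id, c.assay_id) for c in calls} == \
            {("S1", "A1"), ("S1", "A2"), ("S2", "A1"), ("S2", "A2")}

    def test_calling_is_invariant_to_reading_order(self, two_assay_panel):
        calls_fwd, _ = call_plate(self._plate(1), two_assay_panel, seed=0)
        calls_rev, _ = call_plate(self._plate(-1), two_assay_panel, seed=0)
        assert [(c.sample_id, c.assay_id, c.call) for c in calls_fwd] == \
            [(c.sample_id, c.assay_id, c.call) for c in calls_rev]

    def test_expected_genotypes_called(self, two_assay_panel):
        calls, _ = call_plate(self._plate(), two_assay_panel, seed=0)
        by_key = {(c.sample_id, c.assay_id): c for c in calls}
        assert by_key[("S1", "A1")].call == VIC_HOM
        assert by_key[("S2", "A1")].call == HET
        assert by_key[("S1", "A1")].base_genotype == "AA"
        assert by_key[("S2", "A2")].base_genotype == "CT"
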