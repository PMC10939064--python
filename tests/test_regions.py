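import itertools

import numpy as np
import pytest

from kneecart import (
    AmbiguousCompartmentError,
    Bone,
    Compartment,
    CohortCase,
    DicomMeta,
    RegionCode,
    Sex,
    Side,
    ThicknessProfile,
    average_thirds,
    build_reference,
    infer_compartment,
    load_default_reference,
    map_regions,
    reference_mean,
)
from kneecart.errors import ReferenceError_
from kneecart.geometry import MeasurementLine
from kneecart.regions import RefCell, ReferenceTable
from kneecart.types import Third, region_code


def profile_from_values(values, bone=Bone.FEMUR):
    lines = [
        MeasurementLine(index=i, origin=(0.0, 0.0), direction=(1.0, 0.0), thickness_mm=v)
        for i, v in enumerate(values, start=1)
    ]
    return ThicknessProfile(bone=bone, lines=lines, spacing=(0.4, 0.4))


class TestAverageThirds:
    def test_constant_profile(self):
        thirds = average_thirds(profile_from_values([4.0] * 36))
        assert thirds == [(4.0, 12)] * 3

    def test_block_constants(self):
        values = [2.0] * 12 + [3.0] * 12 + [4.0] * 12
        assert [m for m, _ in average_thirds(profile_from_values(values))] == [2.0, 3.0, 4.0]

    def test_missing_block_reported_as_missing(self):
        values = [None] * 12 + [1.5] * 24
        thirds = average_thirds(profile_from_values(values))
        assert thirds == [(None, 0), (1.5, 12), (1.5, 12)]

    def test_partial_block_mean_skips_missing_lines(self):
        values = [2.0, None] * 6 + [1.0] * 24
        mean, n = average_thirds(profile_from_values(values))[0]
        assert (mean, n) == (2.0, 6)

    def test_missing_as_zero_counts_absent_lines(self):
        values = [2.0, None] * 6 + [1.0] * 24
        mean, n = average_thirds(profile_from_values(values), missing_as_zero=True)[0]
        assert (mean, n) == (1.0, 12)


class TestMapRegions:
    def test_anterior_first_mapping(self):
        report = map_regions([(2.0, 12), (3.0, 12), (4.0, 12)], Bone.FEMUR, Compartment.MEDIAL, True)
        assert report.mean_for(RegionCode.FMA) == 2.0
        assert report.mean_for(RegionCode.FMC) == 3.0
        assert report.mean_for(RegionCode.FMP) == 4.0

    def test_anterior_first_false_reverses_a_and_p(self):
        report = map_regions([(2.0, 12), (3.0, 12), (4.0, 12)], Bone.FEMUR, Compartment.MEDIAL, False)
        assert report.mean_for(RegionCode.FMA) == 4.0
        assert report.mean_for(RegionCode.FMC) == 3.0
        assert report.mean_for(RegionCode.FMP) == 2.0

    def test_constant_thirds_tibia_lateral(self):
        report = map_regions([(1.0, 12)] * 3, Bone.TIBIA, Compartment.LATERAL, True)
        for code in (RegionCode.TLA, RegionCode.TLC, RegionCode.TLP):
            assert report.mean_for(code) == 1.0

    @pytest.mark.parametrize("bone", Bone)
    @pytest.mark.parametrize("compartment", Compartment)
    def test_flag_flip_equals_a_p_swap(self, bone, compartment):
        thirds = [(1.0, 12), (2.0, 10), (3.0, 12)]
        fwd = map_regions(thirds, bone, compartment, True)
        rev = map_regions(thirds, bone, compartment, False)
        swap = {Third.ANTERIOR: Third.POSTERIOR, Third.CENTRAL: Third.CENTRAL,
                Third.POSTERIOR: Third.ANTERIOR}
        for code, entry in fwd.entries.items():
            swapped = region_code(code.bone, code.compartment, swap[code.third])
            assert rev.entries[swapped] == entry

    def test_full_enumeration_yields_12_codes(self):
        codes = {
            region_code(b, c, t)
            for b, c, t in itertools.product(Bone, Compartment, Third)
        }
        assert len(codes) == 12
        assert codes == set(RegionCode)


class TestInferCompartment:
    def _meta(self, slice_index, n_slices, side=Side.RIGHT):
        return DicomMeta(0.4, 0.4, 512, 512, side, Sex.M, slice_index, n_slices)

    def test_override_wins(self):
        meta = self._meta(18, 36)
        assert infer_compartment(meta, Compartment.MEDIAL) is Compartment.MEDIAL

    def test_quarter_slice_right_knee_is_lateral(self):
        assert infer_compartment(self._meta(9, 36)) is Compartment.LATERAL

    def test_three_quarter_slice_right_knee_is_medial(self):
        assert infer_compartment(self._meta(27, 36)) is Compartment.MEDIAL

    def test_laterality_switches_assignment(self):
        assert infer_compartment(self._meta(9, 36, Side.LEFT)) is Compartment.MEDIAL

    def test_central_slice_without_override_is_ambiguous(self):
        with pytest.raises(AmbiguousCompartmentError):
            infer_compartment(self._meta(18, 36))


class TestBuildReference:
    def _case(self, value, sex=Sex.M, side=Side.LEFT):
        return CohortCase(regions={RegionCode.FMA: value}, sex=sex, side=side)

    def test_mean_and_sample_sd(self):
        table = build_reference([self._case(2.0), self._case(2.2)])
        cell = table.get(Sex.M, Side.LEFT, RegionCode.FMA)
        assert cell.mean_mm == pytest.approx(2.1)
        assert cell.sd_mm == pytest.approx(0.1414, abs=1e-4)

    def test_identical_cases_have_zero_sd(self):
        table = build_reference([self._case(2.0), self._case(2.0), self._case(2.0)])
        assert table.get(Sex.M, Side.LEFT, RegionCode.FMA).sd_mm == 0.0

    def test_underpopulated_cell_warns_and_is_skipped(self):
        with pytest.warns(UserWarning, match="left unpopulated"):
            table = build_reference([self._case(2.0), self._case(2.1, sex=Sex.W)])
        assert table.cells == {}


class TestReferenceMean:
    def test_packaged_femoral_average(self):
        assert reference_mean(load_default_reference(), Bone.FEMUR) == 1.98

    def test_constant_table(self):
        table = ReferenceTable()
        for sex in Sex:
            for side in Side:
                for code in RegionCode:
                    if code.bone is Bone.TIBIA:
                        continue
                    table.cells[(sex, side, code)] = RefCell(2.5, 0.1)
        assert reference_mean(table, Bone.FEMUR) == 2.5

    def test_enumerated_cells(self):
        table = ReferenceTable()
        keys = [
            (sex, side, code)
            for sex in Sex for side in Side for code in RegionCode
            if code.bone is Bone.FEMUR
        ]
        for i, key in enumerate(keys, start=1):
            table.cells[key] = RefCell(i * 0.1, 0.0)
        assert reference_mean(table, Bone.FEMUR) == 1.25

    def test_missing_cells_listed(self):
        with pytest.raises(ReferenceError_, match="TMA"):
            reference_mean(load_default_reference(), Bone.TIBIA)

    def test_reference_roundtrip_csv(self, tmp_path):
        table = load_default_reference()
        table.to_csv(tmp_path / "ref.csv")
        back = ReferenceTable.from_csv(tmp_path / "ref.csv")
        assert back.cells == table.cells
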