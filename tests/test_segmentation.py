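"""Sawtooth smoothing of fold-propensity signs into regions."""

import numpy as np
import pytest

from phosfold import (
    RegionSet,
    envelope_track,
    fold_propensity_profile,
    initial_classification,
    sawtooth_smooth,
    segment,
)
from phosfold.segmentation import DISORDERED, STRUCTURED, Region, regions_to_tsv
from phosfold.synthetic import SetSpec, generate_set
from phosfold.windows import Profile


def profile_of(values):
    return Profile(values=np.asarray(values, dtype=float), window_length=21, statistic="mean")


def labels_of(pattern):
    """'S'/'D' string -> boolean labels (True = structured)."""
    return np.array([c == "S" for c in pattern])


class TestInitialClassification:
    def test_sign_mapping(self):
        fp = profile_of([0.5, 0.1, -0.2, -0.1, 0.3])
        assert initial_classification(fp).tolist() == [True, True, False, False, True]

    def test_exact_zero_is_disordered(self):
        fp = profile_of([0.0])
        assert initial_classification(fp).tolist() == [False]

    def test_all_positive_all_structured(self):
        fp = profile_of([1.0] * 10)
        assert initial_classification(fp).all()


class TestSawtoothSmooth:
    def test_short_idr_reabsorbed_when_surrounding_fp_positive(self):
        labels = labels_of("S" * 30 + "D" * 5 + "S" * 30)
        fp = profile_of([1.0] * 30 + [-0.1] * 5 + [1.0] * 30)
        regions = sawtooth_smooth(labels, fp).regions
        assert regions == [Region(1, 65, STRUCTURED)]

    def test_short_idr_kept_when_41_window_mean_negative(self):
        labels = labels_of("S" * 30 + "D" * 5 + "S" * 30)
        fp = profile_of([0.05] * 30 + [-3.0] * 5 + [0.05] * 30)
        regions = sawtooth_smooth(labels, fp).regions
        assert regions == [
            Region(1, 30, STRUCTURED),
            Region(31, 35, DISORDERED),
            Region(36, 65, STRUCTURED),
        ]

    def test_short_structured_gap_merges_idrs(self):
        labels = labels_of("D" * 20 + "S" * 5 + "D" * 20)
        fp = profile_of([-1.0] * 20 + [1.0] * 5 + [-1.0] * 20)
        regions = sawtooth_smooth(labels, fp).regions
        assert regions == [Region(1, 45, DISORDERED)]

    def test_long_disordered_run_is_fixed_point(self):
        labels = labels_of("D" * 40)
        fp = profile_of([-1.0] * 40)
        regions = sawtooth_smooth(labels, fp).regions
        assert regions == [Region(1, 40, DISORDERED)]

    def test_terminal_structured_run_exempt_from_merging(self):
        labels = labels_of("S" * 5 + "D" * 20)
        fp = profile_of([2.0] * 5 + [-1.0] * 20)
        regions = sawtooth_smooth(labels, fp).regions
        assert regions[0] == Region(1, 5, STRUCTURED)

    def test_terminal_short_idr_subject_to_reaveraging(self):
        labels = labels_of("D" * 4 + "S" * 40)
        fp = profile_of([-0.1] * 4 + [1.0] * 40)
        regions = sawtooth_smooth(labels, fp).regions
        assert regions == [Region(1, 44, STRUCTURED)]

    def test_reaveraging_window_truncated_at_ends(self):
        # run midpoint near position 3: window is [1, 23], not 41 wide
        labels = labels_of("D" * 5 + "S" * 60)
        fp_vals = np.concatenate([[-1.0] * 5, [0.05] * 60])
        regions = sawtooth_smooth(labels, profile_of(fp_vals)).regions
        # mean over positions 1..23 = (5*-1 + 18*0.05)/23 < 0 -> stays disordered
        assert regions[0] == Region(1, 5, DISORDERED)


class TestSmoothingInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_tiling_and_no_short_interior_structured_runs(self, rng, seed):
        fp = profile_of(np.random.default_rng(seed).normal(0, 0.3, size=300))
        regions = sawtooth_smooth(initial_classification(fp), fp)
        # exact tiling of [1, L]
        assert regions.regions[0].start == 1
        assert regions.regions[-1].end == 300
        for a, b in zip(regions.regions, regions.regions[1:]):
            assert b.start == a.end + 1
            assert a.region_class != b.region_class
        # no interior structured run shorter than 10
        for r in regions.regions[1:-1]:
            if r.region_class == STRUCTURED:
                assert len(r) >= 10

    def test_idempotent_on_pipeline_profiles(self):
        for record in generate_set(SetSpec(n_proteins=10, seed=3, phospho_density=0.0)):
            fp = fold_propensity_profile(record)
            once = segment(fp)
            twice = sawtooth_smooth(once.labels(), fp)
            assert once.regions == twice.regions

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="same sequence"):
            sawtooth_smooth(np.zeros(5, dtype=bool), profile_of([0.0] * 6))


class TestEnvelope:
    def test_structured_region_triangle(self):
        regions = RegionSet([Region(1, 5, STRUCTURED)])
        assert envelope_track(regions).tolist() == [0.0, 0.5, 1.0, 0.5, 0.0]

    def test_disordered_region_negative_triangle(self):
        regions = RegionSet([Region(1, 3, DISORDERED)])
        assert envelope_track(regions).tolist() == [0.0, -1.0, 0.0]

    def test_even_length_regions_keep_class_sign(self):
        regions = RegionSet([Region(1, 2, STRUCTURED), Region(3, 4, DISORDERED)])
        track = envelope_track(regions)
        assert (track[:2] > 0).all() and (track[2:] < 0).all()

    def test_single_position_region_gets_full_amplitude(self):
        regions = RegionSet(
            [Region(1, 1, STRUCTURED), Region(2, 21, DISORDERED)]
        )
        assert envelope_track(regions)[0] == 1.0


def test_region_tsv_dialects():
    regions = RegionSet([Region(1, 10, STRUCTURED), Region(11, 30, DISORDERED)])
    one_based = regions_to_tsv("P1", regions)
    assert "P1\t1\t10\tstructured" in one_based
    assert "P1\t11\t30\tdisordered" in one_based
    bed = regions_to_tsv("P1", regions, bed=True)
    assert bed.splitlines() == ["P1\t0\t10\tstructured", "P1\t10\t30\tdisordered"]
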