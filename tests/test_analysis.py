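"""Windowed IDR charge distributions and dNCPR, per protein and per set."""

import numpy as np
import pytest

from phosfold import (
    ProteinRecord,
    RegionSet,
    compare_sets,
    delta_ncpr,
    idr_window_net_charges,
    window_charge_distribution,
)
from phosfold.analysis import distribution_to_tsv
from phosfold.segmentation import DISORDERED, STRUCTURED, Region
from phosfold.synthetic import SetSpec, generate_set


def idr(start, end):
    return RegionSet([Region(start, end, DISORDERED)])


class TestIdrWindowNetCharges:
    def test_single_window_sums_region_charge(self):
        rec = ProteinRecord("P", "G" * 4 + "K" + "G" * 16)
        values = idr_window_net_charges(rec, idr(1, 21))
        assert values.tolist() == [1.0]

    def test_two_overlapping_windows_for_length_22(self):
        rec = ProteinRecord("P", "G" * 22)
        assert idr_window_net_charges(rec, idr(1, 22)).tolist() == [0.0, 0.0]

    def test_phospho_site_in_every_window_drops_each_by_two(self):
        rec = ProteinRecord("P", "G" * 10 + "S" + "G" * 14, {11})
        regions = idr(1, 25)
        unmod = idr_window_net_charges(rec, regions, phospho_mode="unmodified")
        phos = idr_window_net_charges(rec, regions, phospho_mode="phosphorylated")
        assert np.array_equal(phos, unmod - 2.0)

    def test_windows_never_straddle_region_boundaries(self):
        seq = "G" * 43
        rec = ProteinRecord("P", seq)
        regions = RegionSet(
            [
                Region(1, 21, DISORDERED),
                Region(22, 22, STRUCTURED),
                Region(23, 43, DISORDERED),
            ]
        )
        # each 21-long IDR admits exactly one window; nothing crosses pos 22
        assert len(idr_window_net_charges(rec, regions)) == 2

    def test_region_shorter_than_window_contributes_nothing(self):
        rec = ProteinRecord("P", "G" * 30)
        regions = RegionSet(
            [Region(1, 20, DISORDERED), Region(21, 30, STRUCTURED)]
        )
        assert len(idr_window_net_charges(rec, regions)) == 0

    def test_drop_equals_twice_sites_inside_window(self, two_block_record):
        from phosfold import fold_propensity_profile, segment

        regions = segment(fold_propensity_profile(two_block_record))
        unmod = idr_window_net_charges(two_block_record, regions, 21, "unmodified")
        phos = idr_window_net_charges(two_block_record, regions, 21, "phosphorylated")
        offset = 0
        for region in regions.disordered_regions():
            if len(region) < 21:
                continue
            for w, start in enumerate(range(region.start, region.end - 19)):
                k = sum(
                    1
                    for p in two_block_record.phospho_sites
                    if start <= p <= start + 20
                )
                assert phos[offset + w] - unmod[offset + w] == -2.0 * k
            offset += len(region) - 20


class TestWindowChargeDistribution:
    def test_counts_and_bins(self):
        dist = window_charge_distribution([1.0, 1.0, 0.0])
        assert dist.counts[dist.bin_values.tolist().index(0)] == 1
        assert dist.counts[dist.bin_values.tolist().index(1)] == 2
        assert dist.clipped == 0

    def test_out_of_range_values_clipped_not_dropped(self):
        dist = window_charge_distribution([15.0])
        assert dist.clipped == 1
        assert dist.counts.sum() == 0
        assert dist.counts.sum() + dist.clipped == dist.n_windows

    def test_range_extremes_per_residue(self):
        # +/-10 summed over 21 residues is +/-0.476 per residue
        assert round(10 / 21, 3) == 0.476

    def test_fractional_charges_round_to_nearest_bin(self):
        dist = window_charge_distribution([0.4, 0.6])
        assert dist.counts[dist.bin_values.tolist().index(0)] == 1
        assert dist.counts[dist.bin_values.tolist().index(1)] == 1

    def test_normalized_sums_to_one_excluding_clipped(self):
        dist = window_charge_distribution([0.0, 2.0, 15.0])
        assert dist.normalized.sum() == pytest.approx(1.0)

    def test_tsv_export_reports_totals(self):
        text = distribution_to_tsv(window_charge_distribution([0.0, 11.0]))
        assert "# n_windows=2 clipped=1" in text


class TestDeltaNcpr:
    def test_three_sites_in_hundred_residue_idr(self):
        seq = "G" * 50 + "S" * 50
        rec = ProteinRecord("P", seq, {60, 70, 80})
        assert delta_ncpr(rec, idr(1, 100)) == pytest.approx(-0.06)

    def test_no_sites_gives_zero(self):
        rec = ProteinRecord("P", "G" * 100)
        assert delta_ncpr(rec, idr(1, 100)) == 0.0

    def test_every_residue_phosphorylated_hits_lower_bound(self):
        rec = ProteinRecord("P", "S" * 50, set(range(1, 51)))
        assert delta_ncpr(rec, idr(1, 50)) == -2.0

    def test_zero_residue_scope_is_missing_not_zero(self):
        rec = ProteinRecord("P", "G" * 50, {10})
        all_structured = RegionSet([Region(1, 50, STRUCTURED)])
        assert delta_ncpr(rec, all_structured) is None

    def test_scopes_differ_when_sites_outside_idr(self):
        rec = ProteinRecord("P", "S" * 100, {5, 60})
        regions = RegionSet(
            [Region(1, 50, STRUCTURED), Region(51, 100, DISORDERED)]
        )
        assert delta_ncpr(rec, regions, "idr_only") == pytest.approx(-2 / 50)
        assert delta_ncpr(rec, regions, "whole_protein") == pytest.approx(-4 / 100)

    def test_always_within_bounds(self, rng):
        from conftest import random_record

        for _ in range(50):
            rec = random_record(rng, min_len=30, max_len=60)
            value = delta_ncpr(rec, idr(1, len(rec.sequence)))
            assert -2.0 <= value <= 0.0


class TestCompareSets:
    def make_member(self, seq, sites=()):
        rec = ProteinRecord("P", seq, set(sites))
        return (rec, idr(1, len(seq)))

    def test_identical_sets_are_symmetric(self):
        member = self.make_member("G" * 10 + "S" + "G" * 19, {11})
        cmp = compare_sets([member], [member])
        assert np.array_equal(cmp.set_a.unmodified.counts, cmp.set_b.unmodified.counts)
        assert np.array_equal(cmp.set_a.difference, cmp.set_b.difference)

    def test_no_sites_means_zero_difference(self):
        member = self.make_member("G" * 40)
        cmp = compare_sets([member], [member])
        assert not cmp.set_a.difference.any()
        assert cmp.set_a.mean_delta_ncpr == 0.0

    def test_empty_set_raises_with_name(self):
        member = self.make_member("G" * 40)
        with pytest.raises(ValueError, match="set_b"):
            compare_sets([member], [])

    def test_difference_series_sums_to_zero_without_clipping(self):
        member = self.make_member("G" * 30 + "S" + "G" * 9, {31})
        cmp = compare_sets([member], [member])
        assert cmp.set_a.difference.sum() == pytest.approx(0.0, abs=1e-12)

    def test_pooled_counts_conserved(self):
        a = self.make_member("G" * 25)
        b = self.make_member("G" * 30)
        cmp = compare_sets([a, b], [a])
        per_protein = (25 - 20) + (30 - 20)
        assert cmp.set_a.n_windows == per_protein
        assert cmp.set_a.unmodified.counts.sum() + cmp.set_a.unmodified.clipped == per_protein


def test_planted_density_recovers_expected_delta_ncpr():
    """Planted per-IDR-residue density p gives mean dNCPR = -2p within 3 SE."""
    p = 0.017
    values = []
    for seed in (11, 12):
        for record, regions in generate_set(
            SetSpec(n_proteins=60, seed=seed, phospho_density=p), with_regions=True
        ):
            d = delta_ncpr(record, regions)
            if d is not None:
                values.append(d)
    mean = np.mean(values)
    se = np.std(values, ddof=1) / np.sqrt(len(values))
    assert abs(mean - (-2 * p)) < 3 * se + 1e-12
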