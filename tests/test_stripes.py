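import numpy as np
import pytest

from embryoexpress.core import NucleusRecord
from embryoexpress.errors import DegenerateGeometryError, InputError
from embryoexpress.simulate import simulate_stripe_nuclei
from embryoexpress.stripes import (StripeParams, assign_membership,
                                   bin_dv_profile, bin_nuclei, call_stripes,
                                   detect_stripes, measure_stripe)

# equivalent nucleus diameter of the stripe fixture, in normalized units
FIXTURE_NUCLEUS_DIAMETER = 2.0 * np.sqrt(30.0 / np.pi) / 500.0 * 2.0


def _nucleus(i, ap, dv, value=100.0):
    return NucleusRecord(id=i, row=dv * 100, col=ap * 100, area=30.0,
                         ap=ap, dv=dv, mean_ch2=value)


class TestBinNuclei:
    def test_single_bin_holds_everything(self):
        nuclei = [_nucleus(i, ap, 0.5) for i, ap in enumerate([0.1, 0.5, 0.9])]
        bins = bin_nuclei(nuclei, bin_width=1.0)
        assert len(bins) == 1
        assert sorted(bins[0].member_ids) == [0, 1, 2]

    def test_two_bins_partition(self):
        nuclei = [_nucleus(0, 0.1, 0.5), _nucleus(1, 0.9, 0.5)]
        bins = bin_nuclei(nuclei, bin_width=0.5)
        assert bins[0].member_ids == [0] and bins[1].member_ids == [1]

    def test_boundary_goes_to_upper_bin(self):
        bins = bin_nuclei([_nucleus(0, 0.5, 0.5)], bin_width=0.5)
        assert bins[1].member_ids == [0]

    def test_partition_property(self):
        records, _ = simulate_stripe_nuclei(n_nuclei=500, seed=1)
        bins = bin_nuclei(records, bin_width=0.07)
        ids = [i for b in bins for i in b.member_ids]
        assert sorted(ids) == [r.id for r in records]

    def test_missing_coordinates_rejected(self):
        bad = NucleusRecord(id=0, row=1, col=1, area=10.0)
        with pytest.raises(InputError):
            bin_nuclei([bad], 0.1)


class TestBinDVProfile:
    def test_constant_intensity(self):
        nuclei = [_nucleus(i, 0.05, dv, 42.0)
                  for i, dv in enumerate(np.linspace(0.1, 0.9, 30))]
        bins = bin_nuclei(nuclei, 0.1)
        prof = bin_dv_profile(bins[0], nuclei)
        finite = prof.values[~np.isnan(prof.values)]
        assert np.allclose(finite, 42.0)

    def test_bright_cluster_peaks_at_its_position(self):
        nuclei = ([_nucleus(i, 0.05, dv, 100.0)
                   for i, dv in enumerate(np.linspace(0.05, 0.95, 40))]
                  + [_nucleus(100 + i, 0.05, 0.6 + 0.005 * i, 2000.0)
                     for i in range(5)])
        bins = bin_nuclei(nuclei, 0.1)
        prof = bin_dv_profile(bins[0], nuclei, grid_step=0.01)
        peak_dv = prof.grid[np.nanargmax(prof.values)]
        assert abs(peak_dv - 0.61) <= 0.02

    def test_empty_bin_flagged(self):
        nuclei = [_nucleus(0, 0.9, 0.5)]
        bins = bin_nuclei(nuclei, 0.1)
        prof = bin_dv_profile(bins[0], nuclei)
        assert prof.empty and np.isnan(prof.values).all()


class TestDetectStripes:
    def test_single_stripe_traced_at_correct_dv(self):
        records, _ = simulate_stripe_nuclei(stripe_centers=(0.6,),
                                            stripe_width=0.1, seed=2)
        bins = bin_nuclei(records, 0.05)
        traces = detect_stripes(bins, records)
        assert len(traces) == 1
        assert all(abs(p.dv - 0.6) <= 0.02 for p in traces[0].peaks)

    def test_two_parallel_stripes_never_merged(self):
        for seed in range(3):
            records, _ = simulate_stripe_nuclei(
                stripe_centers=(0.4, 0.7), stripe_width=0.08, seed=seed)
            traces = detect_stripes(bin_nuclei(records, 0.05), records)
            assert len(traces) == 2
            mean_dvs = sorted(np.mean([p.dv for p in t.peaks])
                              for t in traces)
            assert abs(mean_dvs[0] - 0.4) < 0.02
            assert abs(mean_dvs[1] - 0.7) < 0.02

    def test_uniform_intensity_yields_no_traces(self):
        records, _ = simulate_stripe_nuclei(stripe_centers=(), seed=3)
        assert detect_stripes(bin_nuclei(records, 0.05), records) == []

    def test_too_few_bins_rejected(self):
        records, _ = simulate_stripe_nuclei(n_nuclei=100, seed=4)
        with pytest.raises(InputError):
            detect_stripes(bin_nuclei(records, 0.5), records)


class TestAssignMembership:
    @pytest.fixture()
    def traced(self):
        records, _ = simulate_stripe_nuclei(stripe_centers=(0.6,),
                                            stripe_width=0.1, seed=5)
        bins = bin_nuclei(records, 0.05)
        trace = detect_stripes(bins, records)[0]
        return records, bins, trace

    def test_nucleus_at_peak_is_member(self, traced):
        records, bins, trace = traced
        members = set(assign_membership(trace, bins, records))
        peak = trace.peaks[0]
        bin_members = bins[peak.bin_index].member_ids
        by_id = {r.id: r for r in records}
        closest = min(bin_members, key=lambda i: abs(by_id[i].dv - peak.dv))
        assert closest in members

    def test_distant_nucleus_not_member(self, traced):
        records, bins, trace = traced
        members = set(assign_membership(trace, bins, records))
        for r in records:
            if abs(r.dv - 0.6) > 0.15:       # 3 half-widths away
                assert r.id not in members

    def test_exclude_override_honoured(self, traced):
        records, bins, trace = traced
        members = assign_membership(trace, bins, records)
        dropped = members[0]
        curated = assign_membership(trace, bins, records, exclude=[dropped])
        assert dropped not in curated
        assert set(curated) == set(members) - {dropped}

    def test_membership_soundness(self, traced):
        records, bins, trace = traced
        by_id = {r.id: r for r in records}
        members = assign_membership(trace, bins, records)
        intervals = {p.bin_index: (p.half_lo, p.half_hi)
                     for p in trace.peaks}
        for b in bins:
            if b.index not in intervals:
                continue
            lo, hi = intervals[b.index]
            for nid in b.member_ids:
                if nid in members:
                    assert lo <= by_id[nid].dv <= hi


class TestMeasureStripe:
    def test_one_nucleus_thick_line_has_zero_width(self):
        nuclei = [_nucleus(i, ap, 0.5, 500.0)
                  for i, ap in enumerate(np.linspace(0.1, 0.9, 30))]
        m = measure_stripe([r.id for r in nuclei], nuclei)
        assert m.overall_width == pytest.approx(0.0, abs=1e-12)

    def test_all_members_at_one_ap_rejected(self):
        nuclei = [_nucleus(i, 0.5, dv) for i, dv in enumerate([0.4, 0.6])]
        with pytest.raises(DegenerateGeometryError):
            measure_stripe([0, 1], nuclei)

    def test_width_recovery_within_nucleus_diameter(self):
        for w in (0.05, 0.10, 0.15):
            records, truth = simulate_stripe_nuclei(
                stripe_centers=(0.6,), stripe_width=w, seed=6)
            results = call_stripes(records)
            assert len(results) == 1
            measured = results[0][1].overall_width
            assert abs(measured - w) <= FIXTURE_NUCLEUS_DIAMETER

    def test_width_monotone_in_true_width(self):
        widths = []
        for w in (0.05, 0.10, 0.15):
            records, _ = simulate_stripe_nuclei(
                stripe_centers=(0.6,), stripe_width=w, seed=7)
            widths.append(call_stripes(records)[0][1].overall_width)
        assert widths[0] < widths[1] < widths[2]

    def test_sheared_stripe_measured_perpendicular(self):
        records, _ = simulate_stripe_nuclei(
            stripe_centers=(0.5,), stripe_width=0.10,
            ap_range=(0.15, 0.85), rotation_deg=20.0, seed=8)
        result = call_stripes(records)[0][1]
        members = {r.id: r for r in records if r.id in result.member_ids}
        dv_extent = (max(r.dv for r in members.values())
                     - min(r.dv for r in members.values()))
        assert result.overall_width < dv_extent
        assert abs(result.overall_width - 0.10) <= FIXTURE_NUCLEUS_DIAMETER

    def test_rotation_equivariance(self):
        widths = {}
        for rot in (0.0, 20.0):
            records, _ = simulate_stripe_nuclei(
                stripe_centers=(0.5,), stripe_width=0.10,
                ap_range=(0.15, 0.85), rotation_deg=rot, seed=9)
            widths[rot] = call_stripes(records)[0][1].overall_width
        assert abs(widths[20.0] - widths[0.0]) / widths[0.0] < 0.05
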