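import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from maldisort.binning import (
    BinSpec,
    BinningScheme,
    assign_bin,
    build_feature_table,
    check_jitter_compatibility,
    default_digested_scheme,
    default_intact_scheme,
    encode,
    feature_table_from_peaklists,
)
from maldisort.peaklist_io import ManifestEntry, PeakList, SpotManifest, write_peaklist


def brute_force_assign_index(mz_values, scheme):
    """Independent oracle: linear scan over every center in the scheme with
    the same range-membership, tolerance and lower-center tie rule."""
    centers = scheme.centers()
    c_start = np.concatenate([np.full(s.n_centers, s.range_start) for s in scheme.specs])
    c_end = np.concatenate([np.full(s.n_centers, s.range_end) for s in scheme.specs])
    c_width = np.concatenate([np.full(s.n_centers, s.width) for s in scheme.specs])
    out = np.empty(len(mz_values), dtype=np.int64)
    chunk = 2000
    for lo in range(0, len(mz_values), chunk):
        m = np.asarray(mz_values[lo:lo + chunk])[:, None]
        dist = np.abs(m - centers[None, :])
        eligible = (m >= c_start) & (m < c_end) & (dist <= c_width / 2.0)
        dist = np.where(eligible, dist, np.inf)
        best = np.argmin(dist, axis=1)  # first minimum = lower center on ties
        hit = np.isfinite(dist[np.arange(len(best)), best])
        out[lo:lo + chunk] = np.where(hit, best, -1)
    return out


class TestDefaultSchemes:
    def test_intact_scheme_counts_and_parameters(self):
        s = default_intact_scheme()
        assert [spec.n_centers for spec in s.specs] == [1000, 500, 900, 500, 160]
        assert s.n_bins == 3060
        assert [spec.width for spec in s.specs] == [1.25, 2.2, 3.5, 8, 35]
        assert [spec.spacing for spec in s.specs] == [1, 2, 5, 10, 50]
        first = s.specs[0].centers()
        assert first[0] == 500 and first[-1] == 1499

    def test_digested_scheme_counts_and_parameters(self):
        s = default_digested_scheme()
        assert s.n_bins == 6794
        assert all(spec.width == 0.5 for spec in s.specs)
        assert all(spec.spacing == 1 for spec in s.specs)
        first = s.specs[0].centers()
        assert first[0] == 200 and first[-1] == 998

    def test_labels_unique_and_scheme_fixed(self):
        s = default_digested_scheme()
        labels = s.labels()
        assert len(labels) == len(set(labels)) == 6794
        assert labels[0] == "200"


class TestAssignBin:
    @pytest.mark.parametrize("mz,expected", [
        (1000.2, "1000"),   # within 0.25 Da tolerance of center 1000
        (1000.4, None),     # nearest center 1000 but 0.4 > 0.25
        (998.6, None),      # seam gap between 999 and 1000 ranges
        (200.0, "200"),
        (6998.1, "6998"),
    ])
    def test_digested_examples(self, mz, expected):
        assert assign_bin(mz, default_digested_scheme()) == expected

    def test_out_of_range_returns_none(self):
        assert assign_bin(25000.0, default_intact_scheme()) is None
        assert assign_bin(100.0, default_digested_scheme()) is None

    def test_midpoint_tie_goes_to_lower_center(self):
        # intact range 1: spacing 1, width 1.25 -> windows overlap; 700.5 is
        # exactly between centers 700 and 701 and within both tolerances
        assert assign_bin(700.5, default_intact_scheme()) == "700"

    def test_nonpositive_mz_rejected(self):
        with pytest.raises(ValueError):
            assign_bin(0.0, default_intact_scheme())

    @pytest.mark.parametrize("scheme_factory,lo,hi", [
        (default_intact_scheme, 100.0, 25000.0),
        (default_digested_scheme, 100.0, 8000.0),
    ])
    def test_oracle_equivalence_random_mz(self, scheme_factory, lo, hi):
        """assign_bin agrees with a brute-force nearest-center scan on 1e5
        random m/z values."""
        scheme = scheme_factory()
        rng = np.random.default_rng(20230923)
        mz = rng.uniform(lo, hi, size=100_000)
        fast = scheme.assign_index(mz)
        slow = brute_force_assign_index(mz, scheme)
        np.testing.assert_array_equal(fast, slow)


class TestEncode:
    def test_binary_one_iff_any_peak_assigned(self):
        scheme = default_digested_scheme()
        pl = PeakList.from_peaks("s", "digested", [(1000.2, 50.0), (1000.1, 70.0)])
        row = encode(pl, scheme, "binary")
        labels = scheme.labels()
        assert row[labels.index("1000")] == 1.0
        assert row.sum() == 1.0

    def test_intensity_takes_max_within_bin(self):
        scheme = default_digested_scheme()
        pl = PeakList.from_peaks("s", "digested", [(1000.2, 50.0), (1000.1, 70.0)])
        row = encode(pl, scheme, "intensity")
        assert row[scheme.labels().index("1000")] == 70.0

    def test_intensity_sum_aggregate_option(self):
        scheme = default_digested_scheme()
        pl = PeakList.from_peaks("s", "digested", [(1000.2, 50.0), (1000.1, 70.0)])
        row = encode(pl, scheme, "intensity", aggregate="sum")
        assert row[scheme.labels().index("1000")] == 120.0

    def test_empty_peaklist_all_zero(self):
        row = encode(PeakList(spot_id="s", mode="digested"),
                     default_digested_scheme(), "binary")
        assert not row.any()

    def test_unassigned_peaks_contribute_nothing(self):
        scheme = default_digested_scheme()
        pl = PeakList.from_peaks("s", "digested", [(999.5, 10.0)])  # seam gap
        assert not encode(pl, scheme, "binary").any()

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           power=st.floats(min_value=0.5, max_value=2.0))
    def test_binary_invariant_to_monotone_intensity_rescale(self, scale, power):
        scheme = default_digested_scheme()
        rng = np.random.default_rng(5)
        mz = rng.uniform(300, 6500, size=40)
        inten = rng.uniform(1.0, 100.0, size=40)
        a = encode(PeakList(spot_id="s", mode="digested", mz=mz, intensity=inten),
                   scheme, "binary")
        b = encode(PeakList(spot_id="s", mode="digested", mz=mz,
                            intensity=scale * inten**power), scheme, "binary")
        np.testing.assert_array_equal(a, b)


class TestJitterCompatibility:
    def test_default_jitter_within_widths_where_fragments_occur(self):
        # 50 ppm jitter: every intact range and every digested range below
        # 3 kDa keeps width > 4 sigma; digested ranges >= 3 kDa do not and
        # must be flagged
        assert check_jitter_compatibility(default_intact_scheme(), 5.0e-5) == []
        warnings = check_jitter_compatibility(default_digested_scheme(), 5.0e-5)
        assert len(warnings) == 3
        assert all("width 0.5" in w for w in warnings)

    def test_wide_jitter_flags_narrow_ranges(self):
        warnings = check_jitter_compatibility(default_digested_scheme(), 2.0e-4)
        assert len(warnings) == 5  # all ranges above the first


class TestFeatureTable:
    def _manifest(self, tmp_path, n_spots=4, mode="digested"):
        tmp_path.mkdir(parents=True, exist_ok=True)
        entries = []
        rng = np.random.default_rng(0)
        for i in range(n_spots):
            pl = PeakList(spot_id=f"s{i}", mode=mode,
                          mz=rng.uniform(300, 6500, size=10),
                          intensity=rng.uniform(1, 100, size=10))
            f = tmp_path / f"s{i}.csv"
            write_peaklist(pl, f)
            entries.append(ManifestEntry(f"s{i}", f, "positive" if i % 2 else "negative",
                                         "train", mode))
        return SpotManifest(entries=tuple(entries))

    def test_shape_and_binary_values(self, tmp_path):
        m = self._manifest(tmp_path)
        t = build_feature_table(m, "train", default_digested_scheme(), "binary")
        assert t.data.shape == (4, 6794)
        assert set(np.unique(t.data.to_numpy())) <= {0.0, 1.0}

    def test_columns_fixed_by_scheme_across_disjoint_data(self, tmp_path):
        scheme = default_digested_scheme()
        m1 = self._manifest(tmp_path / "a", 2)
        m2 = self._manifest(tmp_path / "b", 3)
        t1 = build_feature_table(m1, "train", scheme, "binary")
        t2 = build_feature_table(m2, "train", scheme, "binary")
        assert list(t1.data.columns) == list(t2.data.columns)

    def test_mode_scheme_mismatch_rejected_unless_forced(self, tmp_path):
        m = self._manifest(tmp_path, mode="digested")
        with pytest.raises(ValueError, match="mismatch"):
            build_feature_table(m, "train", default_intact_scheme(), "binary",
                                mode="digested")
        t = build_feature_table(m, "train", default_intact_scheme(), "binary",
                                mode="digested", force=True)
        assert t.data.shape == (4, 3060)

    def test_all_out_of_range_spot_kept_as_zero_row(self):
        scheme = default_digested_scheme()
        pl = PeakList.from_peaks("weird", "digested", [(7500.0, 5.0)])
        t = feature_table_from_peaklists([pl], ["positive"], scheme, "binary")
        assert t.data.loc["weird"].sum() == 0

    def test_csv_round_trip(self, tmp_path):
        scheme = default_digested_scheme()
        pl = PeakList.from_peaks("s0", "digested", [(1000.1, 5.0)])
        t = feature_table_from_peaklists([pl], ["positive"], scheme, "binary")
        f = tmp_path / "table.csv"
        t.to_csv(f)
        from maldisort.binning import FeatureTable
        back = FeatureTable.from_csv(f, encoding="binary")
        assert list(back.data.columns) == list(t.data.columns)
        pd.testing.assert_series_equal(back.labels, t.labels)


class TestSchemeSerialization:
    def test_text_round_trip(self, tmp_path):
        s = default_intact_scheme()
        f = tmp_path / "scheme.txt"
        s.to_text(f)
        back = BinningScheme.from_text(f, mode="intact")
        assert back.specs == s.specs

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            BinSpec(10, 5, 1, 1)
        with pytest.raises(ValueError):
            BinningScheme(specs=(BinSpec(0, 10, 1, 1), BinSpec(5, 20, 1, 1)))
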