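"""Feature keys, band/region/epoch operations, and row assembly."""

import numpy as np
import pandas as pd
import pytest

from adspect.containers import TFPower
from adspect.errors import (
    AlignmentError,
    DegenerateInputError,
    MappingError,
    ParameterError,
)
from adspect.features import (
    FeatureTable,
    assemble_features,
    band_epoch_power,
    concat_states,
    epoch_differences,
    feature_keys,
    make_table,
    region_average,
    relative_power,
)
from adspect.schemes import (
    BAND_ORDER,
    BANDS,
    MONTAGE,
    REGIONS,
    epoch_scheme,
)


class TestSchemes:
    def test_region_map_invariants(self):
        assert len(REGIONS) == 7
        assert REGIONS["FM"] == ("FPz", "AFz", "Fz", "FP1", "FP2")
        all_electrodes = [ch for chans in REGIONS.values() for ch in chans]
        assert len(all_electrodes) == len(set(all_electrodes)) == 36
        assert set(MONTAGE) == set(all_electrodes)

    def test_band_scheme(self):
        assert list(BANDS) == ["delta", "theta", "alpha", "beta1", "beta2", "gamma"]
        edges = list(BANDS.values())
        for (lo, hi), (lo2, _) in zip(edges, edges[1:]):
            assert hi == lo2  # contiguous
        assert BANDS["delta"] == (2.0, 4.0) and BANDS["gamma"] == (30.0, 40.0)

    def test_epoch_counts(self):
        assert epoch_scheme("encoding").n_epochs == 11  # 6 base + 5 differences
        assert epoch_scheme("resting").n_epochs == 9    # 5 base + 4 differences
        assert epoch_scheme("encoding").base[0] == ("pre", (-400.0, 0.0))
        assert epoch_scheme("resting").base[0][0] == "0to4"

    def test_feature_key_counts(self):
        assert len(feature_keys("resting")) == 2268   # 7*3*2*6*9
        assert len(feature_keys("encoding")) == 2772  # 7*3*2*6*11


def uniform_tf(value, n_ch=4, fs=128.0, activity="total"):
    n = int(2.5 * fs)
    times = -500.0 + np.arange(n) * 1000.0 / fs
    freqs = np.geomspace(2, 60, 12)
    return TFPower(activity, np.full((n_ch, 12, n), float(value)), freqs, times)


class TestBandEpochPower:
    def test_uniform_power(self):
        tf = uniform_tf(3.5)
        for band in BAND_ORDER:
            np.testing.assert_allclose(band_epoch_power(tf, band, (0, 400)), 3.5)

    def test_zero_power(self):
        assert np.all(band_epoch_power(uniform_tf(0.0), "alpha", (0, 400)) == 0)

    def test_band_indicator(self):
        tf = uniform_tf(0.0)
        alpha = (tf.freqs >= 7) & (tf.freqs < 12)
        tf.power[:, alpha, :] = 2.0
        np.testing.assert_allclose(band_epoch_power(tf, "alpha", (0, 400)), 2.0)
        np.testing.assert_allclose(band_epoch_power(tf, "delta", (0, 400)), 0.0)

    def test_empty_intersection(self):
        with pytest.raises(ParameterError):
            band_epoch_power(uniform_tf(1.0), "alpha", (3000, 3400))


class TestRelativePower:
    def test_uniform_bands(self):
        rp = relative_power(np.ones((6, 3)))
        np.testing.assert_allclose(rp, 100.0 / 6.0)

    def test_single_band(self):
        ap = np.zeros((6, 1))
        ap[0] = 1.0
        np.testing.assert_allclose(relative_power(ap)[:, 0], [100, 0, 0, 0, 0, 0])

    def test_normalization_sums_to_100(self):
        rng = np.random.default_rng(0)
        rp = relative_power(rng.uniform(0.1, 5.0, size=(6, 8)))
        np.testing.assert_allclose(rp.sum(axis=0), 100.0, atol=1e-9)

    def test_all_zero_refused(self):
        with pytest.raises(DegenerateInputError):
            relative_power(np.zeros((6, 2)))


class TestRegionAverage:
    def test_constant(self):
        values = np.full(36, 4.2)
        np.testing.assert_allclose(region_average(values, MONTAGE), 4.2)

    def test_single_electrode_fm(self):
        values = np.zeros(36)
        values[MONTAGE.index("FPz")] = 7.0
        out = region_average(values, MONTAGE)
        np.testing.assert_allclose(out[0], 7.0 / 5.0)  # FM has 5 electrodes
        assert np.all(out[1:] == 0)

    def test_single_electrode_lt(self):
        values = np.zeros(36)
        values[MONTAGE.index("T7")] = 6.0
        out = region_average(values, MONTAGE)
        assert out[1] == pytest.approx(1.0)  # LT has 6 electrodes
        assert out[0] == 0 and np.all(out[2:] == 0)

    def test_missing_electrode_named(self):
        with pytest.raises(MappingError, match="FPz"):
            region_average(np.zeros(3), ("Cz", "Pz", "Oz"))

    def test_linearity(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=36), rng.normal(size=36)
        np.testing.assert_allclose(
            region_average(2 * a + b, MONTAGE),
            2 * region_average(a, MONTAGE) + region_average(b, MONTAGE),
            atol=1e-12,
        )


class TestEpochDifferences:
    def test_constant_gives_zero(self):
        assert np.all(epoch_differences(np.full((3, 6), 2.0)) == 0)

    @pytest.mark.parametrize("n_base,n_diff", [(6, 5), (5, 4)])
    def test_counts(self, n_base, n_diff):
        assert epoch_differences(np.zeros((2, n_base))).shape == (2, n_diff)

    def test_values(self):
        np.testing.assert_allclose(epoch_differences(np.array([1.0, 4.0, 2.0])), [3, -2])

    def test_single_window_refused(self):
        with pytest.raises(ParameterError):
            epoch_differences(np.ones((2, 1)))


def structured_tf_set(fs=128.0):
    """TF power depending only on (band index, base window index): an assembly oracle."""
    n = int(2.5 * fs)
    times = -500.0 + np.arange(n) * 1000.0 / fs
    freqs = np.geomspace(2, 60, 24)
    scheme = epoch_scheme("encoding")
    tfs = {}
    for ai, activity in enumerate(("total", "induced", "evoked")):
        power = np.full((36, freqs.size, n), 0.5)
        for bi, band in enumerate(BAND_ORDER):
            from adspect.schemes import band_mask

            fm = band_mask(freqs, band)
            for wi, (_, (lo, hi)) in enumerate(scheme.base):
                tm = (times >= lo) & (times < hi)
                power[np.ix_(range(36), np.flatnonzero(fm), np.flatnonzero(tm))] = (
                    (bi + 1) * (wi + 1) + 10.0 * ai
                )
        tfs[activity] = TFPower(activity, power, freqs, times)
    return tfs


class TestAssembly:
    def test_row_lengths(self):
        tfs = structured_tf_set()
        row_enc, keys_enc = assemble_features(tfs, "encoding", MONTAGE)
        assert row_enc.shape == (2772,) and len(keys_enc) == 2772

    def test_values_against_independent_computation(self):
        """Spot-check absolute and relative entries from the piecewise oracle."""
        tfs = structured_tf_set()
        row, keys = assemble_features(tfs, "encoding", MONTAGE)
        lookup = {str(k): v for k, v in zip(keys, row)}
        # total activity: AP(band b, window w) = (b+1)(w+1); window '0to4' is index 1
        for bi, band in enumerate(BAND_ORDER):
            assert lookup[f"FM.total.absolute.{band}.0to4"] == pytest.approx(
                (bi + 1) * 2
            )
        # relative power within the 0to4 cell: (b+1)*2 / sum_b (b+1)*2 * 100
        denom = sum((b + 1) * 2 for b in range(6))
        assert lookup["FM.total.relative.delta.0to4"] == pytest.approx(2 / denom * 100)
        # difference epoch: AP(4to8) - AP(0to4) = (b+1)*(3-2)
        assert lookup["PM.total.absolute.gamma.4to8-0to4"] == pytest.approx(6.0)
        # induced offset by +10 relative to total in every cell
        assert lookup["CM.induced.absolute.alpha.0to4"] == pytest.approx(3 * 2 + 10)

    def test_assembly_is_deterministic_and_ordered(self):
        tfs = structured_tf_set()
        row1, keys1 = assemble_features(tfs, "encoding", MONTAGE)
        row2, keys2 = assemble_features(tfs, "encoding", MONTAGE)
        assert keys1 == keys2 == feature_keys("encoding")
        np.testing.assert_array_equal(row1, row2)

    def test_zero_power_propagates_degenerate_error(self):
        n = 320
        times = -500.0 + np.arange(n) * 1000.0 / 128.0
        freqs = np.geomspace(2, 60, 8)
        tfs = {
            a: TFPower(a, np.zeros((36, 8, n)), freqs, times)
            for a in ("total", "induced", "evoked")
        }
        with pytest.raises(DegenerateInputError, match="total"):
            assemble_features(tfs, "encoding", MONTAGE)

    def test_missing_activity(self):
        tfs = structured_tf_set()
        del tfs["evoked"]
        with pytest.raises(ParameterError, match="evoked"):
            assemble_features(tfs, "encoding", MONTAGE)


class TestTables:
    def _table(self, state, n_feat=4, ids=("s1", "s2")):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.normal(size=(len(ids), n_feat)),
            index=list(ids),
            columns=[f"{state}.k{i}" for i in range(n_feat)],
        )
        labels = pd.Series(["SCD", "AD"][: len(ids)], index=list(ids))
        return FeatureTable(values, labels, state)

    def test_concat_three_encoding_sessions(self, tiny_tables):
        enc = concat_states([tiny_tables["enc1"], tiny_tables["enc2"]], "encoding")
        assert enc.n_features == 2 * 2772

    def test_concat_identity(self):
        t = self._table("enc1")
        assert concat_states([t]) is t

    def test_concat_subject_mismatch(self):
        with pytest.raises(AlignmentError):
            concat_states([self._table("enc1"), self._table("enc2", ids=("s2", "s1"))])

    def test_csv_round_trip(self, tmp_path):
        t = self._table("resting")
        path = tmp_path / "resting.csv"
        t.to_csv(path)
        back = FeatureTable.from_csv(path, "resting")
        pd.testing.assert_frame_equal(back.values, t.values, check_names=False)
        assert list(back.labels) == list(t.labels)

    def test_make_table_column_names(self, tiny_tables):
        table = tiny_tables["resting"]
        assert table.n_features == 2268
        assert table.values.columns[0].startswith("resting.FM.total.absolute.delta.")
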