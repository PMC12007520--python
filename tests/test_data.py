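"""ASL series data model: loading, differencing, decoding, NIfTI round trips."""

import numpy as np
import nibabel as nib
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import hadamard

from aslquant import ConfigurationError, DataError
from aslquant.data import (
    ASLSeries,
    ASLTimingSpec,
    hadamard_decode,
    hadamard_encode,
    load_asl,
    load_hadamard_matrix,
    subtract_pairs,
    write_map,
)


def make_timing(n_delays=6, repeats=4, **kw):
    kw.setdefault("labelling", "pcasl")
    kw.setdefault("label_duration", 1.4)
    kw.setdefault("delays", tuple(0.25 * (i + 1) for i in range(n_delays)))
    kw.setdefault("repeats_per_delay", repeats)
    return ASLTimingSpec(**kw)


class TestTimingSpec:
    def test_volume_count_multiplies(self):
        t = make_timing(6, 4)
        assert t.n_volumes == 48

    def test_rejects_unsorted_delays(self):
        with pytest.raises(ConfigurationError):
            make_timing(delays=(1.0, 0.5))

    def test_rejects_nonpositive_delays(self):
        with pytest.raises(ConfigurationError):
            make_timing(delays=(0.0, 0.5))

    def test_rejects_bad_encoding_entries(self):
        with pytest.raises(ConfigurationError, match="entries"):
            make_timing(delays=(0.3,), encoding=np.ones((4, 4)) * 2)

    def test_rejects_nonorthogonal_encoding(self):
        with pytest.raises(ConfigurationError, match="orthogonal"):
            make_timing(delays=(0.3,), encoding=np.ones((4, 4)))


class TestLoadAsl(object):
    def _write(self, tmp_path, data):
        path = tmp_path / "asl.nii.gz"
        nib.save(nib.Nifti1Image(data, np.diag([3.0, 3.0, 5.0, 1.0])), path)
        return path

    def test_valid_series_roundtrip(self, tmp_path):
        data = np.random.default_rng(0).normal(100, 1, (4, 4, 2, 48))
        series = load_asl(self._write(tmp_path, data), make_timing(6, 4))
        assert series.n_volumes == 48
        assert np.allclose(series.voxels, data)
        assert np.allclose(series.voxel_sizes, [3.0, 3.0, 5.0])

    def test_volume_count_mismatch_names_both_counts(self, tmp_path):
        data = np.zeros((4, 4, 2, 47))
        with pytest.raises(ConfigurationError, match="47.*48"):
            load_asl(self._write(tmp_path, data), make_timing(6, 4))

    def test_nan_voxel_rejected_with_index(self, tmp_path):
        data = np.full((4, 4, 2, 48), 10.0)
        data[1, 2, 0, 3] = np.nan
        with pytest.raises(DataError, match=r"\(1, 2, 0, 3\)"):
            load_asl(self._write(tmp_path, data), make_timing(6, 4))

    def test_auto_mask_excludes_background(self, tmp_path):
        data = np.zeros((4, 4, 2, 48))
        data[1:3, 1:3, :, :] = 100.0
        series = load_asl(self._write(tmp_path, data), make_timing(6, 4))
        assert series.mask[1, 1, 0]
        assert not series.mask[0, 0, 0]


class TestSubtractPairs:
    def _series(self, timing, control=100.0, label=99.0):
        nv = timing.n_volumes
        vox = np.zeros((3, 3, 2, nv))
        pairs = nv // 2
        for p in range(pairs):
            l, c = (2 * p, 2 * p + 1) if timing.label_first else (2 * p + 1, 2 * p)
            vox[..., c] = control
            vox[..., l] = label
        return ASLSeries(vox, np.eye(4), timing, np.ones((3, 3, 2), bool))

    def test_control_minus_label(self):
        series = self._series(make_timing(1, 1))
        diff = subtract_pairs(series)
        assert diff.n_volumes == 1
        assert np.allclose(diff.voxels, 1.0)

    def test_sign_convention_invariant_to_label_first(self):
        a = subtract_pairs(self._series(make_timing(1, 1, label_first=True)))
        b = subtract_pairs(self._series(make_timing(1, 1, label_first=False)))
        assert np.allclose(a.voxels, b.voxels)

    def test_48_volumes_to_24_differences(self):
        diff = subtract_pairs(self._series(make_timing(6, 4)))
        assert diff.n_volumes == 24
        delays = diff.delay_per_volume()
        assert len(delays) == 24
        # canonical delay-major grouping: 4 per delay
        assert np.allclose(delays[:4], 0.25)

    def test_orderings_agree_on_volume_content(self):
        rng = np.random.default_rng(1)
        timing_d = make_timing(3, 2, volume_order="delays_then_pairs")
        timing_p = make_timing(3, 2, volume_order="pairs_then_delays")
        # build a series whose pair at (delay d, repeat r) has diff d*10+r
        nd, nr = 3, 2
        vox_d = np.zeros((2, 2, 1, 12))
        vox_p = np.zeros((2, 2, 1, 12))
        for d in range(nd):
            for r in range(nr):
                val = d * 10 + r
                pd = (d * nr + r) * 2
                pp = (r * nd + d) * 2
                vox_d[..., pd + 1] = val
                vox_p[..., pp + 1] = val
        sd = ASLSeries(vox_d, np.eye(4), timing_d, np.ones((2, 2, 1), bool))
        sp = ASLSeries(vox_p, np.eye(4), timing_p, np.ones((2, 2, 1), bool))
        assert np.allclose(subtract_pairs(sd).voxels, subtract_pairs(sp).voxels)

    def test_odd_volume_count_rejected(self):
        vox = np.zeros((2, 2, 1, 3))
        timing = make_timing(1, 1)
        series = ASLSeries(vox, np.eye(4), timing, np.ones((2, 2, 1), bool))
        with pytest.raises(DataError, match="odd"):
            subtract_pairs(series)

    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_linearity(self, seed):
        rng = np.random.default_rng(seed)
        timing = make_timing(2, 2)
        a = rng.normal(size=(2, 2, 1, timing.n_volumes))
        b = rng.normal(size=a.shape)
        mask = np.ones((2, 2, 1), bool)
        d = lambda v: subtract_pairs(ASLSeries(v, np.eye(4), timing, mask)).voxels
        assert np.allclose(d(a + b), d(a) + d(b))


class TestHadamard:
    def _encoded_series(self, x, H, pld=0.3, tau=1.6, repeats=1):
        timing = ASLTimingSpec("pcasl", tau, (pld,), repeats_per_delay=repeats,
                               encoding=H)
        enc = hadamard_encode(x, H)
        return ASLSeries(enc, np.eye(4), timing,
                         np.ones(x.shape[:3], bool))

    @pytest.mark.parametrize("n", [4, 8])
    def test_roundtrip_exact(self, n):
        H = hadamard(n).astype(float)
        x = np.random.default_rng(n).normal(size=(3, 3, 2, n))
        dec = hadamard_decode(self._encoded_series(x, H))
        assert np.abs(dec.voxels - x).max() < 1e-10

    def test_zero_input_zero_output(self):
        H = hadamard(4).astype(float)
        dec = hadamard_decode(self._encoded_series(np.zeros((2, 2, 1, 4)), H))
        assert np.all(dec.voxels == 0)

    def test_single_subbolus_isolated(self):
        H = hadamard(8).astype(float)
        x = np.zeros((2, 2, 1, 8))
        x[..., 0] = 1.0
        dec = hadamard_decode(self._encoded_series(x, H))
        assert np.allclose(dec.voxels[..., 0], 1.0, atol=1e-10)
        assert np.abs(dec.voxels[..., 1:]).max() < 1e-10

    def test_effective_timing_convention(self):
        # equal sub-durations: LD = tau/N, PLD_k = PLD + k * tau/N
        H = hadamard(4).astype(float)
        x = np.random.default_rng(0).normal(size=(2, 2, 1, 4))
        dec = hadamard_decode(self._encoded_series(x, H, pld=0.5, tau=1.6))
        assert np.allclose(dec.eff_ld, 0.4)
        assert np.allclose(dec.eff_pld, [0.5, 0.9, 1.3, 1.7])

    def test_missing_encoding_is_config_error(self):
        series = ASLSeries(np.zeros((2, 2, 1, 4)), np.eye(4),
                           make_timing(2, 1), np.ones((2, 2, 1), bool))
        with pytest.raises(ConfigurationError, match="encoding"):
            hadamard_decode(series)

    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_decode_encode_identity_property(self, seed):
        H = hadamard(4).astype(float)
        x = np.random.default_rng(seed).normal(size=(2, 2, 1, 4))
        dec = hadamard_decode(self._encoded_series(x, H))
        assert np.allclose(dec.voxels, x, atol=1e-10)

    def test_matrix_file_roundtrip(self, tmp_path):
        H = hadamard(4)
        path = tmp_path / "enc.txt"
        np.savetxt(path, H, fmt="%d")
        assert np.array_equal(load_hadamard_matrix(path), H)


class TestWriteMap:
    def test_roundtrip_bitwise(self, tmp_path):
        vol = np.random.default_rng(0).normal(size=(4, 5, 3))
        affine = np.diag([2.0, 3.0, 5.0, 1.0])
        path = write_map(vol, affine, tmp_path / "out.nii.gz")
        img = nib.load(path)
        assert np.array_equal(np.asarray(img.dataobj, dtype=float), vol)
        assert np.allclose(img.affine, affine)

    def test_nonfinite_inside_mask_rejected(self, tmp_path):
        vol = np.zeros((3, 3, 3))
        vol[1, 1, 1] = np.nan
        with pytest.raises(DataError):
            write_map(vol, np.eye(4), tmp_path / "bad.nii.gz",
                      mask=np.ones((3, 3, 3), bool))

    def test_nonfinite_outside_mask_ok(self, tmp_path):
        vol = np.zeros((3, 3, 3))
        vol[0, 0, 0] = np.nan
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        write_map(vol, np.eye(4), tmp_path / "ok.nii.gz", mask=mask)
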