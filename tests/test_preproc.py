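"""Preprocessing chain: separation, steady-state replacement, upsampling,
alignment, dynamic division, run averaging and tSNR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from vasomap.acquire import InterleavedSeries
from vasomap.preproc import (
    ContrastSeries,
    align_nulled,
    average_runs,
    boco_correct,
    preprocess_interleaved,
    replace_nonsteady,
    separate_contrasts,
    temporal_upsample,
    tsnr_map,
)


def _series(data, tag="nulled", dt=2.61, log=("separate",)):
    return ContrastSeries(data=np.asarray(data, dtype=float), tag=tag, dt=dt, log=log)


def _interleaved(n=12, shape=(3, 3, 2), seed=0):
    rng = np.random.default_rng(seed)
    return InterleavedSeries(
        nulled=100 + rng.standard_normal(shape + (n,)),
        not_nulled=100 + rng.standard_normal(shape + (n,)),
        tr_pair=2.61,
    )


class TestSeparate:
    def test_counts_and_tags(self):
        nulled, not_nulled = separate_contrasts(_interleaved(n=369))
        assert nulled.n_volumes == not_nulled.n_volumes == 369
        assert (nulled.tag, not_nulled.tag) == ("nulled", "not_nulled")
        assert nulled.log == ("separate",)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            separate_contrasts(
                InterleavedSeries(
                    nulled=np.zeros((2, 2, 2, 0)),
                    not_nulled=np.zeros((2, 2, 2, 0)),
                    tr_pair=2.61,
                )
            )

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            separate_contrasts(
                InterleavedSeries(
                    nulled=np.zeros((2, 2, 2, 5)),
                    not_nulled=np.zeros((2, 2, 3, 5)),
                    tr_pair=2.61,
                )
            )


class TestReplaceNonsteady:
    def test_literal_rule(self):
        data = np.arange(6.0).reshape(1, 1, 1, 6)  # [a b c d e f]
        out = replace_nonsteady(_series(data), n_replace=4)
        assert list(out.data[0, 0, 0]) == [4, 4, 4, 4, 4, 5]

    def test_zero_is_identity(self):
        data = np.arange(6.0).reshape(1, 1, 1, 6)
        out = replace_nonsteady(_series(data), n_replace=0)
        assert np.array_equal(out.data, data)

    def test_variance_of_replaced_prefix_is_zero(self, rng):
        data = rng.standard_normal((2, 2, 2, 10))
        out = replace_nonsteady(_series(data), n_replace=4)
        assert np.all(out.data[..., :4].std(axis=-1) == 0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            replace_nonsteady(_series(np.zeros((1, 1, 1, 4))), n_replace=4)


class TestTemporalUpsample:
    def test_doubles_length_and_halves_dt(self, rng):
        s = _series(rng.standard_normal((2, 2, 2, 369)))
        out = temporal_upsample(s, 2)
        assert out.n_volumes == 738
        assert out.dt == pytest.approx(s.dt / 2)

    def test_constant_preserved(self):
        s = _series(np.full((1, 1, 1, 20), 7.0))
        for kind in ("cubic", "linear"):
            out = temporal_upsample(s, 2, kind=kind)
            assert np.allclose(out.data, 7.0)

    def test_linear_ramp_midpoints_exact(self):
        ramp = np.arange(20.0).reshape(1, 1, 1, 20)
        for kind in ("cubic", "linear"):
            out = temporal_upsample(_series(ramp), 2, kind=kind)
            # Sample j sits at original index j/2: values are j/2 (end held).
            expected = np.minimum(np.arange(40) / 2.0, 19.0)
            assert np.allclose(out.data[0, 0, 0], expected, atol=1e-9)

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            temporal_upsample(_series(np.zeros((1, 1, 1, 8))), 0)


class TestAlignNulled:
    def test_literal_rule_and_length(self):
        data = np.arange(3.0).reshape(1, 1, 1, 3)
        s = _series(data, log=("separate", "temporal_upsample[2]"))
        out = align_nulled(s)
        assert list(out.data[0, 0, 0]) == [0, 0, 1]
        assert out.n_volumes == 3

    def test_not_idempotent_guarded_by_log(self):
        s = _series(np.zeros((1, 1, 1, 4)), log=("separate", "temporal_upsample[2]"))
        out = align_nulled(s)
        with pytest.raises(ValueError, match="already applied"):
            align_nulled(out)

    def test_requires_upsampled_nulled(self):
        with pytest.raises(ValueError, match="upsampled"):
            align_nulled(_series(np.zeros((1, 1, 1, 4))))
        with pytest.raises(ValueError, match="nulled"):
            align_nulled(
                _series(np.zeros((1, 1, 1, 4)), tag="not_nulled",
                        log=("separate", "temporal_upsample[2]"))
            )


class TestBoco:
    @settings(max_examples=30, deadline=None)
    @given(
        b=arrays(np.float64, 16, elements=st.floats(50.0, 150.0)),
        scale=st.floats(0.5, 1.5),
    )
    def test_exact_cancellation_of_shared_dynamics(self, b, scale):
        """nulled = scale * b(t) divided by b(t) is constant scale."""
        nulled = _series((scale * b).reshape(1, 1, 1, -1))
        not_nulled = _series(b.reshape(1, 1, 1, -1), tag="not_nulled")
        out = boco_correct(nulled, not_nulled)
        assert np.allclose(out.data, scale, rtol=1e-12)

    def test_identity_ratio(self, rng):
        b = 100 + rng.standard_normal((2, 2, 2, 10))
        out = boco_correct(_series(b), _series(b.copy(), tag="not_nulled"))
        assert np.allclose(out.data, 1.0)
        assert out.tag == "vaso_corrected"

    def test_guard_reuses_previous_ratio(self):
        nulled = _series(np.full((1, 1, 1, 4), 90.0))
        denom = np.array([100.0, 100.0, 1.0, 100.0]).reshape(1, 1, 1, 4)
        out = boco_correct(nulled, _series(denom, tag="not_nulled"))
        assert out.data[0, 0, 0, 2] == out.data[0, 0, 0, 1] == pytest.approx(0.9)

    def test_all_zero_denominator_flagged(self):
        nulled = _series(np.ones((1, 2, 1, 3)))
        denom = np.ones((1, 2, 1, 3))
        denom[0, 1] = 0.0
        out = boco_correct(nulled, _series(denom, tag="not_nulled"))
        assert out.qc["bad_denominator"][0, 1, 0]
        assert not out.qc["bad_denominator"][0, 0, 0]
        assert np.all(out.data[0, 1, 0] == 1.0)  # previous-value fill from 1

    def test_upsampled_but_unaligned_rejected(self):
        log = ("separate", "temporal_upsample[2]")
        nulled = _series(np.ones((1, 1, 1, 4)), log=log)
        not_nulled = _series(np.ones((1, 1, 1, 4)), tag="not_nulled", log=log)
        with pytest.raises(ValueError, match="aligned"):
            boco_correct(nulled, not_nulled)

    def test_inconsistent_histories_rejected(self):
        nulled = _series(np.ones((1, 1, 1, 4)), log=("separate", "replace_nonsteady[4]"))
        not_nulled = _series(np.ones((1, 1, 1, 4)), tag="not_nulled", log=("separate",))
        with pytest.raises(ValueError, match="different paths"):
            boco_correct(nulled, not_nulled)


class TestAverageRuns:
    def test_identical_runs_unchanged(self, rng):
        data = rng.standard_normal((2, 2, 2, 8))
        out = average_runs([_series(data), _series(data.copy())])
        assert np.allclose(out.data, data)

    def test_single_run_identity(self, rng):
        data = rng.standard_normal((2, 2, 2, 8))
        assert np.array_equal(average_runs([_series(data)]).data, data)

    def test_noise_reduction_sqrt2(self, rng):
        """Averaging two i.i.d.-noise runs shrinks the noise sd by sqrt(2)."""
        a = rng.standard_normal((8, 8, 8, 50))
        b = rng.standard_normal((8, 8, 8, 50))
        out = average_runs([_series(a), _series(b)])
        ratio = a.std() / out.data.std()
        assert ratio == pytest.approx(np.sqrt(2), rel=0.1)

    def test_mixed_tags_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            average_runs(
                [_series(np.zeros((1, 1, 1, 4))),
                 _series(np.zeros((1, 1, 1, 4)), tag="not_nulled")]
            )


class TestTsnr:
    def test_definition(self):
        data = np.tile([96.0, 104.0], 100).reshape(1, 1, 1, 200)
        tsnr = tsnr_map(_series(data))
        sd = data.std(ddof=1)
        assert tsnr[0, 0, 0] == pytest.approx(100.0 / sd)
        assert tsnr[0, 0, 0] == pytest.approx(25.0, rel=0.01)

    def test_constant_series_gets_sentinel(self):
        tsnr = tsnr_map(_series(np.full((1, 1, 1, 5), 3.0)))
        assert np.isinf(tsnr[0, 0, 0])

    def test_too_short(self):
        with pytest.raises(ValueError):
            tsnr_map(_series(np.zeros((1, 1, 1, 1))))


class TestChainOrder:
    def test_full_chain_step_log(self):
        vaso, bold = preprocess_interleaved(_interleaved(n=12))
        assert vaso.log == (
            "separate",
            "replace_nonsteady[4]",
            "temporal_upsample[2]",
            "align_nulled",
            "boco",
        )
        assert vaso.n_volumes == bold.n_volumes == 24
        assert bold.tag == "bold"

    def test_out_of_order_rejected(self):
        nulled, _ = separate_contrasts(_interleaved(n=12))
        up = temporal_upsample(nulled, 2)
        with pytest.raises(ValueError, match="precede"):
            replace_nonsteady(up)
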