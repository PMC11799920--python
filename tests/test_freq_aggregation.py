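"""FFT decomposition, masks, reciprocal attention, and round aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from freqfed import (
    aggregate_low,
    aggregate_round,
    attention_weights,
    build_unet,
    decompose,
    fft2_centered,
    ifft2_centered,
    invert_reshape,
    make_mask,
    r_schedule,
    recombine_and_invert,
    reshape_to_2d,
    split_weights,
    uniform_attention,
)


# -- reshape ---------------------------------------------------------------


def test_reshape_bookkeeping():
    """(out=8, in=4, 3, 3) kernel -> 12 x 24 matrix with record (4, 3, 3, 8)."""
    w = np.arange(8 * 4 * 3 * 3, dtype=float).reshape(8, 4, 3, 3)
    mat, rec = reshape_to_2d(w)
    assert mat.shape == (12, 24)
    assert rec.canonical_shape == (4, 3, 3, 8)
    # index bookkeeping oracle: element (o, i, y, x) lands at
    # row i*3 + y, column x*8 + o of the canonical (in, kH, kW, out) layout
    for o, i, y, x in [(0, 0, 0, 0), (7, 3, 2, 2), (5, 1, 0, 2), (2, 2, 1, 1)]:
        assert mat[i * 3 + y, x * 8 + o] == w[o, i, y, x]


def test_reshape_degenerate_1x1_kernels():
    w = np.random.default_rng(0).random((5, 2, 1, 1))
    mat, rec = reshape_to_2d(w)
    assert mat.shape == (2, 5)
    np.testing.assert_array_equal(invert_reshape(mat, rec), w)


@settings(deadline=None, derandomize=True)
@given(
    cout=st.integers(1, 6), cin=st.integers(1, 6),
    kh=st.integers(1, 4), kw=st.integers(1, 4),
)
def test_reshape_roundtrip_property(cout, cin, kh, kw):
    w = np.random.default_rng(cout * 100 + cin * 10 + kh + kw).random((cout, cin, kh, kw))
    mat, rec = reshape_to_2d(w)
    assert mat.shape == (cin * kh, kw * cout)
    np.testing.assert_array_equal(invert_reshape(mat, rec), w)


def test_reshape_rejects_non_4d():
    with pytest.raises(ValueError):
        reshape_to_2d(np.zeros((3, 3)))


# -- centered FFT ----------------------------------------------------------


def test_fft_constant_matrix_is_dc_only():
    z = fft2_centered(np.full((4, 4), 3.0))
    expected = np.zeros((4, 4), dtype=complex)
    expected[2, 2] = 16 * 3.0  # DC at the grid center
    np.testing.assert_allclose(z, expected, atol=1e-12)


def test_fft_1x1_identity():
    np.testing.assert_allclose(fft2_centered(np.array([[2.5]])), [[2.5]])


def test_fft_matches_brute_force_dft(rng):
    """Direct O(N^4) double-sum DFT oracle, centered by explicit index shift."""
    for h, w in [(3, 3), (4, 5), (2, 6)]:
        m = rng.standard_normal((h, w))
        z = fft2_centered(m)
        oracle = np.zeros((h, w), dtype=complex)
        for u in range(h):
            for v in range(w):
                acc = 0.0j
                fu, fv = u - h // 2, v - w // 2  # centered frequencies
                for a in range(h):
                    for b in range(w):
                        acc += m[a, b] * np.exp(-2j * np.pi * (fu * a / h + fv * b / w))
                oracle[u, v] = acc
        np.testing.assert_allclose(z, oracle, atol=1e-10)


def test_fft_rejects_nonfinite():
    with pytest.raises(ValueError):
        fft2_centered(np.array([[1.0, np.nan], [0.0, 0.0]]))


def test_fft_roundtrip_random(rng):
    for shape in [(1, 1), (5, 3), (16, 16), (64, 64)]:
        m = rng.standard_normal(shape)
        back = ifft2_centered(fft2_centered(m))
        assert np.abs(back - m).max() <= 1e-10 * max(1.0, np.abs(m).max())


# -- mask ------------------------------------------------------------------


def test_mask_r0_is_dc_only():
    mask = make_mask(8, 8, 0.0)
    assert mask.sum() == 1
    assert mask[4, 4]  # DC sits at the center


def test_mask_r1_is_all_true():
    assert make_mask(8, 6, 1.0).all()


def test_mask_r_half_8x8_has_25_cells():
    mask = make_mask(8, 8, 0.5)
    assert int(mask.sum()) == 25  # |u| <= 2 and |v| <= 2


def test_mask_monotone_and_symmetric():
    prev = None
    for r in (0.0, 0.25, 0.5, 1.0):
        mask = make_mask(8, 8, r)
        if prev is not None:
            assert (prev <= mask).all()  # nesting
        prev = mask
    for r in (0.0, 0.25, 0.5, 0.9):
        mask = make_mask(7, 9, r)
        np.testing.assert_array_equal(mask, mask[::-1, ::-1])


def test_mask_rejects_bad_r():
    with pytest.raises(ValueError):
        make_mask(8, 8, 1.5)
    with pytest.raises(ValueError):
        make_mask(8, 8, -0.1)


# -- decompose / recombine -------------------------------------------------


def test_decompose_completeness(rng):
    z = fft2_centered(rng.standard_normal((8, 8)))
    for r in (0.0, 0.3, 0.7, 1.0):
        low, high = decompose(z, make_mask(8, 8, r))
        np.testing.assert_array_equal(low + high, z)
    all_true = np.ones((8, 8), dtype=bool)
    _, high = decompose(z, all_true)
    assert not high.any()
    low, _ = decompose(z, ~all_true)
    assert not low.any()


def test_decompose_dim_mismatch():
    with pytest.raises(ValueError):
        decompose(np.zeros((4, 4), dtype=complex), np.ones((3, 3), dtype=bool))


def test_recombine_own_low_part_is_identity(rng):
    w = rng.standard_normal((6, 3, 3, 3))
    mat, rec = reshape_to_2d(w)
    z = fft2_centered(mat)
    mask = make_mask(*mat.shape, 0.4)
    low, high = decompose(z, mask)
    out = recombine_and_invert(high, z[mask], mask, rec)
    np.testing.assert_allclose(out, w, atol=1e-10)


def test_recombine_real_output_for_hermitian_inputs(rng):
    for _ in range(5):
        m = rng.standard_normal((10, 12))
        z = fft2_centered(m)
        mask = make_mask(10, 12, 0.5)
        _, high = decompose(z, mask)
        out = recombine_and_invert(high, z[mask] * 0.5, mask)
        assert out.dtype == np.float64  # imaginary residue checked and dropped


# -- attention -------------------------------------------------------------


def test_attention_singleton():
    np.testing.assert_allclose(attention_weights(np.array([[1.0, 2.0, 3.0]])), [[1.0]])


def test_attention_identical_rows_symmetric():
    z = np.tile(np.array([1.0, -2.0, 0.5]), (2, 1))
    np.testing.assert_allclose(attention_weights(z), [[0.5, 0.5], [0.5, 0.5]], atol=1e-15)


def test_attention_matches_brute_force_oracle(rng):
    z = rng.standard_normal((3, 7))
    a = attention_weights(z)
    # brute-force: explicit Gram, elementwise reciprocal, row softmax
    g = np.array([[np.dot(z[i], z[j]) for j in range(3)] for i in range(3)])
    recip = 1.0 / g  # no |G| < eps entries for generic random inputs
    oracle = np.exp(recip) / np.exp(recip).sum(axis=1, keepdims=True)
    np.testing.assert_allclose(a, oracle, rtol=1e-12)


def test_attention_rows_stochastic_positive(rng):
    a = attention_weights(rng.standard_normal((5, 9)))
    np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-12)
    assert (a > 0).all() and (a < 1).all()


def test_attention_zero_gram_guard():
    # orthogonal rows: off-diagonal Gram entries are exactly 0 -> guarded as +eps
    z = np.array([[1.0, 0.0], [0.0, 1.0]])
    a = attention_weights(z)
    np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-12)
    assert np.isfinite(a).all()


# -- aggregate_low ---------------------------------------------------------


def test_aggregate_low_single_client(rng):
    z = rng.standard_normal((1, 6))
    np.testing.assert_allclose(aggregate_low(z, np.array([[1.0]])), z[0])


def test_aggregate_low_identical_clients(rng):
    row = rng.standard_normal(6)
    z = np.tile(row, (4, 1))
    np.testing.assert_allclose(aggregate_low(z, attention_weights(z)), row, atol=1e-12)


def test_aggregate_low_uniform_equals_plain_mean(rng):
    z = rng.standard_normal((4, 6))
    np.testing.assert_allclose(
        aggregate_low(z, uniform_attention(4)), z.mean(axis=0), atol=1e-12
    )


def test_aggregate_low_dim_mismatch(rng):
    with pytest.raises(ValueError):
        aggregate_low(rng.standard_normal((3, 5)), uniform_attention(2))


# -- aggregate_round -------------------------------------------------------


def _shared_maps(n_clients, seed0=20):
    maps = []
    for k in range(n_clients):
        model = build_unet(1, 3, depth=1, base_width=4, seed=seed0 + k)
        _, w_r = split_weights(model, "paf_fed")
        maps.append(w_r)
    return maps


def test_aggregate_round_single_client_is_identity():
    (wr,) = _shared_maps(1)
    (out,) = aggregate_round([wr], r=0.5, attention_mode="reciprocal")
    for name in wr:
        np.testing.assert_allclose(out[name], wr[name], atol=1e-8)


def test_aggregate_round_identical_clients_is_identity():
    wr = _shared_maps(1)[0]
    outs = aggregate_round([wr, dict(wr), dict(wr)], r=0.5, attention_mode="reciprocal")
    for out in outs:
        for name in wr:
            np.testing.assert_allclose(out[name], wr[name], atol=1e-8)


def test_aggregate_round_fedavg_limit():
    """r=1 with uniform attention reduces to the element-wise mean."""
    maps = _shared_maps(3)
    outs = aggregate_round(maps, r=1.0, attention_mode="uniform")
    for name in maps[0]:
        mean = np.mean([m[name] for m in maps], axis=0)
        for out in outs:
            np.testing.assert_allclose(out[name], mean, atol=1e-8)


def test_aggregate_round_permutation_equivariance():
    maps = _shared_maps(4)
    outs = aggregate_round(maps, r=0.5, attention_mode="reciprocal")
    perm = [2, 0, 3, 1]
    outs_p = aggregate_round([maps[i] for i in perm], r=0.5, attention_mode="reciprocal")
    for dst, src in enumerate(perm):
        for name in maps[0]:
            np.testing.assert_allclose(outs_p[dst][name], outs[src][name], atol=1e-8)


def test_aggregate_round_vector_tensors_use_plain_mean():
    maps = _shared_maps(3)
    outs = aggregate_round(maps, r=0.0, attention_mode="reciprocal")
    name = next(n for n in maps[0] if maps[0][n].ndim == 1)
    mean = np.mean([m[name] for m in maps], axis=0)
    for out in outs:
        np.testing.assert_allclose(out[name], mean, atol=1e-12)


def test_aggregate_round_name_mismatch_raises():
    a, b = _shared_maps(2)
    del b[next(iter(b))]
    with pytest.raises(ValueError):
        aggregate_round([a, b], r=0.5)


# -- r schedule ------------------------------------------------------------


def test_r_schedule_adaptive_endpoints():
    assert r_schedule(0, 10, "adaptive", r0=0.0, r1=0.5) == 0.0
    assert r_schedule(10, 10, "adaptive", r0=0.0, r1=0.5) == 0.5
    assert r_schedule(5, 10, "adaptive", r0=0.0, r1=0.5) == pytest.approx(0.25)


def test_r_schedule_fixed():
    assert r_schedule(3, 10, "fixed", r_fixed=0.25) == 0.25


def test_r_schedule_rejects_bad_rounds():
    with pytest.raises(ValueError):
        r_schedule(11, 10, "adaptive")
    with pytest.raises(ValueError):
        r_schedule(-1, 10, "adaptive")
    with pytest.raises(ValueError):
        r_schedule(0, 0, "adaptive")
    with pytest.raises(ValueError):
        r_schedule(0, 10, "sometimes")
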