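"""Fourier-Transform-Attention (FTA) aggregation of client weight tensors.

At each communication round the server collects the shared weight tensors
W_R from every client and, per tensor, (1) reshapes a conv kernel
W in R^{cin x d1 x d2 x cout} into a 2D matrix of size (cin*d1) x (d2*cout),
(2) takes a centered 2D FFT, (3) splits the spectrum into a low-frequency
part z^l (inside an axis-wise rectangle of fractional half-extent r around
the DC coefficient) and a high-frequency part z^h, (4) weights the clients'
low parts with a reciprocal self-attention

    A = softmax_rows( 1 / (Z_l Z_l^T) ),   z_hat = A Z_l,

(5) averages z_hat over clients into a single low-frequency component shared
by everyone, and (6) re-inserts each client's own high-frequency part before
inverting the FFT.  Clients whose low-frequency components are *dissimilar*
from the rest receive larger attention weights (the reciprocal flips the
Gram similarities), which damps the pull of fast-converging clients on the
aggregate.

The threshold r may be fixed or grow linearly over rounds,
r(t) = r0 + (r1 - r0) * t / T, so that early rounds share almost nothing and
later rounds share a wider low-frequency band.

Tensors with fewer than two axes (BN vectors, biases) carry no meaningful
2D frequency structure and are aggregated by a plain element-wise mean.
All arithmetic is double precision; results are cast back to the input
dtype at the end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

#: guard against division blow-up in the reciprocal Gram matrix
RECIPROCAL_EPS = 1e-8

#: maximum tolerated imaginary residue (relative to the real part's scale)
#: after the inverse transform; anything larger signals a broken-symmetry mask
IMAG_TOL = 1e-8


@dataclass(frozen=True)
class ShapeRecord:
    """Bookkeeping to invert the 4D -> 2D reshape exactly.

    ``canonical_shape`` is (cin, d1, d2, cout) after permuting the common
    (out, in, kH, kW) layout; the matrix is (cin*d1) x (d2*cout).
    """

    canonical_shape: Tuple[int, int, int, int]

    @property
    def matrix_shape(self) -> Tuple[int, int]:
        cin, d1, d2, cout = self.canonical_shape
        return (cin * d1, d2 * cout)


def reshape_to_2d(weight: np.ndarray) -> Tuple[np.ndarray, ShapeRecord]:
    """Reshape a (out, in, kH, kW) conv kernel to a (in*kH) x (kW*out) matrix."""
    weight = np.asarray(weight)
    if weight.ndim != 4:
        raise ValueError(f"reshape_to_2d expects a 4D tensor, got ndim={weight.ndim}")
    cout, cin, d1, d2 = weight.shape
    canonical = weight.transpose(1, 2, 3, 0)  # (cin, d1, d2, cout)
    record = ShapeRecord((cin, d1, d2, cout))
    return canonical.reshape(record.matrix_shape), record


def invert_reshape(matrix: np.ndarray, record: ShapeRecord) -> np.ndarray:
    """Exact inverse of :func:`reshape_to_2d`."""
    cin, d1, d2, cout = record.canonical_shape
    return matrix.reshape(cin, d1, d2, cout).transpose(3, 0, 1, 2)


def fft2_centered(matrix: np.ndarray) -> np.ndarray:
    """2D DFT with the zero-frequency coefficient shifted to the grid center."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("non-finite entries in matrix passed to fft2_centered")
    return np.fft.fftshift(np.fft.fft2(matrix))


def ifft2_centered(spectrum: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2_centered` (complex output; caller handles residue)."""
    return np.fft.ifft2(np.fft.ifftshift(spectrum))


def centered_frequencies(n: int) -> np.ndarray:
    """Integer frequency coordinates after the center shift (0 at index n//2)."""
    return np.arange(n) - n // 2


def make_mask(h: int, w: int, r: float) -> np.ndarray:
    """Boolean low-frequency mask: |u| <= r*H/2 and |v| <= r*W/2, centered.

    Monotone in r, symmetric under (u, v) -> (-u, -v) for r < 1, and always
    true at the DC coefficient (0, 0).
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"frequency threshold r must be in [0, 1], got {r}")
    u = np.abs(centered_frequencies(h))
    v = np.abs(centered_frequencies(w))
    # tiny slack so exact integer thresholds (e.g. r*H/2 == 2.0) are inclusive
    return (u[:, None] <= r * h / 2 + 1e-12) & (v[None, :] <= r * w / 2 + 1e-12)


def decompose(spectrum: np.ndarray, mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Split a centered spectrum into (low, high) parts; low + high == spectrum."""
    spectrum = np.asarray(spectrum)
    if spectrum.shape != mask.shape:
        raise ValueError(f"mask shape {mask.shape} != spectrum shape {spectrum.shape}")
    low = np.where(mask, spectrum, 0.0)
    high = np.where(mask, 0.0, spectrum)
    return low, high


def _embed_real(z: np.ndarray) -> np.ndarray:
    """Complex vector -> real vector by concatenating real and imaginary parts."""
    return np.concatenate([z.real, z.imag])


def attention_weights(z_rows: np.ndarray) -> np.ndarray:
    """Row-stochastic reciprocal-Gram attention matrix over K clients.

    ``z_rows`` is K x m, one real-embedded low-frequency vector per client.
    G = Z Z^T; entries with |G| < eps are replaced by eps * sign(G) (sign of
    zero taken as +1); A = row-wise softmax of 1/G.
    """
    z_rows = np.asarray(z_rows, dtype=np.float64)
    if z_rows.ndim != 2:
        raise ValueError("attention_weights expects a K x m matrix of client rows")
    gram = z_rows @ z_rows.T
    sign = np.where(gram >= 0, 1.0, -1.0)
    guarded = np.where(np.abs(gram) < RECIPROCAL_EPS, RECIPROCAL_EPS * sign, gram)
    recip = 1.0 / guarded
    shifted = recip - recip.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    return expd / expd.sum(axis=1, keepdims=True)


def uniform_attention(k: int) -> np.ndarray:
    return np.full((k, k), 1.0 / k)


def aggregate_low(z_rows: np.ndarray, attention: np.ndarray) -> np.ndarray:
    """Attention-weighted then client-averaged low-frequency component.

    z_hat_i = sum_u A_iu z_u ; the returned vector is (1/K) sum_i z_hat_i and
    is shared by all clients.
    """
    z_rows = np.asarray(z_rows, dtype=np.float64)
    attention = np.asarray(attention, dtype=np.float64)
    k = z_rows.shape[0]
    if attention.shape != (k, k):
        raise ValueError(f"attention shape {attention.shape} incompatible with K={k}")
    z_hat = attention @ z_rows
    return z_hat.mean(axis=0)


def recombine_and_invert(z_high: np.ndarray, z_low_bar: np.ndarray, mask: np.ndarray,
                         record: ShapeRecord | None = None) -> np.ndarray:
    """Fuse the aggregated low part with a client's high part and invert.

    ``z_high`` is the client's full centered spectrum with zeros on the mask
    support; ``z_low_bar`` holds the aggregated complex coefficients at the
    mask's True positions (row-major order).  The imaginary residue of the
    inverse transform must be negligible (Hermitian-symmetric spectra of
    real-sourced weights guarantee this) and is discarded.
    """
    z_high = np.asarray(z_high, dtype=np.complex128)
    if z_high.shape != mask.shape:
        raise ValueError("z_high / mask shape mismatch")
    spectrum = z_high.copy()
    spectrum[mask] = np.asarray(z_low_bar, dtype=np.complex128)
    out = ifft2_centered(spectrum)
    scale = max(1.0, np.abs(out.real).max())
    if np.abs(out.imag).max() > IMAG_TOL * scale:
        raise ArithmeticError(
            "imaginary residue above tolerance after inverse FFT "
            "(broken-symmetry frequency mask?)"
        )
    matrix = out.real
    return invert_reshape(matrix, record) if record is not None else matrix


def _aggregate_tensor(stack: List[np.ndarray], r: float, attention_mode: str) -> List[np.ndarray]:
    """FTA aggregation of one named tensor across K clients."""
    k = len(stack)
    if stack[0].ndim == 4:
        mats, records = zip(*(reshape_to_2d(w) for w in stack))
    else:  # 2D dense tensor: transform directly
        mats, records = tuple(np.asarray(w, dtype=np.float64) for w in stack), (None,) * k
    spectra = [fft2_centered(m) for m in mats]
    h, w = mats[0].shape
    mask = make_mask(h, w, r)
    lows_highs = [decompose(z, mask) for z in spectra]
    z_rows = np.stack([_embed_real(low[mask]) for low, _ in lows_highs])
    if attention_mode == "reciprocal":
        att = attention_weights(z_rows)
    elif attention_mode == "uniform":
        att = uniform_attention(k)
    else:
        raise ValueError(f"unknown attention_mode {attention_mode!r}")
    bar = aggregate_low(z_rows, att)
    m = mask.sum()
    z_low_bar = bar[:m] + 1j * bar[m:]
    return [
        recombine_and_invert(high, z_low_bar, mask, rec)
        for (_, high), rec in zip(lows_highs, records)
    ]


def aggregate_round(client_wrs: Sequence[Mapping[str, np.ndarray]], r: float,
                    attention_mode: str = "reciprocal") -> List[Dict[str, np.ndarray]]:
    """Aggregate the clients' shared tensor maps for one server round.

    4D conv kernels and 2D matrices go through the FTA pipeline per tensor;
    vectors and scalars (BN gamma/beta, biases) are element-wise averaged.
    Returns one aggregated map per client, in input order.
    """
    if len(client_wrs) == 0:
        raise ValueError("aggregate_round needs at least one client")
    names = set(client_wrs[0])
    for i, wr in enumerate(client_wrs[1:], start=1):
        if set(wr) != names:
            raise ValueError(f"client {i} tensor names differ from client 0")
    k = len(client_wrs)
    out: List[Dict[str, np.ndarray]] = [{} for _ in range(k)]
    for name in client_wrs[0]:
        stack = [np.asarray(wr[name]) for wr in client_wrs]
        shapes = {a.shape for a in stack}
        if len(shapes) != 1:
            raise ValueError(f"shape mismatch across clients for tensor {name!r}")
        dtype = stack[0].dtype
        if stack[0].ndim in (2, 4):
            aggregated = _aggregate_tensor(stack, r, attention_mode)
        else:
            mean = np.mean(np.stack([a.astype(np.float64) for a in stack]), axis=0)
            aggregated = [mean.copy() for _ in range(k)]
        for i in range(k):
            out[i][name] = aggregated[i].astype(dtype, copy=False)
    return out


def r_schedule(t: int, total_rounds: int, mode: str = "adaptive", r_fixed: float = 0.25,
               r0: float = 0.0, r1: float = 0.5) -> float:
    """Low-frequency threshold for round t: fixed, or r0 + (r1-r0) * t / T."""
    if total_rounds < 1:
        raise ValueError("total_rounds must be >= 1")
    if not 0 <= t <= total_rounds:
        raise ValueError(f"round index {t} outside [0, {total_rounds}]")
    if mode == "fixed":
        return float(r_fixed)
    if mode == "adaptive":
        return float(r0 + (r1 - r0) * t / total_rounds)
    raise ValueError(f"unknown r-schedule mode {mode!r}; use 'fixed' or 'adaptive'")
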