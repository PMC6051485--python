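"""Dilated convolution primitives on plain numpy arrays.

Feature maps are laid out as ``(channels, *spatial)`` and weights as
``(out_channels, in_channels, *kernel)``.  Stride is always 1 and padding is
symmetric zero-padding sized so the spatial shape is preserved, which
requires an odd number of taps on every kernel axis.  Forward passes go
through an im2col gather followed by a single BLAS matmul; the input
gradient of a stride-1 same-padded convolution is itself a convolution with
the spatially flipped, channel-transposed kernel, so the backward pass
reuses the same machinery.
"""

from __future__ import annotations

import numpy as np


def same_padding(kernel: tuple[int, ...], dilation: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(((k - 1) * d) // 2 for k, d in zip(kernel, dilation))


def im2col(x: np.ndarray, kernel: tuple[int, ...], dilation: tuple[int, ...]) -> np.ndarray:
    """Gather dilated patches of ``x`` into a ``(n_pixels, in_ch * n_taps)`` matrix."""
    c, spatial = x.shape[0], x.shape[1:]
    nd = len(spatial)
    pad = same_padding(kernel, dilation)
    xp = np.pad(x, ((0, 0),) + tuple((p, p) for p in pad))
    extent = tuple((k - 1) * d + 1 for k, d in zip(kernel, dilation))
    win = np.lib.stride_tricks.sliding_window_view(xp, extent, axis=tuple(range(1, nd + 1)))
    win = win[(slice(None),) * (1 + nd) + tuple(slice(None, None, d) for d in dilation)]
    win = np.moveaxis(win, 0, nd)  # (*spatial, C, *kernel)
    n_pix = int(np.prod(spatial))
    n_taps = int(np.prod(kernel))
    return np.ascontiguousarray(win).reshape(n_pix, c * n_taps)


def conv_forward(
    x: np.ndarray,
    weight: np.ndarray,
    bias: np.ndarray | None,
    dilation: tuple[int, ...],
    return_cols: bool = False,
):
    """Resolution-preserving convolution. Returns ``(out, cols)`` when asked."""
    out_ch = weight.shape[0]
    kernel = weight.shape[2:]
    spatial = x.shape[1:]
    cols = im2col(x, kernel, dilation)
    out = cols @ weight.reshape(out_ch, -1).T
    if bias is not None:
        out += bias
    out = np.ascontiguousarray(out.T).reshape((out_ch,) + spatial)
    if return_cols:
        return out, cols
    return out


def conv_backward_params(dout: np.ndarray, cols: np.ndarray, kernel_shape: tuple[int, ...]):
    """Gradients w.r.t. weight and bias from the stashed im2col matrix."""
    out_ch = dout.shape[0]
    dflat = dout.reshape(out_ch, -1)  # (out_ch, P)
    dw = (dflat @ cols).reshape(kernel_shape)
    db = dflat.sum(axis=1)
    return dw, db


def conv_backward_input(dout: np.ndarray, weight: np.ndarray, dilation: tuple[int, ...]) -> np.ndarray:
    """Gradient w.r.t. the convolution input.

    Valid because stride is 1, padding is symmetric and kernels are odd:
    the adjoint is the correlation with the flipped kernel and swapped
    channel axes at the same dilation.
    """
    nd = weight.ndim - 2
    w_flip = weight[(slice(None), slice(None)) + (slice(None, None, -1),) * nd]
    w_t = np.ascontiguousarray(w_flip.swapaxes(0, 1))
    return conv_forward(dout, w_t, None, dilation)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)
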