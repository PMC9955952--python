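"""Ordinal (cumulative) encoding of PI-RADS categories.

Five classes are used throughout the package::

    0  non-lesion
    1  PI-RADS 1/2  (score 1 lesions are grouped with score 2)
    2  PI-RADS 3
    3  PI-RADS 4
    4  PI-RADS 5

A class ``c`` is encoded as a 4-bit cumulative vector whose k-th bit
(1-indexed) answers "is the class >= k?", i.e. ``[1]*c + [0]*(4-c)``.
Unlike one-hot codes, adjacent grades share bits, so the progression of
the disease is preserved in the supervision signal: a PI-RADS 4 target
differs from PI-RADS 3 in exactly one channel.

Ground-truth label maps become 4-channel binary masks with the nesting
property ``channel[k+1] <= channel[k]`` pixelwise; the network predicts
the four channels with independent sigmoids, so predicted vectors may be
non-monotone and decoding is defined to be robust to that.
"""

from __future__ import annotations

import numpy as np

#: total number of classes (non-lesion + four PI-RADS categories)
N_CLASSES = 5
#: number of bits / mask channels in the cumulative code
N_ORDINAL_BITS = N_CLASSES - 1

PIRADS_NAMES = ("non-lesion", "PI-RADS 1/2", "PI-RADS 3", "PI-RADS 4", "PI-RADS 5")


class InvalidClassError(ValueError):
    """Raised for a class label outside {0..4}."""


def encode_ordinal(cls: int) -> np.ndarray:
    """Encode a single PI-RADS class as its 4-bit cumulative vector.

    Parameters
    ----------
    cls
        Integer class label in ``{0, 1, 2, 3, 4}``.

    Returns
    -------
    numpy.ndarray
        ``uint8`` vector of length 4; bit k (0-indexed) is 1 iff
        ``cls >= k + 1``.
    """
    c = int(cls)
    if c != cls or not 0 <= c < N_CLASSES:
        raise InvalidClassError(f"class label must be an integer in [0, {N_CLASSES - 1}], got {cls!r}")
    bits = np.zeros(N_ORDINAL_BITS, dtype=np.uint8)
    bits[:c] = 1
    return bits


def decode_ordinal(bits: np.ndarray, threshold: float = 0.5) -> int:
    """Decode 4 per-bit probabilities back to a class label.

    Each value is binarized at ``threshold`` and the class is the length
    of the *leading* run of ones.  For monotone (valid) vectors this is
    the exact inverse of :func:`encode_ordinal`; for non-monotone
    predictions it is conservative — a lesion is never upgraded past the
    first sub-threshold bit (e.g. binarized ``1,0,1,0`` decodes to 1).
    """
    arr = np.asarray(bits, dtype=float)
    if arr.shape != (N_ORDINAL_BITS,):
        raise ValueError(f"expected {N_ORDINAL_BITS} values, got shape {arr.shape}")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("bit probabilities must lie in [0, 1]")
    hard = arr >= threshold
    cls = 0
    for b in hard:
        if not b:
            break
        cls += 1
    return cls


def encode_label_map(label_map: np.ndarray) -> np.ndarray:
    """Encode a per-pixel class image/volume into nested binary channels.

    Parameters
    ----------
    label_map
        Integer array of any shape with values in ``{0..4}``.

    Returns
    -------
    numpy.ndarray
        ``uint8`` array of shape ``(4, *label_map.shape)``; channel k is
        the indicator of ``label_map >= k + 1``, so channels are nested.
    """
    lm = np.asarray(label_map)
    if lm.size and (lm.min() < 0 or lm.max() >= N_CLASSES or not np.issubdtype(lm.dtype, np.integer)):
        raise InvalidClassError("label map must be integer-valued in [0, 4]")
    ks = np.arange(1, N_CLASSES).reshape((N_ORDINAL_BITS,) + (1,) * lm.ndim)
    return (lm[None, ...] >= ks).astype(np.uint8)


def decode_label_map(channels: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Decode 4-channel per-pixel probabilities to a class map.

    Applies the leading-run rule of :func:`decode_ordinal` pixelwise
    (vectorized as a running product along the channel axis).
    """
    ch = np.asarray(channels, dtype=float)
    if ch.ndim < 1 or ch.shape[0] != N_ORDINAL_BITS:
        raise ValueError(f"expected channel axis of size {N_ORDINAL_BITS} first, got shape {ch.shape}")
    if np.any(ch < 0) or np.any(ch > 1):
        raise ValueError("channel probabilities must lie in [0, 1]")
    hard = ch >= threshold
    # leading-run length = sum of cumulative AND along channels
    return np.cumprod(hard, axis=0).sum(axis=0).astype(np.int64)
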