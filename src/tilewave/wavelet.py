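"""Orthonormal discrete wavelet transform along the genomic coordinate.

Probe signals are ordered by genomic position within one chromosome x strand
and projected onto an orthonormal wavelet basis (D = Y W^T). Lengths that are
not a power of two are extended by symmetric reflection to the next power of
two so the transform matrix W stays orthogonal; the synthetic padded positions
are tracked and dropped again on inversion and excluded from inference.

Coefficients are stored flat, with an index map to (scale j, location k):
j = 0 is the coarsest block, j = J the finest detail level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pywt

from .errors import DataError, ShapeError


def _wavedec(data, family, level, axis=-1):
    # full-depth periodized transforms are exact; pywt's depth warning is
    # about boundary effects that periodization does not have
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Level value of .* is too high")
        return pywt.wavedec(data, family, mode=_MODE, level=level, axis=axis)

__all__ = [
    "WaveletPlan",
    "make_plan",
    "forward",
    "inverse",
    "forward_matrix",
    "inverse_matrix",
    "propagate_variance",
]

_MODE = "periodization"  # orthonormal on power-of-two lengths


@dataclass
class WaveletPlan:
    """Precomputed layout of the DWT for signals of a fixed length.

    Attributes
    ----------
    T:
        Number of genuine probes.
    padded_length:
        Power of two >= T actually transformed.
    family:
        ``haar`` or ``db<p>`` (Daubechies with p vanishing moments).
    levels:
        Decomposition depth J (default: full, log2 of padded length).
    index_map:
        ``(j, k)`` per flat coefficient index; j=0 coarse, k 1-based.
    pad_mask:
        Boolean over padded positions, True where the sample is synthetic.
    """

    T: int
    padded_length: int
    family: str
    levels: int
    index_map: list[tuple[int, int]]
    pad_mask: np.ndarray
    _slices: list[slice] = field(repr=False, default_factory=list)

    @cached_property
    def synthesis_matrix(self) -> np.ndarray:
        """Explicit W^T (padded_length x padded_length): column c is the
        padded-domain image of unit coefficient c. Built lazily; only needed
        for variance propagation and brute-force checks."""
        n = self.padded_length
        wt = np.empty((n, n))
        eye = np.eye(n)
        for c in range(n):
            wt[:, c] = _inverse_padded(eye[c], self)
        return wt

    @cached_property
    def squared_synthesis(self) -> np.ndarray:
        return self.synthesis_matrix[: self.T] ** 2


def make_plan(T: int, family: str = "haar", levels: int | None = None) -> WaveletPlan:
    """Build a transform plan for probe signals of length ``T``."""
    if T < 2:
        raise ShapeError(f"signal length must be >= 2, got {T}")
    wavelet = pywt.Wavelet(family)
    if not wavelet.orthogonal:
        raise DataError(f"wavelet family {family!r} is not orthogonal")
    padded = 1 << (int(T - 1)).bit_length()
    max_levels = int(np.log2(padded))
    j_levels = max_levels if levels is None else int(levels)
    if not 1 <= j_levels <= max_levels:
        raise ShapeError(f"levels must be in [1, {max_levels}] for padded length {padded}")
    coeffs = _wavedec(np.zeros(padded), wavelet, j_levels)
    slices = []
    index_map: list[tuple[int, int]] = []
    start = 0
    for j, block in enumerate(coeffs):
        slices.append(slice(start, start + block.size))
        index_map.extend((j, k + 1) for k in range(block.size))
        start += block.size
    if start != padded:
        raise ShapeError("coefficient layout does not cover the padded length")
    pad_mask = np.zeros(padded, dtype=bool)
    pad_mask[T:] = True
    return WaveletPlan(
        T=T,
        padded_length=padded,
        family=family,
        levels=j_levels,
        index_map=index_map,
        pad_mask=pad_mask,
        _slices=slices,
    )


def _pad(signal: np.ndarray, plan: WaveletPlan) -> np.ndarray:
    extra = plan.padded_length - plan.T
    if extra == 0:
        return signal
    return np.pad(signal, (0, extra), mode="symmetric")


def forward(signal: np.ndarray, plan: WaveletPlan) -> np.ndarray:
    """Project a probe signal onto the wavelet basis.

    Returns the padded-length coefficient vector; energy on the padded signal
    is preserved (orthonormality / Parseval).
    """
    y = np.asarray(signal, dtype=float)
    if y.shape != (plan.T,):
        raise ShapeError(f"expected signal of length {plan.T}, got shape {y.shape}")
    coeffs = _wavedec(_pad(y, plan), plan.family, plan.levels)
    return np.concatenate(coeffs)


def _split(coeffs: np.ndarray, plan: WaveletPlan) -> list[np.ndarray]:
    return [coeffs[s] for s in plan._slices]


def _inverse_padded(coeffs: np.ndarray, plan: WaveletPlan) -> np.ndarray:
    return pywt.waverec(_split(coeffs, plan), plan.family, mode=_MODE)


def inverse(coeffs: np.ndarray, plan: WaveletPlan) -> np.ndarray:
    """Reconstruct the probe-domain signal; synthetic padded positions are dropped."""
    c = np.asarray(coeffs, dtype=float)
    if c.shape != (plan.padded_length,):
        raise ShapeError(f"expected {plan.padded_length} coefficients, got shape {c.shape}")
    return _inverse_padded(c, plan)[: plan.T]


def forward_matrix(Y: np.ndarray, plan: WaveletPlan) -> np.ndarray:
    """Row-wise forward transform of an arrays x probes matrix (D = Y W^T)."""
    y = np.asarray(Y, dtype=float)
    if y.ndim != 2 or y.shape[1] != plan.T:
        raise ShapeError(f"expected an (N, {plan.T}) matrix, got shape {y.shape}")
    extra = plan.padded_length - plan.T
    if extra:
        y = np.pad(y, ((0, 0), (0, extra)), mode="symmetric")
    coeffs = _wavedec(y, plan.family, plan.levels, axis=-1)
    return np.concatenate(coeffs, axis=-1)


def inverse_matrix(C: np.ndarray, plan: WaveletPlan) -> np.ndarray:
    """Row-wise inverse transform; padded positions dropped."""
    c = np.asarray(C, dtype=float)
    if c.ndim != 2 or c.shape[1] != plan.padded_length:
        raise ShapeError(f"expected an (N, {plan.padded_length}) matrix, got shape {c.shape}")
    blocks = [c[:, s] for s in plan._slices]
    return pywt.waverec(blocks, plan.family, mode=_MODE, axis=-1)[:, : plan.T]


def propagate_variance(coeff_variances: np.ndarray, plan: WaveletPlan) -> np.ndarray:
    """Map independent per-coefficient variances to per-probe variances.

    The inverse transform is linear, x_t = sum_c w_{t,c} d_c, and the
    posterior coefficients are independent across (j, k), so
    var(x_t) = sum_c w_{t,c}^2 var(d_c).
    """
    v = np.asarray(coeff_variances, dtype=float)
    if v.shape != (plan.padded_length,):
        raise ShapeError(f"expected {plan.padded_length} variances, got shape {v.shape}")
    if np.any(v < 0):
        raise DataError("coefficient variances must be nonnegative")
    return plan.squared_synthesis @ v
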