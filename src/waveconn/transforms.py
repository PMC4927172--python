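"""Discrete and maximal-overlap discrete wavelet transforms.

Implements the pyramid algorithms with periodic (circular) boundary
handling, their inverses, the additive multiresolution analysis, and the
dyadic scale -> frequency-band mapping.  The MODWT is the non-downsampled,
shift-invariant variant: it keeps N coefficients at every scale and uses
the rescaled filters g/sqrt(2), h/sqrt(2).  The DWT halves the length at
each level; odd intermediate lengths are handled by carrying the last
scaling coefficient through unchanged, so the transform stays orthonormal
for arbitrary N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from waveconn.filters import WaveletFilter

__all__ = [
    "WaveletDecomposition",
    "ScaleBand",
    "modwt",
    "dwt",
    "inverse_modwt",
    "inverse_dwt",
    "mra_details",
    "scale_to_band",
]


@dataclass
class WaveletDecomposition:
    """Per-scale wavelet coefficients of one time series.

    ``coeffs_per_scale[j-1]`` holds the level-j wavelet coefficients
    W_j; ``smooth`` holds the level-J scaling coefficients V_J.  For the
    MODWT every sequence has length N; for the DWT lengths follow the
    recursive halving with at most one carried scaling coefficient per
    level (``carries``).
    """

    method: str  # "DWT" or "MODWT"
    filter: WaveletFilter
    levels: int
    coeffs_per_scale: list[np.ndarray]
    smooth: np.ndarray
    input_length: int
    boundary_mask_per_scale: list[np.ndarray] = field(default_factory=list)
    carries: list[bool] = field(default_factory=list)  # DWT odd-length carry flags

    @property
    def n_scales(self) -> int:
        return self.levels

    def energy(self) -> float:
        """Total squared norm over all coefficient vectors."""
        return float(
            sum(w @ w for w in self.coeffs_per_scale) + self.smooth @ self.smooth
        )

    def export_text(self, path) -> None:
        """Write per-scale coefficients as delimited text (one row per scale)."""
        with open(path, "w") as fh:
            fh.write(f"# method={self.method} filter={self.filter.name} "
                     f"levels={self.levels} N={self.input_length}\n")
            for j, w in enumerate(self.coeffs_per_scale, start=1):
                fh.write(f"W{j}\t" + "\t".join(repr(float(v)) for v in w) + "\n")
            fh.write(f"V{self.levels}\t"
                     + "\t".join(repr(float(v)) for v in self.smooth) + "\n")


@dataclass(frozen=True)
class ScaleBand:
    """Frequency band (low_hz, high_hz] covered by a dyadic wavelet scale."""

    scale: int
    low_hz: float
    high_hz: float


def _check_input(x: np.ndarray, levels: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("input series must be one-dimensional")
    if x.size < 2:
        raise ValueError("input series must have at least 2 samples")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    return x


def _modwt_boundary_mask(L: int, j: int, n: int) -> np.ndarray:
    # L_j = (2^j - 1)(L - 1) + 1 is the level-j equivalent filter width;
    # the first L_j - 1 coefficients are influenced by circular wrap-around.
    width = (2**j - 1) * (L - 1) + 1
    mask = np.zeros(n, dtype=bool)
    mask[: min(width - 1, n)] = True
    return mask


def _modwt_core(X: np.ndarray, filt: WaveletFilter, levels: int):
    """MODWT pyramid on the last axis of a (..., N) array."""
    n = X.shape[-1]
    L = filt.length
    g = filt.scaling_coeffs / np.sqrt(2.0)
    h = filt.wavelet_coeffs / np.sqrt(2.0)
    v = X
    coeffs = []
    for j in range(1, levels + 1):
        step = 2 ** (j - 1)
        w_j = np.zeros_like(v)
        v_j = np.zeros_like(v)
        for ell in range(L):
            # rolled[..., t] = v[..., (t - step*ell) mod n]
            rolled = np.roll(v, step * ell, axis=-1)
            w_j += h[ell] * rolled
            v_j += g[ell] * rolled
        coeffs.append(w_j)
        v = v_j
    return coeffs, v, n


def modwt(x, filt: WaveletFilter, levels: int = 4) -> WaveletDecomposition:
    """Maximal-overlap DWT to the given depth, circular boundary.

    Uses the rescaled filters g/sqrt(2), h/sqrt(2) so that the transform
    conserves energy: sum_j ||W_j||^2 + ||V_J||^2 = ||x||^2.
    """
    x = _check_input(x, levels)
    n = x.size
    L = filt.length
    if (2 ** (levels - 1)) * (L - 1) + 1 > n:
        warnings.warn(
            f"level-{levels} equivalent filter width exceeds series length {n}; "
            "all deepest-scale coefficients are boundary-influenced",
            stacklevel=2,
        )
    coeffs, v, _ = _modwt_core(x, filt, levels)
    return WaveletDecomposition(
        method="MODWT",
        filter=filt,
        levels=levels,
        coeffs_per_scale=coeffs,
        smooth=v,
        input_length=n,
        boundary_mask_per_scale=[
            _modwt_boundary_mask(L, j, n) for j in range(1, levels + 1)
        ],
    )


def inverse_modwt(d: WaveletDecomposition) -> np.ndarray:
    """Reconstruct the original series from a MODWT decomposition."""
    if d.method != "MODWT":
        raise ValueError("inverse_modwt requires a MODWT decomposition")
    g = d.filter.scaling_coeffs / np.sqrt(2.0)
    h = d.filter.wavelet_coeffs / np.sqrt(2.0)
    L = d.filter.length
    v = d.smooth
    for j in range(d.levels, 0, -1):
        step = 2 ** (j - 1)
        w = d.coeffs_per_scale[j - 1]
        v_prev = np.zeros(d.input_length)
        for ell in range(L):
            # rolled[t] = a[(t + step*ell) mod n]
            v_prev += h[ell] * np.roll(w, -step * ell)
            v_prev += g[ell] * np.roll(v, -step * ell)
        v = v_prev
    return v


def mra_details(d: WaveletDecomposition) -> tuple[list[np.ndarray], np.ndarray]:
    """Additive multiresolution analysis D_1..D_J, S_J from a MODWT.

    Each detail D_j is the inverse transform of the decomposition with
    every component except W_j zeroed; S_J likewise from V_J alone.  By
    linearity sum_j D_j + S_J reconstructs the input exactly.
    """
    if d.method != "MODWT":
        raise ValueError("multiresolution details are defined here for MODWT only")
    n = d.input_length
    details = []
    for j in range(1, d.levels + 1):
        iso = WaveletDecomposition(
            method="MODWT",
            filter=d.filter,
            levels=d.levels,
            coeffs_per_scale=[
                d.coeffs_per_scale[k - 1] if k == j else np.zeros(n)
                for k in range(1, d.levels + 1)
            ],
            smooth=np.zeros(n),
            input_length=n,
        )
        details.append(inverse_modwt(iso))
    iso = WaveletDecomposition(
        method="MODWT",
        filter=d.filter,
        levels=d.levels,
        coeffs_per_scale=[np.zeros(n)] * d.levels,
        smooth=d.smooth,
        input_length=n,
    )
    smooth = inverse_modwt(iso)
    return details, smooth


def _dwt_step(v: np.ndarray, g: np.ndarray, h: np.ndarray):
    """One level of the circular DWT pyramid on the last axis (even length)."""
    m = v.shape[-1]
    L = g.size
    half = m // 2
    t = np.arange(half)
    idx = (2 * t[:, None] + 1 - np.arange(L)[None, :]) % m
    w = (v[..., idx] * h).sum(axis=-1)
    vnext = (v[..., idx] * g).sum(axis=-1)
    return w, vnext


def _inverse_dwt_step(w: np.ndarray, vnext: np.ndarray, g: np.ndarray, h: np.ndarray):
    m = 2 * w.size
    L = g.size
    v = np.zeros(m)
    t = np.arange(w.size)
    idx = (2 * t[:, None] + 1 - np.arange(L)[None, :]) % m
    for ell in range(L):
        np.add.at(v, idx[:, ell], h[ell] * w + g[ell] * vnext)
    return v


def _dwt_boundary_count(L: int, j: int) -> int:
    # Number of level-j DWT coefficients influenced by the circular boundary.
    return int(np.ceil((L - 2) * (1 - 2.0 ** (-j))))


def _dwt_core(X: np.ndarray, filt: WaveletFilter, levels: int):
    """DWT pyramid with the odd-length carry rule on the last axis."""
    g = filt.scaling_coeffs
    h = filt.wavelet_coeffs
    v = X
    coeffs, carries = [], []
    for j in range(1, levels + 1):
        odd = v.shape[-1] % 2 == 1
        carries.append(odd)
        core, tail = (v[..., :-1], v[..., -1:]) if odd else (v, v[..., :0])
        if core.shape[-1] == 0:
            raise ValueError(
                f"series too short to decompose to level {levels} "
                f"(exhausted at level {j})"
            )
        w, vnext = _dwt_step(core, g, h)
        v = np.concatenate([vnext, tail], axis=-1)
        coeffs.append(w)
    return coeffs, v, carries


def dwt(x, filt: WaveletFilter, levels: int = 4) -> WaveletDecomposition:
    """Circular DWT pyramid with the odd-length carry rule.

    When an intermediate scaling sequence has odd length, its last
    coefficient is set aside untouched and re-appended to the next
    scaling sequence, so at most one extra scaling coefficient is
    preserved at each level and the transform remains orthonormal for
    arbitrary input length.
    """
    x = _check_input(x, levels)
    coeffs, v, carries = _dwt_core(x, filt, levels)
    masks = []
    for j, w in enumerate(coeffs, start=1):
        nb = min(_dwt_boundary_count(filt.length, j), w.size)
        mask = np.zeros(w.size, dtype=bool)
        mask[:nb] = True
        masks.append(mask)
    return WaveletDecomposition(
        method="DWT",
        filter=filt,
        levels=levels,
        coeffs_per_scale=coeffs,
        smooth=v,
        input_length=x.size,
        boundary_mask_per_scale=masks,
        carries=carries,
    )


def inverse_dwt(d: WaveletDecomposition) -> np.ndarray:
    """Reconstruct the original series from a DWT decomposition."""
    if d.method != "DWT":
        raise ValueError("inverse_dwt requires a DWT decomposition")
    g = d.filter.scaling_coeffs
    h = d.filter.wavelet_coeffs
    v = d.smooth
    for j in range(d.levels, 0, -1):
        w = d.coeffs_per_scale[j - 1]
        if d.carries[j - 1]:
            core, tail = v[:-1], v[-1:]
        else:
            core, tail = v, v[:0]
        v = np.concatenate([_inverse_dwt_step(w, core, g, h), tail])
    return v


def scale_to_band(tr_seconds: float, scale: int) -> ScaleBand:
    """Frequency band captured by wavelet scale j at sampling interval TR.

    With sampling rate fs = 1/TR (Nyquist fs/2), scale j covers
    (fs/2^(j+1), fs/2^j]; e.g. at TR = 2 s scale 1 is 0.125-0.25 Hz and
    scale 2 is 0.0625-0.125 Hz.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if scale < 1:
        raise ValueError("scale must be >= 1")
    fs = 1.0 / tr_seconds
    return ScaleBand(scale=scale, low_hz=fs / 2 ** (scale + 1), high_hz=fs / 2**scale)


def decompose_matrix(ts: np.ndarray, filt: WaveletFilter, method: str,
                     levels: int = 4) -> list[WaveletDecomposition]:
    """Decompose every column of a (timepoints x regions) matrix.

    Runs the pyramid once on the whole region-by-time array (the
    recursions are identical across regions) and returns one
    :class:`WaveletDecomposition` per region.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("expect a (timepoints x regions) matrix")
    X = ts.T  # regions x timepoints
    n = X.shape[1]
    method = method.upper()
    if method == "MODWT":
        coeffs, smooth, _ = _modwt_core(X, filt, levels)
        masks = [_modwt_boundary_mask(filt.length, j, n)
                 for j in range(1, levels + 1)]
        carries = []
    elif method == "DWT":
        coeffs, smooth, carries = _dwt_core(X, filt, levels)
        masks = []
        for j, w in enumerate(coeffs, start=1):
            nb = min(_dwt_boundary_count(filt.length, j), w.shape[-1])
            mask = np.zeros(w.shape[-1], dtype=bool)
            mask[:nb] = True
            masks.append(mask)
    else:
        raise ValueError(f"unknown method {method!r}")
    return [
        WaveletDecomposition(
            method=method, filter=filt, levels=levels,
            coeffs_per_scale=[w[r] for w in coeffs], smooth=smooth[r],
            input_length=n, boundary_mask_per_scale=masks,
            carries=list(carries),
        )
        for r in range(X.shape[0])
    ]
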