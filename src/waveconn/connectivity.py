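"""Scale-wise association matrices from wavelet coefficients.

The wavelet correlation between two regions at scale j is the Pearson
correlation of their level-j wavelet coefficient sequences — a
frequency-band-specific estimate of functional connectivity that
remains well behaved for long-memory signals where broadband
correlation is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from waveconn.transforms import WaveletDecomposition, mra_details

__all__ = [
    "ConnectivityMatrix",
    "wavelet_correlation_matrix",
    "partial_correlation_matrix",
    "summary_weighted_metrics",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric region-by-region association matrix at one scale."""

    values: np.ndarray
    scale: int
    subject_id: str = ""
    method: str = ""
    family: str = ""
    length: int = 0
    estimator: str = "correlation"
    flagged_regions: tuple[int, ...] = field(default_factory=tuple)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def validate(self, atol: float = 1e-12) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix has non-finite entries")
        if np.max(np.abs(v - v.T)) > atol:
            raise ValueError("connectivity matrix must be symmetric")
        if np.max(np.abs(np.diag(v) - 1.0)) > atol:
            raise ValueError("connectivity matrix must have unit diagonal")

    def upper_triangle(self) -> np.ndarray:
        """Strictly-upper-triangular entries as a flat vector."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]

    def to_text(self, path, labels=None) -> None:
        """Write as dense delimited text with a header row of region labels."""
        n = self.n_regions
        labels = labels or [f"R{i}" for i in range(n)]
        with open(path, "w") as fh:
            fh.write("\t".join(labels) + "\n")
            for row in self.values:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def _scale_coefficients(decomps: list[WaveletDecomposition], scale: int,
                        use_details: bool, exclude_boundary: bool) -> np.ndarray:
    if not decomps:
        raise ValueError("need at least one decomposition")
    d0 = decomps[0]
    if scale < 1 or scale > d0.levels:
        raise ValueError(f"scale {scale} outside decomposition depth {d0.levels}")
    for d in decomps:
        if (d.method, d.filter.name, d.input_length, d.levels) != (
            d0.method, d0.filter.name, d0.input_length, d0.levels,
        ):
            raise ValueError("all regions must share method, filter, length, depth")
    if use_details:
        rows = [mra_details(d)[0][scale - 1] for d in decomps]
    else:
        rows = [d.coeffs_per_scale[scale - 1] for d in decomps]
    mat = np.vstack(rows)
    if exclude_boundary and decomps[0].boundary_mask_per_scale:
        keep = ~decomps[0].boundary_mask_per_scale[scale - 1]
        if keep.sum() >= 2:
            mat = mat[:, keep]
    return mat


def wavelet_correlation_matrix(
    decomps: list[WaveletDecomposition],
    scale: int,
    use_details: bool = False,
    exclude_boundary: bool = False,
) -> ConnectivityMatrix:
    """Pearson correlation of scale-j coefficients across region pairs.

    Regions whose coefficient sequence has zero variance are flagged
    (``flagged_regions``) and their off-diagonal entries set to NaN
    rather than silently zero; callers must handle or exclude them.
    """
    mat = _scale_coefficients(decomps, scale, use_details, exclude_boundary)
    sd = mat.std(axis=1)
    flagged = tuple(int(i) for i in np.nonzero(sd == 0.0)[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr = np.asarray(corr, dtype=float)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    d0 = decomps[0]
    cm = ConnectivityMatrix(
        values=corr, scale=scale, method=d0.method,
        family=d0.filter.family, length=d0.filter.length,
        flagged_regions=flagged,
    )
    if not flagged:
        cm.validate()
    return cm


def partial_correlation_matrix(
    decomps: list[WaveletDecomposition],
    scale: int,
    ridge: float = 0.0,
    use_details: bool = False,
    exclude_boundary: bool = False,
) -> ConnectivityMatrix:
    """Partial (inverse-covariance) correlation of scale-j coefficients.

    Standardised negative precision entries: for regions i, j the entry
    is the correlation conditioned on every other region.  If the
    covariance is singular (fewer coefficient samples than regions) a
    ridge penalty ``ridge * mean(diag)`` must be supplied.
    """
    mat = _scale_coefficients(decomps, scale, use_details, exclude_boundary)
    p, n = mat.shape
    cov = np.cov(mat)
    if ridge > 0.0:
        cov = cov + ridge * np.mean(np.diag(cov)) * np.eye(p)
    elif n <= p:
        raise np.linalg.LinAlgError(
            f"{n} coefficient samples for {p} regions: covariance singular; "
            "pass ridge > 0"
        )
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular covariance; pass ridge > 0 to regularise"
        ) from exc
    d = np.sqrt(np.diag(prec))
    pcorr = -prec / np.outer(d, d)
    np.fill_diagonal(pcorr, 1.0)
    pcorr = np.clip((pcorr + pcorr.T) / 2.0, -1.0, 1.0)
    d0 = decomps[0]
    cm = ConnectivityMatrix(
        values=pcorr, scale=scale, method=d0.method,
        family=d0.filter.family, length=d0.filter.length,
        estimator="partial_correlation",
    )
    cm.validate()
    return cm


def summary_weighted_metrics(m: ConnectivityMatrix) -> tuple[float, float]:
    """Mean and variance of the strictly-upper-triangular entries."""
    ut = m.upper_triangle()
    return float(np.mean(ut)), float(np.var(ut))
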