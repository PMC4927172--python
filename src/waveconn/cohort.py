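"""Synthetic two-group cohorts of long-memory regional time series.

Emulates the statistical structure of resting-state fMRI region
signals: each region is a mixture of a global factor, a module
(community) factor and idiosyncratic noise, all temporally coloured as
fractional Gaussian noise (fGn) with a common Hurst exponent, so the
signals exhibit the slowly decaying positive autocorrelation (long
memory) characteristic of BOLD data.  The mixture weights imply an
exact block-structured target correlation matrix; the patient group
receives an additive connectivity perturbation, either broadband or
restricted to one wavelet band.

Defaults mirror the study dimensions this package is designed around:
29 subjects per group, 90 regions, 177 retained volumes at TR = 2 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from waveconn.filters import make_filter
from waveconn.transforms import WaveletDecomposition, modwt, mra_details

__all__ = [
    "CohortSpec",
    "Cohort",
    "GroundTruth",
    "generate_cohort",
    "fgn",
    "fgn_autocovariance",
    "estimate_hurst",
]


def fgn_autocovariance(hurst: float, n_lags: int) -> np.ndarray:
    """Autocovariance of unit-variance fGn at lags 0..n_lags-1."""
    k = np.arange(n_lags, dtype=float)
    return 0.5 * (np.abs(k + 1) ** (2 * hurst) - 2 * np.abs(k) ** (2 * hurst)
                  + np.abs(k - 1) ** (2 * hurst))


def fgn(n: int, hurst: float, rng: np.random.Generator,
        size: int = 1) -> np.ndarray:
    """Sample fractional Gaussian noise by circulant embedding.

    Embeds the length-n autocovariance in a circulant of order 2n and
    colours complex white noise with the square root of its spectrum
    (Davies-Harte).  The embedding is nonnegative-definite for fGn with
    0 < H < 1; tiny negative eigenvalues from rounding are clipped,
    which degrades gracefully into spectral synthesis.

    Returns an array of shape (size, n) of independent unit-variance
    series.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie in (0, 1)")
    gamma = fgn_autocovariance(hurst, n + 1)
    row = np.concatenate([gamma[:-1], gamma[-1:], gamma[1:-1][::-1]])  # order 2n
    lam = np.fft.rfft(row).real
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    # Hermitian white noise with unit E|w|^2 (endpoints real)
    w = (rng.standard_normal((size, lam.size))
         + 1j * rng.standard_normal((size, lam.size))) / np.sqrt(2.0)
    w[:, 0] = np.sqrt(2.0) * w[:, 0].real
    w[:, -1] = np.sqrt(2.0) * w[:, -1].real
    x = np.fft.irfft(np.sqrt(m * lam) * w, n=m, axis=1)
    return x[:, :n]


@dataclass
class CohortSpec:
    """Parameters of the synthetic two-group cohort.

    ``within_corr``/``between_corr`` set the target correlation inside
    and across modules for the control group; ``group_effect`` is added
    to both in the patient group (broadband by default, or confined to
    wavelet scale ``effect_scale``).
    """

    n_per_group: int = 29
    n_regions: int = 90
    n_timepoints: int = 177
    tr_seconds: float = 2.0
    hurst: float = 0.8
    n_modules: int = 4
    within_corr: float = 0.4
    between_corr: float = 0.1
    group_effect: float = 0.15
    effect_scale: int | None = None
    seed: int = 0

    def module_labels(self) -> np.ndarray:
        """Regions split into n_modules near-equal contiguous blocks."""
        labels = np.empty(self.n_regions, dtype=int)
        for m, block in enumerate(
                np.array_split(np.arange(self.n_regions), self.n_modules)):
            labels[block] = m
        return labels

    def target_matrix(self, group: str = "control") -> np.ndarray:
        """Implied region-correlation matrix for one group.

        Broadband exact target; when ``effect_scale`` is set the patient
        perturbation lives in one band only and the broadband patient
        matrix equals the control one.
        """
        rho_w, rho_b = self.within_corr, self.between_corr
        if group == "patient" and self.effect_scale is None:
            rho_w = rho_w + self.group_effect
            rho_b = rho_b + self.group_effect
        labels = self.module_labels()
        same = labels[:, None] == labels[None, :]
        mat = np.where(same, rho_w, rho_b)
        np.fill_diagonal(mat, 1.0)
        return mat

    def _weights(self, group: str) -> tuple[float, float, float]:
        rho_w, rho_b = self.within_corr, self.between_corr
        if group == "patient" and self.effect_scale is None:
            rho_w += self.group_effect
            rho_b += self.group_effect
        if not 0.0 <= rho_b <= rho_w < 1.0:
            raise ValueError(
                f"need 0 <= between_corr <= within_corr < 1 (group {group}: "
                f"within={rho_w}, between={rho_b}); implied covariance not PSD"
            )
        return np.sqrt(rho_b), np.sqrt(rho_w - rho_b), np.sqrt(1.0 - rho_w)

    def validate(self) -> None:
        if self.n_per_group < 1 or self.n_regions < 2 or self.n_timepoints < 8:
            raise ValueError("cohort dimensions too small")
        if not 0.0 < self.hurst < 1.0:
            raise ValueError("hurst must lie in (0, 1)")
        if self.n_modules < 1 or self.n_modules > self.n_regions:
            raise ValueError("n_modules must lie in [1, n_regions]")
        for grp in ("control", "patient"):
            self._weights(grp)
            w = np.linalg.eigvalsh(self.target_matrix(grp))
            if w.min() < -1e-10:
                raise ValueError("implied correlation matrix not PSD")
        if self.effect_scale is not None and self.effect_scale < 1:
            raise ValueError("effect_scale must be >= 1")


@dataclass
class GroundTruth:
    """Exact generative structure emitted alongside the data."""

    target_control: np.ndarray
    target_patient: np.ndarray
    module_labels: np.ndarray
    hurst: float
    effect_scale: int | None
    group_effect: float

    def describe(self) -> str:
        band = ("broadband" if self.effect_scale is None
                else f"wavelet scale {self.effect_scale}")
        return (f"patient connectivity elevated by {self.group_effect:+.3f} "
                f"({band}); Hurst {self.hurst}")


@dataclass
class Cohort:
    """Simulated subjects: array (n_subjects, n_timepoints, n_regions)."""

    data: np.ndarray
    subject_ids: list[str]
    groups: list[str]
    tr_seconds: float
    ground_truth: GroundTruth
    spec: CohortSpec

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def subjects(self):
        for i, (sid, grp) in enumerate(zip(self.subject_ids, self.groups)):
            yield sid, grp, self.data[i]


def _band_detail(x: np.ndarray, scale: int) -> np.ndarray:
    """The scale-j multiresolution detail of one series (LA8 analysis)."""
    d = modwt(x, make_filter("LA", 8), levels=max(4, scale))
    return mra_details(d)[0][scale - 1]


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate the two-group cohort described by ``spec``.

    Control-group regions follow the exact block target correlation;
    the patient group receives the connectivity perturbation either by
    shifting the mixture weights (broadband) or by routing part of the
    idiosyncratic variance through a band-limited module factor
    (``effect_scale``).  Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_timepoints, spec.n_regions
    labels = spec.module_labels()
    data = []
    ids, groups = [], []
    for group, prefix in (("control", "ctrl"), ("patient", "pat")):
        a, b, c = spec._weights(group)
        for s in range(spec.n_per_group):
            glob = fgn(n, spec.hurst, rng)[0]
            mods = fgn(n, spec.hurst, rng, size=spec.n_modules)
            idio = fgn(n, spec.hurst, rng, size=p)
            if group == "patient" and spec.effect_scale is not None:
                # swap part of each region's scale-j idiosyncratic detail
                # for a shared module detail: correlation rises in that
                # band only, other scales are untouched
                lam2 = min(spec.group_effect / max(c * c, 1e-12), 1.0)
                lam = np.sqrt(lam2)
                shared = np.vstack([
                    _band_detail(fgn(n, spec.hurst, rng)[0],
                                 spec.effect_scale)
                    for _ in range(spec.n_modules)
                ])
                own = np.vstack([_band_detail(e, spec.effect_scale)
                                 for e in idio])
                idio = idio - lam * own + lam * shared[labels]
            x = a * glob[None, :] + b * mods[labels] + c * idio
            data.append(x.T)  # timepoints x regions
            ids.append(f"{prefix}{s + 1:03d}")
            groups.append(group)
    gt = GroundTruth(
        target_control=spec.target_matrix("control"),
        target_patient=spec.target_matrix("patient"),
        module_labels=labels,
        hurst=spec.hurst,
        effect_scale=spec.effect_scale,
        group_effect=spec.group_effect,
    )
    return Cohort(
        data=np.array(data), subject_ids=ids, groups=groups,
        tr_seconds=spec.tr_seconds, ground_truth=gt, spec=spec,
    )


def estimate_hurst(x, decomp: WaveletDecomposition | None = None,
                   filt=None, levels: int | None = None) -> float:
    """Wavelet-variance log-regression estimate of the Hurst exponent.

    For fGn the level-j wavelet variance scales as tau_j^(2H-2) with
    tau_j = 2^(j-1) (slope -1 for white noise, flattening as memory
    lengthens); the slope of log2(variance) on log2(tau_j) across
    scales therefore estimates 2H - 2.  Requires at least 3 usable
    scales.
    """
    if decomp is None:
        x = np.asarray(x, dtype=float)
        if filt is None:
            filt = make_filter("LA", 8)
        if levels is None:
            levels = max(3, min(int(np.log2(x.size)) - 3, 6))
        decomp = modwt(x, filt, levels)
    if decomp.levels < 3:
        raise ValueError("need at least 3 scales to estimate the Hurst exponent")
    # use interior (non-boundary) coefficients where enough remain: the
    # circular wrap turns any trend into a jump that only they escape
    variances = []
    masks = decomp.boundary_mask_per_scale or [None] * decomp.levels
    for w, mask in zip(decomp.coeffs_per_scale, masks):
        if mask is not None and (~mask).sum() >= 16:
            w = w[~mask]
        variances.append(w @ w / w.size)
    variances = np.array(variances)
    if np.any(variances <= 0):
        raise ValueError("degenerate (zero-variance) wavelet coefficients")
    log_tau = np.arange(decomp.levels)  # log2(2^(j-1))
    slope = np.polyfit(log_tau, np.log2(variances), 1)[0]
    return float((slope + 2.0) / 2.0)
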