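"""Band-wise common spatial patterns (CSP) and log-variance features.

CSP finds spatial filters w maximizing the ratio of class-conditional
band-limited variances, via the generalized eigenproblem
``C1 w = lambda (C1 + C2) w``.  Filters are scaled so that
``W (C1 + C2) W^T = I`` (rows of W are filters).  Per analysis band the m
most class-1-dominant and m most class-2-dominant filters are kept; each
trial is then summarized by the log of each projection's variance
normalized by the within-band total, giving the 1 x N feature vector with
``N = 4 * m`` over the mu and beta bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps

from .synth import BETA_BAND, LABELS, MU_BAND, Trial, TrialSet

DEFAULT_BANDS = (MU_BAND, BETA_BAND)

_RIDGE = 1e-8  # regularization on the composite covariance
_LOG_FLOOR = 1e-12  # guard for zero-variance projections


def bandpass(samples: np.ndarray, sampling_rate_hz: float,
             band: tuple[float, float]) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis."""
    sos = sps.butter(2, band, btype="bandpass", fs=sampling_rate_hz, output="sos")
    return sps.sosfiltfilt(sos, samples, axis=-1)


@dataclass(frozen=True)
class ClassCovariances:
    """Trace-normalized mean spatial covariances, one per class (left, right)."""

    cov_left: np.ndarray
    cov_right: np.ndarray
    n_left: int
    n_right: int

    @property
    def cov_per_class(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.cov_left, self.cov_right)


@dataclass(frozen=True)
class CSPFilterBlock:
    """Filters for one band: rows are spatial filters, 2m of them."""

    filters: np.ndarray  # [2m x n_ch]
    eigenvalues: np.ndarray  # class-left eigenvalues for each kept filter
    band: tuple[float, float]
    m: int


@dataclass(frozen=True)
class CSPModel:
    """Per-band CSP filter blocks; feature length is ``4 * m`` for 2 bands."""

    blocks: tuple[CSPFilterBlock, ...]
    sampling_rate_hz: float

    @property
    def bands(self) -> tuple[tuple[float, float], ...]:
        return tuple(b.band for b in self.blocks)

    @property
    def m(self) -> int:
        return self.blocks[0].m

    @property
    def n_features(self) -> int:
        return sum(2 * b.m for b in self.blocks)


def _trial_covariance(samples: np.ndarray) -> np.ndarray:
    c = samples @ samples.T
    return c / np.trace(c)


def class_covariances(trials: TrialSet, band: tuple[float, float]) -> ClassCovariances:
    """Band-pass every trial, average trace-normalized spatial covariances per class."""
    fs = trials.config.sampling_rate_hz
    per_class: dict[str, list[np.ndarray]] = {lab: [] for lab in LABELS}
    for trial in trials:
        filtered = bandpass(trial.samples, fs, band)
        per_class[trial.label].append(_trial_covariance(filtered))
    for lab, covs in per_class.items():
        if not covs:
            raise ValueError(f"class {lab!r} has zero trials")
    mean = {lab: np.mean(covs, axis=0) for lab, covs in per_class.items()}
    sym = {lab: 0.5 * (c + c.T) for lab, c in mean.items()}
    return ClassCovariances(
        cov_left=sym["left"], cov_right=sym["right"],
        n_left=len(per_class["left"]), n_right=len(per_class["right"]),
    )


def fit_csp(covs: ClassCovariances, m: int,
            band: tuple[float, float] = MU_BAND) -> CSPFilterBlock:
    """Solve ``C1 w = lambda (C1+C2) w`` and keep the m top / m bottom filters.

    Eigenvectors are scaled so ``W (C1+C2) W^T = I``.  A small ridge
    (1e-8 x I) regularizes a near-singular composite covariance.
    """
    c1, c2 = covs.cov_per_class
    n_ch = c1.shape[0]
    if 2 * m > n_ch:
        raise ValueError(f"2m = {2 * m} filters exceed {n_ch} channels")
    composite = c1 + c2 + _RIDGE * np.eye(n_ch)
    try:
        eigvals, eigvecs = sla.eigh(c1, composite)
    except sla.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "composite covariance is singular; increase trials or channels"
        ) from exc
    order = np.argsort(eigvals)[::-1]  # descending: class-left variance first
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = np.concatenate([np.arange(m), np.arange(n_ch - m, n_ch)])
    return CSPFilterBlock(
        filters=eigvecs[:, keep].T, eigenvalues=eigvals[keep], band=band, m=m,
    )


def fit_csp_model(trials: TrialSet,
                  bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
                  m: int = 1) -> CSPModel:
    """Fit one CSP filter block per analysis band."""
    blocks = tuple(
        fit_csp(class_covariances(trials, band), m, band=band) for band in bands
    )
    return CSPModel(blocks=blocks, sampling_rate_hz=trials.config.sampling_rate_hz)


def csp_features(trial: Trial | np.ndarray, model: CSPModel) -> np.ndarray:
    """1 x N log-variance feature vector (N = 4m for the two default bands).

    Per band: band-pass, project through the 2m filters, and take the log of
    each projection's variance normalized by the within-band total.
    """
    samples = trial.samples if isinstance(trial, Trial) else np.asarray(trial, float)
    feats = []
    for block in model.blocks:
        filtered = bandpass(samples, model.sampling_rate_hz, block.band)
        projected = block.filters @ filtered
        variances = projected.var(axis=1)
        total = variances.sum()
        normalized = variances / total if total > 0 else variances
        feats.append(np.log(np.maximum(normalized, _LOG_FLOOR)))
    return np.concatenate(feats)


def csp_feature_matrix(trials: TrialSet, model: CSPModel) -> np.ndarray:
    """Stack per-trial feature vectors into [n_trials x N]."""
    return np.stack([csp_features(t, model) for t in trials], axis=0)
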