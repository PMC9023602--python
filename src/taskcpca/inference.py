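"""Inference on spatial loadings: bootstrap significance and
phase-randomization surrogates.

Bootstrap: subjects are resampled with replacement, the group CPCA is
refitted per replicate, replicate components are aligned to the
reference solution by greedy maximal-|correlation| matching with sign
flips, and each region's loading is tested with the normal
approximation z = loading / bootstrap SE (two-sided).  The analytic z
ratio makes very small thresholds (p < 1e-4) reachable at practical
replicate counts.

Phase randomization: every region's series is Fourier transformed, the
positive-frequency coefficients are multiplied by random unit phases
*shared across regions*, and the series inverse-transformed.  This
preserves each region's power spectrum and all cross-spectral
magnitudes (hence zero-lag spatial covariance) while destroying any
locking to event timing — the stimulus-independence null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ParcellatedBold, ValidationError
from .cpca import CPCAResults, fit_group_cpca

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdedMap",
    "bootstrap_loadings",
    "threshold_map",
    "phase_randomize",
    "align_components",
]


def align_components(
    reference: np.ndarray, replicate: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one matching of replicate to reference columns by
    maximal |correlation|, with sign flips; ties broken by column order.

    Returns (permutation, signs) such that
    ``replicate[:, permutation] * signs`` aligns with the reference.
    """
    K = reference.shape[1]
    corr = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            a, b = reference[:, i], replicate[:, j]
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            corr[i, j] = (a @ b) / denom if denom > 0 else 0.0
    perm = np.full(K, -1)
    signs = np.ones(K)
    used: set[int] = set()
    abs_corr = np.abs(corr)
    # greedy: repeatedly take the largest remaining |correlation|
    for _ in range(K):
        best = -1.0
        bi = bj = -1
        for i in range(K):
            if perm[i] >= 0:
                continue
            for j in range(K):
                if j in used:
                    continue
                if abs_corr[i, j] > best + 1e-15:
                    best, bi, bj = abs_corr[i, j], i, j
        perm[bi] = bj
        used.add(bj)
        signs[bi] = 1.0 if corr[bi, bj] >= 0 else -1.0
    return perm, signs


@dataclass
class ThresholdedMap:
    """Bootstrap-thresholded spatial map for one component."""

    loadings: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    alpha: float
    region_labels: list[str] | None = None

    def thresholded_loadings(self) -> np.ndarray:
        """Loadings with subthreshold regions rendered as zero."""
        return np.where(self.mask, self.loadings, 0.0)

    def to_frame(self) -> pd.DataFrame:
        labels = self.region_labels or [
            f"region{i:03d}" for i in range(len(self.loadings))
        ]
        return pd.DataFrame(
            {
                "region": labels,
                "loading": self.loadings,
                "se": self.se,
                "z": self.z,
                "p": self.p,
                "mask": self.mask.astype(int),
            }
        )


def bootstrap_loadings(
    zhat_list: list[np.ndarray],
    reference: CPCAResults,
    n_boot: int = 500,
    rng_seed=None,
    max_failure_fraction: float = 0.10,
) -> dict:
    """Bootstrap SEs and p-values for the retained loading columns.

    Returns a dict with ``se``, ``z``, ``p`` (regions x retained) and
    ``n_effective`` replicates.  Replicates whose refit fails are
    dropped and logged; more than ``max_failure_fraction`` failures is
    an error.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be at least 100")
    rng = np.random.default_rng(rng_seed)
    n_sub = len(zhat_list)
    K = reference.retained
    ref = reference.loadings[:, :K]
    boots = np.empty((n_boot, ref.shape[0], K))
    failures = 0
    kept = 0
    for b in range(n_boot):
        idx = rng.integers(0, n_sub, size=n_sub)
        try:
            rep = fit_group_cpca(
                [zhat_list[i] for i in idx], n_components=K, flag_global=False
            )
        except (np.linalg.LinAlgError, ValidationError) as err:  # pragma: no cover
            failures += 1
            logger.warning("bootstrap replicate %d failed: %s", b, err)
            continue
        perm, signs = align_components(ref, rep.loadings[:, :K])
        boots[kept] = rep.loadings[:, perm] * signs
        kept += 1
    if failures > max_failure_fraction * n_boot:
        raise ValidationError(
            f"{failures}/{n_boot} bootstrap replicates failed to fit"
        )
    boots = boots[:kept]
    se = boots.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, ref / se, np.inf * np.sign(ref))
    p = 2.0 * stats.norm.sf(np.abs(z))
    degenerate = np.sum(se <= 0)
    if degenerate:
        logger.warning(
            "%d region/component cells have zero bootstrap SE (degenerate "
            "resampling); their p-values are 0", degenerate,
        )
    return {"se": se, "z": z, "p": p, "n_effective": kept, "replicates": boots}


def threshold_map(
    loadings: np.ndarray,
    p_values: np.ndarray,
    alpha: float = 1e-4,
    se: np.ndarray | None = None,
    region_labels: list[str] | None = None,
) -> ThresholdedMap:
    """Binary suprathreshold mask at ``p < alpha``.

    Subthreshold loadings are rendered as zero in the thresholded map
    but retained in the full output.
    """
    loadings = np.asarray(loadings, dtype=float)
    p_values = np.asarray(p_values, dtype=float)
    if loadings.shape != p_values.shape:
        raise ValidationError("loadings and p-values must have equal length")
    if se is None:
        se = np.full_like(loadings, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = stats.norm.isf(p_values / 2.0) * np.sign(loadings)
    return ThresholdedMap(
        loadings=loadings,
        se=np.asarray(se, dtype=float),
        z=z,
        p=p_values,
        mask=p_values < alpha,
        alpha=alpha,
        region_labels=region_labels,
    )


def phase_randomize(bold: ParcellatedBold, rng_seed=None) -> ParcellatedBold:
    """Shared-phase Fourier surrogate of one subject's run.

    All regions receive the same random phase rotation at each positive
    frequency, so per-region power spectra and cross-spectral
    magnitudes are preserved exactly while event-locking is destroyed.
    Constant series are returned unchanged (their spectrum is zero away
    from DC).
    """
    data = bold.data
    n = data.shape[0]
    if n < 8:
        raise ValidationError("phase randomization needs at least 8 volumes")
    rng = np.random.default_rng(rng_seed)
    spec = np.fft.rfft(data, axis=0)
    n_freq = spec.shape[0]
    phases = np.ones(n_freq, dtype=complex)
    # rotate strictly positive, non-Nyquist frequencies; DC (and Nyquist
    # for even n) must stay real
    hi = n_freq - 1 if n % 2 == 0 else n_freq
    k = hi - 1
    phases[1:hi] = np.exp(2j * np.pi * rng.random(k))
    surrogate = np.fft.irfft(spec * phases[:, None], n=n, axis=0)
    return ParcellatedBold(
        data=surrogate,
        repetition_time=bold.repetition_time,
        region_labels=list(bold.region_labels),
        subject_id=bold.subject_id,
    )
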