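"""Tissue classification by Gaussian-mixture EM with bias-field correction.

One- or two-channel (T1, T2-FLAIR) images are classified into four classes
(background, CSF, GM, WM) by expectation-maximization for a Gaussian mixture
with diagonal covariance across channels, interleaved with re-estimation of a
smooth multiplicative bias field per channel (low-order 3-D polynomial fitted
to the log-ratio of observed to expected intensity). No spatial tissue priors
are used: class identity is resolved after convergence by ranking the
bias-corrected T1 class means (CSF < GM < WM, background darkest).

Total intracranial volume (TIV) is the summed GM+WM+CSF probability times the
voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.cluster.vq import kmeans2

from .volume import Volume

__all__ = ["TissueSegmentation", "SegmentationError", "segment_em", "total_intracranial_volume"]

_VAR_FLOOR = 1e-8
_CLASS_ORDER = ("background", "csf", "gm", "wm")  # ascending T1 mean


class SegmentationError(ValueError):
    pass


@dataclass
class TissueSegmentation:
    """EM result: per-class probability maps plus bias model and class stats."""

    probabilities: dict[str, Volume]          # keys: background, csf, gm, wm
    bias_fields: list[Volume]                 # one per channel, strictly positive
    bias_corrected: list[Volume]              # raw / bias, one per channel
    class_means: dict[str, np.ndarray]        # per class, one value per channel
    class_sds: dict[str, np.ndarray]
    mixing_weights: dict[str, float]
    convergence: list[dict] = field(default_factory=list)
    converged: bool = True

    @property
    def grid(self) -> Volume:
        return self.probabilities["gm"]

    def hard_labels(self) -> Volume:
        """Argmax labels coded as in the phantom module (0=bg,1=csf,2=gm,3=wm)."""
        stack = np.stack([self.probabilities[c].data for c in _CLASS_ORDER])
        return self.grid.like(np.argmax(stack, axis=0).astype(np.int16))

    def brain_probability(self) -> Volume:
        p = sum(self.probabilities[c].data for c in ("csf", "gm", "wm"))
        return self.grid.like(p)


def _poly_basis(shape: tuple[int, ...], order: int) -> np.ndarray:
    """Monomials of total degree <= order over [-1, 1]^3, shape (n_basis, n_voxels)."""
    axes = [np.linspace(-1, 1, s) for s in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    rows = []
    for px, py, pz in product(range(order + 1), repeat=3):
        if px + py + pz <= order:
            rows.append((grids[0] ** px * grids[1] ** py * grids[2] ** pz).ravel())
    return np.asarray(rows)


def _log_gauss(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)


def _init_means(data: np.ndarray, n_classes: int, seed: int) -> np.ndarray:
    """k-means on evenly spaced T1 intensity quantiles.

    Clustering quantile *values* (rather than raw voxels) flattens the
    histogram so a dominant background mass cannot swallow several classes;
    channel-1 means then come from the induced T1 assignment.
    """
    rng = np.random.default_rng(seed)
    t1 = data[:, 0]
    lo, hi = np.quantile(t1, (0.001, 0.999))
    support = np.linspace(lo, hi, 999)
    seeds = lo + (hi - lo) * (np.arange(n_classes) + 0.5) / n_classes
    centers0, _ = kmeans2(support[:, None], seeds[:, None], minit="matrix", seed=rng)
    centers0 = np.sort(centers0.ravel())
    means = np.empty((n_classes, data.shape[1]))
    assign = np.argmin(np.abs(t1[:, None] - centers0[None, :]), axis=1)
    for k in range(n_classes):
        sel = assign == k
        means[k] = data[sel].mean(axis=0) if sel.any() else np.quantile(data, (k + 0.5) / n_classes, axis=0)
    return means


def segment_em(
    channels: list[Volume] | Volume,
    n_classes: int = 4,
    bias_order: int = 3,
    init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 60,
    bias_update_every: int = 4,
    seed: int = 0,
) -> TissueSegmentation:
    """Fit the Gaussian-mixture/bias model to one or two aligned channels.

    ``init`` may supply class means (n_classes x n_channels, any order);
    otherwise k-means on intensity quantiles is used. The bias field is a
    polynomial of total degree ``bias_order`` per channel (0 disables
    correction). A warning entry is recorded in the convergence log if the
    relative log-likelihood change has not dropped below ``tol`` by
    ``max_iter``.
    """
    if isinstance(channels, Volume):
        channels = [channels]
    if not 1 <= len(channels) <= 2:
        raise SegmentationError("segment_em accepts 1 or 2 channels")
    grid = channels[0]
    for ch in channels[1:]:
        if not grid.same_grid(ch):
            raise SegmentationError("channels must share grid and affine")
    raw = np.stack([ch.data.astype(float).ravel() for ch in channels], axis=1)  # V x C
    if not np.all(np.isfinite(raw)):
        raise SegmentationError("input contains non-finite voxels")
    n_vox, n_chan = raw.shape
    shape = grid.shape

    if init is None:
        means = _init_means(raw, n_classes, seed)
    else:
        means = np.atleast_2d(np.asarray(init, dtype=float))
        if means.shape != (n_classes, n_chan):
            raise SegmentationError(f"init means must have shape {(n_classes, n_chan)}")
        means = means.copy()
    variances = np.full((n_classes, n_chan), raw.var(axis=0) / n_classes**2 + _VAR_FLOOR)
    weights = np.full(n_classes, 1.0 / n_classes)

    basis = _poly_basis(shape, bias_order) if bias_order > 0 else None
    log_bias = np.zeros((n_chan, n_vox))
    corrected = raw.copy()

    log: list[dict] = []
    prev_ll = -np.inf
    converged = False
    resp = np.empty((n_vox, n_classes))
    for it in range(max_iter):
        # E-step
        logp = np.empty((n_vox, n_classes))
        for k in range(n_classes):
            lg = np.log(weights[k] + 1e-300)
            for c in range(n_chan):
                lg = lg + _log_gauss(corrected[:, c], means[k, c], variances[k, c])
            logp[:, k] = lg
        m = logp.max(axis=1)
        np.exp(logp - m[:, None], out=resp)
        norm = resp.sum(axis=1)
        ll = float((m + np.log(norm)).mean())
        resp /= norm[:, None]

        # M-step
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n_vox
        means = (resp.T @ corrected) / nk[:, None]
        for k in range(n_classes):
            d2 = (corrected - means[k]) ** 2
            variances[k] = (resp[:, k] @ d2) / nk[k] + _VAR_FLOOR

        bias_updated = False
        if basis is not None and (it + 1) % bias_update_every == 0:
            bias_updated = _update_bias(raw, corrected, resp, means, basis, log_bias)

        rel = abs(ll - prev_ll) / (abs(prev_ll) + 1e-12)
        log.append({"iter": it, "loglik": ll, "bias_updated": bias_updated})
        if it > 0 and not bias_updated and rel < tol:
            converged = True
            break
        prev_ll = ll

    if not converged:
        log.append({"warning": f"no convergence after {max_iter} iterations"})

    # order classes by bias-corrected T1 mean: background < CSF < GM < WM
    order = np.argsort(means[:, 0])
    names = (_CLASS_ORDER[:n_classes] if n_classes <= 4
             else _CLASS_ORDER + tuple(f"class{i}" for i in range(4, n_classes)))
    probs = {
        name: grid.like(resp[:, order[i]].reshape(shape)) for i, name in enumerate(names)
    }
    bias_fields = [grid.like(np.exp(log_bias[c]).reshape(shape)) for c in range(n_chan)]
    bias_corrected = [grid.like(corrected[:, c].reshape(shape)) for c in range(n_chan)]
    return TissueSegmentation(
        probabilities=probs,
        bias_fields=bias_fields,
        bias_corrected=bias_corrected,
        class_means={name: means[order[i]].copy() for i, name in enumerate(names)},
        class_sds={name: np.sqrt(variances[order[i]]) for i, name in enumerate(names)},
        mixing_weights={name: float(weights[order[i]]) for i, name in enumerate(names)},
        convergence=log,
        converged=converged,
    )


def _update_bias(
    raw: np.ndarray,
    corrected: np.ndarray,
    resp: np.ndarray,
    means: np.ndarray,
    basis: np.ndarray,
    log_bias: np.ndarray,
) -> bool:
    """Refit the multiplicative bias per channel from the responsibility-weighted
    log-ratio of observed to reconstructed intensity; zero-mean in log space."""
    n_chan = raw.shape[1]
    # weight: voxels explained by bright classes carry the bias information;
    # near-zero expected intensity makes the log-ratio meaningless.
    for c in range(n_chan):
        expected = resp @ means[:, c]
        good = expected > 0.05 * np.abs(means[:, c]).max()
        if good.sum() < basis.shape[0] * 10:
            return False
        ratio = np.clip(raw[good, c] / expected[good], 0.2, 5.0)
        a = basis[:, good]
        coef, *_ = np.linalg.lstsq((a * 1.0).T, np.log(ratio), rcond=None)
        lb = basis.T @ coef
        lb -= lb[good].mean()
        log_bias[c] = lb
        corrected[:, c] = raw[:, c] / np.exp(lb)
    return True


def total_intracranial_volume(seg: TissueSegmentation, voxel_volume_mm3: float | None = None) -> float:
    """TIV in mL: summed GM+WM+CSF probability times voxel volume."""
    if voxel_volume_mm3 is None:
        voxel_volume_mm3 = seg.grid.voxel_volume_mm3
    total = float(sum(seg.probabilities[c].data.sum() for c in ("gm", "wm", "csf")))
    return total * voxel_volume_mm3 / 1000.0
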