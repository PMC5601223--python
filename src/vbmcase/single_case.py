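"""Single-subject-versus-control-group voxelwise statistics.

One patient map is compared against a group of control maps by ordinary
least squares with design columns [intercept, patient indicator, centered
nuisance covariates]; the t statistic of the patient indicator with
df = n - rank(X) reduces exactly to the Crawford-Howell single-case t when
no covariates are present.

Suprathreshold voxels are extracted at an uncorrected t-quantile threshold
or with family-wise-error control by Bonferroni or by random-field theory
(expected Euler characteristic of a t field, with field smoothness
estimated from standardized residuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy import optimize
from scipy import stats as sps
from scipy.special import gammaln

from .volume import Volume

__all__ = [
    "DesignSpec",
    "TMap",
    "Cluster",
    "ClusterSet",
    "crawford_howell_t",
    "single_case_glm",
    "estimate_smoothness_fwhm",
    "resel_counts",
    "rft_critical_t",
    "threshold_map",
]

TAILS = ("one_tailed_increase", "two_tailed")
_4LN2 = 4.0 * np.log(2.0)


@dataclass
class DesignSpec:
    """Nuisance covariates and tail convention for one map kind.

    Age enters every design; TIV enters only the volumetric (GMC/GMV)
    analyses. Junction and nFSI maps are tested one-tailed for increases
    only; GMC/GMV two-tailed for focal hypertrophy and atrophy.
    """

    map_kind: str = "GMC"
    tail: str = "two_tailed"
    covariates: np.ndarray | None = None  # (n_controls + 1) x p, patient row LAST
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tail not in TAILS:
            raise ValueError(f"tail must be one of {TAILS}")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if not np.all(np.isfinite(self.covariates)):
                raise ValueError("covariates must be finite")

    @classmethod
    def for_kind(cls, map_kind: str, covariates: np.ndarray | None = None,
                 covariate_names: tuple[str, ...] = ()) -> "DesignSpec":
        tail = "one_tailed_increase" if map_kind in ("JM", "NFSI") else "two_tailed"
        return cls(map_kind=map_kind, tail=tail, covariates=covariates,
                   covariate_names=covariate_names)


@dataclass
class TMap:
    t: Volume
    df: int
    n_controls: int
    design: DesignSpec
    mask: Volume
    residuals: np.ndarray | None = None  # n_subjects x n_mask_voxels


@dataclass
class Cluster:
    voxels: np.ndarray          # (k, 3) int indices
    size: int
    peak_t: float
    peak_ijk: tuple[int, int, int]
    sign: int                   # +1 increase, -1 decrease

    def to_json(self) -> dict:
        return {
            "size": int(self.size),
            "peak_t": float(self.peak_t),
            "peak_ijk": [int(i) for i in self.peak_ijk],
            "sign": int(self.sign),
        }


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: dict[str, Any]
    grid: Volume | None = None

    def __len__(self) -> int:
        return len(self.clusters)

    def any_finding(self) -> bool:
        return len(self.clusters) > 0

    def binary_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, bool)
        for c in self.clusters:
            m[tuple(c.voxels.T)] = True
        return m

    def to_json(self) -> dict:
        return {"threshold": {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                              for k, v in self.threshold.items()},
                "clusters": [c.to_json() for c in self.clusters]}


# --------------------------------------------------------------------- GLM
def crawford_howell_t(x: float, control_values: Sequence[float]) -> tuple[float, int]:
    """Closed-form single-case t: (x - mean) / (sd * sqrt(1 + 1/n)), df = n - 1."""
    c = np.asarray(control_values, dtype=float)
    if c.size < 2:
        raise ValueError("need at least 2 control values")
    s = c.std(ddof=1)
    if s == 0:
        raise ValueError("zero control variance")
    t = (x - c.mean()) / (s * np.sqrt(1.0 + 1.0 / c.size))
    return float(t), int(c.size - 1)


def _design_matrix(n_controls: int, covariates: np.ndarray | None) -> np.ndarray:
    n = n_controls + 1
    cols = [np.ones(n), np.r_[np.zeros(n_controls), 1.0]]
    if covariates is not None:
        cov = np.atleast_2d(covariates)
        if cov.shape[0] != n:
            raise ValueError(f"covariates must have {n} rows (patient last), got {cov.shape[0]}")
        cov = cov - cov.mean(axis=0)
        cols.extend(cov.T)
    return np.column_stack(cols)


def single_case_glm(
    patient_map: Volume | np.ndarray,
    control_maps: Sequence[Volume] | np.ndarray,
    design: DesignSpec | None = None,
    mask: Volume | None = None,
    keep_residuals: bool = True,
) -> TMap:
    """Voxelwise OLS of one patient against >= 3 controls.

    Rows are the controls followed by the patient; the reported t is the
    patient-indicator coefficient over its standard error, df = n - rank(X).
    """
    design = design or DesignSpec()
    if isinstance(patient_map, Volume):
        grid = patient_map
        pat = patient_map.data
        ctrl = np.stack([c.data for c in control_maps])
        for c in control_maps:
            if not grid.same_grid(c):
                raise ValueError("control maps must share the patient grid")
    else:
        pat = np.asarray(patient_map)
        ctrl = np.asarray(control_maps)
        grid = Volume(pat) if pat.ndim == 3 else None
    n_controls = ctrl.shape[0]
    if n_controls < 3:
        raise ValueError("need at least 3 control maps")

    if mask is None:
        mvox = np.ones(pat.shape, bool)
    else:
        mvox = mask.data.astype(bool)
    y = np.vstack([ctrl[:, mvox], pat[mvox][None, :]]).astype(float)  # n x V

    x = _design_matrix(n_controls, design.covariates)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        names = ("intercept", "patient") + tuple(design.covariate_names or
                                                 (f"cov{i}" for i in range(x.shape[1] - 2)))
        raise ValueError(f"rank-deficient design matrix (columns {names})")
    if x.shape[0] <= x.shape[1]:
        raise ValueError("fewer subjects than design columns")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = x.shape[0] - rank
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta[1] / se, 0.0)

    t_full = np.zeros(pat.shape)
    t_full[mvox] = tvals
    mask_vol = (grid.like(mvox.astype(np.uint8)) if grid is not None
                else Volume(mvox.astype(np.uint8)))
    t_vol = grid.like(t_full) if grid is not None else Volume(t_full)
    return TMap(
        t=t_vol,
        df=int(df),
        n_controls=n_controls,
        design=design,
        mask=mask_vol,
        residuals=resid if keep_residuals else None,
    )


# ------------------------------------------------------------- smoothness / RFT
def estimate_smoothness_fwhm(
    residual_maps: np.ndarray | Sequence[Volume],
    mask: Volume | np.ndarray | None = None,
) -> np.ndarray:
    """Per-axis field FWHM (voxels) from standardized residual maps.

    Residuals are standardized to unit variance per voxel across maps; the
    per-axis variance lambda of their first differences gives
    FWHM = sqrt(4 ln 2 / lambda), clipped below at 1 voxel.
    """
    if isinstance(residual_maps, np.ndarray) and residual_maps.ndim == 2:
        raise ValueError("residual maps must be image-shaped (n, x, y, z)")
    if not isinstance(residual_maps, np.ndarray):
        residual_maps = np.stack([r.data for r in residual_maps])
    n = residual_maps.shape[0]
    if n < 10:
        raise ValueError("need at least 10 residual maps")
    shape = residual_maps.shape[1:]
    if mask is None:
        mvox = np.ones(shape, bool)
    else:
        mvox = (mask.data if isinstance(mask, Volume) else mask).astype(bool)

    sd = residual_maps.std(axis=0, ddof=0)
    if np.all(sd[mvox] < 1e-14):
        raise ValueError("residuals are constant; smoothness undefined")
    u = residual_maps / np.where(sd > 1e-14, sd, np.inf)

    fwhm = np.empty(3)
    for ax in range(3):
        pair = mvox & np.roll(mvox, -1, axis=ax)
        sl = [slice(None)] * 3
        sl[ax] = slice(0, shape[ax] - 1)
        pair = pair[tuple(sl)]
        d = np.diff(u, axis=ax + 1)[:, pair]
        lam = float((d**2).mean())
        if lam <= 0:
            raise ValueError("degenerate residual differences")
        fwhm[ax] = max(1.0, np.sqrt(_4LN2 / lam))
    return fwhm


def resel_counts(mask: Volume | np.ndarray, fwhm_vox: Sequence[float] | float) -> tuple[float, float, float, float]:
    """Resel counts (R0..R3) of the mask approximated as a box.

    The mask is replaced by a box with the mask's voxel count and the aspect
    ratio of its bounding box; sides are expressed in units of the per-axis
    FWHM.
    """
    m = (mask.data if isinstance(mask, Volume) else np.asarray(mask)).astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    f = np.broadcast_to(np.asarray(fwhm_vox, dtype=float), (3,))
    idx = np.argwhere(m)
    extents = idx.max(axis=0) - idx.min(axis=0) + 1.0
    scale = (m.sum() / extents.prod()) ** (1.0 / 3.0)
    sides = extents * scale / f
    r1 = float(sides.sum())
    r2 = float(sides[0] * sides[1] + sides[0] * sides[2] + sides[1] * sides[2])
    r3 = float(sides.prod())
    return (1.0, r1, r2, r3)


def _ec_density_t(t: np.ndarray | float, d: int, df: int) -> np.ndarray | float:
    """Expected Euler-characteristic density of a t field, dimension d."""
    t = np.asarray(t, dtype=float)
    c = (1.0 + t**2 / df) ** ((1.0 - df) / 2.0)
    if d == 0:
        return sps.t.sf(t, df)
    if d == 1:
        return np.sqrt(_4LN2) / (2 * np.pi) * c
    if d == 2:
        b = np.exp(gammaln((df + 1) / 2.0) - gammaln(df / 2.0))
        return _4LN2 / (2 * np.pi) ** 1.5 * c * t / np.sqrt(df / 2.0) * b
    if d == 3:
        return _4LN2**1.5 / (2 * np.pi) ** 2 * c * ((df - 1) * t**2 / df - 1.0)
    raise ValueError("dimension must be 0..3")


def expected_ec(t: float, resels: Sequence[float], df: int) -> float:
    return float(sum(r * _ec_density_t(t, d, df) for d, r in enumerate(resels) if r > 0))


def rft_critical_t(resels: Sequence[float], df: int, alpha: float = 0.05) -> float:
    """Smallest t with expected Euler characteristic <= alpha (FWE threshold)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    resels = tuple(float(r) for r in resels)
    if len(resels) != 4 or any(r < 0 for r in resels) or not any(r > 0 for r in resels):
        raise ValueError("resel counts must be four non-negative numbers, at least one positive")
    if df < 4:
        raise ValueError("df must be >= 4")

    def f(t: float) -> float:
        return expected_ec(t, resels, df) - alpha

    # the EC curve is non-monotone near t=0 (the 3-D density changes sign);
    # the FWE threshold is the upper-tail crossing, found from above.
    hi = 10.0
    while f(hi) > 0 and hi < 1e4:
        hi *= 2.0
    if f(hi) > 0:
        raise ValueError("expected EC does not drop below alpha; check resel counts")
    grid = np.linspace(hi, 0.5, 512)
    vals = np.array([f(t) for t in grid])
    pos = np.nonzero(vals > 0)[0]
    if pos.size == 0:
        # search volume so small that EC < alpha everywhere above 0.5:
        # fall back to the pointwise quantile (exact for a single 0-dim resel)
        return float(sps.t.isf(alpha, df))
    i = pos[0]  # first positive scanning downward from hi
    return float(optimize.brentq(f, grid[i], grid[i - 1], xtol=1e-6))


# ------------------------------------------------------------- thresholding
def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), int)
    if connectivity == 6:
        return ndi.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndi.generate_binary_structure(3, 2)
    raise ValueError("connectivity must be 6, 18 or 26")


def _extract(tdata: np.ndarray, above: np.ndarray, sign: int, struct: np.ndarray,
             min_cluster: int) -> list[Cluster]:
    lab, n = ndi.label(above, structure=struct)
    out = []
    for i in range(1, n + 1):
        vox = np.argwhere(lab == i)
        if len(vox) < max(1, min_cluster):
            continue
        vals = sign * tdata[tuple(vox.T)]
        j = int(np.argmax(vals))
        out.append(Cluster(voxels=vox, size=len(vox), peak_t=float(sign * vals[j]),
                           peak_ijk=tuple(int(v) for v in vox[j]), sign=sign))
    return out


def threshold_map(
    tmap: TMap,
    mode: str = "uncorrected",
    alpha: float = 1e-4,
    min_cluster: int = 0,
    connectivity: int = 26,
    fwhm_vox: Sequence[float] | None = None,
    per_side_alpha: bool = True,
) -> ClusterSet:
    """Extract suprathreshold clusters at the named threshold.

    ``mode``: 'uncorrected' (t quantile at alpha), 'fwe_bonferroni'
    (alpha / n mask voxels) or 'fwe_rft' (expected-Euler-characteristic
    threshold; smoothness taken from ``fwhm_vox`` or estimated from the
    TMap residuals). Two-tailed designs threshold both signs, by default
    each side at the stated alpha.
    """
    mvox = tmap.mask.data.astype(bool)
    if not mvox.any():
        raise ValueError("empty analysis mask")
    n_mask = int(mvox.sum())
    two_tailed = tmap.design.tail == "two_tailed"
    side_alpha = alpha if (per_side_alpha or not two_tailed) else alpha / 2.0

    if mode == "uncorrected":
        crit = float(sps.t.isf(side_alpha, tmap.df))
    elif mode == "fwe_bonferroni":
        crit = float(sps.t.isf(side_alpha / n_mask, tmap.df))
    elif mode == "fwe_rft":
        if fwhm_vox is None:
            if tmap.residuals is None:
                raise ValueError("fwe_rft needs residuals or an explicit fwhm_vox")
            resid_imgs = np.zeros((tmap.residuals.shape[0], *tmap.mask.shape))
            resid_imgs[:, mvox] = tmap.residuals
            fwhm_vox = estimate_smoothness_fwhm(resid_imgs, tmap.mask)
        crit = rft_critical_t(resel_counts(tmap.mask, fwhm_vox), tmap.df, side_alpha)
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")

    struct = _connectivity_structure(connectivity)
    tdata = np.where(mvox, tmap.t.data, 0.0)
    clusters = _extract(tdata, tdata > crit, +1, struct, min_cluster)
    if two_tailed:
        clusters += _extract(tdata, tdata < -crit, -1, struct, min_cluster)

    descriptor = {
        "mode": mode,
        "alpha": alpha,
        "per_side_alpha": bool(per_side_alpha),
        "critical_t": crit,
        "tail": tmap.design.tail,
        "df": tmap.df,
        "connectivity": connectivity,
        "min_cluster": min_cluster,
        "map_kind": tmap.design.map_kind,
    }
    return ClusterSet(clusters=clusters, threshold=descriptor, grid=tmap.t)
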