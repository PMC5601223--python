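"""Diagnostic evaluation of the post-processing maps.

Implements the study-level bookkeeping: leave-one-out specificity over
controls (a control with any suprathreshold cluster is a false positive),
concordant/discordant classification of clusters against a target region
(resection mask, hypothesis lobe, or for phantoms the planted lesion),
proportions with 95% confidence intervals, 2x2 odds ratios for surgical
outcome, and spatial colocalization of maps (direct voxel contact).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Sequence

import numpy as np
from scipy import ndimage as ndi
from statsmodels.stats.proportion import proportion_confint

from .single_case import ClusterSet, DesignSpec, single_case_glm, threshold_map
from .volume import Volume

__all__ = [
    "ConcordanceCount",
    "ProportionResult",
    "ORResult",
    "proportion_with_ci",
    "odds_ratio_woolf",
    "classify_clusters",
    "map_colocalization",
    "loo_specificity",
]


@dataclass
class ConcordanceCount:
    subject_id: str
    map_kind: str
    threshold: dict[str, Any]
    n_clusters_total: int
    concordant: int
    discordant: int

    def __post_init__(self) -> None:
        if self.concordant + self.discordant != self.n_clusters_total:
            raise ValueError("concordant + discordant must equal the cluster total")

    @property
    def patient_concordant(self) -> bool:
        return self.concordant > 0

    @property
    def patient_discordant(self) -> bool:
        return self.discordant > 0


@dataclass
class ProportionResult:
    k: int
    n: int
    estimate_pct: float
    ci_low_pct: float
    ci_high_pct: float
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError("need 0 <= k <= n")


@dataclass
class ORResult:
    table: tuple[float, float, float, float]  # a, b, c, d
    odds_ratio: float
    ci_low: float
    ci_high: float
    haldane_corrected: bool = False


def proportion_with_ci(k: int, n: int, method: str = "wilson", conf: float = 0.95) -> ProportionResult:
    """Proportion as a percentage with a 95% CI (Wilson or Clopper-Pearson)."""
    if n == 0:
        raise ValueError("n must be positive")
    if method not in ("wilson", "clopper_pearson"):
        raise ValueError(f"unknown CI method {method!r}")
    sm_method = "wilson" if method == "wilson" else "beta"
    lo, hi = proportion_confint(k, n, alpha=1.0 - conf, method=sm_method)
    return ProportionResult(
        k=int(k), n=int(n),
        estimate_pct=100.0 * k / n,
        ci_low_pct=100.0 * float(lo),
        ci_high_pct=100.0 * float(hi),
        method=method,
    )


def odds_ratio_woolf(a: float, b: float, c: float, d: float, conf_z: float = 1.96) -> ORResult:
    """Odds ratio (a*d)/(b*c) with Woolf's log-method CI.

    If any cell is zero, the Haldane-Anscombe correction adds 0.5 to every
    cell (flagged in the result). Two zero cells in one row or column leave
    the OR undefined.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    a_, b_, c_, d_ = cells
    if (a_ == 0 and b_ == 0) or (c_ == 0 and d_ == 0) or (a_ == 0 and c_ == 0) or (b_ == 0 and d_ == 0):
        raise ValueError("odds ratio undefined: two zero cells share a row or column")
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt((1.0 / cells).sum())
    return ORResult(
        table=(a, b, c, d),
        odds_ratio=float(or_),
        ci_low=float(np.exp(np.log(or_) - conf_z * se)),
        ci_high=float(np.exp(np.log(or_) + conf_z * se)),
        haldane_corrected=corrected,
    )


def classify_clusters(
    cluster_set: ClusterSet,
    target_mask: Volume | np.ndarray,
    subject_id: str = "",
    rule: str = "any_voxel",
) -> ConcordanceCount:
    """Concordant iff a cluster touches the target region.

    ``rule='any_voxel'``: at least one cluster voxel inside the mask
    (lobar/resection-level granularity); ``rule='peak'``: the peak voxel must
    lie inside.
    """
    tm = (target_mask.data if isinstance(target_mask, Volume) else np.asarray(target_mask)).astype(bool)
    if not tm.any():
        raise ValueError("empty target mask")
    conc = 0
    for cl in cluster_set.clusters:
        if rule == "any_voxel":
            hit = bool(tm[tuple(cl.voxels.T)].any())
        elif rule == "peak":
            hit = bool(tm[cl.peak_ijk])
        else:
            raise ValueError(f"unknown concordance rule {rule!r}")
        conc += int(hit)
    total = len(cluster_set.clusters)
    return ConcordanceCount(
        subject_id=subject_id,
        map_kind=str(cluster_set.threshold.get("map_kind", "")),
        threshold=cluster_set.threshold,
        n_clusters_total=total,
        concordant=conc,
        discordant=total - conc,
    )


def map_colocalization(
    cluster_sets: dict[str, ClusterSet],
    shape: tuple[int, int, int],
    target_mask: Volume | np.ndarray | None = None,
    connectivity: int = 26,
) -> dict[tuple[str, str], dict[str, bool]]:
    """Pairwise map overlap: true iff clusters of two maps share a voxel or are
    directly adjacent (default 26-neighborhood contact).

    When a target mask is given, contact is reported separately inside and
    outside the target region.
    """
    if len(cluster_sets) < 2:
        raise ValueError("need cluster sets for at least 2 map kinds")
    struct = np.ones((3, 3, 3), bool) if connectivity == 26 else ndi.generate_binary_structure(3, 1)
    masks = {k: cs.binary_mask(shape) for k, cs in cluster_sets.items()}
    tm = None
    if target_mask is not None:
        tm = (target_mask.data if isinstance(target_mask, Volume) else np.asarray(target_mask)).astype(bool)
        if tm.shape != shape:
            raise ValueError("target mask grid mismatch")

    out: dict[tuple[str, str], dict[str, bool]] = {}
    kinds = sorted(masks)
    for i, ka in enumerate(kinds):
        dil_a = ndi.binary_dilation(masks[ka], structure=struct)
        for kb in kinds[i + 1:]:
            contact = dil_a & masks[kb]
            entry = {"overlap": bool(contact.any())}
            if tm is not None:
                entry["inside_target"] = bool((contact & tm).any())
                entry["outside_target"] = bool((contact & ~tm).any())
            out[(ka, kb)] = entry
    return out


def loo_specificity(
    control_maps: Sequence[Volume] | np.ndarray,
    map_kind: str = "NFSI",
    mask: Volume | None = None,
    covariates: np.ndarray | None = None,
    covariate_names: tuple[str, ...] = (),
    mode: str = "fwe_bonferroni",
    alpha: float = 0.05,
    min_cluster: int = 0,
    connectivity: int = 26,
    ci_method: str = "wilson",
    threshold_fn: Callable[..., ClusterSet] | None = None,
) -> tuple[ProportionResult, list[bool]]:
    """Leave-one-out specificity: each control tested against the remainder.

    A control with >= 1 suprathreshold cluster is a false positive;
    specificity = true negatives / total, with its CI. Returns the
    proportion and the per-control false-positive flags.
    """
    if isinstance(control_maps, np.ndarray):
        maps = [Volume(control_maps[i]) for i in range(control_maps.shape[0])]
    else:
        maps = list(control_maps)
    n = len(maps)
    if n < 4:
        raise ValueError("leave-one-out specificity needs at least 4 controls")
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if cov is not None and cov.shape[0] != n:
        raise ValueError("one covariate row per control required")

    fp_flags: list[bool] = []
    for i in range(n):
        rest = [maps[j] for j in range(n) if j != i]
        c = None
        if cov is not None:
            c = np.vstack([cov[[j for j in range(n) if j != i]], cov[i][None, :]])
        design = DesignSpec.for_kind(map_kind, covariates=c, covariate_names=covariate_names)
        tmap = single_case_glm(maps[i], rest, design=design, mask=mask)
        if threshold_fn is not None:
            cs = threshold_fn(tmap)
        else:
            cs = threshold_map(tmap, mode=mode, alpha=alpha, min_cluster=min_cluster,
                               connectivity=connectivity)
        fp_flags.append(cs.any_finding())

    tn = n - sum(fp_flags)
    return proportion_with_ci(tn, n, method=ci_method), fp_flags
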