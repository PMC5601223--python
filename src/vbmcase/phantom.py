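"""Synthetic brain phantoms with known ground truth.

The module generates control and patient cohorts in a common template space:
a three-compartment ellipsoidal "brain" (WM core, GM ribbon, CSF shell) is
deformed per subject by a smooth random diffeomorphism with known Jacobian,
modulated by a smooth multiplicative bias field and corrupted by noise.
Patients additionally carry a planted lesion with the MRI signature of a
focal cortical dysplasia: blurring of the gray-white junction on T1, focal
FLAIR hyperintensity, and focal thickening or thinning of the GM ribbon.

Conventions
-----------
The stored :class:`DeformationField` displacement ``u`` maps *template*
coordinates to *native* coordinates (the resampling warp), in voxel units.
"Spatial normalization" of a native image is therefore a single forward
interpolation at ``y + u(y)``; modulation by ``jacobian_det = det(I + Du)``
then satisfies the change-of-variables identity

    integral over template of  M(y + u(y)) * |J(y)|  dy
        =  integral over native of  M(x)  dx

so the modulated gray-matter integral recovers native gray-matter volume.
Native-space rendering inverts the warp once by fixed-point iteration at
simulation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .volume import Volume

__all__ = [
    "LabeledTemplate",
    "DeformationField",
    "LesionSpec",
    "SubjectRecord",
    "VariabilitySpec",
    "CohortConfig",
    "Cohort",
    "ConfigurationError",
    "SimulationError",
    "build_template",
    "sample_subject",
    "plant_fcd",
    "generate_cohort",
    "normalize_to_template",
    "BACKGROUND",
    "CSF",
    "GM",
    "WM",
]

BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
_CLASS_NAMES = {BACKGROUND: "background", CSF: "csf", GM: "gm", WM: "wm"}


class ConfigurationError(ValueError):
    """Raised when phantom geometry or cohort configuration is invalid."""


class SimulationError(RuntimeError):
    """Raised when a requested random deformation cannot be made diffeomorphic."""


# --------------------------------------------------------------------------- types
@dataclass
class LabeledTemplate:
    """Template anatomy: per-voxel tissue labels plus per-class intensity models.

    Intensities are in arbitrary units; the defaults follow the qualitative
    contrast of the two sequences (T1: CSF < GM < WM; FLAIR: CSF suppressed,
    GM brighter than WM).
    """

    labels: Volume
    t1_means: dict[int, float]
    t1_sds: dict[int, float]
    flair_means: dict[int, float]
    flair_sds: dict[int, float]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return self.labels.voxel_size

    def class_mean_image(self, channel: str) -> Volume:
        means = self.t1_means if channel == "t1" else self.flair_means
        lut = np.zeros(max(means) + 1)
        for k, v in means.items():
            lut[k] = v
        return self.labels.like(lut[self.labels.data.astype(int)])

    def brain_mask(self) -> np.ndarray:
        return self.labels.data != BACKGROUND


@dataclass
class DeformationField:
    """Template-to-native resampling warp with its Jacobian determinant.

    ``displacement`` has shape (3, *grid) and is in voxel units; ``jacobian_det``
    is det(I + Du) per voxel and is strictly positive for a diffeomorphism.
    """

    displacement: np.ndarray
    jacobian_det: Volume

    @classmethod
    def identity(cls, like: Volume) -> "DeformationField":
        return cls(np.zeros((3, *like.shape)), like.like(np.ones(like.shape)))


@dataclass
class LesionSpec:
    """Parameters of one planted FCD-like lesion.

    junction_blur: fraction of GM/WM contrast replaced by the midpoint
    intensity in the interface shell (0 = none, 1 = full blur).
    flair_delta: FLAIR offset inside the lesion in units of the WM FLAIR SD.
    thickness_factor: radial GM ribbon scaling (>1 thickening, <1 thinning).
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    junction_blur: float = 0.0
    flair_delta: float = 0.0
    thickness_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ConfigurationError("lesion radius must be > 0")
        if not 0.0 <= self.junction_blur <= 1.0:
            raise ConfigurationError("junction_blur must lie in [0, 1]")
        if self.thickness_factor <= 0:
            raise ConfigurationError("thickness_factor must be > 0")


@dataclass
class SubjectRecord:
    id: str
    group: str  # "control" | "patient"
    age: float
    seed: int
    lesion: LesionSpec | None = None
    tiv_ml: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.group == "control" and self.lesion is not None:
            raise ConfigurationError("controls must not carry a lesion")


@dataclass
class VariabilitySpec:
    """Inter-subject variability of the generator.

    Amplitudes chosen to emulate residual anatomical variability after
    high-dimensional normalization: a few-mm smooth warp, a gentle
    multiplicative bias field, and additive Gaussian noise well below
    tissue contrast.
    """

    deformation_amplitude_mm: float = 2.0
    deformation_smoothness_mm: float = 8.0
    bias_order: int = 2
    bias_amplitude: float = 0.05  # SD of log-bias
    noise_sd_t1: float = 0.02
    noise_sd_flair: float = 0.02
    rician: bool = False


@dataclass
class SubjectData:
    record: SubjectRecord
    t1: Volume
    flair: Volume
    deformation: DeformationField
    true_labels: Volume
    lesion_mask: Volume | None = None


@dataclass
class CohortConfig:
    n_controls: int = 10
    n_patients: int = 0
    age_range: tuple[float, float] = (19.0, 64.0)
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.5
    variability: VariabilitySpec = field(default_factory=VariabilitySpec)
    # lesion parameter ranges sampled uniformly per patient
    lesion_radius_mm: tuple[float, float] = (6.0, 9.0)
    lesion_junction_blur: tuple[float, float] = (0.8, 1.0)
    lesion_flair_delta: tuple[float, float] = (4.0, 6.0)
    lesion_thickness_factor: tuple[float, float] = (1.0, 1.0)


@dataclass
class Cohort:
    template: LabeledTemplate
    subjects: list[SubjectData]
    metadata: pd.DataFrame


# --------------------------------------------------------------------------- template
def build_template(
    shape: Sequence[int] = (64, 64, 64),
    voxel_size_mm: float = 1.5,
    brain_fraction: float = 0.82,
    gm_thickness_mm: float = 4.5,
    csf_thickness_mm: float = 3.0,
    axis_ratios: Sequence[float] = (1.0, 0.92, 0.86),
    t1_means: dict[int, float] | None = None,
    t1_sds: dict[int, float] | None = None,
    flair_means: dict[int, float] | None = None,
    flair_sds: dict[int, float] | None = None,
) -> LabeledTemplate:
    """Build the three-compartment ellipsoidal template.

    The brain is a set of concentric ellipsoids: WM core, a GM ribbon of
    ``gm_thickness_mm``, and a CSF shell of ``csf_thickness_mm``; everything
    outside is background. Deterministic for fixed parameters.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 32:
        raise ConfigurationError("template shape must be 3-D with >= 32 voxels per axis")
    if gm_thickness_mm < 2 * voxel_size_mm:
        raise ConfigurationError(
            f"GM ribbon thickness {gm_thickness_mm} mm is below 2 voxels "
            f"({2 * voxel_size_mm} mm) and cannot form a connected ribbon"
        )

    extent = np.array(shape) * voxel_size_mm
    outer = brain_fraction * extent.min() / 2.0 * np.asarray(axis_ratios, dtype=float)
    gm_outer = outer - csf_thickness_mm
    wm_outer = gm_outer - gm_thickness_mm
    if np.any(wm_outer < 3 * voxel_size_mm):
        raise ConfigurationError("shape too small to contain WM core, GM ribbon and CSF shell")

    center = (np.array(shape) - 1) / 2.0 * voxel_size_mm
    coords = np.meshgrid(*[np.arange(s) * voxel_size_mm for s in shape], indexing="ij")
    # normalized ellipsoidal radius per compartment boundary
    def _inside(semi_axes: np.ndarray) -> np.ndarray:
        r2 = sum(((c - c0) / a) ** 2 for c, c0, a in zip(coords, center, semi_axes))
        return r2 <= 1.0

    labels = np.full(shape, BACKGROUND, dtype=np.int16)
    labels[_inside(outer)] = CSF
    labels[_inside(gm_outer)] = GM
    labels[_inside(wm_outer)] = WM

    for k in (CSF, GM, WM):
        if not np.any(labels == k):
            raise ConfigurationError(f"compartment {_CLASS_NAMES[k]} is empty for this geometry")

    t1_means = dict(t1_means or {BACKGROUND: 0.0, CSF: 0.20, GM: 0.45, WM: 0.75})
    t1_sds = dict(t1_sds or {BACKGROUND: 0.01, CSF: 0.02, GM: 0.02, WM: 0.02})
    flair_means = dict(flair_means or {BACKGROUND: 0.0, CSF: 0.10, GM: 0.60, WM: 0.50})
    flair_sds = dict(flair_sds or {BACKGROUND: 0.01, CSF: 0.02, GM: 0.02, WM: 0.02})
    for sds in (t1_sds, flair_sds):
        if any(s <= 0 for s in sds.values()):
            raise ConfigurationError("all class intensity SDs must be > 0")

    return LabeledTemplate(
        labels=Volume.from_voxel_size(labels, voxel_size_mm),
        t1_means=t1_means,
        t1_sds=t1_sds,
        flair_means=flair_means,
        flair_sds=flair_sds,
    )


# --------------------------------------------------------------------------- deformation
def _jacobian_det(displacement_vox: np.ndarray) -> np.ndarray:
    """det(I + Du) by central finite differences, displacement in voxel units."""
    grads = np.empty((3, 3, *displacement_vox.shape[1:]))
    for i in range(3):
        for j in range(3):
            grads[i, j] = np.gradient(displacement_vox[i], axis=j)
            if i == j:
                grads[i, j] += 1.0
    g = np.moveaxis(grads, (0, 1), (-2, -1))
    return np.linalg.det(g)


def sample_deformation(
    template: LabeledTemplate,
    amplitude_mm: float,
    smoothness_mm: float,
    rng: np.random.Generator,
    max_rescale_attempts: int = 8,
) -> DeformationField:
    """Smooth random displacement field, rescaled until det(I + Du) > 0.

    The field is Gaussian white vector noise smoothed to ``smoothness_mm``,
    zero-meaned and scaled so the RMS displacement magnitude equals
    ``amplitude_mm``.
    """
    shape = template.shape
    vs = template.voxel_size
    if amplitude_mm == 0:
        return DeformationField.identity(template.labels)

    sigma_vox = smoothness_mm / vs
    u = rng.standard_normal((3, *shape))
    for c in range(3):
        u[c] = ndi.gaussian_filter(u[c], sigma=sigma_vox, mode="constant")
        u[c] -= u[c].mean()
    rms = np.sqrt((u**2).sum(axis=0).mean())
    u *= amplitude_mm / rms  # mm
    u_vox = u / vs[:, None, None, None]

    for _ in range(max_rescale_attempts):
        jac = _jacobian_det(u_vox)
        if jac.min() > 0.05:
            return DeformationField(u_vox, template.labels.like(jac))
        u_vox *= 0.7
    raise SimulationError(
        f"deformation amplitude {amplitude_mm} mm could not be made diffeomorphic "
        f"after {max_rescale_attempts} rescaling attempts"
    )


def _invert_displacement(u_vox: np.ndarray, n_iter: int = 20) -> np.ndarray:
    """Fixed-point inverse of x -> x + u(x): returns v with v(x) ~= -u(x + v(x))."""
    grid = np.indices(u_vox.shape[1:]).astype(float)
    v = np.zeros_like(u_vox)
    for _ in range(n_iter):
        coords = grid + v
        for c in range(3):
            v[c] = -ndi.map_coordinates(u_vox[c], coords, order=1, mode="nearest")
    return v


def _sample(data: np.ndarray, displacement_vox: np.ndarray, order: int) -> np.ndarray:
    coords = np.indices(data.shape).astype(float) + displacement_vox
    return ndi.map_coordinates(data.astype(float), coords, order=order, mode="nearest")


def normalize_to_template(native: Volume, deformation: DeformationField, order: int = 1) -> Volume:
    """Resample a native-space image onto the template grid via the known warp."""
    out = _sample(native.data, deformation.displacement, order=order)
    return native.like(out)


def _polynomial_bias(shape: tuple[int, ...], order: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """exp of a random polynomial in normalized coords, log-SD ~= amplitude, mean log 0."""
    if order == 0 or amplitude == 0:
        return np.ones(shape)
    axes = [np.linspace(-1, 1, s) for s in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    logb = np.zeros(shape)
    for px in range(order + 1):
        for py in range(order + 1 - px):
            for pz in range(order + 1 - px - py):
                if px == py == pz == 0:
                    continue
                logb += rng.standard_normal() * grids[0] ** px * grids[1] ** py * grids[2] ** pz
    logb -= logb.mean()
    sd = logb.std()
    if sd > 0:
        logb *= amplitude / sd
    return np.exp(logb)


def sample_subject(
    template: LabeledTemplate,
    record: SubjectRecord,
    variability: VariabilitySpec,
) -> SubjectData:
    """Render one subject: warp, bias, noise — reproducible from ``record.seed``.

    Returns native-space T1/FLAIR, the template-to-native deformation (with
    Jacobian), and the subject's true native labels.
    """
    rng = np.random.default_rng(record.seed)
    deformation = sample_deformation(
        template, variability.deformation_amplitude_mm, variability.deformation_smoothness_mm, rng
    )

    if variability.deformation_amplitude_mm == 0:
        labels = template.labels.data.copy()
    else:
        v = _invert_displacement(deformation.displacement)
        labels = _sample(template.labels.data, v, order=0).astype(np.int16)

    channels = {}
    for chan, noise_sd in (("t1", variability.noise_sd_t1), ("flair", variability.noise_sd_flair)):
        means = template.t1_means if chan == "t1" else template.flair_means
        lut = np.zeros(max(means) + 1)
        for k, m in means.items():
            lut[k] = m
        img = lut[labels]
        bias = _polynomial_bias(template.shape, variability.bias_order, variability.bias_amplitude, rng)
        img = img * bias
        if noise_sd > 0:
            if variability.rician:
                img = np.sqrt(
                    (img + rng.normal(0, noise_sd, img.shape)) ** 2
                    + rng.normal(0, noise_sd, img.shape) ** 2
                )
            else:
                img = img + rng.normal(0, noise_sd, img.shape)
        channels[chan] = template.labels.like(img)

    return SubjectData(
        record=record,
        t1=channels["t1"],
        flair=channels["flair"],
        deformation=deformation,
        true_labels=template.labels.like(labels),
    )


# --------------------------------------------------------------------------- lesion
def _interface_shell(labels: np.ndarray) -> np.ndarray:
    """GM or WM voxels with a 26-neighbor of the other class."""
    struct = np.ones((3, 3, 3), bool)
    gm, wm = labels == GM, labels == WM
    gm_d = ndi.binary_dilation(gm, structure=struct)
    wm_d = ndi.binary_dilation(wm, structure=struct)
    return (gm & wm_d) | (wm & gm_d)


def plant_fcd(
    t1: Volume,
    flair: Volume,
    true_labels: Volume,
    spec: LesionSpec,
    template: LabeledTemplate,
) -> tuple[Volume, Volume, Volume, Volume]:
    """Plant an FCD-like lesion; voxels outside the sphere are untouched.

    Returns (t1', flair', labels', lesion_mask) where lesion_mask marks the
    voxels actually modified by any of the three effects.
    """
    labels = true_labels.data.astype(np.int16).copy()
    vs = true_labels.voxel_size
    center_vox = np.asarray(spec.center_mm) / vs
    ijk = np.round(center_vox).astype(int)
    if np.any(ijk < 0) or np.any(ijk >= np.array(labels.shape)):
        raise ConfigurationError("lesion center outside the image")
    if labels[tuple(ijk)] not in (GM, WM):
        # "on or near the interface": snap to the closest interface voxel
        # within ~3 voxels (per-subject warps shift the template interface)
        shell = np.argwhere(_interface_shell(labels))
        if shell.size == 0:
            raise ConfigurationError("no gray-white interface in this image")
        d2 = ((shell - center_vox) ** 2).sum(axis=1)
        j = int(np.argmin(d2))
        if d2[j] > 3.0**2:
            raise ConfigurationError(
                "lesion center must lie on or near the gray-white interface")
        ijk = shell[j]
        center_vox = ijk.astype(float)

    grid = np.indices(labels.shape)
    dist_mm = np.sqrt(sum(((grid[a] - center_vox[a]) * vs[a]) ** 2 for a in range(3)))
    sphere = dist_mm <= spec.radius_mm
    if np.any(center_vox * vs < spec.radius_mm) or np.any(
        (np.array(labels.shape) - 1 - center_vox) * vs < spec.radius_mm
    ):
        raise ConfigurationError("lesion radius exceeds the image extent around the center")
    brain_in_sphere = sphere & (labels != BACKGROUND)
    if brain_in_sphere.sum() < 0.25 * sphere.sum():
        raise ConfigurationError("lesion radius extends mostly outside the brain")

    t1_out = t1.data.astype(float).copy()
    flair_out = flair.data.astype(float).copy()
    modified = np.zeros(labels.shape, bool)

    # 1. radial thickening / thinning of the GM ribbon by relabeling
    if spec.thickness_factor != 1.0:
        gm_thick_mm = _ribbon_thickness_mm(labels, vs)
        gm_region = labels == GM
        if spec.thickness_factor > 1.0:
            extra = (spec.thickness_factor - 1.0) * gm_thick_mm
            d_to_gm = ndi.distance_transform_edt(~gm_region, sampling=vs)
            grow = sphere & np.isin(labels, (WM, CSF)) & (d_to_gm <= extra)
            _relabel(grow, GM, labels, t1_out, flair_out, template)
            modified |= grow
        else:
            shrink = (1.0 - spec.thickness_factor) * gm_thick_mm / 2.0
            d_to_non = ndi.distance_transform_edt(gm_region, sampling=vs)
            peel = sphere & gm_region & (d_to_non <= shrink)
            d_wm = ndi.distance_transform_edt(labels != WM, sampling=vs)
            d_csf = ndi.distance_transform_edt(labels != CSF, sampling=vs)
            to_wm = peel & (d_wm <= d_csf)
            _relabel(to_wm, WM, labels, t1_out, flair_out, template)
            _relabel(peel & ~to_wm, CSF, labels, t1_out, flair_out, template)
            modified |= peel

    # 2. junction blurring: pull interface-shell T1 toward the GM/WM midpoint
    if spec.junction_blur > 0:
        shell = _interface_shell(labels) & sphere
        mid = 0.5 * (template.t1_means[GM] + template.t1_means[WM])
        t1_out[shell] += spec.junction_blur * (mid - t1_out[shell])
        modified |= shell

    # 3. FLAIR hyperintensity in lesional gray and white matter
    if spec.flair_delta != 0:
        tissue = sphere & np.isin(labels, (GM, WM))
        flair_out[tissue] += spec.flair_delta * template.flair_sds[WM]
        modified |= tissue

    return (
        t1.like(t1_out),
        flair.like(flair_out),
        true_labels.like(labels),
        true_labels.like(modified.astype(np.uint8)),
    )


def _ribbon_thickness_mm(labels: np.ndarray, vs: np.ndarray) -> float:
    """Median GM ribbon thickness, estimated as 2x max in-ribbon EDT."""
    d = ndi.distance_transform_edt(labels == GM, sampling=vs)
    vals = d[labels == GM]
    return float(2.0 * np.percentile(vals, 95)) if vals.size else 0.0


def _relabel(
    where: np.ndarray,
    new_label: int,
    labels: np.ndarray,
    t1: np.ndarray,
    flair: np.ndarray,
    template: LabeledTemplate,
) -> None:
    """Relabel voxels, shifting intensities by the class-mean difference so the
    existing noise/bias realization is preserved."""
    if not np.any(where):
        return
    old = labels[where]
    t1_lut = np.zeros(max(template.t1_means) + 1)
    fl_lut = np.zeros(max(template.flair_means) + 1)
    for k in template.t1_means:
        t1_lut[k] = template.t1_means[k]
        fl_lut[k] = template.flair_means[k]
    t1[where] += t1_lut[new_label] - t1_lut[old]
    flair[where] += fl_lut[new_label] - fl_lut[old]
    labels[where] = new_label


# --------------------------------------------------------------------------- cohort
def pick_interface_center(
    template: LabeledTemplate, radius_mm: float, rng: np.random.Generator
) -> tuple[float, float, float]:
    """A random gray-white interface voxel with the lesion sphere inside the image."""
    labels = template.labels.data
    vs = template.voxel_size
    shell = _interface_shell(labels)
    idx = np.argwhere(shell)
    lo = radius_mm / vs
    hi = np.array(labels.shape) - 1 - lo
    ok = np.all((idx >= lo) & (idx <= hi), axis=1)
    idx = idx[ok]
    if idx.size == 0:
        raise ConfigurationError("no interface voxel can host a lesion of this radius")
    pick = idx[rng.integers(len(idx))]
    return tuple(pick * vs)


def generate_cohort(
    config: CohortConfig,
    master_seed: int,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Generate a full cohort deterministically from ``master_seed``.

    Controls first, then patients; per-subject seeds are spawned from the
    master seed, so the whole cohort is a pure function of (config, seed).
    If ``out_dir`` is given, all images, truth volumes and the metadata TSV
    are written there.
    """
    if config.n_controls < 3:
        raise ConfigurationError("need at least 3 controls for single-case statistics")

    template = build_template(config.shape, config.voxel_size_mm)
    ss = np.random.SeedSequence(master_seed)
    n_total = config.n_controls + config.n_patients
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_total + 1)]
    meta_rng = np.random.default_rng(child_seeds[-1])

    subjects: list[SubjectData] = []
    rows = []
    for i in range(n_total):
        is_patient = i >= config.n_controls
        group = "patient" if is_patient else "control"
        sid = f"{'pat' if is_patient else 'con'}{i - config.n_controls if is_patient else i:03d}"
        age = float(meta_rng.uniform(*config.age_range))
        lesion = None
        if is_patient:
            radius = float(meta_rng.uniform(*config.lesion_radius_mm))
            lesion = LesionSpec(
                center_mm=pick_interface_center(template, radius, meta_rng),
                radius_mm=radius,
                junction_blur=float(meta_rng.uniform(*config.lesion_junction_blur)),
                flair_delta=float(meta_rng.uniform(*config.lesion_flair_delta)),
                thickness_factor=float(meta_rng.uniform(*config.lesion_thickness_factor)),
            )
        record = SubjectRecord(id=sid, group=group, age=age, seed=child_seeds[i], lesion=lesion)
        subj = sample_subject(template, record, config.variability)
        if lesion is not None:
            t1, flair, labels, mask = plant_fcd(subj.t1, subj.flair, subj.true_labels, lesion, template)
            subj = replace(subj, t1=t1, flair=flair, true_labels=labels, lesion_mask=mask)
        subjects.append(subj)
        rows.append(
            {
                "id": sid,
                "group": group,
                "age": round(age, 2),
                "seed": record.seed,
                "lesion_radius_mm": lesion.radius_mm if lesion else "",
                "lesion_junction_blur": lesion.junction_blur if lesion else "",
                "lesion_flair_delta": lesion.flair_delta if lesion else "",
                "lesion_thickness_factor": lesion.thickness_factor if lesion else "",
            }
        )

    metadata = pd.DataFrame(rows)
    cohort = Cohort(template=template, subjects=subjects, metadata=metadata)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.template.labels.save(out / "template_labels.nii.gz")
    cohort.metadata.to_csv(out / "subjects.tsv", sep="\t", index=False)
    for s in cohort.subjects:
        s.t1.save(out / f"{s.record.id}_t1.nii.gz")
        s.flair.save(out / f"{s.record.id}_flair.nii.gz")
        s.true_labels.save(out / f"{s.record.id}_labels.nii.gz")
        s.deformation.jacobian_det.save(out / f"{s.record.id}_jacdet.nii.gz")
        if s.lesion_mask is not None:
            s.lesion_mask.save(out / f"{s.record.id}_lesion.nii.gz")
    return out
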