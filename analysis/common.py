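"""Shared configuration of the demonstration analysis.

One modest cohort (12 controls, 6 patients, 48^3 grid at 1.5 mm) keeps every
numbered script runnable in a couple of minutes on one CPU; the package's
tests exercise larger sweeps.
"""

from pathlib import Path

from vbmcase import phantom as ph

SEED = 20170726
RESULTS = Path(__file__).resolve().parents[1] / "results"

COHORT = ph.CohortConfig(
    n_controls=12,
    n_patients=6,
    shape=(48, 48, 48),
    voxel_size_mm=1.5,
    lesion_radius_mm=(6.0, 9.0),
    lesion_junction_blur=(0.8, 1.0),
    lesion_flair_delta=(4.0, 6.0),
)


def load_cohort() -> ph.Cohort:
    """Regenerate the cohort deterministically (cheaper than re-reading NIfTI)."""
    return ph.generate_cohort(COHORT, master_seed=SEED)
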