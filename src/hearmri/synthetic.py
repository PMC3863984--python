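"""Synthetic normalized infant-brain cohorts for end-to-end testing.

Real inputs to the pipeline are spatially normalized T1 volumes and
per-contrast functional Z/contrast maps.  No such cohort is publicly
deposited, so this module emulates their statistical role: anatomical
volumes are a smooth ellipsoidal "brain" plus fixed-location Gaussian
blobs (SIFT detects blob-like components), where designated discriminative
sites differ in amplitude between the hearing-impaired (HI) and
normal-hearing (NH) groups; contrast maps are spatially smooth noise inside
a brain mask plus group-dependent activation/deactivation sites and
subject-specific nuisance activations.  A 3-level sedation covariate is
assigned per subject, independent of group by default.

Site placement is deterministic given the grid shape: sites sit at the
centers (and, if more are needed, quarter-points) of the interior blocks of
the canonical 20-voxel cube partition, so planted structure survives cube
partitioning.  Planted blobs are mildly anisotropic so that the SIFT
orientation assignment is stable across subjects; discriminative sites
alternate which group they favor, producing both patient-type and
healthy-type structural features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import partition_cubes, save_volume, load_volume

CONTRASTS = ("speech_vs_silence", "speech_vs_tones", "tones_vs_silence")
GROUPS = ("HI", "NH")

#: per-axis anisotropy patterns cycled over sites (units of the blob radius)
_ANISO = (
    (1.5, 1.0, 0.7),
    (0.7, 1.5, 1.0),
    (1.0, 0.7, 1.5),
)


class ConfigurationError(ValueError):
    """Invalid cohort specification."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Amplitudes are in arbitrary map units; the anatomical background has
    amplitude ~1, so ``blob_effect`` ~1 is a strong structural effect and
    ``noise_sd`` is the i.i.d. (structural) / smoothed (functional) noise
    standard deviation on that same scale.
    """

    n_hi: int = 9
    n_nh: int = 10
    grid_shape: tuple[int, int, int] = (60, 60, 40)
    n_discriminative_blobs: int = 4
    blob_effect: float = 0.75
    n_activation_sites: int = 3
    activation_effect: float = 0.75
    noise_sd: float = 0.08
    seed: int = 0
    subject_variability: float = 0.5
    blob_radius: float = 2.5
    n_shared_blobs: int = 3
    n_nuisance_blobs: int = 2
    base_activation: float = 0.5
    sedation_confounded: bool = False
    #: 0 = every subject expresses both markers equally; 1 = subjects
    #: alternate between expressing only the structural or only the
    #: functional group marker (complementary error types across arms)
    modality_balance: float = 0.0

    def validate(self) -> None:
        if self.n_hi < 1 or self.n_nh < 1:
            raise ConfigurationError("need at least one subject per group")
        if len(self.grid_shape) != 3 or any(d < 1 for d in self.grid_shape):
            raise ConfigurationError(f"bad grid shape {self.grid_shape}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_discriminative_blobs < 0 or self.n_activation_sites < 0:
            raise ConfigurationError("site counts must be >= 0")


@dataclass
class Site:
    """A planted signal site: center voxel, which group it favors, sign."""

    center: tuple[float, float, float]
    favored: str  # "HI" or "NH"
    sign: int = 1
    aniso: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    anatomical: np.ndarray
    contrasts: dict[str, np.ndarray]
    sedation: int
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


# ---------------------------------------------------------------------------
# deterministic site placement


def _candidate_points(grid_shape) -> list[tuple[float, float, float]]:
    """Block centers of the canonical 20-cube partition, then quarter-points."""
    cubes = [c for c in partition_cubes(grid_shape, 20) if min(c.extent) >= 20]
    if not cubes:  # grid smaller than one full cube: fall back to all blocks
        cubes = partition_cubes(grid_shape, 20)
    pts = [
        tuple(c.origin[a] + c.extent[a] / 2.0 for a in range(3)) for c in cubes
    ]
    for off in ((-5.0, 5.0, 0.0), (5.0, -5.0, 0.0), (0.0, 5.0, -5.0)):
        for c in cubes:
            if min(c.extent) >= 20:
                pts.append(
                    tuple(c.origin[a] + c.extent[a] / 2.0 + off[a] for a in range(3))
                )
    return pts


def _allocate_sites(spec: CohortSpec):
    pts = _candidate_points(spec.grid_shape)
    need = (
        spec.n_discriminative_blobs
        + spec.n_shared_blobs
        + len(CONTRASTS) * spec.n_activation_sites
    )
    if need > len(pts):
        raise ConfigurationError(
            f"grid {spec.grid_shape} too small for {need} planted sites"
        )
    it = iter(pts)
    structural = [
        Site(next(it), favored=GROUPS[s % 2], aniso=_ANISO[s % len(_ANISO)])
        for s in range(spec.n_discriminative_blobs)
    ]
    shared = [
        Site(next(it), favored="both", aniso=_ANISO[(s + 1) % len(_ANISO)])
        for s in range(spec.n_shared_blobs)
    ]
    functional = {}
    for ci, contrast in enumerate(CONTRASTS):
        functional[contrast] = [
            Site(
                next(it),
                favored=GROUPS[(s + ci) % 2],
                sign=1 if s % 2 == 0 else -1,
                aniso=_ANISO[s % len(_ANISO)],
            )
            for s in range(spec.n_activation_sites)
        ]
    return structural, shared, functional


def structural_sites(spec: CohortSpec) -> list[Site]:
    """Discriminative structural blob sites (fixed given the grid shape)."""
    return _allocate_sites(spec)[0]


def shared_sites(spec: CohortSpec) -> list[Site]:
    """Anatomy blobs present in every subject."""
    return _allocate_sites(spec)[1]


def activation_sites(spec: CohortSpec) -> dict[str, list[Site]]:
    """Per-contrast activation sites with group-dependent amplitude."""
    return _allocate_sites(spec)[2]


# ---------------------------------------------------------------------------
# rendering


def _add_blob(volume, center, radius, amplitude, aniso=(1.0, 1.0, 1.0)):
    """Add an (anisotropic) Gaussian blob in-place, in a local bounding box."""
    sig = np.asarray(aniso, dtype=float) * radius
    lo = [max(0, int(np.floor(center[a] - 4 * sig[a]))) for a in range(3)]
    hi = [min(volume.shape[a], int(np.ceil(center[a] + 4 * sig[a])) + 1) for a in range(3)]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    axes = [np.arange(lo[a], hi[a], dtype=float) - center[a] for a in range(3)]
    q = (
        (axes[0][:, None, None] / sig[0]) ** 2
        + (axes[1][None, :, None] / sig[1]) ** 2
        + (axes[2][None, None, :] / sig[2]) ** 2
    )
    volume[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * np.exp(-q / 2.0)


def _ellipsoid_field(grid_shape) -> np.ndarray:
    """Soft brain-shaped background in [0, 1]."""
    ax = [np.arange(d, dtype=float) for d in grid_shape]
    center = [(d - 1) / 2.0 for d in grid_shape]
    semi = [0.45 * d for d in grid_shape]
    r = np.sqrt(
        ((ax[0][:, None, None] - center[0]) / semi[0]) ** 2
        + ((ax[1][None, :, None] - center[1]) / semi[1]) ** 2
        + ((ax[2][None, None, :] - center[2]) / semi[2]) ** 2
    )
    return 1.0 / (1.0 + np.exp((r - 1.0) * 8.0))


def brain_mask(grid_shape) -> np.ndarray:
    """Boolean ellipsoidal brain mask used for the functional maps."""
    return _ellipsoid_field(grid_shape) > 0.5


def _gain(rng, spec: CohortSpec) -> float:
    """Per-subject, per-site multiplicative response variability."""
    return float(max(0.15, rng.normal(1.0, spec.subject_variability)))


def _smooth_noise(rng, grid_shape, sd, mask):
    if sd == 0:
        return np.zeros(grid_shape)
    f = gaussian_filter(rng.standard_normal(grid_shape), sigma=1.5)
    s = f[mask].std()
    if s > 0:
        f /= s
    return f * sd


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Generate ``n_hi`` HI followed by ``n_nh`` NH subjects, reproducibly."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    structural, shared, functional = _allocate_sites(spec)
    background = 0.9 * _ellipsoid_field(spec.grid_shape)
    mask = brain_mask(spec.grid_shape)
    sed_p = {
        "HI": (0.6, 0.3, 0.1) if spec.sedation_confounded else (1 / 3,) * 3,
        "NH": (0.1, 0.3, 0.6) if spec.sedation_confounded else (1 / 3,) * 3,
    }

    subjects = []
    labels = ["HI"] * spec.n_hi + ["NH"] * spec.n_nh
    counters = {"HI": 0, "NH": 0}
    for group in labels:
        counters[group] += 1
        sid = f"{group.lower()}{counters[group]:02d}"
        # alternate which modality this subject's group marker shows up in
        if counters[group] % 2 == 1:
            mult_struct = 1.0 + spec.modality_balance
            mult_func = 1.0 - spec.modality_balance
        else:
            mult_struct = 1.0 - spec.modality_balance
            mult_func = 1.0 + spec.modality_balance

        anat = background.copy()
        for site in shared:
            _add_blob(anat, site.center, spec.blob_radius, 0.7 * _gain(rng, spec), site.aniso)
        for site in structural:
            gain = _gain(rng, spec)
            amp = spec.blob_effect * gain * mult_struct if group == site.favored else 0.0
            if amp != 0.0:
                _add_blob(anat, site.center, spec.blob_radius, amp, site.aniso)
        if spec.noise_sd > 0:
            anat += rng.normal(0.0, spec.noise_sd, spec.grid_shape)

        contrasts = {}
        for contrast in CONTRASTS:
            cmap = _smooth_noise(rng, spec.grid_shape, spec.noise_sd, mask)
            for site in functional[contrast]:
                gain = _gain(rng, spec)
                amp = spec.base_activation + (
                    spec.activation_effect * mult_func if group == site.favored else 0.0
                )
                _add_blob(cmap, site.center, spec.blob_radius, site.sign * amp * gain, site.aniso)
            for _ in range(spec.n_nuisance_blobs):
                for _try in range(50):
                    c = tuple(rng.uniform(0, d - 1) for d in spec.grid_shape)
                    if mask[tuple(int(round(v)) for v in c)]:
                        break
                amp = rng.uniform(0.4, 0.9) * (1 if rng.random() < 0.5 else -1)
                _add_blob(cmap, c, spec.blob_radius, amp)
            cmap *= mask
            contrasts[contrast] = cmap

        sedation = int(rng.choice([1, 2, 3], p=sed_p[group]))
        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                group=group,
                anatomical=anat,
                contrasts=contrasts,
                sedation=sedation,
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# I/O


def write_cohort(subjects: list[SyntheticSubject], directory) -> Path:
    """Write one NIfTI per volume plus a CSV manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id, "group": s.group, "sedation": s.sedation}
        anat_path = directory / f"{s.subject_id}_anat.nii.gz"
        save_volume(s.anatomical, anat_path, s.affine)
        row["anat_path"] = anat_path.name
        for contrast in CONTRASTS:
            p = directory / f"{s.subject_id}_{contrast}.nii.gz"
            save_volume(s.contrasts[contrast], p, s.affine)
            row[f"{contrast}_path"] = p.name
        rows.append(row)
    manifest = directory / "manifest.csv"
    columns = ["subject_id", "group", "sedation", "anat_path"] + [
        f"{c}_path" for c in CONTRASTS
    ]
    pd.DataFrame(rows, columns=columns).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> list[SyntheticSubject]:
    """Load a cohort written by :func:`write_cohort` (paths relative to manifest)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    subjects = []
    for _, row in df.iterrows():
        anat, affine = load_volume(base / row["anat_path"])
        contrasts = {
            c: load_volume(base / row[f"{c}_path"])[0] for c in CONTRASTS
        }
        subjects.append(
            SyntheticSubject(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                anatomical=anat,
                contrasts=contrasts,
                sedation=int(row["sedation"]),
                affine=affine,
            )
        )
    return subjects


def site_mean_intensity(volume: np.ndarray, center, radius: float = 2.5) -> float:
    """Mean intensity in a small box around a planted site center."""
    lo = [max(0, int(c - radius)) for c in center]
    hi = [min(volume.shape[a], int(center[a] + radius) + 1) for a in range(3)]
    sub = volume[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    return float(sub.mean())
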