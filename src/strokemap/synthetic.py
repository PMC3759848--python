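"""Seeded synthetic stroke-phantom cohorts.

Emulates the structure of a rodent middle-cerebral-artery-occlusion (MCAo)
imaging study: a sham group plus two lesion sub-groups (striatal-only and
striatal+cortical), each subject carrying a T2-hyperintense lesion mask in
the right hemisphere, a smooth lesion-centred expansion field with
ventricular enlargement, the resulting Jacobian determinant map, and four
behavioural scores (left/right foot-fault percentages and grip strengths)
coupled linearly to lesion volume.

Lesions are unions of spheres rather than anatomically realistic shapes:
only their topology (focal, unilateral, two characteristic sizes) matters
to the downstream statistics.  Displacement fields are built by
superposing Gaussian-mollified point sources over the lesion and
ventricular voxels, which yields a smooth, curl-free expansion whose
integrated volume creation matches the requested fractional change — a
plausible stand-in for the output of a fluid (viscous) registration,
whose regularisation weights mu and lambda are mirrored here by the
mollification width.

Every random draw descends from a single integer seed through per-subject
child streams, so cohorts are byte-reproducible and independent of subject
iteration order.  A ground-truth ledger (template lesion masks, true
per-subject volumes, true behavioural slopes) accompanies each cohort for
recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, special
from scipy.fft import irfftn, next_fast_len, rfftn

from .deformation import JacobianMap, jacobian_determinant, roi_volume


@dataclass
class BehaviourModel:
    """Linear score model: intercept + slope * lesion volume + noise.

    ``slope`` is in score units per mm^3 of lesion; ``sd`` is the residual
    standard deviation of the Gaussian noise.
    """

    intercept: float
    slope: float
    sd: float


def default_behaviour_models() -> dict[str, BehaviourModel]:
    """Score models for the four behavioural measures.

    Contralateral (left) scores are coupled to lesion volume with the
    directions seen in MCAo rats — foot-faults rise, grip strength falls —
    while the ipsilateral (right) scores are uncoupled.  Foot-fault
    intercept and residual SD use the 20% / 10% values of the model power
    analysis; grip strength is in gram-force with a healthy baseline of
    1000 g.
    """
    return {
        "ffl": BehaviourModel(intercept=20.0, slope=1.5, sd=10.0),
        "ffr": BehaviourModel(intercept=20.0, slope=0.0, sd=10.0),
        "gsl": BehaviourModel(intercept=1000.0, slope=-15.0, sd=100.0),
        "gsr": BehaviourModel(intercept=1000.0, slope=0.0, sd=100.0),
    }


SCORE_NAMES = ("ffl", "ffr", "gsl", "gsr")
GROUP_SHAM = "sham"
GROUP_STRIATAL = "striatal"
GROUP_STRIATAL_CORTICAL = "striatal_cortical"


@dataclass
class SyntheticConfig:
    """Parameters of the phantom cohort generator.

    Grid and voxel dimensions default to the acquisition geometry of a
    high-field rodent protocol (0.234 x 0.234 mm in plane, 0.5 mm slices).
    ``smoothness_mu`` and ``smoothness_lambda`` are analogues of the fluid
    registration viscosity weights (normalised standard values 1 and 0);
    they set the mollification width of the synthetic deformation sources.
    Lesion centres default to a deep (striatal) and a superficial
    (cortical) location in the right hemisphere, scaled to the grid.
    """

    seed: int = 0
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_dims_mm: tuple[float, float, float] = (0.234, 0.234, 0.5)
    n_sham: int = 16
    n_striatal: int = 21
    n_striatal_cortical: int = 21
    lesion_centres: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None
    centre_jitter_sd: float = 1.0        # voxels
    striatal_radius_mm: tuple[float, float] = (1.2, 0.12)   # mean, SD
    cortical_radius_mm: tuple[float, float] = (1.0, 0.10)
    deformation_magnitude: float = 0.3   # peak fractional expansion in lesion
    smoothness_mu: float = 1.0
    smoothness_lambda: float = 0.0
    ventricle_enlargement: float = 0.3   # fractional expansion of ventricle ROI
    hyperintensity_contrast: float = 3.0  # lesion intensity in contralateral SDs
    noise_sd: float = 5.0                # image noise SD (a.u.; tissue = 100)
    field_noise_vox: float = 0.05        # SD of the smooth random field (voxels)
    behaviour_models: dict[str, BehaviourModel] = dc_field(
        default_factory=default_behaviour_models
    )
    make_fields: bool = True
    make_images: bool = True

    def __post_init__(self):
        shape = tuple(int(s) for s in self.grid_shape)
        if len(shape) != 3 or min(shape) < 8:
            raise ValueError("grid_shape must be three integers >= 8")
        self.grid_shape = shape
        if min(self.n_sham, self.n_striatal, self.n_striatal_cortical) < 0:
            raise ValueError("group sizes must be non-negative")
        if self.striatal_radius_mm[0] <= 0 or self.cortical_radius_mm[0] <= 0:
            raise ValueError("lesion radii must be positive")
        for m in self.behaviour_models.values():
            if m.sd < 0:
                raise ValueError("behaviour residual SD must be non-negative")
        if self.lesion_centres is None:
            sx, sy, sz = shape
            self.lesion_centres = (
                (0.69 * sx, 0.50 * sy, 0.50 * sz),   # striatal
                (0.75 * sx, 0.66 * sy, 0.50 * sz),   # cortical
            )

    # -- fixed geometry -----------------------------------------------------

    @property
    def midline(self) -> int:
        """First voxel index of the right (lesion) hemisphere along axis 0."""
        return self.grid_shape[0] // 2

    def brain_mask(self) -> np.ndarray:
        """Ellipsoidal brain mask centred in the grid (semi-axes 0.44*shape)."""
        # centred at (s-1)/2 so the mask is symmetric under a midline flip
        return _ellipsoid(
            self.grid_shape,
            centre=[(s - 1) / 2 for s in self.grid_shape],
            semi_axes=[0.44 * s for s in self.grid_shape],
        )

    def ventricle_mask(self) -> np.ndarray:
        """Fixed ventricular ROI: a small ellipsoid near the midline,
        in the lesion hemisphere."""
        sx, sy, sz = self.grid_shape
        return _ellipsoid(
            self.grid_shape,
            centre=(0.59 * sx, 0.50 * sy, 0.50 * sz),
            semi_axes=(1.8, 1.8, 2.5),
        )

    def smoothing_sigma_mm(self) -> float:
        """Mollification width of the deformation sources (mm).

        Scaled so the default regularisation (mu=1, lambda=0) keeps nearly
        all smeared source mass inside the brain for boundary-near lesions.
        """
        return max(0.25, 0.5 * self.smoothness_mu + 0.25 * self.smoothness_lambda)


@dataclass
class Subject:
    subject_id: str
    group: str
    lesion_mask: np.ndarray
    scores: dict[str, float]
    image: np.ndarray | None = None
    field: np.ndarray | None = None
    jacobian: JacobianMap | None = None

    @property
    def lesion_volume_mm3(self) -> float:
        return self._volume

    _volume: float = 0.0


@dataclass
class Cohort:
    """A generated phantom cohort with its shared grid and ground truth."""

    subjects: list[Subject]
    brain_mask: np.ndarray
    voxel_dims_mm: tuple[float, float, float]
    config: SyntheticConfig
    ground_truth: dict

    def __len__(self) -> int:
        return len(self.subjects)

    def lesion_masks(self) -> np.ndarray:
        """(n, X, Y, Z) boolean stack of lesion masks."""
        return np.stack([s.lesion_mask for s in self.subjects])

    def scores(self, name: str) -> np.ndarray:
        return np.array([s.scores[name] for s in self.subjects], dtype=float)

    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def log_jacobians(self) -> np.ndarray:
        """(n, X, Y, Z) stack of log-Jacobian maps (requires make_fields)."""
        if self.subjects and self.subjects[0].jacobian is None:
            raise ValueError("cohort was generated without deformation fields")
        return np.stack([s.jacobian.log_j for s in self.subjects])

    def behaviour_table(self):
        import pandas as pd

        rows = {
            s.subject_id: {"group": s.group, **s.scores} for s in self.subjects
        }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "subject_id"
        return df


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ellipsoid(shape, centre, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, centre, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _sphere_mm(shape, voxel_dims_mm, centre_vox, radius_mm) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, d in zip(grids, centre_vox, voxel_dims_mm):
        acc = acc + ((g - c) * d) ** 2
    return acc <= radius_mm ** 2


# ---------------------------------------------------------------------------
# displacement-field construction
# ---------------------------------------------------------------------------

_KERNEL_CACHE: dict = {}


def _mollified_source_kernel(shape, voxel_dims_mm, sigma_mm) -> np.ndarray:
    """Vector kernel of a unit-volume Gaussian-mollified point source.

    The radial field of a unit source smeared with an isotropic Gaussian of
    width sigma is u(r) = M(r) / (4 pi r^2) r_hat, with M(r) the enclosed
    source fraction.  Its divergence is exactly the Gaussian density, so a
    source distribution of total strength Q creates Q units of volume.
    Returned as an odd-sized (2X-1, 2Y-1, 2Z-1, 3) array in mm, centred.
    Cached per (shape, voxel dims, sigma) since cohorts reuse one geometry.
    """
    key = (tuple(shape), tuple(voxel_dims_mm), float(sigma_mm))
    if key in _KERNEL_CACHE:
        return _KERNEL_CACHE[key]
    half = [s - 1 for s in shape]
    coords = np.meshgrid(
        *[np.arange(-h, h + 1) * d for h, d in zip(half, voxel_dims_mm)],
        indexing="ij",
    )
    r2 = sum(c ** 2 for c in coords)
    r = np.sqrt(r2)
    s = sigma_mm
    with np.errstate(divide="ignore", invalid="ignore"):
        enclosed = special.erf(r / (s * math.sqrt(2))) - (
            math.sqrt(2 / math.pi) * (r / s) * np.exp(-r2 / (2 * s * s))
        )
        radial = enclosed / (4 * math.pi * r2 * r)  # u / r along each axis
    centre = tuple(h for h in half)
    radial[centre] = 0.0  # u(0) = 0 by symmetry
    kernel = np.stack([radial * c for c in coords], axis=-1)
    if len(_KERNEL_CACHE) > 8:
        _KERNEL_CACHE.clear()
    _KERNEL_CACHE[key] = kernel
    return kernel


def _source_field(
    source_density: np.ndarray,
    voxel_dims_mm,
    sigma_mm: float,
) -> np.ndarray:
    """Displacement field (voxel units) of a volumetric source distribution.

    ``source_density`` holds, per voxel, the volume (mm^3) to be created
    there.  The field is the convolution of the mollified point-source
    kernel with the density, computed by FFT, then converted from mm to
    voxel units per axis.
    """
    shape = source_density.shape
    kernel_fft, fshape = _kernel_fft(shape, tuple(voxel_dims_mm), float(sigma_mm))
    src_fft = rfftn(source_density, fshape)
    out = np.empty(shape + (3,), dtype=float)
    # 'same'-mode linear convolution: the kernel is centred at shape - 1
    start = [s - 1 for s in shape]
    region = tuple(slice(st, st + s) for st, s in zip(start, shape))
    for ax in range(3):
        full = irfftn(src_fft * kernel_fft[ax], fshape)
        out[..., ax] = full[region] / voxel_dims_mm[ax]
    return out


_KERNEL_FFT_CACHE: dict = {}


def _kernel_fft(shape, voxel_dims_mm, sigma_mm):
    """FFT of the mollified source kernel, cached per geometry."""
    key = (tuple(shape), voxel_dims_mm, sigma_mm)
    if key in _KERNEL_FFT_CACHE:
        return _KERNEL_FFT_CACHE[key]
    kernel = _mollified_source_kernel(shape, voxel_dims_mm, sigma_mm)
    # a circular convolution of length >= 2s-1 leaves the extracted central
    # ('same') region free of wrap-around aliasing, so the smaller transform
    # is exact for that region
    fshape = tuple(int(next_fast_len(2 * s - 1)) for s in shape)
    ffts = tuple(rfftn(kernel[..., ax], fshape) for ax in range(3))
    if len(_KERNEL_FFT_CACHE) > 4:
        _KERNEL_FFT_CACHE.clear()
    _KERNEL_FFT_CACHE[key] = (ffts, fshape)
    return ffts, fshape


def make_lesion_displacement_field(
    mask: np.ndarray,
    config: SyntheticConfig,
    ventricle_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Smooth expansion field for a lesion (and optional ventricular) mask.

    Inside the lesion the field creates ``deformation_magnitude`` of
    fractional volume; the ventricular ROI expands by
    ``ventricle_enlargement``.  Because each source voxel emits its target
    volume through a divergence-controlled radial kernel, the integral of
    (J - 1) over the brain approximates the configured total volume change.
    A small smooth random field (SD ``field_noise_vox`` voxels) models
    registration noise when ``rng`` is given.  If the requested magnitude
    would fold the grid (min J <= 0) the field is scaled down iteratively;
    an unattainable request raises.
    """
    mask = np.asarray(mask).astype(bool)
    voxel_vol = float(np.prod(config.voxel_dims_mm))
    density = np.zeros(config.grid_shape, dtype=float)
    if mask.any() and config.deformation_magnitude != 0:
        density[mask] += config.deformation_magnitude * voxel_vol
    if ventricle_mask is not None and config.ventricle_enlargement != 0:
        density[np.asarray(ventricle_mask, dtype=bool)] += (
            config.ventricle_enlargement * voxel_vol
        )
    if density.any():
        field = _source_field(
            density, config.voxel_dims_mm, config.smoothing_sigma_mm()
        )
    else:
        field = np.zeros(config.grid_shape + (3,), dtype=float)

    if rng is not None and config.field_noise_vox > 0:
        noise = rng.standard_normal(config.grid_shape + (3,))
        for ax in range(3):
            noise[..., ax] = ndimage.gaussian_filter(noise[..., ax], sigma=1.5)
        sd = noise.std()
        if sd > 0:
            field = field + noise * (config.field_noise_vox / sd)

    for _ in range(12):
        jac = jacobian_determinant(field, config.voxel_dims_mm)
        if jac.j.min() > 0:
            return field
        import warnings

        warnings.warn(
            "deformation magnitude folds the grid; scaling field by 0.8",
            stacklevel=2,
        )
        field = field * 0.8
    raise ValueError("could not construct a diffeomorphic field at any scale")


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def generate_behaviour(
    lesion_volumes_mm3,
    config: SyntheticConfig,
    seed: int,
) -> "np.ndarray | object":
    """Sample the four behavioural scores from the linear volume model.

    score = intercept + slope * volume + Normal(0, sd); foot-fault
    percentages are clamped to [0, 100], grip strengths to >= 0.  Returns a
    pandas DataFrame with one row per subject and columns ffl/ffr/gsl/gsr.
    """
    import pandas as pd

    volumes = np.asarray(lesion_volumes_mm3, dtype=float)
    if (volumes < 0).any():
        raise ValueError("lesion volumes must be non-negative")
    rng = np.random.default_rng(seed)
    out = {}
    for name in SCORE_NAMES:
        model = config.behaviour_models[name]
        if model.sd < 0:
            raise ValueError("behaviour residual SD must be non-negative")
        raw = (
            model.intercept
            + model.slope * volumes
            + rng.normal(0.0, model.sd, size=volumes.shape) * (model.sd > 0)
        )
        if name.startswith("ff"):
            raw = np.clip(raw, 0.0, 100.0)
        else:
            raw = np.maximum(raw, 0.0)
        out[name] = raw
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _subject_rng(seed: int, index: int) -> np.random.Generator:
    """Independent per-subject stream, invariant to generation order."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _draw_lesion_mask(
    group: str,
    config: SyntheticConfig,
    brain: np.ndarray,
    rng: np.random.Generator,
    jitter: bool = True,
    max_retries: int = 25,
) -> np.ndarray:
    shape = config.grid_shape
    mid = config.midline
    c_str, c_ctx = config.lesion_centres
    right = np.zeros(shape, dtype=bool)
    right[mid:] = True
    for _ in range(max_retries):
        mask = np.zeros(shape, dtype=bool)
        jit = rng.normal(0.0, config.centre_jitter_sd, size=(2, 3)) if jitter else np.zeros((2, 3))
        r_str = max(0.2, rng.normal(*config.striatal_radius_mm))
        mask |= _sphere_mm(shape, config.voxel_dims_mm, np.add(c_str, jit[0]), r_str)
        if group == GROUP_STRIATAL_CORTICAL:
            r_ctx = max(0.2, rng.normal(*config.cortical_radius_mm))
            mask |= _sphere_mm(
                shape, config.voxel_dims_mm, np.add(c_ctx, jit[1]), r_ctx
            )
        if mask.any() and (mask <= (brain & right)).all():
            return mask
    raise ValueError(
        f"could not place a {group} lesion inside the right hemisphere "
        f"after {max_retries} jitter draws; enlarge the grid or reduce "
        "radius/jitter"
    )


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full phantom cohort from a configuration and its seed.

    Subjects are produced on independent child streams of ``config.seed``:
    the same configuration always yields byte-identical data, and each
    subject's data does not depend on how many subjects precede it.
    """
    brain = config.brain_mask()
    ventricle = config.ventricle_mask()
    groups = (
        [GROUP_SHAM] * config.n_sham
        + [GROUP_STRIATAL] * config.n_striatal
        + [GROUP_STRIATAL_CORTICAL] * config.n_striatal_cortical
    )
    voxel_vol = float(np.prod(config.voxel_dims_mm))

    subjects: list[Subject] = []
    volumes = []
    for i, group in enumerate(groups):
        rng = _subject_rng(config.seed, i)
        if group == GROUP_SHAM:
            mask = np.zeros(config.grid_shape, dtype=bool)
        else:
            mask = _draw_lesion_mask(group, config, brain, rng)
        volume = float(mask.sum()) * voxel_vol
        volumes.append(volume)

        image = None
        if config.make_images:
            image = np.where(brain, 100.0, 0.0)
            if config.noise_sd > 0:
                image = image + rng.normal(0.0, config.noise_sd, config.grid_shape) * brain
            image[mask] += config.hyperintensity_contrast * config.noise_sd

        field = jac = None
        if config.make_fields:
            vent = ventricle if group != GROUP_SHAM else None
            field = make_lesion_displacement_field(mask, config, vent, rng=rng)
            jac = jacobian_determinant(field, config.voxel_dims_mm)

        subj = Subject(
            subject_id=f"sub{i:03d}",
            group=group,
            lesion_mask=mask,
            scores={},
            image=image,
            field=field,
            jacobian=jac,
        )
        subj._volume = volume
        subjects.append(subj)

    behaviour = generate_behaviour(
        volumes, config, seed=np.random.SeedSequence(config.seed, spawn_key=(10_000,)).generate_state(1)[0]
    )
    for subj, (_, row) in zip(subjects, behaviour.iterrows()):
        subj.scores = {name: float(row[name]) for name in SCORE_NAMES}

    # zero-jitter templates define the ground-truth lesioned/coupled region
    template_rng = np.random.default_rng(0)
    tmpl_str = _sphere_mm(
        config.grid_shape, config.voxel_dims_mm,
        config.lesion_centres[0], config.striatal_radius_mm[0],
    )
    tmpl_ctx = tmpl_str | _sphere_mm(
        config.grid_shape, config.voxel_dims_mm,
        config.lesion_centres[1], config.cortical_radius_mm[0],
    )
    del template_rng
    ground_truth = {
        "template_striatal": tmpl_str,
        "template_striatal_cortical": tmpl_ctx,
        "coupled_region": tmpl_ctx,
        "ventricle_mask": ventricle,
        "lesion_volumes_mm3": list(volumes),
        "behaviour_slopes": {
            k: m.slope for k, m in config.behaviour_models.items()
        },
        "deformation_magnitude": config.deformation_magnitude,
    }
    return Cohort(
        subjects=subjects,
        brain_mask=brain,
        voxel_dims_mm=tuple(config.voxel_dims_mm),
        config=config,
        ground_truth=ground_truth,
    )
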