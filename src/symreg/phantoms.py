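"""Brain-like synthetic phantoms with known ground-truth deformations.

Every other module is testable end-to-end on these phantoms without any
external imaging data.  A phantom "head" is piecewise-smooth tissue on a
2-D or 3-D grid: an outer ellipsoidal shell (skull/scalp analog), a darker
ring under it (CSF analog), homogeneous parenchyma, and ``n_rois``
ellipsoidal blobs with distinct intensities that double as labeled ROIs.
Intensities are lightly smoothed (tissue interfaces are not voxel-sharp)
and corrupted with additive Gaussian noise — emulating skull-stripped,
affinely pre-aligned, resampled brain MR volumes.  Not emulated: bias
fields, Rician noise statistics, partial-volume mixtures, or real
anatomical geometry; a test that is green on phantoms establishes the
correctness of the machinery, not clinical-grade accuracy.

The ground-truth deformation is Gaussian-smoothed vector noise rescaled to
a chosen peak magnitude, redrawn (bounded retries) until it is fold-free,
so ``subject = warp(template, true_field) + noise`` holds by construction
and the true field is a valid recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .field_algebra import count_folds
from .grids import DisplacementField, Volume
from .warp import warp_array

__all__ = ["PhantomSpec", "PhantomPair", "Phantom", "make_phantom", "make_cohort"]


@dataclass
class PhantomSpec:
    """Recipe for one phantom pair; a pure function of its fields.

    ``deformation_amplitude`` is the peak displacement magnitude in voxels,
    ``smoothness_sigma`` the Gaussian width (voxels) of the random field,
    ``noise_sd`` the additive intensity noise (images span roughly [0, 1]).
    """

    shape: tuple = (64, 64)
    n_rois: int = 4
    deformation_amplitude: float = 3.0
    smoothness_sigma: float = 6.0
    noise_sd: float = 0.01
    seed: int = 0
    max_field_retries: int = 20

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        if len(self.shape) not in (2, 3):
            raise ValueError("phantoms are 2-D or 3-D")
        if self.deformation_amplitude < 0:
            raise ValueError("deformation_amplitude must be >= 0")
        if self.smoothness_sigma <= 0:
            raise ValueError("smoothness_sigma must be positive")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")

    def noise_free(self) -> "PhantomSpec":
        """The same recipe with the intensity noise switched off."""
        return PhantomSpec(
            shape=self.shape, n_rois=self.n_rois,
            deformation_amplitude=self.deformation_amplitude,
            smoothness_sigma=self.smoothness_sigma, noise_sd=0.0,
            seed=self.seed, max_field_retries=self.max_field_retries,
        )


@dataclass
class Phantom:
    """One cohort member: an image and its ROI label map."""

    image: Volume
    labels: Volume


@dataclass
class PhantomPair:
    """Template/subject pair with the ground-truth field that links them."""

    template: Volume
    subject: Volume
    labels_T: Volume
    labels_S: Volume
    true_field: DisplacementField


# ---------------------------------------------------------------------------
# anatomy


def _normalized_coords(shape):
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def _base_anatomy(rng: np.random.Generator, spec: PhantomSpec) -> dict:
    """Draw the per-phantom shape parameters (blob layout, head axes)."""
    D = len(spec.shape)
    axes = np.array([0.88, 0.78, 0.83][:D])
    centers, radii = [], []
    tries = 0
    while len(centers) < spec.n_rois and tries < 500:
        tries += 1
        c = rng.uniform(-0.5, 0.5, size=D)
        if np.sum((c / (0.55 * axes)) ** 2) > 1.0:
            continue
        r = rng.uniform(0.10, 0.16)
        if all(np.linalg.norm(c - c0) > 0.9 * (r + r0) for c0, r0 in zip(centers, radii)):
            centers.append(c)
            radii.append(r)
    while len(centers) < spec.n_rois:  # give up on spacing, just place them
        centers.append(rng.uniform(-0.4, 0.4, size=D))
        radii.append(rng.uniform(0.10, 0.16))
    intens = 0.55 + 0.35 * rng.permutation(spec.n_rois) / max(spec.n_rois - 1, 1)
    return {"axes": axes, "centers": np.array(centers),
            "radii": np.array(radii), "blob_intensities": intens}


def _render(anatomy: dict, spec: PhantomSpec, rng: np.random.Generator):
    """Rasterize anatomy into a smooth intensity image and a label map."""
    coords = _normalized_coords(spec.shape)
    r_ell = np.sqrt(sum((x / a) ** 2 for x, a in zip(coords, anatomy["axes"])))

    img = np.zeros(spec.shape)
    img[r_ell < 1.0] = 0.80          # skull/scalp shell
    img[r_ell < 0.90] = 0.15         # CSF-analog ring
    img[r_ell < 0.78] = 0.45         # parenchyma

    labels = np.zeros(spec.shape, dtype=np.int32)
    for k in range(spec.n_rois):
        d = np.sqrt(sum((x - c) ** 2 for x, c in zip(coords, anatomy["centers"][k])))
        mask = d < anatomy["radii"][k]
        img[mask] = anatomy["blob_intensities"][k]
        labels[mask] = k + 1

    img = gaussian_filter(img, sigma=1.0)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return img, labels


# ---------------------------------------------------------------------------
# deformation


def _random_smooth_field(rng: np.random.Generator, spec: PhantomSpec
                         ) -> DisplacementField:
    """Gaussian-smoothed vector noise, peak magnitude = amplitude, fold-free.

    The smoothed noise is attenuated by a broad Gaussian window centred on
    the grid (where the head sits) before rescaling, so the stated amplitude
    deforms the anatomy rather than the empty background; without the
    window the peak of an unconstrained random field frequently lands
    outside the head and the pair carries almost no anatomical deformation.
    """
    D = len(spec.shape)
    if spec.deformation_amplitude == 0:
        return DisplacementField(np.zeros((D,) + spec.shape))
    coords = _normalized_coords(spec.shape)
    envelope = np.exp(-sum(x**2 for x in coords) / (2 * 0.45**2))
    for _ in range(spec.max_field_retries):
        v = rng.standard_normal((D,) + spec.shape)
        for c in range(D):
            v[c] = gaussian_filter(v[c], sigma=spec.smoothness_sigma) * envelope
        mag = np.sqrt((v**2).sum(axis=0)).max()
        if mag == 0:
            continue
        v *= spec.deformation_amplitude / mag
        field = DisplacementField(v)
        if count_folds(field) == 0:
            return field
    raise RuntimeError(
        "could not draw a fold-free field within "
        f"{spec.max_field_retries} retries; deformation_amplitude "
        f"{spec.deformation_amplitude} is too large for smoothness_sigma "
        f"{spec.smoothness_sigma}"
    )


# ---------------------------------------------------------------------------
# public generators


def make_phantom(spec: PhantomSpec) -> PhantomPair:
    """Generate one template/subject pair with known ground truth.

    The subject is the template warped by the (fold-free) true field, with
    independent noise realizations on each image; the subject's labels are
    the nearest-neighbour warp of the template's.  Fully reproducible from
    ``spec.seed``.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_shape, rng_noise_t, rng_noise_s, rng_field = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    anatomy = _base_anatomy(rng_shape, spec)
    clean, labels_T = _render(anatomy, spec.noise_free(), rng_shape)
    true_field = _random_smooth_field(rng_field, spec)

    subject = warp_array(clean, true_field.vectors)
    template = clean
    if spec.noise_sd > 0:
        template = template + rng_noise_t.normal(0.0, spec.noise_sd, spec.shape)
        subject = subject + rng_noise_s.normal(0.0, spec.noise_sd, spec.shape)
    labels_S = warp_array(labels_T, true_field.vectors, interpolation="nearest")
    return PhantomPair(
        template=Volume(template),
        subject=Volume(subject),
        labels_T=Volume(labels_T),
        labels_S=Volume(labels_S),
        true_field=true_field,
    )


def make_cohort(n: int, spec: PhantomSpec) -> list:
    """Generate ``n`` anatomically varied phantoms on one grid.

    All members share the blob count and labeling (ROI ``k`` corresponds
    across subjects) but differ in head axes, blob positions, radii,
    intensities and noise — the substrate for the pairing plans.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 members")
    ss = np.random.SeedSequence(spec.seed)
    base_rng = np.random.default_rng(ss.spawn(1)[0])
    base = _base_anatomy(base_rng, spec)
    members = []
    for child in np.random.SeedSequence((spec.seed, 1)).spawn(n):
        rng = np.random.default_rng(child)
        anatomy = {
            "axes": base["axes"] * (1.0 + 0.06 * rng.standard_normal(len(spec.shape))),
            "centers": base["centers"]
            + 0.05 * rng.standard_normal(base["centers"].shape),
            "radii": np.clip(
                base["radii"] * (1.0 + 0.15 * rng.standard_normal(spec.n_rois)),
                0.06, 0.22,
            ),
            "blob_intensities": np.clip(
                base["blob_intensities"] + 0.05 * rng.standard_normal(spec.n_rois),
                0.5, 0.95,
            ),
        }
        img, labels = _render(anatomy, spec, rng)
        members.append(Phantom(image=Volume(img), labels=Volume(labels)))
    return members
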