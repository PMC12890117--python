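"""Particle-immunoagglutination quantification from fluorescence micrographs.

Antibody-conjugated fluorescent polystyrene particles agglutinate in the
presence of antigen and are retained in the paper pores.  Their extent is
quantified from green-fluorescence images: isolate the green channel,
eliminate background below an intensity threshold (default 100/255), label
connected components, discard components smaller than a size threshold
(default 50 px — those are free, non-agglutinated particles), and sum the
pixel areas of the survivors across the images of one assay (normally 3).
Only pixel areas enter the score, never fluorescence intensities, because
absolute intensity on a paper substrate is not reliably quantifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "ParticleRecord",
    "AgglutinationScore",
    "extract_green",
    "binarize",
    "label_components",
    "filter_agglutinated",
    "agglutination_score",
]

DEFAULT_INTENSITY_THRESHOLD = 100
DEFAULT_SIZE_THRESHOLD = 50
DEFAULT_N_IMAGES = 3


@dataclass(frozen=True)
class ParticleRecord:
    """One labeled connected component (a particle or particle cluster)."""

    label: int
    area: int
    centroid: tuple[float, float]


@dataclass(frozen=True)
class AgglutinationScore:
    """Summed pixel area of agglutinated clusters across the assay's images."""

    total_pixels: int
    per_image: tuple[int, ...]
    intensity_threshold: int
    size_threshold: int

    @property
    def n_images(self) -> int:
        return len(self.per_image)


def extract_green(image: np.ndarray) -> np.ndarray:
    """Return the raw green plane of an 8-bit RGB image, unchanged.

    No colour deconvolution or white balance: the physical assay isolates
    green optically with a bandpass filter, so the G plane is the signal.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise InvalidInputError(
            f"expected an (h, w, 3) RGB image, got shape {image.shape}"
        )
    return image[..., 1]


def binarize(gray: np.ndarray, threshold: int = DEFAULT_INTENSITY_THRESHOLD) -> np.ndarray:
    """Threshold a grayscale image: pixels *below* ``threshold`` are
    eliminated, so the mask keeps intensity ≥ threshold (100 is kept at the
    default)."""
    if not (0 <= threshold <= 255):
        raise ConfigurationError(f"intensity threshold must be in [0, 255], got {threshold}")
    gray = np.asarray(gray)
    return gray >= threshold


def label_components(mask: np.ndarray, connectivity: int = 8) -> list[ParticleRecord]:
    """Label maximal connected regions of a binary mask.

    ``connectivity`` is 8 (default; diagonal pixels touch) or 4.
    """
    if connectivity not in (4, 8):
        raise ConfigurationError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    labeled = sk_label(mask, connectivity=2 if connectivity == 8 else 1)
    return [
        ParticleRecord(label=int(r.label), area=int(r.area), centroid=tuple(map(float, r.centroid)))
        for r in regionprops(labeled)
    ]


def filter_agglutinated(
    records: list[ParticleRecord],
    size_threshold: int = DEFAULT_SIZE_THRESHOLD,
) -> list[ParticleRecord]:
    """Keep only agglutinated clusters: components *smaller than* the size
    threshold are free particles and are removed (area ≥ 50 kept at the
    default)."""
    return [r for r in records if r.area >= size_threshold]


def agglutination_score(
    images: "list[np.ndarray]",
    intensity_threshold: int = DEFAULT_INTENSITY_THRESHOLD,
    size_threshold: int = DEFAULT_SIZE_THRESHOLD,
    connectivity: int = 8,
    expected_images: int = DEFAULT_N_IMAGES,
) -> AgglutinationScore:
    """Total agglutinated pixel area over the images of one assay.

    Composes green extraction → intensity thresholding → connected-component
    labeling → size filtering per image and sums surviving areas.  A number
    of images different from the conventional 3 triggers a warning, not an
    error.
    """
    if len(images) < 1:
        raise InvalidInputError("need at least one image")
    if expected_images is not None and len(images) != expected_images:
        warnings.warn(
            f"got {len(images)} images; the assay convention is {expected_images}",
            stacklevel=2,
        )
    per_image = []
    for image in images:
        mask = binarize(extract_green(image), intensity_threshold)
        records = filter_agglutinated(
            label_components(mask, connectivity=connectivity), size_threshold
        )
        per_image.append(int(sum(r.area for r in records)))
    return AgglutinationScore(
        total_pixels=int(sum(per_image)),
        per_image=tuple(per_image),
        intensity_threshold=intensity_threshold,
        size_threshold=size_threshold,
    )
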