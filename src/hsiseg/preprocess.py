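"""Reflectance normalization, denoising, masking and patch handling.

The preprocessing chain turns a raw capture triplet into the representation
both segmentation frameworks consume:

1. flat-field normalization ``r = (It - Id) / (Iw - Id)`` per pixel per band;
2. optional spectral low-rank denoising (global truncated SVD on the
   pixels x bands matrix, with optional smoothing of the low-rank spatial
   coefficient maps — a deliberately simple spectral-low-rank denoiser with
   a swappable interface);
3. a tissue foreground mask from iterative 2-cluster k-means on per-pixel
   reflectance summaries plus morphological clean-up (the capture surface is
   a dark porous material, so the brighter cluster is tissue);
4. background zeroing, signature extraction for the pixel-wise framework,
   and 32x32 patch extraction / fourfold flip augmentation / stitching for
   the patch-based framework.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology
from sklearn.cluster import KMeans

from .io import CaptureTriplet, HSICube, LabelMask, SpectralAxis

__all__ = [
    "ReflectanceCube",
    "SignatureMatrix",
    "PatchSet",
    "CalibrationError",
    "normalize_reflectance",
    "denoise_lowrank",
    "compute_foreground_mask",
    "zero_background",
    "extract_signatures",
    "extract_patches",
    "augment_flips",
    "stitch_patches",
]

logger = logging.getLogger("hsiseg")

DENOM_EPS = 1e-6          # |Iw - Id| below this counts as degenerate
DEFAULT_PATCH_SIZE = (32, 32)


class CalibrationError(ValueError):
    """White/dark references are unusable for normalization."""


@dataclass
class ReflectanceCube:
    """Normalized reflectance cube with its tissue foreground mask."""

    values: np.ndarray
    axis: SpectralAxis
    foreground: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[2] != self.axis.band_count:
            raise ValueError("reflectance values must be H x W x band_count")
        fg = np.asarray(self.foreground)
        if fg.shape != v.shape[:2]:
            raise ValueError("foreground mask must match spatial dims")
        self.values = v
        self.foreground = fg.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def as_cube(self) -> HSICube:
        return HSICube(self.values, self.axis, "reflectance")


@dataclass
class SignatureMatrix:
    """Foreground spectra flattened to rows, with their pixel coordinates."""

    rows: np.ndarray                       # N x band_count
    pixel_index: np.ndarray                # N x 2 (row, col)
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.rows.ndim != 2:
            raise ValueError("signature rows must be 2-D")
        if len(self.pixel_index) != len(self.rows):
            raise ValueError("pixel_index must be co-indexed with rows")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class PatchSet:
    """Co-indexed cube patches, label patches and grid positions.

    ``grid_origin[i]`` is the upper-left corner of patch ``i`` in the
    (possibly mirror-padded) source frame; ``source_shape`` is the original
    unpadded spatial shape so stitching can crop the padding back off.
    ``is_augmented`` flags flip-augmented copies, which stitching ignores.
    """

    patches: list[np.ndarray]
    labels: list[np.ndarray]
    grid_origin: list[tuple[int, int]]
    source_shape: tuple[int, int]
    patch_size: tuple[int, int] = DEFAULT_PATCH_SIZE
    padded_shape: tuple[int, int] | None = None
    is_augmented: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.patches)
        if not (len(self.labels) == len(self.grid_origin) == n):
            raise ValueError("patches, labels and grid_origin must be co-indexed")
        if not self.is_augmented:
            self.is_augmented = [False] * n
        if self.padded_shape is None:
            self.padded_shape = self.source_shape
        ph, pw = self.patch_size
        for (r, c) in self.grid_origin:
            if r < 0 or c < 0 or r + ph > self.padded_shape[0] \
                    or c + pw > self.padded_shape[1]:
                raise ValueError(f"patch origin {(r, c)} does not fit the frame")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def originals(self) -> list[int]:
        return [i for i, aug in enumerate(self.is_augmented) if not aug]


# --------------------------------------------------------------------------
# Normalization (flat-field correction)
# --------------------------------------------------------------------------

def normalize_reflectance(triplet: CaptureTriplet,
                          clip_negative: bool = True,
                          eps: float = DENOM_EPS,
                          max_degenerate_fraction: float = 0.5
                          ) -> ReflectanceCube:
    """Flat-field normalization ``r = (It - Id) / (Iw - Id)``.

    Entries whose denominator magnitude falls below ``eps`` are set to 0 and
    counted; if more than ``max_degenerate_fraction`` of all entries are
    degenerate the white/dark pair is considered unusable and a
    :class:`CalibrationError` is raised. With ``clip_negative`` (default),
    negative reflectance from noise is floored at 0. The foreground mask is
    initialised to all-ones; :func:`compute_foreground_mask` refines it.
    """
    it = triplet.target.values.astype(float)
    iw = triplet.white.values.astype(float)
    idark = triplet.dark.values.astype(float)
    denom = iw - idark
    degenerate = np.abs(denom) < eps
    n_deg = int(degenerate.sum())
    if n_deg > max_degenerate_fraction * denom.size:
        raise CalibrationError(
            f"{n_deg}/{denom.size} white-dark denominators are degenerate")
    if n_deg:
        logger.warning("normalize_reflectance: %d degenerate denominators "
                       "set to zero reflectance", n_deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(degenerate, 0.0, (it - idark) / np.where(degenerate, 1.0,
                                                              denom))
    if clip_negative:
        r = np.maximum(r, 0.0)
    fg = np.ones(r.shape[:2], dtype=bool)
    return ReflectanceCube(r, triplet.target.axis, fg)


# --------------------------------------------------------------------------
# Low-rank spectral denoising
# --------------------------------------------------------------------------

def denoise_lowrank(cube: ReflectanceCube, rank: int,
                    iterations: int = 1,
                    spatial_smoothing: bool = False,
                    smoothing_sigma: float = 1.0) -> ReflectanceCube:
    """Spectral low-rank denoising by truncated SVD.

    The cube is matricised to pixels x bands, projected onto its top ``rank``
    right-singular vectors, and reshaped back. With ``spatial_smoothing`` the
    low-rank spatial coefficient maps are additionally smoothed with a small
    Gaussian (a cheap nonlocal-similarity surrogate) before reconstruction.
    ``iterations=0`` returns the input unchanged; without smoothing the
    operation is a projection, so repeated application is idempotent.
    """
    if rank <= 0:
        raise ValueError("rank must be a positive integer")
    if rank >= cube.axis.band_count:
        raise ValueError("rank must be smaller than the band count")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    values = cube.values
    h, w, b = values.shape
    for _ in range(iterations):
        mat = values.reshape(-1, b)
        # thin SVD on pixels x bands; right singular vectors span spectra
        _, _, vt = np.linalg.svd(mat, full_matrices=False)
        basis = vt[:rank]                          # rank x bands
        coeffs = mat @ basis.T                     # pixels x rank
        if spatial_smoothing:
            maps = coeffs.reshape(h, w, rank)
            maps = ndimage.gaussian_filter(maps, (smoothing_sigma,
                                                  smoothing_sigma, 0))
            coeffs = maps.reshape(-1, rank)
        values = (coeffs @ basis).reshape(h, w, b)
    return ReflectanceCube(values, cube.axis, cube.foreground.copy())


# --------------------------------------------------------------------------
# Foreground masking and background zeroing
# --------------------------------------------------------------------------

def compute_foreground_mask(cube: ReflectanceCube,
                            n_clusters: int = 2,
                            min_object_px: int = 16,
                            morph_radius: int = 2,
                            max_iterations: int = 10,
                            seed: int = 0) -> np.ndarray:
    """Tissue/background separation by iterative clustering + morphology.

    Pixels are first clustered (k-means, k=``n_clusters``) on per-pixel
    reflectance summaries (mean plus quartiles across bands); the brightest
    cluster seeds the tissue set, since the capture surface is a dark porous
    material. The background set is then iteratively re-split in two and any
    sub-cluster whose mean spectrum is spectrally closer (smaller SAM angle)
    to the tissue mean than to the darkest-background mean is moved to
    tissue — this recovers dark but spectrally tissue-like regions such as
    heavily pigmented tumor. Iteration stops when nothing moves or after
    ``max_iterations``. Finally a morphological opening/closing of radius
    ``morph_radius`` is applied and connected components smaller than
    ``min_object_px`` are removed. Degenerate scenes (a single cluster)
    yield an all-ones mask with a warning.
    """
    from .unmix import spectral_angle

    h, w, _ = cube.shape
    feats = np.stack([
        cube.values.mean(axis=2),
        np.percentile(cube.values, 25, axis=2),
        np.percentile(cube.values, 50, axis=2),
        np.percentile(cube.values, 75, axis=2),
    ], axis=-1).reshape(-1, 4)
    spectra = cube.values.reshape(-1, cube.axis.band_count)
    if np.allclose(feats.std(axis=0), 0.0) or \
            len(np.unique(feats, axis=0)) < n_clusters:
        warnings.warn("degenerate scene: all pixels in one cluster, "
                      "returning all-ones mask")
        return np.ones((h, w), dtype=bool)

    km = KMeans(n_clusters=n_clusters, n_init=4, random_state=seed)
    assign = km.fit_predict(feats)
    tissue_cluster = int(np.argmax(km.cluster_centers_[:, 0]))
    mask = assign == tissue_cluster

    def _mean_spectrum(sel: np.ndarray) -> np.ndarray:
        return spectra[sel].mean(axis=0)

    for _ in range(max_iterations):
        background = ~mask
        if background.sum() < 2:
            break
        sub_feats = feats[background]
        if len(np.unique(sub_feats, axis=0)) < 2:
            break
        sub_km = KMeans(n_clusters=2, n_init=4, random_state=seed)
        sub_assign = sub_km.fit_predict(sub_feats)
        dark_sub = int(np.argmin(sub_km.cluster_centers_[:, 0]))
        tissue_ref = _mean_spectrum(mask)
        idx = np.flatnonzero(background)
        dark_ref = _mean_spectrum(
            np.isin(np.arange(len(mask)), idx[sub_assign == dark_sub]))
        moved = False
        for c in range(2):
            if c == dark_sub:
                continue
            members = idx[sub_assign == c]
            mean_spec = spectra[members].mean(axis=0)
            if np.linalg.norm(mean_spec) == 0 \
                    or np.linalg.norm(tissue_ref) == 0 \
                    or np.linalg.norm(dark_ref) == 0:
                continue
            if spectral_angle(mean_spec, tissue_ref) < \
                    spectral_angle(mean_spec, dark_ref):
                mask[members] = True
                moved = True
        if not moved:
            break
    mask2d = mask.reshape(h, w)

    if morph_radius > 0:
        selem = morphology.disk(morph_radius)
        mask2d = morphology.opening(mask2d, selem)
        mask2d = morphology.closing(mask2d, selem)
    if min_object_px > 0:
        lab, n_comp = ndimage.label(mask2d)
        sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                                   index=np.arange(1, n_comp + 1))
        small = np.flatnonzero(sizes < min_object_px) + 1
        if small.size:
            mask2d = mask2d & ~np.isin(lab, small)
    if not mask2d.any():
        warnings.warn("foreground mask empty after clean-up; "
                      "returning all-ones mask")
        return np.ones((h, w), dtype=bool)
    return mask2d.astype(bool)


def zero_background(cube: ReflectanceCube,
                    mask: np.ndarray) -> ReflectanceCube:
    """Set background spectra to flat zero and attach the mask."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask spatial dims must match the cube")
    values = np.where(mask[..., None], cube.values, 0.0)
    return ReflectanceCube(values, cube.axis, mask)


def extract_signatures(cube: ReflectanceCube,
                       mask: np.ndarray | None = None,
                       labels: LabelMask | None = None,
                       sample_id: str = ""
                       ) -> tuple[SignatureMatrix, np.ndarray | None]:
    """Flatten foreground spectra to an N x bands matrix (row-major order).

    Returns the signature matrix and, when ``labels`` is given, the
    co-indexed 0/1 label vector.
    """
    mask = cube.foreground if mask is None else np.asarray(mask).astype(bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask spatial dims must match the cube")
    if not mask.any():
        raise ValueError("empty foreground mask: no signatures to extract")
    coords = np.argwhere(mask)                     # row-major scan order
    rows = cube.values[mask]
    sig = SignatureMatrix(rows=rows, pixel_index=coords, sample_id=sample_id)
    label_vec = None
    if labels is not None:
        if labels.shape != cube.shape[:2]:
            raise ValueError("label mask dims must match the cube")
        label_vec = labels.values[mask].astype(int)
    return sig, label_vec


# --------------------------------------------------------------------------
# Patch extraction, augmentation, stitching
# --------------------------------------------------------------------------

def _mirror_pad_to_multiple(arr: np.ndarray, ph: int, pw: int) -> np.ndarray:
    h, w = arr.shape[:2]
    pad_h = (-h) % ph
    pad_w = (-w) % pw
    if pad_h == 0 and pad_w == 0:
        return arr
    pad = [(0, pad_h), (0, pad_w)] + [(0, 0)] * (arr.ndim - 2)
    return np.pad(arr, pad, mode="reflect")


def extract_patches(cube: ReflectanceCube,
                    labels: LabelMask | None = None,
                    patch_size: tuple[int, int] = DEFAULT_PATCH_SIZE,
                    drop_empty: bool = True,
                    dye_filter: Callable[[np.ndarray, np.ndarray], bool]
                    | None = None) -> PatchSet:
    """Tile the cube into non-overlapping patches from origin (0, 0).

    Dimensions not divisible by the patch size are mirror-padded up to the
    next multiple (stitching crops the padding back off). Patches with no
    foreground pixels are dropped when ``drop_empty``; ``dye_filter(patch,
    patch_foreground) -> bool`` drops patches it returns True for (e.g. a
    skin-dye detector).
    """
    ph, pw = patch_size
    h, w, _ = cube.shape
    if ph > h or pw > w:
        raise ValueError(f"patch size {patch_size} exceeds cube dims {(h, w)}")
    values = _mirror_pad_to_multiple(cube.values, ph, pw)
    fg = _mirror_pad_to_multiple(cube.foreground.astype(np.uint8), ph, pw)
    if labels is not None:
        if labels.shape != (h, w):
            raise ValueError("label mask dims must match the cube")
        lab = _mirror_pad_to_multiple(labels.values, ph, pw)
    else:
        lab = np.zeros(values.shape[:2], dtype=np.uint8)

    patches, lab_patches, origins = [], [], []
    hp, wp = values.shape[:2]
    for r in range(0, hp, ph):
        for c in range(0, wp, pw):
            patch = values[r:r + ph, c:c + pw]
            patch_fg = fg[r:r + ph, c:c + pw].astype(bool)
            if drop_empty and not patch_fg.any():
                continue
            if dye_filter is not None and dye_filter(patch, patch_fg):
                continue
            patches.append(patch)
            lab_patches.append(lab[r:r + ph, c:c + pw])
            origins.append((r, c))
    return PatchSet(patches=patches, labels=lab_patches, grid_origin=origins,
                    source_shape=(h, w), patch_size=(ph, pw),
                    padded_shape=(hp, wp))


def sam_dye_filter(dye_reference: np.ndarray,
                   angle_threshold: float = 0.10,
                   max_dye_fraction: float = 0.25
                   ) -> Callable[[np.ndarray, np.ndarray], bool]:
    """Build a patch predicate that drops dye-stained patches.

    A foreground pixel counts as dyed when its spectral angle to
    ``dye_reference`` is below ``angle_threshold`` radians; the patch is
    dropped when more than ``max_dye_fraction`` of its foreground pixels are
    dyed.
    """
    from .unmix import spectral_angle

    def predicate(patch: np.ndarray, patch_fg: np.ndarray) -> bool:
        if not patch_fg.any():
            return False
        spectra = patch[patch_fg]
        norms = np.linalg.norm(spectra, axis=1)
        ok = norms > 0
        if not ok.any():
            return False
        angles = np.array([spectral_angle(s, dye_reference)
                           for s in spectra[ok]])
        return float((angles < angle_threshold).mean()) > max_dye_fraction

    return predicate


def augment_flips(patchset: PatchSet) -> PatchSet:
    """Fourfold flip augmentation: original + vertical + horizontal + both.

    Label patches are flipped identically; augmented copies are flagged so
    stitching only uses the originals.
    """
    if len(patchset) == 0:
        raise ValueError("cannot augment an empty patch set")
    patches, labels, origins, aug = [], [], [], []
    for p, l, o, a in zip(patchset.patches, patchset.labels,
                          patchset.grid_origin, patchset.is_augmented):
        for i, (fv, fh) in enumerate([(False, False), (True, False),
                                      (False, True), (True, True)]):
            q, m = p, l
            if fv:
                q, m = q[::-1], m[::-1]
            if fh:
                q, m = q[:, ::-1], m[:, ::-1]
            patches.append(np.ascontiguousarray(q))
            labels.append(np.ascontiguousarray(m))
            origins.append(o)
            aug.append(a or i > 0)
    return PatchSet(patches=patches, labels=labels, grid_origin=origins,
                    source_shape=patchset.source_shape,
                    patch_size=patchset.patch_size,
                    padded_shape=patchset.padded_shape,
                    is_augmented=aug)


def stitch_patches(predictions: Sequence[np.ndarray],
                   patchset: PatchSet) -> np.ndarray:
    """Place per-patch 2-D predictions back on the source frame.

    ``predictions`` is co-indexed with the *original* (non-augmented)
    patches. Tiles that were dropped at extraction stay 0 (non-tumor); the
    mirror-padded margin is cropped off.
    """
    originals = patchset.originals
    if len(predictions) != len(originals):
        raise ValueError(
            f"got {len(predictions)} predictions for {len(originals)} "
            "original patches")
    ph, pw = patchset.patch_size
    canvas = np.zeros(patchset.padded_shape, dtype=float)
    for pred, idx in zip(predictions, originals):
        pred = np.asarray(pred)
        if pred.shape != (ph, pw):
            raise ValueError(f"prediction shape {pred.shape} != patch size")
        r, c = patchset.grid_origin[idx]
        canvas[r:r + ph, c:c + pw] = pred
    h, w = patchset.source_shape
    return canvas[:h, :w]
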