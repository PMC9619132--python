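"""Synthetic skin-lesion phantoms for end-to-end pipeline testing.

Generates labelled capture triplets (tissue / white-reference / dark-signal
cubes plus tumor and tissue masks) with the statistical structure the
segmentation frameworks assume: chromophore-driven tumor/normal spectral
contrast in the 420-750 nm range, a smooth illumination gradient, additive
sensor noise, and a dark low-albedo background surface.

The chromophore curves are analytic stand-ins — an exponentially decaying
melanin absorbance, Gaussian-mixture hemoglobin bands (oxyhemoglobin peaks
at 542 and 577 nm, deoxyhemoglobin at 555 nm) and a power-law scattering
baseline — not literature extinction tables. They reproduce the qualitative
features that drive tissue contrast (melanin monotonically decreasing with
wavelength, the hemoglobin double valley at 540/570 nm) while staying fully
self-contained and license-free.

Reflectance follows a Beer-Lambert-style forward model,

    r(lambda) = albedo(lambda) * exp(-sum_c conc_c * A_c(lambda)),

and the synthetic camera applies ``target = L * r + dark + noise`` with a
white capture ``white = L + dark + noise`` of a unit-reflectance surface, so
flat-field normalization of a noiseless phantom recovers ``r`` exactly.
Tumor regions carry higher melanin and total-hemoglobin concentrations than
normal tissue; a margin-softness parameter mixes the two concentration
fields near the border to emulate the hard margin-detection regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .io import (CaptureTriplet, HSICube, LabelMask, SpectralAxis,
                 default_axis)

__all__ = [
    "ChromophoreModel",
    "PhantomConfig",
    "TumorBlob",
    "PhantomSample",
    "build_chromophore_model",
    "reflectance_from_concentrations",
    "generate_phantom",
    "generate_dataset",
]

CHROMOPHORES = ("melanin", "hb_oxy", "hb_deoxy", "scattering")


@dataclass(frozen=True)
class ChromophoreModel:
    """Analytic absorbance-like curves for the main skin chromophores."""

    axis: SpectralAxis
    absorbers: dict[str, np.ndarray]
    baseline_albedo: np.ndarray

    def curve(self, name: str) -> np.ndarray:
        return self.absorbers[name]


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def build_chromophore_model(axis: SpectralAxis) -> ChromophoreModel:
    """Build the analytic chromophore curves on a spectral axis.

    The axis must lie within 380-800 nm (the supported visible range).
    """
    wl = axis.wavelengths_nm
    if wl[0] < 380.0 or wl[-1] > 800.0:
        raise ValueError("spectral axis must lie within 380-800 nm")
    # Melanin: exponential decay with wavelength (monotone decreasing).
    melanin = 1.8 * np.exp(-(wl - 380.0) / 180.0)
    # Oxyhemoglobin: Soret-side rise plus the 542/577 nm double peak.
    hb_oxy = (1.2 * _gaussian(wl, 542.0, 12.0)
              + 1.1 * _gaussian(wl, 577.0, 11.0)
              + 0.9 * _gaussian(wl, 420.0, 25.0))
    # Deoxyhemoglobin: single broad band around 555 nm.
    hb_deoxy = (1.5 * _gaussian(wl, 555.0, 20.0)
                + 0.8 * _gaussian(wl, 430.0, 25.0))
    # Scattering baseline: weak power-law absorbance-equivalent.
    scattering = 0.5 * (wl / 500.0) ** (-1.2)
    albedo = 0.85 * np.ones_like(wl)
    return ChromophoreModel(
        axis=axis,
        absorbers={"melanin": melanin, "hb_oxy": hb_oxy,
                   "hb_deoxy": hb_deoxy, "scattering": scattering},
        baseline_albedo=albedo)


def reflectance_from_concentrations(
        model: ChromophoreModel,
        concentrations: dict[str, float] | Sequence[float]) -> np.ndarray:
    """Beer-Lambert reflectance spectrum for a chromophore mixture.

    Zero concentrations return the flat baseline albedo; increasing any
    concentration lowers reflectance pointwise.
    """
    if not isinstance(concentrations, dict):
        concentrations = dict(zip(CHROMOPHORES, concentrations))
    total = np.zeros(model.axis.band_count)
    for name, conc in concentrations.items():
        conc = float(conc)
        if conc < 0:
            raise ValueError(f"concentration of {name!r} must be >= 0")
        total = total + conc * model.curve(name)
    return model.baseline_albedo * np.exp(-total)


# --------------------------------------------------------------------------
# Phantom geometry and configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TumorBlob:
    """A soft elliptical tumor region, in fractions of the image size."""

    center: tuple[float, float] = (0.5, 0.5)
    radii: tuple[float, float] = (0.24, 0.24)   # ~1/3 of the tissue area
    softness: float = 0.03     # margin width as a fraction of the image


# Concentrations chosen so tumor tissue carries more melanin and more total
# hemoglobin than normal tissue (vascularization + deep melanin), giving a
# tumor/normal mean-spectrum separation of a few degrees of spectral angle.
_NORMAL_CONC = {"melanin": 0.35, "hb_oxy": 0.25, "hb_deoxy": 0.10,
                "scattering": 0.30}
_TUMOR_CONC = {"melanin": 0.95, "hb_oxy": 0.55, "hb_deoxy": 0.35,
               "scattering": 0.30}
_BACKGROUND_ALBEDO = 0.02     # black porous capture surface


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int] = (96, 96)
    band_count: int = 311
    wavelength_start_nm: float = 420.0
    wavelength_end_nm: float = 730.0
    tissue_center: tuple[float, float] = (0.5, 0.5)
    tissue_radii: tuple[float, float] = (0.42, 0.42)
    tumor_blobs: tuple[TumorBlob, ...] = (TumorBlob(),)
    normal_concentrations: dict = field(default_factory=lambda: dict(_NORMAL_CONC))
    tumor_concentrations: dict = field(default_factory=lambda: dict(_TUMOR_CONC))
    illumination_gradient: float = 0.15
    dark_level: float = 0.01
    noise_sd: float = 0.004
    dye_blobs: tuple[TumorBlob, ...] = ()
    seed: int = 0

    def axis(self) -> SpectralAxis:
        # span the full visible window at any band count (1 nm step at 311)
        if self.band_count == 1:
            return SpectralAxis(np.array([self.wavelength_start_nm]))
        step = (self.wavelength_end_nm - self.wavelength_start_nm) \
            / (self.band_count - 1)
        return default_axis(self.band_count, self.wavelength_start_nm, step)


@dataclass
class PhantomSample:
    triplet: CaptureTriplet
    gt_tumor: LabelMask
    gt_tissue: np.ndarray
    metadata: dict


def _soft_ellipse(h: int, w: int, center: tuple[float, float],
                  radii: tuple[float, float], softness: float) -> np.ndarray:
    """Field in [0,1]: ~1 inside the ellipse, 0 outside, smooth edge."""
    rows = (np.arange(h) + 0.5) / h
    cols = (np.arange(w) + 0.5) / w
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    d = np.sqrt(((rr - center[0]) / radii[0]) ** 2
                + ((cc - center[1]) / radii[1]) ** 2)
    if softness <= 0:
        return (d <= 1.0).astype(float)
    # smoothstep edge with compact support: exactly 1 inside d <= 1-s,
    # exactly 0 outside d >= 1+s, 0.5 on the boundary
    scale = softness / min(radii)
    t = np.clip((1.0 + scale - d) / (2.0 * scale), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Generate one labelled capture triplet, fully determined by the seed."""
    h, w = config.shape
    axis = config.axis()
    model = build_chromophore_model(axis)
    rng = np.random.default_rng(config.seed)

    tissue_field = _soft_ellipse(h, w, config.tissue_center,
                                 config.tissue_radii, softness=0.0)
    gt_tissue = tissue_field > 0.5

    tumor_field = np.zeros((h, w))
    for blob in config.tumor_blobs:
        tumor_field = np.maximum(
            tumor_field,
            _soft_ellipse(h, w, blob.center, blob.radii, blob.softness))
    tumor_field *= gt_tissue
    gt_tumor = tumor_field > 0.5
    if gt_tumor.any() and not gt_tumor[gt_tissue].any():
        raise ValueError("tumor blobs fall entirely outside the tissue ellipse")
    if any(not gt_tissue[_soft_ellipse(h, w, b.center, b.radii, 0.0) > 0.5].all()
           for b in config.tumor_blobs if
           (_soft_ellipse(h, w, b.center, b.radii, 0.0) > 0.5).any()):
        raise ValueError("tumor blob extends outside the tissue ellipse")

    normal_spec = reflectance_from_concentrations(
        model, config.normal_concentrations)
    tumor_spec = reflectance_from_concentrations(
        model, config.tumor_concentrations)
    background_spec = np.full(axis.band_count, _BACKGROUND_ALBEDO)
    background_spec = background_spec * (axis.wavelengths_nm / 500.0) ** 0.1

    # Per-pixel reflectance: mix tumor/normal through the soft tumor field.
    mix = tumor_field[..., None]
    reflectance = normal_spec[None, None, :] * (1 - mix) + tumor_spec * mix
    reflectance = np.where(gt_tissue[..., None], reflectance,
                           background_spec[None, None, :])

    # Optional dye-stained regions: strong flat absorber over tissue.
    dye_mask = np.zeros((h, w), dtype=bool)
    for blob in config.dye_blobs:
        m = _soft_ellipse(h, w, blob.center, blob.radii, 0.0) > 0.5
        dye_mask |= m & gt_tissue
    if dye_mask.any():
        dye_spec = 0.08 + 0.25 * _gaussian(axis.wavelengths_nm, 640.0, 40.0)
        reflectance[dye_mask] = dye_spec

    # Smooth illumination field: unit mean with a planar gradient.
    cols = (np.arange(w) + 0.5) / w - 0.5
    rows = (np.arange(h) + 0.5) / h - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    illum = 1.0 + config.illumination_gradient * (0.7 * cc + 0.3 * rr)
    illum3 = illum[..., None]

    dark = np.full((h, w, axis.band_count), config.dark_level)
    noise = lambda: (rng.normal(0.0, config.noise_sd, size=(h, w, axis.band_count))
                     if config.noise_sd > 0 else 0.0)
    target = illum3 * reflectance + dark + noise()
    white = illum3 * 1.0 + dark + noise()
    dark_capture = dark + noise() * 0.25

    triplet = CaptureTriplet(
        target=HSICube(np.clip(target, 0.0, None), axis, "raw_target"),
        white=HSICube(np.clip(white, 1e-6, None), axis, "white_reference"),
        dark=HSICube(np.clip(dark_capture, 0.0, None), axis, "dark_signal"))

    metadata = {
        "seed": config.seed,
        "tumor_pixel_fraction": float(gt_tumor.sum() / max(gt_tissue.sum(), 1)),
        "normal_mean_spectrum": normal_spec,
        "tumor_mean_spectrum": tumor_spec,
        "background_spectrum": background_spec,
        "reflectance_field": reflectance,
        "dye_mask": dye_mask,
        "config": config,
    }
    return PhantomSample(
        triplet=triplet,
        gt_tumor=LabelMask(gt_tumor.astype(np.uint8), provenance="phantom"),
        gt_tissue=gt_tissue,
        metadata=metadata)


def default_config_sampler(rng: np.random.Generator,
                           base: PhantomConfig) -> PhantomConfig:
    """Jitter geometry around the base config; ~33% tumor-pixel prevalence.

    The default tumor radius is set so the expected tumor area is about one
    third of the tissue ellipse, matching the prevalence of tumor-labelled
    signatures the frameworks are tuned for; the sampler jitters position and
    size around that operating point.
    """
    tissue_r = float(np.mean(base.tissue_radii))
    # area ratio (r_t/r_e)^2 ~= 1/3  =>  r_t ~= 0.577 r_e
    r = tissue_r * 0.577 * rng.uniform(0.85, 1.15)
    # keep the blob inside the tissue ellipse
    max_off = max(tissue_r - r - 0.02, 0.0)
    dc = rng.uniform(-max_off, max_off, size=2) * 0.7
    blob = TumorBlob(center=(0.5 + dc[0], 0.5 + dc[1]),
                     radii=(r * rng.uniform(0.9, 1.1), r),
                     softness=base.tumor_blobs[0].softness if base.tumor_blobs
                     else 0.03)
    return replace(base, tumor_blobs=(blob,),
                   seed=int(rng.integers(0, 2 ** 31 - 1)))


def generate_dataset(n_samples: int,
                     config_sampler: Callable[[np.random.Generator,
                                               PhantomConfig], PhantomConfig]
                     | None = None,
                     seed: int = 0,
                     base_config: PhantomConfig | None = None
                     ) -> list[PhantomSample]:
    """Generate a reproducible list of phantom samples.

    ``config_sampler(rng, base)`` draws one per-sample config; the default
    sampler jitters tumor geometry around ~33% tumor-pixel prevalence.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    base = base_config or PhantomConfig()
    sampler = config_sampler or default_config_sampler
    rng = np.random.default_rng(seed)
    return [generate_phantom(sampler(rng, base)) for _ in range(n_samples)]
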