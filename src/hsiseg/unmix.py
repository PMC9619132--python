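"""Pixel-wise spectral framework: SAM, unmixing and classifier schemes.

Each foreground pixel is treated as an independent spectral signature.
Three segmentation schemes are provided:

* **Kmeans+SAM** (unsupervised): signatures are grouped into seven clusters
  by k-means, then each cluster is assigned tumor or normal by comparing the
  summed spectral-angle similarity of its member pixels to a small reference
  library (three normal and three tumor signatures by default).
* **Signature+SVM** (supervised): the raw reflectance signature is the
  feature vector of a kernel SVM.
* **Abundance+SVM** (supervised): signatures are first unmixed against a
  basis of endmembers extracted with the N-Findr maximum-simplex-volume
  algorithm, and the per-pixel abundance vector (default eight coefficients)
  is the feature vector.

The spectral angle mapper (SAM) between two spectra is the angle
``arccos(<x, y> / (|x||y|))`` — scale-invariant, so illumination amplitude
cancels. Abundances default to fully-constrained least squares (FCLS:
nonnegative coefficients summing to one); unconstrained and
nonnegative-only solvers are available for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import nnls as _scipy_nnls
from sklearn.cluster import KMeans
from sklearn.model_selection import cross_val_score
from sklearn.svm import SVC

from .evalkit import SegmentationResult
from .preprocess import ReflectanceCube, SignatureMatrix, extract_signatures
from .io import LabelMask

__all__ = [
    "EndmemberSet",
    "AbundanceMatrix",
    "ReferenceLibrary",
    "PixelClassifierModel",
    "ClassifierConfig",
    "spectral_angle",
    "nfindr_endmembers",
    "simplex_volume",
    "estimate_abundances",
    "kmeans_sam_segment",
    "subsample_equal_interval",
    "fit_pixel_classifier",
    "tune_pixel_classifier",
    "segment_pixelwise",
    "pixelwise_segmenter_factory",
]

# SVM defaults observed by Bayesian optimisation in the source study
DEFAULT_BOX_CONSTRAINT = 44.184
DEFAULT_KERNEL_SCALE = 4.0136
DEFAULT_N_ENDMEMBERS = 8
DEFAULT_N_CLUSTERS = 7


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class EndmemberSet:
    """Spectral basis of k "pure pixel" signatures (rows)."""

    spectra: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.spectra, dtype=float)
        if s.ndim != 2 or s.shape[0] < 2:
            raise ValueError("endmember set needs a k x bands matrix, k >= 2")
        if np.linalg.matrix_rank(s) < s.shape[0]:
            raise ValueError("endmember spectra must be linearly independent")
        self.spectra = s

    @property
    def k(self) -> int:
        return self.spectra.shape[0]

    @property
    def band_count(self) -> int:
        return self.spectra.shape[1]


@dataclass
class AbundanceMatrix:
    """Per-pixel mixing coefficients against an endmember basis."""

    values: np.ndarray                   # N x k
    endmembers: EndmemberSet
    residual_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != self.endmembers.k:
            raise ValueError("abundance matrix must be N x k")
        self.values = v


@dataclass
class ReferenceLibrary:
    """Labelled reference signatures for SAM comparison."""

    spectra: np.ndarray                  # m x bands
    class_of: Sequence[str]              # "normal" | "tumor" per row

    def __post_init__(self) -> None:
        s = np.asarray(self.spectra, dtype=float)
        labels = list(self.class_of)
        if s.ndim != 2 or len(labels) != s.shape[0]:
            raise ValueError("spectra and class_of must be co-indexed")
        bad = set(labels) - {"normal", "tumor"}
        if bad:
            raise ValueError(f"unknown reference classes: {bad}")
        if "normal" not in labels or "tumor" not in labels:
            raise ValueError("need at least one spectrum per class")
        self.spectra = s
        self.class_of = labels

    def of_class(self, cls: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.class_of) if c == cls]
        return self.spectra[idx]


@dataclass(frozen=True)
class ClassifierConfig:
    kernel: str = "rbf"
    box_constraint: float = DEFAULT_BOX_CONSTRAINT
    kernel_scale: float = DEFAULT_KERNEL_SCALE

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        if self.box_constraint <= 0 or self.kernel_scale <= 0:
            raise ValueError("box_constraint and kernel_scale must be > 0")

    @property
    def gamma(self) -> float:
        # MATLAB-style kernel scale sigma: K = exp(-|x-y|^2 / sigma^2)
        return 1.0 / (self.kernel_scale ** 2)


@dataclass
class PixelClassifierModel:
    feature_mode: str                    # "signature" | "abundance"
    config: ClassifierConfig
    svm: SVC

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.svm.predict(features).astype(int)

    def decision_scores(self, features: np.ndarray) -> np.ndarray:
        return self.svm.decision_function(features)


# --------------------------------------------------------------------------
# Spectral angle mapper
# --------------------------------------------------------------------------

def spectral_angle(x: np.ndarray, y: np.ndarray) -> float:
    """Angle in radians between two spectra; 0 iff positive scalar multiples."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("spectra must have equal length")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("spectral angle undefined for zero vectors")
    cosv = np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0)
    return float(np.arccos(cosv))


def _angles_to_refs(spectra: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Per-row minimum spectral angle to any reference row (vectorised)."""
    norms = np.linalg.norm(spectra, axis=1, keepdims=True)
    ref_norms = np.linalg.norm(refs, axis=1, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    cos = np.clip((spectra / safe) @ (refs / ref_norms).T, -1.0, 1.0)
    angles = np.arccos(cos)
    angles[norms.ravel() == 0] = np.pi / 2      # zero spectra: uninformative
    return angles.min(axis=1)


# --------------------------------------------------------------------------
# N-Findr endmember extraction
# --------------------------------------------------------------------------

def _project(signatures: np.ndarray, k: int) -> np.ndarray:
    """Center and project signatures to k-1 principal components."""
    mean = signatures.mean(axis=0)
    centered = signatures - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if np.sum(s > max(s[0], 1e-300) * 1e-9) < k - 1:
        raise ValueError(f"data rank below {k - 1}: cannot span a "
                         f"{k}-vertex simplex")
    return centered @ vt[:k - 1].T


def simplex_volume(points: np.ndarray) -> float:
    """(Unnormalised) volume of the simplex spanned by k points in k-1 dims.

    Proportional to ``|det [1; points^T]|``; the constant factor 1/(k-1)!
    is irrelevant for maximisation.
    """
    k = points.shape[0]
    m = np.ones((k, k))
    m[:, 1:] = points
    return abs(float(np.linalg.det(m)))


def nfindr_endmembers(signatures: SignatureMatrix | np.ndarray,
                      k: int = DEFAULT_N_ENDMEMBERS,
                      seed: int = 0,
                      max_sweeps: int = 10,
                      n_restarts: int = 3) -> EndmemberSet:
    """N-Findr: select the k signatures spanning the maximum-volume simplex.

    Signatures are projected to k-1 dimensions; from a seeded random start,
    full replacement sweeps swap in any pixel that enlarges the simplex
    volume until convergence (or ``max_sweeps``). Multiple restarts guard
    against local maxima; the result is deterministic given the seed.
    """
    data = signatures.rows if isinstance(signatures, SignatureMatrix) \
        else np.asarray(signatures, dtype=float)
    n = data.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} signatures, got {n}")
    proj = _project(data, k)
    rng = np.random.default_rng(seed)

    best_idx, best_vol = None, -1.0
    for _ in range(n_restarts):
        idx = list(rng.choice(n, size=k, replace=False))
        vol = simplex_volume(proj[idx])
        tries = 0
        while vol <= 0 and tries < 50:
            idx = list(rng.choice(n, size=k, replace=False))
            vol = simplex_volume(proj[idx])
            tries += 1
        for _sweep in range(max_sweeps):
            changed = False
            for pos in range(k):
                cand = np.array(idx)
                for j in range(n):
                    if j in idx:
                        continue
                    cand[pos] = j
                    v = simplex_volume(proj[cand])
                    if v > vol * (1 + 1e-12):
                        vol = v
                        idx = list(cand)
                        changed = True
                cand = np.array(idx)
            if not changed:
                break
        if vol > best_vol:
            best_vol, best_idx = vol, idx
    if best_idx is None or best_vol <= 0:
        raise ValueError("could not find a non-degenerate simplex")
    return EndmemberSet(spectra=data[np.array(best_idx)],
                        source=f"nfindr(k={k}, seed={seed})")


def exhaustive_endmembers(signatures: np.ndarray, k: int
                          ) -> tuple[np.ndarray, float]:
    """Brute-force max-volume subset (testing oracle; use only for small N)."""
    data = np.asarray(signatures, dtype=float)
    proj = _project(data, k)
    best, best_vol = None, -1.0
    for subset in combinations(range(data.shape[0]), k):
        v = simplex_volume(proj[list(subset)])
        if v > best_vol:
            best_vol, best = v, subset
    return np.array(best), best_vol


# --------------------------------------------------------------------------
# Abundance estimation
# --------------------------------------------------------------------------

def _fcls_single(E: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Fully-constrained LS for one pixel via active-set elimination.

    Solves min |E^T a - s|^2 subject to sum(a) = 1, a >= 0 by repeatedly
    solving the equality-constrained problem on the passive set and zeroing
    the most negative coefficient.
    """
    k = E.shape[0]
    passive = list(range(k))
    a = np.zeros(k)
    for _ in range(k):
        G = E[passive]                      # p x bands
        gram = G @ G.T
        p = len(passive)
        kkt = np.zeros((p + 1, p + 1))
        kkt[:p, :p] = gram
        kkt[:p, p] = 1.0
        kkt[p, :p] = 1.0
        rhs = np.concatenate([G @ s, [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
        a_p = sol[:p]
        if (a_p >= -1e-12).all() or p == 1:
            a[:] = 0.0
            a[passive] = np.maximum(a_p, 0.0)
            total = a.sum()
            if total > 0:
                a /= total
            return a
        passive.pop(int(np.argmin(a_p)))
    a[:] = 0.0
    a[passive] = 1.0 / len(passive)
    return a


def estimate_abundances(signatures: SignatureMatrix | np.ndarray,
                        endmembers: EndmemberSet,
                        mode: str = "fcls") -> AbundanceMatrix:
    """Per-pixel abundances of each signature against the endmember basis.

    ``fcls`` (default) enforces nonnegativity and sum-to-one; ``nnls``
    enforces nonnegativity only; ``ols`` is unconstrained least squares.
    """
    data = signatures.rows if isinstance(signatures, SignatureMatrix) \
        else np.asarray(signatures, dtype=float)
    E = endmembers.spectra
    if E.shape[1] != data.shape[1]:
        raise ValueError("endmember and signature band counts differ")
    if E.shape[0] > E.shape[1]:
        raise ValueError("endmember count must not exceed band count")
    cond = np.linalg.cond(E @ E.T)
    if cond > 1e10:
        warnings.warn(f"ill-conditioned endmember matrix (cond={cond:.2e})")
    if mode == "ols":
        coeffs, *_ = np.linalg.lstsq(E.T, data.T, rcond=None)
        values = coeffs.T
    elif mode == "nnls":
        values = np.stack([_scipy_nnls(E.T, s)[0] for s in data])
    elif mode == "fcls":
        values = np.stack([_fcls_single(E, s) for s in data])
    else:
        raise ValueError(f"unknown abundance mode {mode!r}")
    residual = np.linalg.norm(data - values @ E, axis=1)
    return AbundanceMatrix(values=values, endmembers=endmembers,
                           residual_norm=residual)


# --------------------------------------------------------------------------
# Kmeans+SAM unsupervised segmentation
# --------------------------------------------------------------------------

def kmeans_sam_segment(cube: ReflectanceCube,
                       refs: ReferenceLibrary,
                       n_clusters: int = DEFAULT_N_CLUSTERS,
                       seed: int = 0) -> SegmentationResult:
    """Cluster foreground spectra, then label whole clusters by SAM.

    For every cluster the summed per-pixel minimum angle to the tumor
    references is compared with the summed angle to the normal references;
    the cluster is tumor iff the tumor sum is strictly smaller (ties go to
    non-tumor, favouring specificity). The per-pixel score is the normal
    angle minus the tumor angle, so larger means more tumor-like.
    Background pixels are never labelled tumor.
    """
    if not cube.foreground.any():
        raise ValueError("cube has no foreground pixels")
    sig, _ = extract_signatures(cube)
    spectra = sig.rows
    tumor_refs = refs.of_class("tumor")
    normal_refs = refs.of_class("normal")
    if tumor_refs.shape[0] and normal_refs.shape[0] and \
            tumor_refs.shape == normal_refs.shape and \
            np.allclose(tumor_refs, normal_refs):
        warnings.warn("tumor and normal references are identical; "
                      "every cluster ties and resolves to non-tumor")

    n_clusters = min(n_clusters, len(spectra))
    if n_clusters == 1:
        assign = np.zeros(len(spectra), dtype=int)
    else:
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        assign = km.fit_predict(spectra)

    tumor_angle = _angles_to_refs(spectra, tumor_refs)
    normal_angle = _angles_to_refs(spectra, normal_refs)
    pixel_tumor = np.zeros(len(spectra), dtype=bool)
    for c in range(n_clusters):
        members = assign == c
        if not members.any():
            continue
        if tumor_angle[members].sum() < normal_angle[members].sum():
            pixel_tumor[members] = True

    mask = np.zeros(cube.shape[:2], dtype=np.uint8)
    scores = np.full(cube.shape[:2], -np.pi, dtype=float)
    rr, cc = sig.pixel_index[:, 0], sig.pixel_index[:, 1]
    mask[rr, cc] = pixel_tumor.astype(np.uint8)
    scores[rr, cc] = normal_angle - tumor_angle
    return SegmentationResult(mask=mask, scores=scores,
                              foreground=cube.foreground,
                              metadata={"method": "kmeans_sam",
                                        "n_clusters": n_clusters,
                                        "seed": seed})


# --------------------------------------------------------------------------
# Supervised classifier schemes
# --------------------------------------------------------------------------

def subsample_equal_interval(signatures: np.ndarray,
                             labels: np.ndarray | None = None,
                             fraction: float = 0.10
                             ) -> tuple[np.ndarray, np.ndarray | None]:
    """Deterministic equal-interval row subsampling (stride = round(1/f))."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    stride = max(int(round(1.0 / fraction)), 1)
    idx = np.arange(0, len(signatures), stride)
    sub = signatures[idx]
    sub_labels = labels[idx] if labels is not None else None
    return sub, sub_labels


def fit_pixel_classifier(features: np.ndarray,
                         labels: np.ndarray,
                         config: ClassifierConfig | None = None,
                         feature_mode: str = "signature"
                         ) -> PixelClassifierModel:
    """Fit the kernel SVM on signature or abundance feature vectors."""
    config = config or ClassifierConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes to fit a classifier")
    svm = SVC(C=config.box_constraint, kernel=config.kernel,
              gamma=config.gamma if config.kernel == "rbf" else "scale")
    svm.fit(features, labels)
    return PixelClassifierModel(feature_mode=feature_mode, config=config,
                                svm=svm)


def tune_pixel_classifier(features: np.ndarray,
                          labels: np.ndarray,
                          budget: int = 20,
                          search: str = "random",
                          seed: int = 0,
                          cv: int = 3) -> dict:
    """Hyperparameter search over kernel / box constraint / kernel scale.

    Sequential model-based ("Bayesian") optimisation is approximated by a
    seeded random search over the same space — kernel in {linear, rbf}, box
    constraint and kernel scale log-uniform in [1e-2, 1e3] — scored by
    cross-validated accuracy. The returned config records the search mode;
    the default config is always included so the result never regresses
    below it.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if search not in ("random", "bayes"):
        raise ValueError("search must be 'random' or 'bayes'")
    if search == "bayes":
        warnings.warn("no sequential model-based optimizer available; "
                      "falling back to seeded random search")
    rng = np.random.default_rng(seed)
    candidates = [ClassifierConfig()]
    for _ in range(budget):
        kernel = str(rng.choice(["linear", "rbf"]))
        box = float(10 ** rng.uniform(-2, 3))
        scale = float(10 ** rng.uniform(-2, 3))
        candidates.append(ClassifierConfig(kernel=kernel, box_constraint=box,
                                           kernel_scale=scale))
    best, best_score = None, -np.inf
    for cand in candidates:
        svm = SVC(C=cand.box_constraint, kernel=cand.kernel,
                  gamma=cand.gamma if cand.kernel == "rbf" else "scale")
        score = float(np.mean(cross_val_score(svm, features, labels, cv=cv)))
        if score > best_score:
            best, best_score = cand, score
    return {"kernel": best.kernel, "box_constraint": best.box_constraint,
            "kernel_scale": best.kernel_scale, "cv_accuracy": best_score,
            "search": "random", "budget": budget, "seed": seed}


def segment_pixelwise(cube: ReflectanceCube,
                      model: PixelClassifierModel,
                      endmembers: EndmemberSet | None = None
                      ) -> SegmentationResult:
    """Classify every foreground pixel and reshape back to image space.

    ``endmembers`` is required (and only used) for abundance-mode models.
    Background is forced non-tumor; continuous decision scores are kept for
    ROC analysis.
    """
    if model.feature_mode == "abundance" and endmembers is None:
        raise ValueError("abundance-mode model needs an endmember set")
    mask = np.zeros(cube.shape[:2], dtype=np.uint8)
    scores = np.full(cube.shape[:2], -np.inf, dtype=float)
    if not cube.foreground.any():
        return SegmentationResult(mask=mask,
                                  scores=np.where(np.isinf(scores), -1e6,
                                                  scores),
                                  foreground=cube.foreground,
                                  metadata={"method": "svm",
                                            "feature_mode": model.feature_mode})
    sig, _ = extract_signatures(cube)
    if model.feature_mode == "abundance":
        features = estimate_abundances(sig, endmembers).values
    else:
        features = sig.rows
    n_features = model.svm.n_features_in_
    if features.shape[1] != n_features:
        raise ValueError(f"model expects {n_features} features, "
                         f"got {features.shape[1]}")
    pred = model.predict(features)
    dec = model.decision_scores(features)
    rr, cc = sig.pixel_index[:, 0], sig.pixel_index[:, 1]
    mask[rr, cc] = pred.astype(np.uint8)
    scores[rr, cc] = dec
    scores = np.where(np.isinf(scores), np.nanmin(dec) - 1.0, scores)
    return SegmentationResult(mask=mask, scores=scores,
                              foreground=cube.foreground,
                              metadata={"method": "svm",
                                        "feature_mode": model.feature_mode})


# --------------------------------------------------------------------------
# Segmenter factories for the evaluation protocols
# --------------------------------------------------------------------------

def pixelwise_segmenter_factory(method: str = "svm-signature",
                                refs: ReferenceLibrary | None = None,
                                endmembers: EndmemberSet | None = None,
                                config: ClassifierConfig | None = None,
                                train_fraction: float = 0.10,
                                n_clusters: int = DEFAULT_N_CLUSTERS
                                ) -> Callable:
    """Build a ``segmenter_factory(train_samples, seed)`` for the evalkit.

    ``method`` is one of ``kmeans-sam``, ``svm-signature``,
    ``svm-abundance``. Supervised methods pool the foreground signatures of
    the training samples, keep an equal-interval ``train_fraction``
    subsample, and fit the SVM on it (on abundance features when an
    endmember set is supplied).
    """
    if method not in ("kmeans-sam", "svm-signature", "svm-abundance"):
        raise ValueError(f"unknown pixel-wise method {method!r}")
    if method == "kmeans-sam" and refs is None:
        raise ValueError("kmeans-sam needs a reference library")
    if method == "svm-abundance" and endmembers is None:
        raise ValueError("svm-abundance needs an endmember set")

    def factory(train_samples: Sequence[tuple[ReflectanceCube, LabelMask]],
                seed: int) -> Callable[[ReflectanceCube], SegmentationResult]:
        if method == "kmeans-sam":
            return lambda cube: kmeans_sam_segment(cube, refs,
                                                   n_clusters=n_clusters,
                                                   seed=seed)
        feats, labs = [], []
        for cube, labels in train_samples:
            sig, y = extract_signatures(cube, labels=labels)
            x = (estimate_abundances(sig, endmembers).values
                 if method == "svm-abundance" else sig.rows)
            feats.append(x)
            labs.append(y)
        features = np.concatenate(feats)
        labels_all = np.concatenate(labs)
        sub_x, sub_y = subsample_equal_interval(features, labels_all,
                                                fraction=train_fraction)
        if len(np.unique(sub_y)) < 2:     # tiny folds: fall back to full set
            sub_x, sub_y = features, labels_all
        mode = "abundance" if method == "svm-abundance" else "signature"
        model = fit_pixel_classifier(sub_x, sub_y, config=config,
                                     feature_mode=mode)
        return lambda cube: segment_pixelwise(cube, model,
                                              endmembers=endmembers)

    return factory
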