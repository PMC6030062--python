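"""Synthetic stimulus generators and preprocessing transforms.

Generators
----------
* :func:`make_rectangle_classes` — white-box image prototypes on a black
  background (the minimal visual instantiation of the model).
* :func:`make_synthetic_digits` — digit-like raw grayscale images whose
  per-class brightness is Gamma-distributed, emulating the class-brightness
  correlation of handwritten-digit data.
* :func:`make_synthetic_logatomes` — spectrogram-like stimuli: per-class
  time-frequency blob templates scaled by Gamma intensities with Poisson
  count noise, standing in for preprocessed nonsense-syllable recordings.
* :func:`build_sentence` — assemble a test "sentence" of utterances with at
  least two examples of each class.

Preprocessing
-------------
* :func:`normalize_shape_only` — normalize an image to total mass ``A`` with
  every pixel at least 1 (the input format required by shape-only circuits).
* :func:`brighten_preserving` — same normalization but rescaling each image
  foreground by its relative raw brightness ``f``, preserving brightness
  information.
* :func:`brighten_class_dependent` — additionally amplify the foreground by
  a label-dependent offset ``v(l)``, manufacturing a strong class-brightness
  dependence.
* :func:`trim_spectrogram` — center-of-mass trimming of spectrograms to a
  fixed duration, with edge/low-energy discard rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .model import Dataset, GammaPoissonParams, sample_dataset

__all__ = [
    "PreprocConfig",
    "TrimConfig",
    "TrimResult",
    "DEFAULT_V",
    "make_rectangle_classes",
    "make_synthetic_digits",
    "normalize_shape_only",
    "brighten_preserving",
    "brighten_class_dependent",
    "trim_spectrogram",
    "logatome_params",
    "make_synthetic_logatomes",
    "build_sentence",
    "to_counts",
]

logger = logging.getLogger(__name__)

#: Label-dependent foreground amplification offsets v(l) for the ten digit
#: classes of the brightness-enhanced image protocol.
DEFAULT_V = np.array([2.3, 3.4, 3.3, 4.0, 4.8, 5.3, 5.9, 6.7, 6.9, 7.5])


@dataclass
class PreprocConfig:
    """Constants of the image normalization / brightening transforms.

    ``A`` is the total mass every normalized image is mapped to, ``D`` the
    number of pixels (so the foreground carries mass ``A - D`` on top of the
    all-ones background), ``v`` the per-label brightening offsets, and
    ``gain`` a scale applied before rounding continuous data to counts.
    """

    A: float = 500.0
    D: int = 400
    v: NDArray[np.float64] = field(default_factory=lambda: DEFAULT_V.copy())
    gain: float = 1.0

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if not self.A > self.D:
            raise ValueError("A must exceed D so the foreground mass A-D is positive")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


@dataclass
class TrimConfig:
    """Constants of the spectrogram trimming pipeline.

    ``n_top_bins`` time bins of highest energy define the center of mass;
    the spectrogram is cut to ``half_width`` columns either side of it
    (width ``2*half_width + 1``); windows retaining less than
    ``energy_keep_fraction`` of the total energy are discarded.
    """

    n_top_bins: int = 20
    half_width: int = 50
    energy_keep_fraction: float = 0.65
    n_mel: int = 128

    def __post_init__(self) -> None:
        if min(self.n_top_bins, self.half_width, self.n_mel) < 1:
            raise ValueError("trim sizes must be positive")
        if not 0.0 < self.energy_keep_fraction < 1.0:
            raise ValueError("energy_keep_fraction must lie in (0, 1)")

    @property
    def width(self) -> int:
        return 2 * self.half_width + 1


@dataclass
class TrimResult:
    """Outcome of trimming one spectrogram: either the trimmed matrix or a
    discard ``reason`` (``"edge"`` or ``"energy"``)."""

    data: NDArray[np.float64] | None
    reason: str | None = None
    energy_fraction: float | None = None

    @property
    def kept(self) -> bool:
        return self.data is not None


def make_rectangle_classes(
    n_classes: int,
    image_side: int,
    box_sizes: list[int] | list[tuple[int, int]],
    seed: int | None = None,
    alpha: ArrayLike | None = None,
    beta: ArrayLike | None = None,
    lam: ArrayLike | None = None,
) -> GammaPoissonParams:
    """Model parameters whose prototypes are white boxes on black background.

    Each class is a uniformly bright rectangle (``box_sizes[c]``, a side
    length or ``(height, width)``) at a random position inside an
    ``image_side x image_side`` image, normalized to sum one.  Intensity
    parameters may be given as ``alpha``/``beta`` or as class means ``lam``
    (then ``alpha = 20`` per class, i.e. tight intensity distributions so
    classes are well separated in brightness); default means increase with
    class index so class 1 is the dimmest.
    """
    if len(box_sizes) != n_classes:
        raise ValueError("need one box size per class")
    rng = np.random.default_rng(seed)
    W = np.zeros((n_classes, image_side * image_side))
    for c, size in enumerate(box_sizes):
        h, w = (size, size) if np.isscalar(size) else size
        if h > image_side or w > image_side:
            raise ValueError(f"box {h}x{w} does not fit in a {image_side}-pixel image")
        r = int(rng.integers(0, image_side - h + 1))
        col = int(rng.integers(0, image_side - w + 1))
        img = np.zeros((image_side, image_side))
        img[r:r + h, col:col + w] = 1.0
        W[c] = img.ravel() / img.sum()
    if alpha is None or beta is None:
        if lam is None:
            lam = 50.0 * (2.0 ** np.arange(n_classes))
        lam = np.asarray(lam, dtype=float)
        alpha = np.full(n_classes, 20.0)
        beta = alpha / lam
    return GammaPoissonParams.create(W=W, alpha=alpha, beta=beta)


def _stroke_prototype(image_side: int, rng: np.random.Generator) -> NDArray[np.float64]:
    """A smoothed random-walk stroke on the image grid, normalized to sum one."""
    img = np.zeros((image_side, image_side))
    r, col = rng.integers(2, image_side - 2, size=2)
    for _ in range(4 * image_side):
        img[r, col] += 1.0
        r = int(np.clip(r + rng.integers(-1, 2), 0, image_side - 1))
        col = int(np.clip(col + rng.integers(-1, 2), 0, image_side - 1))
    img = (img + 0.5 * (np.roll(img, 1, 0) + np.roll(img, -1, 0)
                        + np.roll(img, 1, 1) + np.roll(img, -1, 1))) / 3.0
    return img.ravel() / img.sum()


def make_synthetic_digits(
    n_per_class: int,
    n_classes: int = 10,
    image_side: int = 20,
    seed: int | None = None,
    mean_brightness: float = 100.0,
    brightness_cv: float = 0.25,
    shape_similarity: float = 0.7,
) -> tuple[NDArray[np.float64], NDArray[np.int64]]:
    """Raw digit-like grayscale images with class-correlated brightness.

    Class prototypes are smoothed random-walk strokes; consecutive pairs of
    classes share a fraction ``shape_similarity`` of a common stroke, so some
    classes are hard to tell apart on shape alone (as confusable handwritten
    digits are).  Each image scales its prototype by a brightness drawn from
    a class-specific Gamma whose means increase with class index
    (within-class coefficient of variation ``brightness_cv``), then adds
    mild pixel noise.  Over a label-balanced batch the relative brightness
    factor ``f`` averages one by construction.

    Returns ``(raw, labels)`` with ``raw`` of shape
    ``(n_classes * n_per_class, image_side**2)`` and 1-based labels.
    """
    rng = np.random.default_rng(seed)
    D = image_side * image_side
    bases = [_stroke_prototype(image_side, rng)
             for _ in range((n_classes + 1) // 2)]
    protos = np.zeros((n_classes, D))
    for c in range(n_classes):
        own = _stroke_prototype(image_side, rng)
        protos[c] = shape_similarity * bases[c // 2] + (1.0 - shape_similarity) * own
        protos[c] /= protos[c].sum()
    # class mean brightnesses spread linearly, overall mean = mean_brightness
    class_means = mean_brightness * (0.55 + 0.9 * np.arange(n_classes) / max(n_classes - 1, 1))
    shape = 1.0 / brightness_cv**2
    raw = np.empty((n_classes * n_per_class, D))
    labels = np.empty(n_classes * n_per_class, dtype=np.int64)
    for c in range(n_classes):
        sl = slice(c * n_per_class, (c + 1) * n_per_class)
        b = rng.gamma(shape, class_means[c] / shape, size=n_per_class)
        imgs = b[:, None] * protos[c][None, :]
        imgs += rng.uniform(0.0, 0.02 * class_means[c] / D, size=imgs.shape)
        raw[sl] = imgs
        labels[sl] = c + 1
    perm = rng.permutation(raw.shape[0])
    return raw[perm], labels[perm]


def normalize_shape_only(raw: ArrayLike, cfg: PreprocConfig) -> NDArray[np.float64]:
    """Normalize image(s) to total mass ``A`` with a floor of one per pixel:

        y_d = (A - D) * raw_d / sum(raw) + 1.

    Accepts a single flattened image or a batch (rows = images).  The output
    is invariant to positive rescaling of the input.
    """
    raw = np.asarray(raw, dtype=float)
    single = raw.ndim == 1
    batch = np.atleast_2d(raw)
    if batch.shape[1] != cfg.D:
        raise ValueError(f"expected {cfg.D} pixels, got {batch.shape[1]}")
    if np.any(batch < 0):
        raise ValueError("raw images must be non-negative")
    sums = batch.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("raw images must have positive total brightness")
    out = (cfg.A - cfg.D) * batch / sums + 1.0
    return out[0] if single else out


def _brightness_factors(raw_batch: NDArray[np.float64]) -> NDArray[np.float64]:
    b = raw_batch.sum(axis=1)
    return b / b.mean()


def brighten_preserving(raw_batch: ArrayLike, cfg: PreprocConfig) -> NDArray[np.float64]:
    """Brightness-preserving normalization ``y = (y_SA - 1) * f + 1``.

    ``f`` is each image's raw brightness relative to the batch mean, so the
    batch mean of ``f`` is one and the class-specific brightness structure of
    the raw data survives normalization; the background stays at one.
    """
    raw_batch = np.atleast_2d(np.asarray(raw_batch, dtype=float))
    y_sa = normalize_shape_only(raw_batch, cfg)
    f = _brightness_factors(raw_batch)
    return (y_sa - 1.0) * f[:, None] + 1.0


def brighten_class_dependent(raw_batch: ArrayLike, labels: ArrayLike,
                             cfg: PreprocConfig) -> NDArray[np.float64]:
    """Class-dependent foreground amplification ``y = (y_SA - 1)(f + v(l)) + 1``.

    On top of the image's own brightness factor ``f``, the foreground is
    amplified by the label-dependent offset ``v(l)`` (1-based labels index
    ``cfg.v``), producing total brightness ``(A - D)(f + v(l)) + D`` while the
    background remains exactly one.
    """
    raw_batch = np.atleast_2d(np.asarray(raw_batch, dtype=float))
    labels = np.asarray(labels)
    if labels.shape != (raw_batch.shape[0],):
        raise ValueError("need one label per image")
    if np.any(labels < 1) or np.any(labels > len(cfg.v)):
        raise ValueError(f"labels must lie in 1..{len(cfg.v)}")
    y_sa = normalize_shape_only(raw_batch, cfg)
    f = _brightness_factors(raw_batch)
    amp = f + cfg.v[labels - 1]
    return (y_sa - 1.0) * amp[:, None] + 1.0


def trim_spectrogram(spec: ArrayLike, cfg: TrimConfig | None = None) -> TrimResult:
    """Cut a spectrogram to a fixed duration around its high-energy center.

    The ``n_top_bins`` time bins of highest total energy define an
    energy-weighted center of mass (rounded to the nearest column, ties
    toward the earlier column); the window spans ``half_width`` columns to
    either side.  Discards with reason ``"edge"`` when the window leaves the
    recording and ``"energy"`` when it retains less than
    ``energy_keep_fraction`` of the total energy.
    """
    cfg = cfg or TrimConfig()
    spec = np.atleast_2d(np.asarray(spec, dtype=float))
    T = spec.shape[1]
    if T < 1:
        raise ValueError("spectrogram must have at least one time bin")
    energy = spec.sum(axis=0)
    k = cfg.n_top_bins
    if T < k:
        logger.info("spectrogram has %d < %d time bins; using all of them", T, k)
        top = np.arange(T)
    else:
        # columns tied with the k-th largest energy are all included, so the
        # center of mass is well defined for flat energy profiles
        thresh = np.sort(energy)[-k]
        top = np.flatnonzero(energy >= thresh)
    e_top = energy[top]
    if e_top.sum() <= 0:
        return TrimResult(None, reason="energy", energy_fraction=0.0)
    com = float(np.dot(top, e_top) / e_top.sum())
    center = int(np.ceil(com - 0.5))  # nearest, ties toward earlier column
    lo, hi = center - cfg.half_width, center + cfg.half_width
    if lo < 0 or hi >= T:
        return TrimResult(None, reason="edge")
    window = spec[:, lo:hi + 1]
    frac = float(window.sum() / energy.sum()) if energy.sum() > 0 else 0.0
    if frac < cfg.energy_keep_fraction:
        return TrimResult(None, reason="energy", energy_fraction=frac)
    return TrimResult(window.copy(), energy_fraction=frac)


def logatome_params(
    n_classes: int = 4,
    cfg: TrimConfig | None = None,
    seed: int | None = None,
    lam: ArrayLike | None = None,
    alpha: float = 30.0,
) -> GammaPoissonParams:
    """Gamma-Poisson parameters whose prototypes are spectrogram-like blobs.

    Each class template is a distinct smooth time-frequency blob (plus a weak
    broadband floor) on an ``n_mel x (2*half_width+1)`` grid, normalized to
    sum one; class mean intensities ``lam`` default to a spread of loudnesses
    so utterance classes differ systematically in brightness.
    """
    cfg = cfg or TrimConfig()
    rng = np.random.default_rng(seed)
    F, T = cfg.n_mel, cfg.width
    ff, tt = np.meshgrid(np.arange(F), np.arange(T), indexing="ij")
    W = np.empty((n_classes, F * T))
    # distinct syllables occupy distinct spectral regions: each class gets its
    # own frequency band (with jitter) and a random temporal articulation
    for c in range(n_classes):
        band = (c + 0.5) / n_classes
        tpl = np.full((F, T), 0.05 / (F * T))
        for _ in range(2):
            f0 = np.clip(band + rng.normal(0.0, 0.06), 0.05, 0.95) * F
            t0 = rng.uniform(0.25, 0.75) * T
            sf = rng.uniform(0.06, 0.12) * F
            st = rng.uniform(0.10, 0.25) * T
            tpl += np.exp(-0.5 * (((ff - f0) / sf) ** 2 + ((tt - t0) / st) ** 2))
        W[c] = tpl.ravel() / tpl.sum()
    if lam is None:
        lam = 200.0 * (1.0 + 1.2 * np.arange(n_classes))
    lam = np.asarray(lam, dtype=float)
    a = np.full(n_classes, float(alpha))
    return GammaPoissonParams.create(W=W, alpha=a, beta=a / lam)


def make_synthetic_logatomes(
    n_classes: int = 4,
    n_per_class: int = 60,
    seed: int | None = None,
    cfg: TrimConfig | None = None,
    lam: ArrayLike | None = None,
    alpha: float = 30.0,
) -> tuple[Dataset, GammaPoissonParams]:
    """Synthetic utterance spectrograms from class templates.

    Samples each utterance by scaling its class template with a Gamma
    intensity and applying element-wise Poisson count noise — the generative
    model on spectrogram-shaped prototypes.  Returns the dataset (with true
    class and intensity recorded) and the generating parameters.
    """
    params = logatome_params(n_classes, cfg, seed, lam, alpha)
    n = n_classes * n_per_class
    seed2 = None if seed is None else (seed + 1) % (2**31)
    data = sample_dataset(params, n, seed=seed2)
    return data, params


def build_sentence(test_set: Dataset, n_utterances: int = 10,
                   seed: int | None = None) -> Dataset:
    """Draw a random "sentence" with at least two utterances of every class.

    Classes come from ``labels`` (or ``true_c``).  Two examples of each class
    are drawn first, remaining slots are filled from the rest of the test
    set, and the utterance order is shuffled.
    """
    labels = test_set.labels if test_set.labels is not None else test_set.true_c
    if labels is None:
        raise ValueError("test set needs labels to balance the sentence")
    classes = np.unique(labels)
    if n_utterances < 2 * len(classes):
        raise ValueError(
            f"{n_utterances} utterances cannot cover {len(classes)} classes twice"
        )
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than two test examples")
        chosen.extend(rng.choice(idx, size=2, replace=False).tolist())
    rest = np.setdiff1d(np.arange(test_set.n), np.asarray(chosen))
    extra = n_utterances - len(chosen)
    if extra > 0:
        if len(rest) < extra:
            raise ValueError("test set too small for the requested sentence length")
        chosen.extend(rng.choice(rest, size=extra, replace=False).tolist())
    order = rng.permutation(len(chosen))
    return test_set.subset(np.asarray(chosen)[order])


def to_counts(Y: ArrayLike, gain: float = 1.0) -> NDArray[np.int64]:
    """Scale continuous stimuli by ``gain`` and round to non-negative counts,
    the domain in which the Poisson/negative-binomial likelihoods are exact."""
    Y = np.asarray(Y, dtype=float) * gain
    return np.maximum(np.rint(Y), 0).astype(np.int64)
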