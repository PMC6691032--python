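"""Pairwise similarity matrices.

The proposal graph is built from a symmetric matrix S giving a rough measure
of how similar every pair of items is.  The matrix only needs to be a rough
guide: graph quality affects sampler *efficiency*, never its stationary
distribution.  Supported sources:

* feature vectors, via negated Euclidean or L1 distance (larger = more
  similar, so that maximum-weight matching prefers near pairs);
* small RGB rasters, via negated L1 distance between 11-bin basic-color
  histograms;
* precomputed matrices (e.g. from latent semantic analysis or SIFT), loaded
  from delimited text and optionally combined after rescaling each source to
  unit off-diagonal variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InvalidArgumentError, InvalidInputError
from .fixtures import StimulusSet

__all__ = [
    "BASIC_COLOR_NAMES",
    "BASIC_COLOR_PROTOTYPES",
    "ColorHistogram",
    "color_histogram",
    "condensed_similarity",
    "pairwise_similarity",
    "combine_similarities",
]

#: The 11 basic color terms, in fixed bin order.
BASIC_COLOR_NAMES = (
    "black", "white", "gray", "red", "orange", "yellow",
    "green", "blue", "purple", "pink", "brown",
)

#: One RGB prototype per basic color (CSS reference values).  Pixels are
#: binned by nearest prototype in Euclidean RGB — a deliberately simple stand-in
#: for a full perceptual color-naming model.
BASIC_COLOR_PROTOTYPES = np.array(
    [
        (0, 0, 0),        # black
        (255, 255, 255),  # white
        (128, 128, 128),  # gray
        (255, 0, 0),      # red
        (255, 165, 0),    # orange
        (255, 255, 0),    # yellow
        (0, 128, 0),      # green
        (0, 0, 255),      # blue
        (128, 0, 128),    # purple
        (255, 192, 203),  # pink
        (165, 42, 42),    # brown
    ],
    dtype=float,
)


@dataclass
class ColorHistogram:
    """Counts of pixels assigned to each of the 11 basic colors."""

    counts: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (11,):
            raise InvalidArgumentError("a basic-color histogram has exactly 11 bins")
        if np.any(self.counts < 0):
            raise InvalidArgumentError("histogram counts must be nonnegative")

    def as_normalized(self) -> "ColorHistogram":
        if self.normalized:
            return self
        total = self.counts.sum()
        if total == 0:
            raise InvalidArgumentError("cannot normalize an empty histogram")
        return ColorHistogram(self.counts / total, normalized=True)


def color_histogram(pixels: np.ndarray, normalize: bool = False) -> ColorHistogram:
    """Classify each RGB pixel to its nearest basic-color prototype and count.

    ``pixels`` is any array reshapeable to ``(n_pixels, 3)`` with channel
    values in [0, 255].  Ties between prototypes break toward the lower bin
    index.  With ``normalize=False`` the counts sum to the pixel count.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.size == 0:
        raise InvalidInputError("empty raster")
    if pixels.shape[-1] != 3:
        raise InvalidInputError(f"expected RGB triples in the last axis, got shape {pixels.shape}")
    flat = pixels.reshape(-1, 3)
    if flat.min() < 0 or flat.max() > 255:
        raise InvalidInputError("RGB values must lie in [0, 255]")
    # squared distance to each prototype; argmin takes the first (lowest bin) on ties
    d2 = ((flat[:, None, :] - BASIC_COLOR_PROTOTYPES[None, :, :]) ** 2).sum(axis=2)
    assignment = np.argmin(d2, axis=1)
    counts = np.bincount(assignment, minlength=11).astype(float)
    if normalize:
        counts = counts / counts.sum()
    return ColorHistogram(counts, normalized=normalize)


def _feature_matrix(stimuli: StimulusSet, metric: str) -> np.ndarray:
    """Per-item vectors the chosen metric operates on (features or histograms)."""
    if metric in ("neg_euclidean", "neg_l1"):
        if stimuli.features is None:
            raise InvalidInputError("metric requires per-item features")
        bad = np.flatnonzero(~np.isfinite(stimuli.features).all(axis=1))
        if bad.size:
            raise InvalidInputError(
                f"non-finite features for item {stimuli.item_ids[bad[0]]!r}"
            )
        return stimuli.features
    if metric == "histogram_l1":
        if stimuli.pixel_data is None:
            raise InvalidInputError("histogram_l1 requires per-item pixel data")
        rows = []
        for item in stimuli.item_ids:
            if item not in stimuli.pixel_data:
                raise InvalidInputError(f"missing pixel data for item {item!r}")
            rows.append(color_histogram(stimuli.pixel_data[item], normalize=True).counts)
        return np.asarray(rows)
    raise InvalidArgumentError(f"unknown metric {metric!r}")


def condensed_similarity(stimuli: StimulusSet, metric: str = "neg_euclidean") -> np.ndarray:
    """Similarities for all n(n-1)/2 unordered pairs, in condensed (pdist) order.

    This is the all-pairs enumeration underlying :func:`pairwise_similarity`;
    its length is exactly the number of unordered item pairs.
    """
    vectors = _feature_matrix(stimuli, metric)
    scipy_metric = "euclidean" if metric == "neg_euclidean" else "cityblock"
    return -pdist(vectors, metric=scipy_metric)


def pairwise_similarity(stimuli: StimulusSet, metric: str = "neg_euclidean") -> np.ndarray:
    """Symmetric n×n similarity matrix over a stimulus set.

    Distances are negated so that *larger is more similar* and maximum-weight
    matching prefers near pairs; the diagonal is 0 and is ignored by every
    consumer (the matcher forbids self-edges).
    """
    return squareform(condensed_similarity(stimuli, metric))


def combine_similarities(matrices: list[np.ndarray]) -> np.ndarray:
    """Combine similarity sources: rescale each to unit off-diagonal variance, then add.

    This is how heterogeneous similarity measures (say a color-histogram
    matrix and a local-feature matrix) are merged on a common scale before
    matching.  Raises if any input has zero off-diagonal variance, naming its
    position.
    """
    if len(matrices) == 0:
        raise InvalidArgumentError("need at least one similarity matrix")
    mats = [np.asarray(m, dtype=float) for m in matrices]
    shape = mats[0].shape
    if len(shape) != 2 or shape[0] != shape[1]:
        raise InvalidArgumentError("similarity matrices must be square")
    n = shape[0]
    off = ~np.eye(n, dtype=bool)
    out = np.zeros(shape)
    for k, m in enumerate(mats):
        if m.shape != shape:
            raise InvalidArgumentError(f"matrix {k} has shape {m.shape}, expected {shape}")
        sd = float(np.std(m[off]))
        if sd == 0:
            raise InvalidArgumentError(f"matrix {k} has zero off-diagonal variance")
        out += m / sd
    np.fill_diagonal(out, 0.0)
    return out
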