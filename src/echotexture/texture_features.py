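"""MaZda-style texture descriptors for ultrasound ROI patches.

Six descriptor families are computed on an 8-bit ROI patch:

* histogram — first-order intensity statistics and percentiles;
* gradient — moments of the 3x3 central-difference gradient magnitude;
* autoregressive model — a four-neighbour causal 2-D AR fit (Teta1..Teta4,
  Sigma) describing directional structure vs. random scatter;
* co-occurrence matrix (GLCM) — eleven Haralick descriptors per offset, for
  the twenty standard offsets {(d,0),(0,d),(d,d),(d,-d) : d=1..5};
* run-length matrix (GLRLM) — five Galloway descriptors per direction, for
  horizontal, vertical and both diagonal scan directions;
* wavelet — per-scale Haar subband energies.

Each family is computed after requantizing the patch to the bit depth used
by the original MaZda workflow (GLCM 6 bits, gradient 8 bits, run-length
4 bits, wavelet 12 bits, i.e. no reduction for the last two on 8-bit input).

Axis convention: offsets are written ``(dx, dy)`` with ``dx`` columns
rightward and ``dy`` rows downward, so ``S(d,d)`` pairs run down-right as
displayed on screen and ``S(d,-d)`` up-right.  The 45-degree run-length
direction scans lines running up-right, offset ``(+1, -1)``.

Statistics that are undefined on the given patch (e.g. gradient kurtosis of
a constant patch) are returned as NaN and listed in
``FeatureVector.undefined`` — never silently zero-filled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pywt

from .ultrasound_io import ROIPatch

__all__ = [
    "QuantizationConfig",
    "QuantizedPatch",
    "GLCM",
    "RunLengthMatrix",
    "FeatureVector",
    "EQ1_FEATURES",
    "GLCM_OFFSETS",
    "RLM_DIRECTIONS",
    "quantize",
    "glcm",
    "glcm_features",
    "rlm_features",
    "gradient_features",
    "ar_model",
    "histogram_features",
    "wavelet_features",
    "extract_all",
    "feature_registry",
]

NormalizationMode = Literal["roi-minmax", "plus-minus-3-sigma", "full-range"]

#: The seven descriptors entering the published prediction equation.
EQ1_FEATURES = (
    "GrKurtosis",
    "Teta2",
    "Teta4",
    "S(2,2)InvDfMom",
    "S(3,-3)Contrast",
    "S(4,-4)DifEntrp",
    "45dgr_ShrtREmp",
)

#: The 20 standard co-occurrence offsets: 4 orientations x distances 1..5.
GLCM_OFFSETS = tuple(
    (dx, dy) for d in range(1, 6) for (dx, dy) in ((d, 0), (0, d), (d, d), (d, -d))
)

#: Run-length scan directions mapped to their (dx, dy) lattice step.
RLM_DIRECTIONS = {
    "Horzl": (1, 0),
    "Vertl": (0, 1),
    "45dgr": (1, -1),
    "135dr": (1, 1),
}

GLCM_FEATURE_NAMES = (
    "AngScMom",
    "Contrast",
    "Correlat",
    "SumOfSqs",
    "InvDfMom",
    "SumAverg",
    "SumVarnc",
    "SumEntrp",
    "Entropy",
    "DifVarnc",
    "DifEntrp",
)

RLM_FEATURE_NAMES = ("ShrtREmp", "LngREmp", "GLevNonU", "RLNonUni", "Fraction")


@dataclass(frozen=True)
class QuantizationConfig:
    """Bit depths and normalization used before each texture family.

    Defaults reproduce the acquisition-analysis settings of the original
    MaZda workflow.  ``entropy_log_base`` selects the logarithm used in all
    entropy-type descriptors (natural log by default).
    """

    glcm_bits: int = 6
    gradient_bits: int = 8
    rlm_bits: int = 4
    wavelet_bits: int = 12
    normalization_mode: NormalizationMode = "roi-minmax"
    entropy_log_base: float | Literal["e"] = "e"

    def __post_init__(self) -> None:
        for name in ("glcm_bits", "gradient_bits", "rlm_bits", "wavelet_bits"):
            bits = getattr(self, name)
            if not 1 <= bits <= 12:
                raise ValueError(f"{name} must be in [1, 12], got {bits}")
        if self.normalization_mode not in ("roi-minmax", "plus-minus-3-sigma", "full-range"):
            raise ValueError(f"unknown normalization mode {self.normalization_mode!r}")

    @property
    def log(self) -> Callable[[np.ndarray], np.ndarray]:
        if self.entropy_log_base == "e":
            return np.log
        if self.entropy_log_base == 10:
            return np.log10
        if self.entropy_log_base == 2:
            return np.log2
        base = float(self.entropy_log_base)
        return lambda x: np.log(x) / math.log(base)


@dataclass
class QuantizedPatch:
    """Patch requantized to ``levels = 2**bits`` gray levels."""

    grid: np.ndarray
    levels: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int64)
        if self.grid.size and (self.grid.min() < 0 or self.grid.max() >= self.levels):
            raise ValueError("quantized values must lie in [0, levels-1]")


@dataclass
class GLCM:
    """Symmetric, normalized gray-level co-occurrence matrix at one offset."""

    offset: tuple[int, int]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        total = self.matrix.sum()
        if self.matrix.size and abs(total - 1.0) > 1e-12:
            raise ValueError(f"GLCM must sum to 1 (got {total})")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("GLCM must be symmetric")

    @property
    def levels(self) -> int:
        return self.matrix.shape[0]


@dataclass
class RunLengthMatrix:
    """Counts of maximal constant-level runs by gray level and run length."""

    direction: str
    counts: np.ndarray  # levels x max_run_length, counts[i, k-1] = runs of length k

    @property
    def total_runs(self) -> int:
        return int(self.counts.sum())

    @property
    def total_pixels(self) -> int:
        k = np.arange(1, self.counts.shape[1] + 1)
        return int((self.counts * k).sum())


@dataclass
class FeatureVector:
    """Named map of texture descriptors.

    ``undefined`` collects names whose value could not be computed on the
    patch (stored as NaN in ``values``).
    """

    values: dict[str, float]
    undefined: set[str] = field(default_factory=set)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def __len__(self) -> int:
        return len(self.values)

    def update(self, other: "FeatureVector") -> None:
        self.values.update(other.values)
        self.undefined |= other.undefined

    def set(self, name: str, value: float) -> None:
        if value is None or not np.isfinite(value):
            self.values[name] = float("nan")
            self.undefined.add(name)
        else:
            self.values[name] = float(value)


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def quantize(
    patch: ROIPatch | np.ndarray,
    bits: int,
    mode: NormalizationMode = "roi-minmax",
) -> QuantizedPatch:
    """Requantize a patch to ``2**bits`` gray levels.

    ``roi-minmax`` maps the patch's own [min, max] linearly onto
    [0, 2**bits - 1] (a constant patch maps to all zeros);
    ``plus-minus-3-sigma`` maps [mean - 3 SD, mean + 3 SD] with clipping;
    ``full-range`` maps the fixed intensity range [0, 255].
    Values are rounded to the nearest level.
    """
    px = patch.pixels if isinstance(patch, ROIPatch) else np.asarray(patch)
    if px.size == 0:
        raise ValueError("cannot quantize an empty patch")
    px = px.astype(float)
    levels = 2**bits
    if mode == "roi-minmax":
        lo, hi = px.min(), px.max()
    elif mode == "plus-minus-3-sigma":
        mu, sd = px.mean(), px.std()
        lo, hi = mu - 3 * sd, mu + 3 * sd
    elif mode == "full-range":
        lo, hi = 0.0, 255.0
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if hi <= lo:
        grid = np.zeros_like(px, dtype=np.int64)
    else:
        scaled = (np.clip(px, lo, hi) - lo) * (levels - 1) / (hi - lo)
        grid = np.rint(scaled).astype(np.int64)
    return QuantizedPatch(grid=grid, levels=levels)


# ---------------------------------------------------------------------------
# co-occurrence matrix
# ---------------------------------------------------------------------------

def glcm(q: QuantizedPatch, offset: tuple[int, int]) -> GLCM:
    """Symmetric normalized co-occurrence matrix for one ``(dx, dy)`` offset.

    Every ordered pixel pair ``(s, s + offset)`` lying inside the patch is
    counted together with its reverse, then the matrix is normalized to sum
    to one.
    """
    dx, dy = offset
    if abs(dx) > 5 or abs(dy) > 5:
        raise ValueError("offsets are limited to |dx|, |dy| <= 5")
    h, w = q.grid.shape
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError(f"offset {offset} not representable in a {h}x{w} patch")
    # source window and shifted window for the (dx, dy) displacement
    ys = slice(max(0, -dy), h - max(0, dy))
    xs = slice(max(0, -dx), w - max(0, dx))
    yt = slice(max(0, dy), h - max(0, -dy))
    xt = slice(max(0, dx), w - max(0, -dx))
    a = q.grid[ys, xs].ravel()
    b = q.grid[yt, xt].ravel()
    n = q.levels
    counts = np.bincount(a * n + b, minlength=n * n).reshape(n, n).astype(float)
    counts = counts + counts.T  # symmetric accumulation
    total = counts.sum()
    if total == 0:
        raise ValueError(f"offset {offset} produced no pixel pairs")
    return GLCM(offset=offset, matrix=counts / total)


def glcm_features(g: GLCM, log: Callable = np.log) -> FeatureVector:
    """Eleven Haralick descriptors of one co-occurrence matrix.

    Names are prefixed ``S(dx,dy)``.  Gray-level indices are 0-based;
    ``0 * log 0`` is taken as 0 in all entropy terms.
    """
    p = g.matrix
    n = g.levels
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    diff = i - j

    fv = FeatureVector({})
    prefix = f"S({g.offset[0]},{g.offset[1]})"

    def ent(dist: np.ndarray) -> float:
        nz = dist[dist > 0]
        return float(-(nz * log(nz)).sum())

    px = p.sum(axis=1)
    mu = float((np.arange(n) * px).sum())
    var = float(((np.arange(n) - mu) ** 2 * px).sum())

    fv.set(prefix + "AngScMom", float((p**2).sum()))
    fv.set(prefix + "Contrast", float((diff**2 * p).sum()))
    if var > 0:
        corr = float(((i * j * p).sum() - mu * mu) / var)
        fv.set(prefix + "Correlat", corr)
    else:
        fv.set(prefix + "Correlat", float("nan"))
    fv.set(prefix + "SumOfSqs", var)
    fv.set(prefix + "InvDfMom", float((p / (1.0 + diff**2)).sum()))

    # sum and difference marginals
    ksum = np.arange(2 * n - 1)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (i + j).ravel(), p.ravel())
    kdiff = np.arange(n)
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(diff).ravel(), p.ravel())

    sum_avg = float((ksum * p_sum).sum())
    fv.set(prefix + "SumAverg", sum_avg)
    fv.set(prefix + "SumVarnc", float(((ksum - sum_avg) ** 2 * p_sum).sum()))
    fv.set(prefix + "SumEntrp", ent(p_sum))
    fv.set(prefix + "Entropy", ent(p))
    mu_d = float((kdiff * p_diff).sum())
    fv.set(prefix + "DifVarnc", float(((kdiff - mu_d) ** 2 * p_diff).sum()))
    fv.set(prefix + "DifEntrp", ent(p_diff))
    return fv


# ---------------------------------------------------------------------------
# run-length matrix
# ---------------------------------------------------------------------------

def _direction_lines(grid: np.ndarray, direction: str):
    """Yield each lattice line of the patch for one scan direction."""
    h, w = grid.shape
    if direction == "Horzl":
        for r in range(h):
            yield grid[r, :]
    elif direction == "Vertl":
        for c in range(w):
            yield grid[:, c]
    elif direction == "45dgr":
        # lines running up-right: traverse anti-diagonals with increasing x
        flipped = grid[::-1, :]  # up-right in image = down-right in flipped
        for k in range(-(h - 1), w):
            yield np.diagonal(flipped, offset=k)
    elif direction == "135dr":
        # lines running down-right
        for k in range(-(h - 1), w):
            yield np.diagonal(grid, offset=k)
    else:
        raise ValueError(f"unknown run-length direction {direction!r}")


def run_length_matrix(q: QuantizedPatch, direction: str) -> RunLengthMatrix:
    """Build the matrix of maximal constant-level runs for one direction."""
    max_len = max(q.grid.shape)
    counts = np.zeros((q.levels, max_len), dtype=np.int64)
    for line in _direction_lines(q.grid, direction):
        line = np.asarray(line)
        if line.size == 0:
            continue
        # run-length encode the line
        boundaries = np.flatnonzero(np.diff(line)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [line.size]))
        for s, e in zip(starts, ends):
            counts[line[s], e - s - 1] += 1
    return RunLengthMatrix(direction=direction, counts=counts)


def rlm_features(q: QuantizedPatch, direction: str) -> FeatureVector:
    """Five Galloway run-length descriptors for one scan direction.

    ``p(i, k)`` are raw run counts; normalization by the total number of
    runs ``C`` happens inside each descriptor.
    """
    rlm = run_length_matrix(q, direction)
    p = rlm.counts.astype(float)
    c = p.sum()
    k = np.arange(1, p.shape[1] + 1, dtype=float)
    fv = FeatureVector({})
    pre = f"{direction}_"
    if c == 0:
        for name in RLM_FEATURE_NAMES:
            fv.set(pre + name, float("nan"))
        return fv
    fv.set(pre + "ShrtREmp", float((p / k**2).sum() / c))
    fv.set(pre + "LngREmp", float((p * k**2).sum() / c))
    fv.set(pre + "GLevNonU", float((p.sum(axis=1) ** 2).sum() / c))
    fv.set(pre + "RLNonUni", float((p.sum(axis=0) ** 2).sum() / c))
    fv.set(pre + "Fraction", float(c / (p * k).sum()))
    return fv


# ---------------------------------------------------------------------------
# gradient
# ---------------------------------------------------------------------------

def gradient_map(patch: ROIPatch | np.ndarray) -> np.ndarray:
    """Central-difference gradient magnitude over the interior pixels."""
    px = (patch.pixels if isinstance(patch, ROIPatch) else np.asarray(patch)).astype(float)
    if px.shape[0] < 3 or px.shape[1] < 3:
        raise ValueError("gradient features need a patch of at least 3x3")
    gx = px[1:-1, 2:] - px[1:-1, :-2]
    gy = px[2:, 1:-1] - px[:-2, 1:-1]
    return np.sqrt(gx**2 + gy**2)


def gradient_features(patch: ROIPatch | np.ndarray) -> FeatureVector:
    """Moments of the 3x3-neighbourhood gradient magnitude.

    Kurtosis is excess kurtosis (normal distribution -> 0).  Skewness and
    kurtosis of a zero-variance gradient map are flagged undefined.
    """
    g = gradient_map(patch)
    return _moment_features(g.ravel(), prefix="Gr", nonzeros=True)


def _moment_features(x: np.ndarray, prefix: str, nonzeros: bool = False) -> FeatureVector:
    fv = FeatureVector({})
    mu = float(x.mean())
    var = float(x.var())  # population variance
    fv.set(prefix + "Mean", mu)
    fv.set(prefix + "Variance", var)
    if var > 0:
        m3 = float(((x - mu) ** 3).mean())
        m4 = float(((x - mu) ** 4).mean())
        fv.set(prefix + "Skewness", m3 / var**1.5)
        fv.set(prefix + "Kurtosis", m4 / var**2 - 3.0)
    else:
        fv.set(prefix + "Skewness", float("nan"))
        fv.set(prefix + "Kurtosis", float("nan"))
    if nonzeros:
        fv.set(prefix + "NonZeros", float((x > 0).mean()))
    return fv


# ---------------------------------------------------------------------------
# autoregressive model
# ---------------------------------------------------------------------------

def ar_model(patch: ROIPatch | np.ndarray) -> FeatureVector:
    """Fit the causal four-neighbour 2-D autoregressive texture model.

    On the mean-subtracted patch ``f``, ordinary least squares over all
    interior sites estimates

        f(x, y) = t1 f(x-1, y) + t2 f(x, y-1) + t3 f(x-1, y-1)
                  + t4 f(x+1, y-1) + e(x, y)

    returning ``Teta1..Teta4`` and ``Sigma`` (the residual standard
    deviation).  A patch with no intensity variation has no identifiable
    parameters; all five outputs are then flagged undefined.
    """
    px = (patch.pixels if isinstance(patch, ROIPatch) else np.asarray(patch)).astype(float)
    if px.shape[0] < 3 or px.shape[1] < 3:
        raise ValueError("the AR model needs a patch of at least 3x3")
    f = px - px.mean()
    y = f[1:, 1:-1].ravel()  # sites with all four neighbours in range
    X = np.column_stack(
        [
            f[1:, :-2].ravel(),   # (x-1, y)
            f[:-1, 1:-1].ravel(), # (x, y-1)
            f[:-1, :-2].ravel(),  # (x-1, y-1)
            f[:-1, 2:].ravel(),   # (x+1, y-1)
        ]
    )
    fv = FeatureVector({})
    if not np.any(X):
        for name in ("Teta1", "Teta2", "Teta3", "Teta4", "Sigma"):
            fv.set(name, float("nan"))
        return fv
    theta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta
    for idx, name in enumerate(("Teta1", "Teta2", "Teta3", "Teta4")):
        fv.set(name, float(theta[idx]))
    fv.set("Sigma", float(resid.std()))
    return fv


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

PERCENTILES = (1, 10, 50, 90, 99)


def histogram_features(patch: ROIPatch | np.ndarray) -> FeatureVector:
    """First-order statistics of the raw intensities.

    Percentiles use the inverted-CDF rule (smallest intensity whose
    cumulative frequency reaches the requested level), so they always equal
    an observed gray value.
    """
    px = (patch.pixels if isinstance(patch, ROIPatch) else np.asarray(patch)).astype(float)
    x = px.ravel()
    fv = _moment_features(x, prefix="")
    for q in PERCENTILES:
        fv.set(f"Perc{q:02d}", float(np.percentile(x, q, method="inverted_cdf")))
    return fv


# ---------------------------------------------------------------------------
# wavelet
# ---------------------------------------------------------------------------

MAX_WAVELET_SCALES = 5


def wavelet_features(patch: ROIPatch | np.ndarray) -> FeatureVector:
    """Per-scale Haar subband energies on the largest centered dyadic square.

    At each scale the low-pass image is decomposed once more; the energy of
    a subband is the mean of its squared coefficients.  ``HL`` holds the
    detail along x (vertical edges), ``LH`` the detail along y.
    """
    px = (patch.pixels if isinstance(patch, ROIPatch) else np.asarray(patch)).astype(float)
    h, w = px.shape
    side = 2 ** int(math.floor(math.log2(min(h, w))))
    if side < 16:
        raise ValueError("wavelet features need a patch of at least 16x16")
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    sub = px[r0 : r0 + side, c0 : c0 + side]
    n_scales = min(MAX_WAVELET_SCALES, int(math.log2(side)))
    fv = FeatureVector({})
    ll = sub
    for s in range(1, n_scales + 1):
        ll, (detail_y, detail_x, detail_xy) = pywt.dwt2(ll, "haar")
        fv.set(f"WavEnLL_{s}", float((ll**2).mean()))
        fv.set(f"WavEnLH_{s}", float((detail_y**2).mean()))
        fv.set(f"WavEnHL_{s}", float((detail_x**2).mean()))
        fv.set(f"WavEnHH_{s}", float((detail_xy**2).mean()))
    return fv


# ---------------------------------------------------------------------------
# full extraction and registry
# ---------------------------------------------------------------------------

FAMILIES = ("histogram", "gradient", "ar_model", "glcm", "rlm", "wavelet")


def extract_all(patch: ROIPatch, config: QuantizationConfig | None = None) -> FeatureVector:
    """Run all six descriptor families on one patch.

    Produces >= 250 named descriptors including the seven predictors of the
    published equation.  Deterministic for a fixed patch and configuration;
    undefined statistics propagate as NaN entries, never silent zeros.
    """
    config = config or QuantizationConfig()
    fv = FeatureVector({})
    fv.update(histogram_features(patch))
    if config.gradient_bits == 8:  # 8 bits on 8-bit input: no requantization
        fv.update(gradient_features(patch))
    else:
        fv.update(gradient_features(quantize(patch, config.gradient_bits,
                                             config.normalization_mode).grid))
    fv.update(ar_model(patch))
    q_glcm = quantize(patch, config.glcm_bits, config.normalization_mode)
    for offset in GLCM_OFFSETS:
        fv.update(glcm_features(glcm(q_glcm, offset), log=config.log))
    q_rlm = quantize(patch, config.rlm_bits, config.normalization_mode)
    for direction in RLM_DIRECTIONS:
        fv.update(rlm_features(q_rlm, direction))
    fv.update(wavelet_features(patch))
    return fv


def feature_family(name: str) -> str:
    """Map a canonical descriptor name to its family tag."""
    if name.startswith("Gr"):
        return "gradient"
    if name.startswith("Teta") or name == "Sigma":
        return "ar_model"
    if name.startswith("S("):
        return "glcm"
    if any(name.startswith(d + "_") for d in RLM_DIRECTIONS):
        return "rlm"
    if name.startswith("WavEn"):
        return "wavelet"
    return "histogram"


def feature_registry() -> "pd.DataFrame":
    """Machine-readable registry of every descriptor the extractor can emit."""
    import pandas as pd

    rows = []
    for name in ("Mean", "Variance", "Skewness", "Kurtosis") + tuple(
        f"Perc{q:02d}" for q in PERCENTILES
    ):
        rows.append((name, "histogram", "raw intensities"))
    for name in ("GrMean", "GrVariance", "GrSkewness", "GrKurtosis", "GrNonZeros"):
        rows.append((name, "gradient", "gradient_bits"))
    for name in ("Teta1", "Teta2", "Teta3", "Teta4", "Sigma"):
        rows.append((name, "ar_model", "raw intensities"))
    for dx, dy in GLCM_OFFSETS:
        for feat in GLCM_FEATURE_NAMES:
            rows.append((f"S({dx},{dy}){feat}", "glcm", "glcm_bits, entropy_log_base"))
    for direction in RLM_DIRECTIONS:
        for feat in RLM_FEATURE_NAMES:
            rows.append((f"{direction}_{feat}", "rlm", "rlm_bits"))
    for s in range(1, MAX_WAVELET_SCALES + 1):
        for band in ("LL", "LH", "HL", "HH"):
            rows.append((f"WavEn{band}_{s}", "wavelet", "wavelet_bits"))
    return pd.DataFrame(rows, columns=["name", "family", "config_dependencies"])
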