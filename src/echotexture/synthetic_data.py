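"""Synthetic inputs for the IMF pipeline.

Because the original carcass cohort is not publicly deposited, this module
generates every input the pipeline needs at desk scale:

* paired (IMFqa, IMFpred) cohorts from a bivariate normal whose means, SDs
  and correlation default to the published cohort summaries (5.10 ± 1.44 %
  vs 5.13 ± 1.31 %, squared correlation 0.76);
* per-group texture-feature cohorts drawn from the published per-group
  means/SDs of the seven equation descriptors;
* marbled speckle images: a smooth echo level modulated by multiplicative
  Rayleigh speckle plus bright elliptical fat deposits (no claim of
  acoustic realism — no point-spread function or scan conversion);
* patches generated by the causal 2-D autoregressive recursion, for
  parameter-recovery testing.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .imf_model import CohortRecord, GroupingScheme, assign_group
from .ultrasound_io import ROIPatch, UltrasoundImage

__all__ = [
    "CohortParams",
    "MarblingImageParams",
    "TABLE_GROUP_STATS",
    "simulate_cohort",
    "simulate_feature_cohort",
    "simulate_marbling_image",
    "simulate_ar_image",
]


@dataclass(frozen=True)
class CohortParams:
    """Bivariate-normal parameters of the (IMFqa, IMFpred) cohort.

    Defaults reproduce the published cohort: the correlation is the square
    root of the reported determination coefficient (R2 = 0.76), so the
    generator's population R2 equals it exactly.
    """

    mean_qa: float = 5.10
    sd_qa: float = 1.44
    mean_pred: float = 5.13
    sd_pred: float = 1.31
    rho: float = math.sqrt(0.76)

    def __post_init__(self) -> None:
        if self.sd_qa <= 0 or self.sd_pred <= 0:
            raise ValueError("standard deviations must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")


#: Published per-group mean/SD of the seven equation descriptors
#: (groups 1..3 = low/medium/high IMF).
TABLE_GROUP_STATS: dict[str, dict[int, tuple[float, float]]] = {
    "GrKurtosis":      {1: (2.14, 0.35), 2: (1.38, 0.83), 3: (3.44, 1.43)},
    "Teta2":           {1: (-0.43, 0.03), 2: (-0.47, 0.03), 3: (-0.47, 0.04)},
    "Teta4":           {1: (0.09, 0.02), 2: (0.10, 0.02), 3: (0.09, 0.03)},
    "S(2,2)InvDfMom":  {1: (0.22, 0.02), 2: (0.23, 0.02), 3: (0.21, 0.02)},
    "S(3,-3)Contrast": {1: (42.13, 9.72), 2: (40.47, 16.46), 3: (53.29, 20.54)},
    "S(4,-4)DifEntrp": {1: (1.17, 0.05), 2: (1.15, 0.08), 3: (1.21, 0.08)},
    "45dgr_ShrtREmp":  {1: (0.91, 0.01), 2: (0.90, 0.01), 3: (0.91, 0.01)},
}


def simulate_cohort(
    n: int,
    params: CohortParams | None = None,
    seed: int | np.random.Generator = 0,
    scheme: GroupingScheme | None = None,
) -> list[CohortRecord]:
    """Draw n paired (IMFqa, IMFpred) records and assign IMF groups."""
    if n < 2:
        raise ValueError("cohort size must be at least 2")
    params = params or CohortParams()
    scheme = scheme or GroupingScheme.printed()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = params.rho * params.sd_qa * params.sd_pred
    sigma = np.array([[params.sd_qa**2, cov], [cov, params.sd_pred**2]])
    draws = rng.multivariate_normal([params.mean_qa, params.mean_pred], sigma, size=n)
    return [
        CohortRecord(
            sample_id=f"synth{i:06d}",
            imf_qa=float(qa),
            imf_pred=float(pred),
            group=assign_group(float(qa), scheme),
        )
        for i, (qa, pred) in enumerate(draws)
    ]


def simulate_feature_cohort(
    n_per_group: int,
    group_stats: Mapping[str, Mapping[int, tuple[float, float]]] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-group feature table of the seven equation descriptors.

    Features are drawn independently within each group from normals with
    the published per-group means/SDs — a deliberate simplification (no
    covariances are published), sufficient for exercising selection and
    group statistics but not the real joint feature distribution.

    Returns ``(features, group_labels)`` with ``3 * n_per_group`` rows.
    """
    if n_per_group < 2:
        raise ValueError("need at least two samples per group")
    stats_map = group_stats or TABLE_GROUP_STATS
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    labels = []
    for g in (1, 2, 3):
        cols = {}
        for name, per_group in stats_map.items():
            mu, sd = per_group[g]
            cols[name] = rng.normal(mu, sd, size=n_per_group)
        frames.append(pd.DataFrame(cols))
        labels.extend([g] * n_per_group)
    features = pd.concat(frames, ignore_index=True)
    return features, np.asarray(labels)


@dataclass(frozen=True)
class MarblingImageParams:
    """Parameters of the marbled speckle image generator."""

    height: int = 256
    width: int = 256
    base_level: float = 90.0
    speckle_scale: float = 0.28        # Rayleigh scale of multiplicative speckle
    streak_count: int = 60             # number of bright elliptical deposits
    streak_intensity: float = 60.0     # peak added intensity per deposit
    streak_axes: tuple[float, float] = (2.0, 12.0)  # semi-axis range, pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError("image dimensions must be at least 64x64")
        if self.streak_count < 0:
            raise ValueError("streak_count must be non-negative")


def simulate_marbling_image(params: MarblingImageParams) -> UltrasoundImage:
    """Synthetic marbled muscle echotexture.

    A smooth base echo level is multiplied by Rayleigh speckle (normalized
    to unit mean), then elongated bright elliptical deposits mimicking
    intramuscular fat streaks are added at random positions and
    orientations.  Output is clipped to [0, 255].
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width

    # smooth spatial variation of the echo level (~10% of base)
    smooth = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=24)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    base = params.base_level * (1.0 + 0.1 * smooth)
    # multiplicative Rayleigh speckle, normalized to unit mean
    rayleigh_mean = params.speckle_scale * math.sqrt(math.pi / 2.0)
    speckle = rng.rayleigh(scale=params.speckle_scale, size=(h, w)) / rayleigh_mean
    img = base * speckle

    yy, xx = np.mgrid[0:h, 0:w]
    lo, hi = params.streak_axes
    for _ in range(params.streak_count):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a = rng.uniform(lo, hi)          # long semi-axis
        b = rng.uniform(lo, min(hi, a))  # short semi-axis
        angle = rng.uniform(0, math.pi)
        ca, sa = math.cos(angle), math.sin(angle)
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        r2 = (u / a) ** 2 + (v / b) ** 2
        img += params.streak_intensity * np.exp(-0.5 * r2 * 4.0)

    px = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return UltrasoundImage(pixels=px, source_id=f"marbling-seed{params.seed}")


def simulate_ar_image(
    theta: Sequence[float],
    sigma: float,
    size: int | tuple[int, int] = 256,
    seed: int | np.random.Generator = 0,
    burn_in: int = 16,
) -> ROIPatch:
    """Patch generated by the causal four-neighbour AR recursion.

        f(x, y) = t1 f(x-1, y) + t2 f(x, y-1) + t3 f(x-1, y-1)
                  + t4 f(x+1, y-1) + e(x, y),  e ~ N(0, sigma^2)

    A ``burn_in`` margin is generated on every side and discarded; the kept
    field is linearly rescaled to [0, 255] and rounded to integers.
    Raises on an unstable recursion (coefficient sum >= 1 in absolute
    value, or divergent field).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (4,):
        raise ValueError("theta must have exactly four components")
    if np.abs(theta).sum() >= 1.0:
        raise ValueError("unstable AR recursion: sum of |theta| must be < 1")
    if isinstance(size, int):
        h = w = size
    else:
        h, w = size
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gh, gw = h + 2 * burn_in, w + 2 * burn_in
    noise = rng.normal(0.0, sigma, size=(gh, gw))
    f = np.zeros((gh, gw))
    f[0, :] = noise[0, :]
    t1, t2, t3, t4 = theta
    for y in range(1, gh):
        prev = f[y - 1]
        # previous-row contribution, with zero boundary outside the grid
        drive = t2 * prev + noise[y]
        drive[1:] += t3 * prev[:-1]
        drive[:-1] += t4 * prev[1:]
        # in-row recursion row[x] = t1 * row[x-1] + drive[x]
        f[y] = signal.lfilter([1.0], [1.0, -t1], drive)
    if not np.all(np.isfinite(f)) or np.abs(f).max() > 1e9:
        raise ValueError("AR recursion diverged")
    kept = f[burn_in : burn_in + h, burn_in : burn_in + w]
    lo, hi = kept.min(), kept.max()
    if hi > lo:
        px = np.rint((kept - lo) * 255.0 / (hi - lo)).astype(np.uint8)
    else:
        px = np.zeros((h, w), dtype=np.uint8)
    return ROIPatch(pixels=px, source_id=f"ar-sigma{sigma}")
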