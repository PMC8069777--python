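"""Intramuscular-fat prediction from texture descriptors.

Holds the published seven-term linear prediction equation, the three-group
IMF classification (low / medium / high marbling), and the stepwise
ordinary-least-squares selection procedure with a variance-inflation-factor
(VIF) gate used to derive such equations from a feature table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PredictionEquation",
    "GroupingScheme",
    "CohortRecord",
    "StepwiseResult",
    "predict_imf",
    "derive_cutoffs",
    "assign_group",
    "stepwise_select",
    "vif",
]


@dataclass(frozen=True)
class PredictionEquation:
    """Linear map from named texture descriptors to IMF% (intercept + dot)."""

    intercept: float
    coefficients: Mapping[str, float]

    @classmethod
    def printed(cls) -> "PredictionEquation":
        """The published seven-term equation, loaded from the package data."""
        with resources.files("echotexture.data").joinpath("equation_printed.json").open() as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionEquation":
        return cls(intercept=float(d["intercept"]),
                   coefficients={k: float(v) for k, v in d["coefficients"].items()})

    @classmethod
    def from_json(cls, path: str | Path) -> "PredictionEquation":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"intercept": self.intercept,
                       "coefficients": dict(self.coefficients)}, fh, indent=2)


@dataclass(frozen=True)
class GroupingScheme:
    """Cutoffs splitting a cohort into low (1), medium (2), high (3) IMF.

    Boundary semantics are inclusive on the outer groups: group 1 iff
    ``imf <= low_cutoff``, group 3 iff ``imf >= high_cutoff``.
    """

    low_cutoff: float
    high_cutoff: float

    def __post_init__(self) -> None:
        if not self.low_cutoff < self.high_cutoff:
            raise ValueError("low_cutoff must be below high_cutoff")

    @classmethod
    def printed(cls) -> "GroupingScheme":
        """The published cutoffs: group 1 <= 4.24%, group 3 >= 5.76%."""
        return cls(low_cutoff=4.24, high_cutoff=5.76)


@dataclass
class CohortRecord:
    """One carcass: chemically quantified IMF, predicted IMF, group label."""

    sample_id: str
    imf_qa: float
    imf_pred: float
    group: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.imf_qa) and np.isfinite(self.imf_pred)):
            raise ValueError("IMF values must be finite")
        if self.group not in (1, 2, 3):
            raise ValueError("group must be 1, 2 or 3")


def cohort_frame(cohort: Sequence[CohortRecord]) -> pd.DataFrame:
    """Cohort records as a DataFrame (sample_id, IMFqa, IMFpred, group)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in cohort],
            "IMFqa": [r.imf_qa for r in cohort],
            "IMFpred": [r.imf_pred for r in cohort],
            "group": [r.group for r in cohort],
        }
    )


# ---------------------------------------------------------------------------
# prediction and grouping
# ---------------------------------------------------------------------------

def predict_imf(fv, eq: PredictionEquation | None = None) -> float:
    """Evaluate the prediction equation on one feature vector.

    ``fv`` may be a FeatureVector, a mapping, or a pandas Series.  Every
    coefficient name must be present with a finite value; a missing or
    undefined descriptor raises an error naming it.
    """
    eq = eq or PredictionEquation.printed()
    inner = getattr(fv, "values", None)
    values = inner if isinstance(inner, dict) else fv
    out = eq.intercept
    for name, coef in eq.coefficients.items():
        if name not in values:
            raise KeyError(f"feature vector is missing required descriptor {name!r}")
        v = float(values[name])
        if not np.isfinite(v):
            raise ValueError(f"required descriptor {name!r} is undefined on this patch")
        out += coef * v
    return float(out)


def derive_cutoffs(imfqa_values: Sequence[float]) -> GroupingScheme:
    """Cutoffs at mean +/- SD/2 of the quantified IMF (sample SD, n-1)."""
    x = np.asarray(imfqa_values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two IMF values to derive cutoffs")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("cannot derive cutoffs from constant IMF values")
    mean = float(x.mean())
    return GroupingScheme(low_cutoff=mean - sd / 2, high_cutoff=mean + sd / 2)


def assign_group(imf: float, scheme: GroupingScheme | None = None) -> int:
    """Classify one IMF% value into group 1, 2 or 3."""
    scheme = scheme or GroupingScheme.printed()
    if not np.isfinite(imf):
        raise ValueError("IMF value must be finite")
    if imf <= scheme.low_cutoff:
        return 1
    if imf >= scheme.high_cutoff:
        return 3
    return 2


# ---------------------------------------------------------------------------
# stepwise selection with a VIF gate
# ---------------------------------------------------------------------------

def vif(design: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Variance inflation factor of each column of the design matrix.

    ``VIF_j = 1 / (1 - R2_j)`` where ``R2_j`` regresses column j (with
    intercept) on all other columns.  A perfectly collinear column reports
    infinity.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("VIF needs a design matrix with at least two columns")
    n, k = X.shape
    if n <= k:
        raise ValueError("VIF needs more rows than columns")
    out = np.empty(k)
    for j in range(k):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = ((y - y.mean()) ** 2).sum()
        if tss == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - (resid**2).sum() / tss
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass
class StepwiseResult:
    """Outcome of forward-backward stepwise OLS selection."""

    selected: list[str]
    intercept: float
    coefficients: dict[str, float]
    vifs: dict[str, float]
    log: list[dict] = field(default_factory=list)

    def to_equation(self) -> PredictionEquation:
        return PredictionEquation(intercept=self.intercept, coefficients=dict(self.coefficients))


def _ols_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS with intercept: (beta, two-sided t p-values per slope, rss)."""
    import statsmodels.api as sm

    n, k = X.shape
    A = sm.add_constant(X, has_constant="add")
    if n <= k + 1:
        beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        return beta, np.full(k, np.nan), float(((y - A @ beta) ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = sm.OLS(y, A).fit()
    return np.asarray(fit.params), np.asarray(fit.pvalues)[1:], float(fit.ssr)


def stepwise_select(
    features: pd.DataFrame,
    imfqa: Sequence[float],
    slentry: float = 0.15,
    slstay: float = 0.15,
    vif_max: float = 10.0,
) -> StepwiseResult:
    """Forward-backward stepwise OLS with an in-loop collinearity gate.

    At each forward step the candidate with the smallest partial p-value
    enters if it clears ``slentry`` *and* entering it keeps every VIF below
    ``vif_max``; candidates that would violate the gate are skipped (logged).
    After each entry, variables whose p-value has drifted above ``slstay``
    are removed.  Candidates containing undefined (NaN) values are dropped
    up front with a log entry rather than imputed.

    Entry/stay defaults follow the common SAS stepwise convention (0.15).
    """
    y = np.asarray(imfqa, dtype=float)
    n = len(y)
    if len(features) != n:
        raise ValueError("features and responses must have the same length")
    log: list[dict] = []
    candidates = []
    for name in features.columns:
        col = features[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            log.append({"action": "drop", "feature": name,
                        "reason": "undefined (non-finite) values"})
        else:
            candidates.append(name)

    selected: list[str] = []
    step = 0
    while True:
        step += 1
        if n <= len(selected) + 2:
            raise ValueError("too few observations for another step")
        remaining = [c for c in candidates if c not in selected]
        if not remaining:
            break
        # current residual variance; nothing left to explain -> stop
        if selected:
            _, _, rss_cur = _ols_pvalues(features[selected].to_numpy(float), y)
        else:
            rss_cur = float(((y - y.mean()) ** 2).sum())
        if rss_cur <= 1e-12 * max(1.0, float((y**2).sum())):
            log.append({"step": step, "action": "stop", "reason": "residuals exhausted"})
            break

        # score every remaining candidate by its partial p-value
        scored = []
        for cand in remaining:
            trial = selected + [cand]
            X = features[trial].to_numpy(float)
            _, p, _ = _ols_pvalues(X, y)
            scored.append((p[-1] if np.isfinite(p[-1]) else np.inf, cand))
        scored.sort(key=lambda t: t[0])

        entered = None
        for p_cand, cand in scored:
            if p_cand >= slentry:
                break
            trial = selected + [cand]
            if len(trial) >= 2:
                trial_vif = vif(features[trial].to_numpy(float))
                if np.any(trial_vif >= vif_max):
                    log.append({"step": step, "action": "skip", "feature": cand,
                                "reason": f"VIF gate (max VIF {np.max(trial_vif):.3g})"})
                    continue
            selected.append(cand)
            log.append({"step": step, "action": "enter", "feature": cand, "p": p_cand})
            entered = cand
            break
        if entered is None:
            break

        # backward pass: drop anything whose p drifted above slstay
        while len(selected) > 1:
            _, p, _ = _ols_pvalues(features[selected].to_numpy(float), y)
            worst = int(np.nanargmax(p))
            if np.isfinite(p[worst]) and p[worst] > slstay:
                removed = selected.pop(worst)
                log.append({"step": step, "action": "remove", "feature": removed,
                            "p": float(p[worst])})
            else:
                break

    if not selected:
        return StepwiseResult(selected=[], intercept=float(y.mean()),
                              coefficients={}, vifs={}, log=log)
    X = features[selected].to_numpy(float)
    beta, _, _ = _ols_pvalues(X, y)
    vifs = (dict(zip(selected, vif(X))) if len(selected) >= 2
            else {selected[0]: 1.0})
    return StepwiseResult(
        selected=list(selected),
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(selected, beta[1:])},
        vifs=vifs,
        log=log,
    )
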