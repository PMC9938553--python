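"""Combined two-marker diagnostic model: split, fit, score, ROC, cut-off.

The diagnostic score is the linear predictor of a logistic regression of
disease status on the mean qMSP Ct values of the two markers,

    score = b0 + b1 * Ct(cg13096260) + b2 * Ct(cg12993163),

with negative marker coefficients because a lower Ct means more methylated
template (more disease-like). A published, frozen instance of this model
ships with the package and is evaluated by pure arithmetic, never refit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import ConfigError, InputError


# ---------------------------------------------------------------------------
# stratified splitting


@dataclass(frozen=True)
class SplitConfig:
    """Stratified train/validation split settings.

    ratio : training fraction (default 2/3, a 2:1 split)
    rounding : per-stratum training count rule — 'nearest' (round half up,
        default), 'up' (ceil) or 'down' (floor)
    seed : RNG seed
    """

    ratio: float = 2 / 3
    rounding: str = "nearest"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ratio < 1:
            raise ConfigError("ratio must lie in (0, 1)")
        if self.rounding not in ("nearest", "up", "down"):
            raise ConfigError(f"unknown rounding {self.rounding!r}")


def _train_count(n: int, cfg: SplitConfig) -> int:
    x = cfg.ratio * n
    if cfg.rounding == "nearest":
        return int(np.floor(x + 0.5))  # round half up
    return int(np.ceil(x)) if cfg.rounding == "up" else int(np.floor(x))


def stratified_split(strata: pd.Series, cfg: SplitConfig | None = None) -> tuple[list, list]:
    """Split sample ids into training/validation sets, per stratum.

    ``strata`` maps sample id (index) to a stratum label (clinical group,
    with CRC typically sub-stratified by stage I–II vs III–IV). Within each
    stratum exactly ``round(ratio * n)`` samples (under the configured
    rounding) go to training; membership is seed-deterministic, the counts
    are not random.
    """
    cfg = cfg or SplitConfig()
    if strata.isna().any():
        raise InputError("every sample needs a stratum label")
    rng = np.random.default_rng(cfg.seed)
    train: list = []
    val: list = []
    for stratum in sorted(strata.unique()):
        ids = np.array(sorted(strata.index[strata == stratum]), dtype=object)
        rng.shuffle(ids)
        k = _train_count(len(ids), cfg)
        train.extend(ids[:k])
        val.extend(ids[k:])
    return train, val


# ---------------------------------------------------------------------------
# the diagnostic model


@dataclass(frozen=True)
class DiagnosticModel:
    """Intercept + per-marker coefficients of the combined logistic score."""

    intercept: float
    coef: dict[str, float]
    frozen: bool = False
    provenance: str = ""

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.coef)

    def score(self, cts: Mapping[str, float] | pd.DataFrame) -> float | np.ndarray:
        """Linear predictor at the given marker Ct values.

        Accepts a mapping marker -> Ct for one sample, or a DataFrame with
        one column per marker for many. Higher score = more disease-like.
        """
        if isinstance(cts, pd.DataFrame):
            missing = set(self.coef) - set(cts.columns)
            if missing:
                raise InputError(f"missing marker columns: {sorted(missing)}")
            X = cts[list(self.coef)].to_numpy(dtype=float)
            if not np.isfinite(X).all():
                raise InputError("non-finite Ct values in score input")
            return self.intercept + X @ np.array(list(self.coef.values()))
        total = self.intercept
        for marker, b in self.coef.items():
            ct = float(cts[marker])
            if not np.isfinite(ct):
                raise InputError(f"non-finite Ct for {marker}")
            total += b * ct
        return total

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coef,
                "provenance": self.provenance,
                "frozen": self.frozen,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DiagnosticModel":
        d = json.loads(text)
        return cls(
            intercept=float(d["intercept"]),
            coef={k: float(v) for k, v in d["coefficients"].items()},
            frozen=bool(d.get("frozen", False)),
            provenance=d.get("provenance", ""),
        )


def published_model() -> DiagnosticModel:
    """The frozen two-marker model shipped with the package
    (score = 15.7174 − 0.3146·Ct_cg13096260 − 0.2224·Ct_cg12993163)."""
    text = resources.files("crcmeth.data").joinpath("published_model.json").read_text()
    return DiagnosticModel.from_json(text)


def fit_model(
    cts: pd.DataFrame,
    labels: Sequence[int],
    markers: Sequence[str] | None = None,
) -> DiagnosticModel:
    """Maximum-likelihood logistic fit of disease status on marker Cts.

    ``cts`` holds one column per marker (post-imputation mean Cts);
    ``labels`` is 1 for disease, 0 for control. Under (quasi-)complete
    separation the unpenalised fit diverges; a ridge-penalised fit is used
    instead and a warning issued.
    """
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise InputError("labels must contain both classes (0 and 1)")
    markers = list(markers or cts.columns)
    X = cts[markers].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise InputError("non-finite Ct values; impute before fitting")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
            params = np.asarray(res.params, dtype=float)
            separated = any("separation" in str(w.message).lower() for w in caught)
            diverged = not np.isfinite(params).all() or np.abs(params).max() > 1e3
        except Exception:
            separated, diverged = True, True
            params = None
    if separated or diverged:
        warnings.warn(
            "complete or quasi-complete separation detected; using a ridge-penalised fit",
            stacklevel=2,
        )
        lr = LogisticRegression(C=100.0, max_iter=1000)
        lr.fit(X, y)
        params = np.r_[lr.intercept_, lr.coef_.ravel()]
    return DiagnosticModel(
        intercept=float(params[0]),
        coef={m: float(b) for m, b in zip(markers, params[1:])},
        provenance="fitted",
    )


# ---------------------------------------------------------------------------
# ROC / cut-off / classification


@dataclass
class RocResult:
    """Empirical ROC: thresholds with sensitivity and 1−specificity, plus AUC.

    AUC uses the trapezoidal rule, which gives tied scores half credit —
    identical to the Mann–Whitney U statistic divided by n1*n2.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Empirical ROC curve and AUC of a score against binary labels."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise InputError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    return RocResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=float(roc_auc_score(y, s)))


def select_cutoff(
    scores: Sequence[float], labels: Sequence[int], method: str = "youden"
) -> float:
    """Score cut-off maximising the Youden index (sens + spec − 1).

    Classification downstream is *strictly greater than* the cut-off, so the
    returned value is the midpoint between the optimal decision boundary and
    the next lower observed score; ties in the Youden index break toward
    higher specificity (higher cut-off). A degenerate input with a single
    distinct score is flagged with a warning.
    """
    if method != "youden":
        raise ConfigError(f"unknown cut-off method {method!r}")
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise InputError("cut-off selection requires both classes")
    uniq = np.unique(s)
    if uniq.size == 1:
        warnings.warn("degenerate scores: single distinct value; cut-off set at that value", stacklevel=2)
        return float(uniq[0])
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    # candidate rules "score > c": c below min (all positive) and each unique score
    best_c, best_j = None, -np.inf
    candidates = np.concatenate([[uniq[0] - 1.0], uniq])
    for c in candidates:
        pred = s > c
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1
        if j > best_j or (j == best_j and best_c is not None and c > best_c):
            best_j, best_c = j, c
    # midpoint between the boundary and the next higher score keeps the rule
    # stable under small perturbations without changing any training call
    above = uniq[uniq > best_c]
    return float((best_c + above[0]) / 2) if above.size else float(best_c)


def classify(
    model: DiagnosticModel, cutoff: float, cts: pd.DataFrame
) -> pd.Series:
    """Positive iff score > cutoff (strict; a score at the cut-off is negative)."""
    s = model.score(cts)
    return pd.Series(np.asarray(s) > cutoff, index=cts.index, name="positive")
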