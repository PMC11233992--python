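"""Two-class linear discriminant analysis with posterior thresholds.

The classifier assumes class-conditional Gaussians with a pooled
covariance.  The discriminant direction w ∝ Σ⁻¹(μ_good − μ_non_good) is
scaled to unit projected within-class variance, so the projected scores
of each class have standard deviation 1 and the posterior of good status
is a logistic function of the score.  The score threshold attaining a
required posterior level (default 0.95) is obtained in closed form by
logit inversion.

Also provided: the published seasonal discriminant functions for the
Saronikos Gulf mesozooplankton index (coefficients on HillN0, Kothe's
species deficit and Chao2, with raw-score thresholds), and two
resampling validators — repeated stratified k-fold cross-validation and
the out-of-bootstrap accuracy estimate.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import GOOD, NON_GOOD
from .screening import ScreeningResult

logger = logging.getLogger("ecostatus")

DEFAULT_FEATURES = ("HillN0", "Kothe", "Chao2")


@dataclass
class DiscriminantModel:
    """A fitted two-class LDA on the good / non-good axis."""

    feature_names: list[str]
    class_means: np.ndarray  # rows: (non_good, good)
    pooled_covariance: np.ndarray
    coefficients: np.ndarray  # unit projected within-class variance
    priors: tuple[float, float]  # (pi_non_good, pi_good)
    projected_means: tuple[float, float]  # (mu_non_good, mu_good)
    projected_sd: float = 1.0

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "class_means": self.class_means.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
            "coefficients": self.coefficients.tolist(),
            "priors": list(self.priors),
            "projected_means": list(self.projected_means),
            "projected_sd": self.projected_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminantModel":
        return cls(
            feature_names=list(d["feature_names"]),
            class_means=np.asarray(d["class_means"], dtype=float),
            pooled_covariance=np.asarray(d["pooled_covariance"], dtype=float),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            priors=tuple(d["priors"]),
            projected_means=tuple(d["projected_means"]),
            projected_sd=float(d["projected_sd"]),
        )


@dataclass(frozen=True)
class PublishedModel:
    """A published seasonal discriminant function, stored verbatim.

    The function is an intercept-free linear form on (HillN0, Kothe,
    Chao2); scores above ``good_threshold`` certify good status at the
    stated posterior level.  Coefficients are never re-derived.
    """

    season: str
    coefficients: dict[str, float]
    good_threshold: float
    threshold_posterior: float

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients)


PUBLISHED_MODELS: dict[str, PublishedModel] = {
    "annual": PublishedModel(
        season="annual",
        coefficients={"HillN0": 0.0907477, "Kothe": 0.0353916, "Chao2": 0.0907477},
        good_threshold=1.86,
        threshold_posterior=0.95,
    ),
    "warm": PublishedModel(
        season="warm",
        coefficients={"HillN0": 0.097, "Kothe": -0.038, "Chao2": 0.097},
        good_threshold=2.0,
        threshold_posterior=0.97,
    ),
    "cold": PublishedModel(
        season="cold",
        coefficients={"HillN0": 0.082, "Kothe": -0.032, "Chao2": 0.082},
        good_threshold=1.91,
        threshold_posterior=0.96,
    ),
}


@dataclass
class ClassificationResult:
    sample_id: str
    lda_value: float
    posterior_good: float  # NaN for published models (threshold rule only)
    assigned: str
    confident: bool


def select_lda_features(screening: list[ScreeningResult]) -> list[str]:
    """Indices both sensitive and meeting the parametric assumptions —
    the eligibility gate for entering the discriminant analysis."""
    feats = [r.index_name for r in screening if r.significant and r.assumptions_met]
    if not feats:
        raise ValueError(
            "no index is both significant and assumption-passing; "
            "supply a manual feature list"
        )
    return feats


def fit_lda(
    features: pd.DataFrame,
    labels: dict[str, str],
    priors: tuple[float, float] | None = None,
    allow_collinear: bool = False,
    _warn: bool = True,
) -> DiscriminantModel:
    """Fit the two-class LDA from a samples x features matrix.

    ``labels`` maps sample ids to good/non_good.  Priors default to the
    empirical class proportions (pi_non_good, pi_good).  The pooled
    within-class covariance uses the standard n - 2 denominator.

    A rank-deficient pooled covariance (collinear features — e.g.
    Kothe's deficit is affine in richness whenever a single reference
    richness is used) raises by default; with ``allow_collinear=True``
    the fit proceeds on the covariance's range via the pseudo-inverse,
    matching the warn-and-continue behavior of the field's standard LDA
    implementations.
    """
    feats = list(features.columns)
    p = len(feats)
    lab = np.array([labels.get(s, "") for s in features.index])
    X = features.to_numpy(dtype=float)
    keep = np.isfinite(X).all(axis=1) & np.isin(lab, [GOOD, NON_GOOD])
    X, lab = X[keep], lab[keep]
    n_g, n_n = int((lab == GOOD).sum()), int((lab == NON_GOOD).sum())
    # strict fits require p+1 per class; tolerant (pseudo-inverse) fits,
    # as used by the resampling validators, only need estimable moments
    min_class = 2 if allow_collinear else p + 1
    if n_g < min_class or n_n < min_class:
        raise ValueError(
            f"each class needs at least {min_class} samples (got good={n_g}, "
            f"non_good={n_n})"
        )
    Xg, Xn = X[lab == GOOD], X[lab == NON_GOOD]
    mu_g, mu_n = Xg.mean(axis=0), Xn.mean(axis=0)
    Sg = (Xg - mu_g).T @ (Xg - mu_g)
    Sn = (Xn - mu_n).T @ (Xn - mu_n)
    cov = (Sg + Sn) / (n_g + n_n - 2)
    eigval = np.linalg.eigvalsh(cov)
    rank_deficient = eigval[0] <= 1e-10 * max(eigval[-1], 0.0) or eigval[-1] <= 0
    if rank_deficient:
        if not allow_collinear:
            raise ValueError(
                "singular pooled covariance; remove collinear features or "
                "pass allow_collinear=True"
            )
        if _warn:
            logger.warning(
                "collinear features: fitting on the pooled covariance's "
                "range via pseudo-inverse"
            )
        w = np.linalg.pinv(cov, rcond=1e-10, hermitian=True) @ (mu_g - mu_n)
    else:
        w = np.linalg.solve(cov, mu_g - mu_n)
    # unit projected within-class variance
    scale = math.sqrt(float(w @ cov @ w))
    if scale <= 0:
        raise ValueError("degenerate projection (zero within-class variance)")
    w = w / scale
    if priors is None:
        priors = (n_n / (n_g + n_n), n_g / (n_g + n_n))
    pi_n, pi_g = priors
    if not (pi_n > 0 and pi_g > 0 and abs(pi_n + pi_g - 1) < 1e-9):
        raise ValueError("priors must be positive and sum to 1")
    return DiscriminantModel(
        feature_names=feats,
        class_means=np.vstack([mu_n, mu_g]),
        pooled_covariance=cov,
        coefficients=w,
        priors=(float(pi_n), float(pi_g)),
        projected_means=(float(w @ mu_n), float(w @ mu_g)),
        projected_sd=1.0,
    )


def lda_value(model: DiscriminantModel | PublishedModel, x) -> float:
    """The discriminant score: the intercept-free linear form w·x."""
    if isinstance(model, PublishedModel):
        coef = np.array([model.coefficients[f] for f in model.feature_names])
    else:
        coef = model.coefficients
    x = np.asarray(x, dtype=float)
    if x.shape != coef.shape:
        raise ValueError(f"expected {coef.shape[0]} features, got {x.shape}")
    return float(coef @ x)


def posterior_good(model: DiscriminantModel, score: float) -> float:
    """Bayes posterior of good status at a projected score.

    Under equal-variance Gaussians on the discriminant axis the
    posterior is logistic in the score and strictly increasing.
    """
    mu_n, mu_g = model.projected_means
    pi_n, pi_g = model.priors
    s2 = model.projected_sd**2
    logit = math.log(pi_g / pi_n) + (mu_g - mu_n) / s2 * (score - (mu_g + mu_n) / 2)
    return float(expit(logit))


def good_threshold(model: DiscriminantModel, level: float = 0.95) -> float:
    """Smallest score whose posterior of good status reaches ``level``.

    Closed-form logit inversion; strictly increasing in ``level`` and
    decreasing in the good-status prior.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    mu_n, mu_g = model.projected_means
    pi_n, pi_g = model.priors
    s2 = model.projected_sd**2
    gap = mu_g - mu_n
    if abs(gap) < 1e-15 or model.projected_sd <= 0:
        raise ValueError("degenerate projection: classes are not separated")
    target_logit = math.log(level / (1 - level))
    return (mu_g + mu_n) / 2 + s2 / gap * (target_logit - math.log(pi_g / pi_n))


def classify(
    model: DiscriminantModel | PublishedModel,
    features: pd.DataFrame,
    level: float = 0.95,
) -> list[ClassificationResult]:
    """Classify samples from their feature rows.

    Fitted models assign by the posterior (> 0.5 is good) and flag
    ``confident`` when the assigned class's posterior exceeds ``level``.
    Published models carry only a raw-score threshold: scores above it
    are good and confident; below it samples are conservatively assigned
    non-good and flagged uncertain.  Rows with undefined feature values
    are skipped with a log entry.
    """
    names = model.feature_names
    missing = [f for f in names if f not in features.columns]
    if missing:
        raise ValueError(f"feature columns missing from input: {missing}")
    out: list[ClassificationResult] = []
    for sid, row in features[names].iterrows():
        x = row.to_numpy(dtype=float)
        if not np.isfinite(x).all():
            logger.info("sample %s skipped: undefined feature value", sid)
            continue
        score = lda_value(model, x)
        if isinstance(model, PublishedModel):
            is_good = score > model.good_threshold
            out.append(
                ClassificationResult(
                    sample_id=str(sid),
                    lda_value=score,
                    posterior_good=math.nan,
                    assigned=GOOD if is_good else NON_GOOD,
                    confident=is_good,
                )
            )
        else:
            post = posterior_good(model, score)
            assigned = GOOD if post > 0.5 else NON_GOOD
            post_assigned = post if assigned == GOOD else 1.0 - post
            out.append(
                ClassificationResult(
                    sample_id=str(sid),
                    lda_value=score,
                    posterior_good=post,
                    assigned=assigned,
                    confident=post_assigned > level,
                )
            )
    return out


def _predict(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    scores = X @ model.coefficients
    posts = np.array([posterior_good(model, s) for s in scores])
    return np.where(posts > 0.5, GOOD, NON_GOOD)


def _stratified_folds(lab: np.ndarray, k: int, rng: np.random.Generator):
    folds = [[] for _ in range(k)]
    for cls in (GOOD, NON_GOOD):
        idx = np.flatnonzero(lab == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    return [np.array(sorted(f)) for f in folds]


def repeated_kfold_cv(
    features: pd.DataFrame,
    labels: dict[str, str],
    k: int = 5,
    repeats: int = 100,
    seed: int | np.random.SeedSequence | None = None,
    priors: tuple[float, float] | None = None,
) -> float:
    """Mean accuracy of stratified k-fold cross-validation, repeated.

    Folds are stratified by class; the model is refit on each training
    split and scored on the held-out fold; accuracies are pooled over
    all held-out cases of a repetition and averaged over repetitions.
    ``k`` is reduced (with a warning) if a class is smaller than k.
    """
    rng = np.random.default_rng(seed)
    lab = np.array([labels.get(s, "") for s in features.index])
    X = features.to_numpy(dtype=float)
    keep = np.isfinite(X).all(axis=1) & np.isin(lab, [GOOD, NON_GOOD])
    X, lab = X[keep], lab[keep]
    min_class = min(int((lab == GOOD).sum()), int((lab == NON_GOOD).sum()))
    if min_class < k:
        logger.warning("reducing k from %d to %d (smallest class size)", k, min_class)
        k = min_class
    cols = list(features.columns)
    accs = []
    for _ in range(repeats):
        folds = _stratified_folds(lab, k, rng)
        correct = 0
        for f in folds:
            mask = np.ones(len(lab), dtype=bool)
            mask[f] = False
            train = pd.DataFrame(X[mask], columns=cols,
                                 index=[f"i{i}" for i in np.flatnonzero(mask)])
            model = fit_lda(
                train,
                {f"i{i}": l for i, l in zip(np.flatnonzero(mask), lab[mask])},
                priors=priors,
                allow_collinear=True,
                _warn=False,
            )
            pred = _predict(model, X[f])
            correct += int((pred == lab[f]).sum())
        accs.append(correct / len(lab))
    return float(np.mean(accs))


def oob_bootstrap(
    features: pd.DataFrame,
    labels: dict[str, str],
    iterations: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    priors: tuple[float, float] | None = None,
) -> float:
    """Out-of-bootstrap accuracy estimate.

    Each iteration resamples cases with replacement within each class
    (stratified), fits the model on the resample, and scores the cases
    never drawn.  Iterations with an empty out-of-bag set or a
    degenerate training set are redrawn (capped at 10x iterations).
    """
    rng = np.random.default_rng(seed)
    lab = np.array([labels.get(s, "") for s in features.index])
    X = features.to_numpy(dtype=float)
    keep = np.isfinite(X).all(axis=1) & np.isin(lab, [GOOD, NON_GOOD])
    X, lab = X[keep], lab[keep]
    cols = list(features.columns)
    idx_g = np.flatnonzero(lab == GOOD)
    idx_n = np.flatnonzero(lab == NON_GOOD)
    accs = []
    attempts = 0
    while len(accs) < iterations:
        attempts += 1
        if attempts > 10 * iterations:
            raise RuntimeError("too many degenerate bootstrap draws")
        boot = np.concatenate(
            [rng.choice(idx_g, size=len(idx_g)), rng.choice(idx_n, size=len(idx_n))]
        )
        oob = np.setdiff1d(np.arange(len(lab)), boot)
        if len(oob) == 0:
            continue
        train = pd.DataFrame(X[boot], columns=cols,
                             index=[f"b{i}" for i in range(len(boot))])
        try:
            model = fit_lda(
                train,
                {f"b{i}": lab[j] for i, j in enumerate(boot)},
                priors=priors,
                allow_collinear=True,
                _warn=False,
            )
        except ValueError:
            continue  # singular resample; redraw
        pred = _predict(model, X[oob])
        accs.append(float((pred == lab[oob]).mean()))
    return float(np.mean(accs))
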