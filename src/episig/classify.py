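"""Signature-based sample classification with a probability-scored SVM.

Signature CpGs are often locally co-methylated, so highly correlated
features are removed first: a greedy pass drops, from the most
correlated remaining pair, the feature with the larger mean absolute
correlation to everything else, until no pairwise |Pearson r| reaches
the cutoff (0.90 by default). An SVM (linear kernel, cost 1 by
default) is then trained on the pruned CpGs over the discovery
samples, features standardized by training statistics. Calibrated
probabilities come from Platt scaling: a sigmoid

    P(case | f) = 1 / (1 + exp(A f + B))

fitted to out-of-fold decision values from an internal stratified
cross-validation. A sample is called "high" (case-like) when its score
exceeds 0.5 and "low" otherwise; a score of exactly 0.5 is called low
with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core_io import BetaMatrix, EpisigError, SampleSheet

# ---------------------------------------------------------------------------
# Correlation pruning
# ---------------------------------------------------------------------------


@dataclass
class PrunedFeatureSet:
    """Result of greedy correlation pruning."""

    kept: list[str]
    removed: list[tuple[str, str]]  # (removed feature, partner that triggered it)
    cutoff: float


def prune_correlated(
    beta_at_signature: BetaMatrix, cutoff: float = 0.90
) -> PrunedFeatureSet:
    """Greedily remove features until no pair has |r| >= cutoff.

    ``beta_at_signature`` holds signature CpGs x *training* samples.
    At each step the pair with the largest |r| is found (ties broken by
    probe-id pair, lexicographically) and the member with the larger
    mean absolute correlation to all other remaining features is
    removed (ties broken by removing the lexicographically larger id).
    Constant features correlate with nothing and are always kept.
    """
    probes = list(beta_at_signature.probe_ids)
    if len(probes) < 2:
        return PrunedFeatureSet(kept=probes, removed=[], cutoff=cutoff)
    if beta_at_signature.shape[1] < 2:
        raise EpisigError("pruning needs >= 2 training samples")
    X = beta_at_signature.values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    corr = np.abs(corr)

    alive = list(range(len(probes)))
    removed: list[tuple[str, str]] = []
    while len(alive) >= 2:
        sub = corr[np.ix_(alive, alive)]
        iu = np.triu_indices(len(alive), k=1)
        vals = sub[iu]
        mx = vals.max()
        if mx < cutoff:
            break
        # worst pair; ties broken by (probe_i, probe_j) lexicographic order
        cand = [
            (probes[alive[i]], probes[alive[j]], alive[i], alive[j])
            for i, j, v in zip(iu[0], iu[1], vals)
            if v == mx
        ]
        cand.sort(key=lambda c: (c[0], c[1]))
        _, _, a, b = cand[0]
        others = [k for k in alive if k not in (a, b)]
        mean_a = corr[a, others].mean() if others else 0.0
        mean_b = corr[b, others].mean() if others else 0.0
        if mean_a > mean_b:
            drop, keep = a, b
        elif mean_b > mean_a:
            drop, keep = b, a
        else:  # tie: drop the lexicographically larger probe id
            drop, keep = (a, b) if probes[a] > probes[b] else (b, a)
        removed.append((probes[drop], probes[keep]))
        alive.remove(drop)

    kept = [probes[i] for i in alive]
    return PrunedFeatureSet(kept=kept, removed=removed, cutoff=cutoff)


# ---------------------------------------------------------------------------
# Model container and Platt calibration
# ---------------------------------------------------------------------------


@dataclass
class ClassifierModel:
    """Serializable trained SVM with Platt probability calibration.

    For the linear kernel only the primal weight vector is stored; for
    the RBF kernel the support vectors and dual coefficients are kept.
    ``impute_values`` are raw-scale training-control means used for the
    missing-feature policy at scoring time.
    """

    features: list[str]
    means: list[float]
    sds: list[float]
    impute_values: list[float]
    kernel: str
    cost: float
    intercept: float
    platt_a: float
    platt_b: float
    seed: int
    weights: list[float] | None = None  # linear kernel
    support_vectors: list[list[float]] | None = None  # rbf kernel
    dual_coef: list[float] | None = None
    gamma: float | None = None

    def to_json(self) -> str:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        return cls(**json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        return cls.from_json(Path(path).read_text())

    def decision_values(self, Z: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            return Z @ np.asarray(self.weights) + self.intercept
        sv = np.asarray(self.support_vectors)
        dual = np.asarray(self.dual_coef)
        d2 = ((Z[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        return (np.exp(-self.gamma * d2) * dual).sum(axis=1) + self.intercept

    def probabilities(self, Z: np.ndarray) -> np.ndarray:
        f = self.decision_values(Z)
        return 1.0 / (1.0 + np.exp(self.platt_a * f + self.platt_b))


def fit_platt(decision_values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Fit the Platt sigmoid P(y=1|f) = 1/(1+exp(A f + B)).

    Uses Platt's smoothed targets t+ = (N+ + 1)/(N+ + 2) and
    t- = 1/(N- + 2) and minimizes the cross-entropy in (A, B).
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EpisigError("Platt calibration needs both classes")
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(ab):
        a, b = ab
        z = a * f + b
        # log(1 + exp(z)) computed stably
        log1pez = np.where(z > 0, z + np.log1p(np.exp(-z)), np.log1p(np.exp(z)))
        return float(np.sum(t * z + log1pez - z))

    a0 = 0.0
    b0 = float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    res = minimize(nll, x0=[a0, b0], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    a, b = res.x
    if a > 0:  # sigmoid must be increasing in the case direction
        warnings.warn("Platt slope non-negative; calibration may be degenerate")
    return float(a), float(b)


# ---------------------------------------------------------------------------
# Training and scoring
# ---------------------------------------------------------------------------


def _feature_matrix(
    beta: BetaMatrix, features: list[str], impute: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Samples x features array plus per-sample missing fraction."""
    sub = beta.values.reindex(features)
    X = sub.to_numpy(dtype=float).T
    missing_frac = np.isnan(X).mean(axis=1)
    if impute is not None:
        X = np.where(np.isnan(X), impute[None, :], X)
    return X, missing_frac


def train_classifier(
    beta: BetaMatrix,
    sheet: SampleSheet,
    features: PrunedFeatureSet | list[str],
    kernel: str = "linear",
    cost: float = 1.0,
    n_calibration_folds: int = 5,
    seed: int = 0,
) -> ClassifierModel:
    """Train the probability-scored SVM on discovery samples.

    Only ``discovery_*`` samples from the sheet are used. Features are
    standardized by training mean/SD; missing training values are
    imputed with the training-control mean (with a warning). The Platt
    sigmoid is fitted on out-of-fold decision values from a stratified
    K-fold split seeded by ``seed``, so training is deterministic.
    """
    feat = features.kept if isinstance(features, PrunedFeatureSet) else list(features)
    if not feat:
        raise EpisigError("no features to train on")
    disc = sheet.discovery()
    if len(disc.table) == 0:
        raise EpisigError("no discovery samples in sheet")
    y = (disc.table["group"] == "case").to_numpy(dtype=int)
    if y.min() == y.max():
        raise EpisigError("training set contains a single class")
    train_beta = beta.subset_samples(list(disc.sample_ids))

    sub = train_beta.values.reindex(feat)
    missing = [f for f in feat if f not in beta.values.index]
    if missing:
        raise EpisigError(f"features absent from beta matrix: {missing[:5]}")
    ctrl_ids = [s for s, g in zip(disc.sample_ids, disc.table["group"]) if g == "control"]
    impute = np.nanmean(sub[ctrl_ids].to_numpy(dtype=float), axis=1)
    X, _ = _feature_matrix(train_beta, feat, impute=None)
    if np.isnan(X).any():
        warnings.warn("imputing missing training values with training-control means")
        X = np.where(np.isnan(X), impute[None, :], X)

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds == 0, 1.0, sds)
    Z = (X - means) / sds

    svc = SVC(kernel=kernel, C=cost, gamma="scale")
    n_splits = min(n_calibration_folds, int((y == 1).sum()), int((y == 0).sum()))
    if n_splits < 2:
        raise EpisigError("need >= 2 samples per class for calibration folds")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    cv_f = np.empty(len(y))
    for tr, te in skf.split(Z, y):
        fold_svc = SVC(kernel=kernel, C=cost, gamma="scale")
        fold_svc.fit(Z[tr], y[tr])
        cv_f[te] = fold_svc.decision_function(Z[te])
    platt_a, platt_b = fit_platt(cv_f, y)

    svc.fit(Z, y)
    if kernel == "linear":
        weights = [float(w) for w in svc.coef_.ravel()]
        sv, dual, gamma = None, None, None
    else:
        weights = None
        sv = [[float(v) for v in row] for row in svc.support_vectors_]
        dual = [float(d) for d in svc.dual_coef_.ravel()]
        gamma = float(svc._gamma)
    return ClassifierModel(
        features=feat,
        means=[float(m) for m in means],
        sds=[float(s) for s in sds],
        impute_values=[float(v) for v in impute],
        kernel=kernel,
        cost=float(cost),
        intercept=float(svc.intercept_[0]),
        platt_a=platt_a,
        platt_b=platt_b,
        seed=int(seed),
        weights=weights,
        support_vectors=sv,
        dual_coef=dual,
        gamma=gamma,
    )


def score_samples(
    model: ClassifierModel,
    beta: BetaMatrix,
    cohort: str | pd.Series | None = None,
    max_missing_fraction: float = 0.20,
) -> pd.DataFrame:
    """Score samples with a trained model.

    Returns a DataFrame (sample_id index) with columns ``score``
    (calibrated probability), ``call`` (high/low/unscoreable) and
    ``cohort``. A sample missing more than ``max_missing_fraction`` of
    the model features is flagged unscoreable; smaller gaps are imputed
    with the stored training-control means. A score of exactly 0.5 is
    called low with a warning.
    """
    features = list(model.features)
    absent = [f for f in features if f not in beta.values.index]
    impute = np.asarray(model.impute_values, dtype=float)
    # features absent from the matrix count as missing for every sample
    # (reindex leaves them as NaN rows before imputation)
    X, missing_frac = _feature_matrix(beta, features, impute=impute)
    Z = (X - np.asarray(model.means)) / np.asarray(model.sds)
    probs = model.probabilities(Z)

    scores = np.where(missing_frac > max_missing_fraction, np.nan, probs)
    calls = np.where(scores > 0.5, "high", "low").astype(object)
    calls[np.isnan(scores)] = "unscoreable"
    if np.any(scores == 0.5):
        warnings.warn("score exactly at the 0.5 boundary; called low")
    n_unscoreable = int(np.isnan(scores).sum())
    if n_unscoreable:
        warnings.warn(
            f"{n_unscoreable} samples unscoreable "
            f"(> {max_missing_fraction:.0%} of model features missing)"
        )
    if absent and not n_unscoreable:
        warnings.warn(
            f"{len(absent)} model features absent; imputed with training means"
        )
    out = pd.DataFrame({"score": scores, "call": calls}, index=beta.sample_ids)
    if cohort is None:
        out["cohort"] = ""
    elif isinstance(cohort, str):
        out["cohort"] = cohort
    else:
        out["cohort"] = cohort.reindex(out.index)
    return out


def evaluate_cohorts(
    reports: pd.DataFrame, expected_class: dict[str, str]
) -> pd.DataFrame:
    """Per-cohort sensitivity/specificity and score ranges.

    ``reports`` is a concatenation of :func:`score_samples` outputs with
    a ``cohort`` column; ``expected_class`` maps each cohort label to
    "case" or "control". Sensitivity is the fraction of expected-case
    samples called high; specificity the fraction of expected-control
    samples called low. Unscoreable samples are excluded. Cohorts with
    no scoreable samples are skipped with a warning.
    """
    rows = []
    for cohort, exp in expected_class.items():
        if exp not in ("case", "control"):
            raise EpisigError(f"expected class must be case/control, got {exp!r}")
        sub = reports[(reports["cohort"] == cohort) & reports["score"].notna()]
        if sub.empty:
            warnings.warn(f"cohort {cohort!r} empty or unscoreable; skipped")
            continue
        n = len(sub)
        n_high = int((sub["call"] == "high").sum())
        row = {
            "cohort": cohort,
            "expected": exp,
            "n": n,
            "n_high": n_high,
            "n_low": n - n_high,
            "score_min": float(sub["score"].min()),
            "score_max": float(sub["score"].max()),
            "sensitivity": n_high / n if exp == "case" else np.nan,
            "specificity": (n - n_high) / n if exp == "control" else np.nan,
        }
        rows.append(row)
    if not rows:
        raise EpisigError("no non-empty cohorts to evaluate")
    return pd.DataFrame(rows).set_index("cohort")
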