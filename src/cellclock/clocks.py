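"""Donor-level age classification and continuous-age (clock) regression.

Age-group classification uses repeated randomized train/test splits at the
donor level (all samples of a donor stay on one side of the split) with a
50-tree random forest; mean Gini (impurity-decrease) importances over the
trials rank features. The aging clock is Lasso regression evaluated by
leave-one-donor-out cross-validation, with the penalty tuned by internal
cross-validation on each training fold; quality is summarized by the
Pearson correlation between chronological and predicted donor ages and the
associated regression p-value.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LassoCV

from .core import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "AgeBinningRule",
    "ClockModel",
    "EvalReport",
    "GiniReport",
    "bin_ages",
    "classify_age_groups",
    "gini_importance",
    "lasso_clock_loocv",
]


# ---------------------------------------------------------------------------
# age binning
# ---------------------------------------------------------------------------

@dataclass
class AgeBinningRule:
    """A deterministic mapping from continuous ages to discrete groups.

    ``breakpoints`` are left-closed: an age equal to a breakpoint falls in
    the bin starting at that breakpoint. ``domain`` bounds are inclusive;
    ages outside raise. For cohorts sampled at fixed discrete timepoints,
    use :meth:`discrete_timepoints`, which labels each exact timepoint.
    """

    name: str
    breakpoints: list[float]
    labels: list[str]
    domain: tuple[float, float]
    unit: str
    timepoints: list[float] | None = None

    def __post_init__(self) -> None:
        if self.timepoints is None and len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError("need one more label than breakpoints")

    # -- named rules ---------------------------------------------------------
    @classmethod
    def three_way_aging(cls) -> "AgeBinningRule":
        """Young < 4, adult 4 <= age < 14, old >= 14 (months)."""
        return cls(
            name="three_way_aging",
            breakpoints=[4.0, 14.0],
            labels=["young", "adult", "old"],
            domain=(0.0, np.inf),
            unit="months",
        )

    @classmethod
    def trimester(cls) -> "AgeBinningRule":
        """First trimester 9-12 weeks, second 13-18 weeks (gestational)."""
        return cls(
            name="trimester",
            breakpoints=[13.0],
            labels=["first", "second"],
            domain=(9.0, 18.0),
            unit="weeks",
        )

    @classmethod
    def discrete_timepoints(
        cls, timepoints: list[float], labels: list[str] | None = None, unit: str = "days"
    ) -> "AgeBinningRule":
        """One class per exact sampling timepoint (lifespan-design cohorts)."""
        tps = sorted(float(t) for t in timepoints)
        if labels is None:
            labels = [f"t{t:g}" for t in tps]
        if len(labels) != len(tps):
            raise ValueError("need one label per timepoint")
        return cls(
            name="discrete",
            breakpoints=[],
            labels=list(labels),
            domain=(min(tps), max(tps)),
            unit=unit,
            timepoints=tps,
        )

    @classmethod
    def custom(
        cls, breakpoints: list[float], labels: list[str], unit: str,
        domain: tuple[float, float] = (0.0, np.inf),
    ) -> "AgeBinningRule":
        return cls(name="custom", breakpoints=list(breakpoints), labels=list(labels),
                   domain=domain, unit=unit)


def bin_ages(ages: np.ndarray, rule: AgeBinningRule) -> np.ndarray:
    """Apply a binning rule; raises on ages outside the rule's domain."""
    ages = np.asarray(ages, dtype=float)
    lo, hi = rule.domain
    bad = (ages < lo) | (ages > hi)
    if bad.any():
        raise ValueError(
            f"ages outside the {rule.name} rule domain [{lo}, {hi}]: {ages[bad][:5]}"
        )
    if rule.timepoints is not None:
        tps = np.asarray(rule.timepoints)
        out = []
        for a in ages:
            hit = np.isclose(tps, a, atol=1e-6)
            if not hit.any():
                raise ValueError(f"age {a} is not one of the declared timepoints {tps}")
            out.append(rule.labels[int(np.argmax(hit))])
        return np.array(out)
    idx = np.digitize(ages, rule.breakpoints, right=False)
    return np.array([rule.labels[i] for i in idx])


# ---------------------------------------------------------------------------
# models and reports
# ---------------------------------------------------------------------------

@dataclass
class ClockModel:
    """A fitted linear age model: coefficients over a feature vocabulary."""

    coefficients: np.ndarray
    intercept: float
    feature_names: list[str]
    penalty: dict
    age_unit: str = "unspecified"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape[0] != len(self.feature_names):
            raise ValueError("coefficient vector length must equal the vocabulary length")

    def predict(self, X: np.ndarray, include_intercept: bool = True) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        y = X @ self.coefficients
        return y + self.intercept if include_intercept else y

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "feature_names": list(self.feature_names),
            "penalty": self.penalty,
            "age_unit": self.age_unit,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClockModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            intercept=float(payload["intercept"]),
            feature_names=list(payload["feature_names"]),
            penalty=dict(payload["penalty"]),
            age_unit=str(payload["age_unit"]),
        )


@dataclass
class EvalReport:
    """Evaluation summary for a classification or regression protocol."""

    task: str  # "classification" | "regression"
    accuracies: np.ndarray | None = None        # per-trial sample-level accuracy
    donor_accuracies: np.ndarray | None = None  # per-trial donor-level (majority-vote)
    predictions: pd.DataFrame | None = None     # per-donor chronological vs predicted age
    pearson_r: float | None = None
    p_value: float | None = None
    n_redraws: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies))

    def to_json(self, path: str | Path) -> None:
        payload: dict = {"task": self.task, "n_redraws": self.n_redraws}
        if self.accuracies is not None:
            payload["accuracies"] = np.asarray(self.accuracies).tolist()
            payload["mean_accuracy"] = self.mean_accuracy
            payload["sd_accuracy"] = self.sd_accuracy
        if self.donor_accuracies is not None:
            payload["donor_accuracies"] = np.asarray(self.donor_accuracies).tolist()
        if self.pearson_r is not None:
            payload["pearson_r"] = self.pearson_r
            payload["p_value"] = self.p_value
        Path(path).write_text(json.dumps(payload))


@dataclass
class GiniReport:
    """Mean Gini importances over repeated classification trials."""

    feature_names: list[str]
    mean_importance: np.ndarray
    per_trial: np.ndarray  # n_trials x d, each row sums to 1

    def ranking(self) -> list[str]:
        order = np.argsort(-self.mean_importance, kind="stable")
        return [self.feature_names[i] for i in order]

    def top(self, k: int = 5) -> list[str]:
        return self.ranking()[:k]


# ---------------------------------------------------------------------------
# donor-level splitting machinery
# ---------------------------------------------------------------------------

def _trial_seed(seed: int, trial: int) -> int:
    """Derive an isolated, reproducible sub-seed for one trial."""
    return int(np.random.SeedSequence([seed, trial]).generate_state(1)[0] % (2**31))


def _donor_split(
    donors: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    unique = pd.unique(donors)
    perm = rng.permutation(unique)
    n_train = max(1, int(round(train_frac * len(unique))))
    n_train = min(n_train, len(unique) - 1)
    train_donors = set(perm[:n_train])
    train_mask = np.array([d in train_donors for d in donors])
    return train_mask, ~train_mask


def _draw_valid_split(
    donors: np.ndarray, labels: np.ndarray, train_frac: float, seed: int, trial: int,
    max_redraws: int = 100,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Donor-level split whose training set contains every class."""
    classes = set(labels)
    redraws = 0
    for attempt in range(max_redraws):
        rng = np.random.default_rng(_trial_seed(seed, trial * max_redraws + attempt))
        train, test = _donor_split(donors, train_frac, rng)
        if set(labels[train]) == classes and test.any():
            return train, test, redraws
        redraws += 1
        logger.debug("trial %d: redrawing split (attempt %d)", trial, attempt + 1)
    raise RuntimeError(
        f"could not draw a class-complete donor split in {max_redraws} attempts; "
        "check that every class has at least two donors"
    )


def _classification_trials(
    ft: FeatureTable, labels: np.ndarray, donor_ids: np.ndarray,
    n_trials: int, train_frac: float, n_trees: int, seed: int,
):
    """Yield (trial, fitted forest, train mask, test mask, redraws)."""
    X = ft.matrix
    labels = np.asarray(labels)
    donors = np.asarray(donor_ids)
    if len(set(labels)) < 2:
        raise ValueError("need at least two classes")
    for trial in range(n_trials):
        train, test, redraws = _draw_valid_split(donors, labels, train_frac, seed, trial)
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=_trial_seed(seed, trial)
        )
        clf.fit(X[train], labels[train])
        yield trial, clf, train, test, redraws


def classify_age_groups(
    ft: FeatureTable,
    labels: np.ndarray,
    donor_ids: np.ndarray,
    n_trials: int = 200,
    train_frac: float = 0.8,
    n_trees: int = 50,
    seed: int = 0,
) -> EvalReport:
    """Repeated donor-level random-forest classification of age groups.

    Each of ``n_trials`` trials holds out ~20% of donors (with all their
    samples), fits a 50-tree random forest (sqrt-features per split) and
    records the fraction of held-out samples with a correctly predicted
    label. A donor-level accuracy (majority vote over a donor's samples,
    ties resolved toward incorrect) is recorded alongside. Splits whose
    training set misses a class are re-drawn, up to a retry cap.
    """
    labels = np.asarray(labels)
    donors = np.asarray(donor_ids)
    accs = np.empty(n_trials)
    donor_accs = np.empty(n_trials)
    total_redraws = 0
    for trial, clf, train, test, redraws in _classification_trials(
        ft, labels, donors, n_trials, train_frac, n_trees, seed
    ):
        total_redraws += redraws
        pred = clf.predict(ft.matrix[test])
        accs[trial] = float(np.mean(pred == labels[test]))
        df = pd.DataFrame({"donor": donors[test], "true": labels[test], "pred": pred})
        correct = 0
        groups = df.groupby("donor", sort=False)
        for _, sub in groups:
            votes = sub["pred"].value_counts()
            top = votes[votes == votes.max()].index
            if len(top) == 1 and top[0] == sub["true"].iloc[0]:
                correct += 1
        donor_accs[trial] = correct / groups.ngroups
    if total_redraws:
        logger.info("re-drew %d class-incomplete splits over %d trials", total_redraws, n_trials)
    return EvalReport(
        task="classification",
        accuracies=accs,
        donor_accuracies=donor_accs,
        n_redraws=total_redraws,
    )


def gini_importance(
    ft: FeatureTable,
    labels: np.ndarray,
    donor_ids: np.ndarray,
    n_trials: int = 200,
    train_frac: float = 0.8,
    n_trees: int = 50,
    seed: int = 0,
) -> GiniReport:
    """Mean impurity-decrease (Gini) feature importances over repeated trials.

    Per-trial importances are normalized to sum to 1 before averaging, so
    the mean importances are comparable across trials and also sum to 1.
    """
    per_trial = np.empty((n_trials, ft.d))
    for trial, clf, train, test, _ in _classification_trials(
        ft, np.asarray(labels), np.asarray(donor_ids), n_trials, train_frac, n_trees, seed
    ):
        imp = clf.feature_importances_
        total = imp.sum()
        per_trial[trial] = imp / total if total > 0 else np.full(ft.d, 1.0 / ft.d)
    return GiniReport(
        feature_names=list(ft.feature_names),
        mean_importance=per_trial.mean(axis=0),
        per_trial=per_trial,
    )


# ---------------------------------------------------------------------------
# Lasso clock with leave-one-donor-out cross-validation
# ---------------------------------------------------------------------------

def _alpha_grid(X: np.ndarray, y: np.ndarray, n_alphas: int = 50) -> np.ndarray:
    """Logarithmic penalty grid spanning [1e-3, 1e1] times the data scale.

    The scale is the smallest penalty that zeroes every coefficient
    (max |Xc' yc| / n), the conventional top of a Lasso path.
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    alpha_max = np.abs(Xc.T @ yc).max() / X.shape[0]
    if alpha_max <= 0:
        alpha_max = 1.0
    return alpha_max * np.logspace(-3, 1, n_alphas)


def lasso_clock_loocv(
    ft: FeatureTable,
    ages: np.ndarray,
    donor_ids: np.ndarray,
    seed: int = 0,
    standardize: bool = False,
    inner_cv: int = 5,
    n_alphas: int = 50,
    age_unit: str = "unspecified",
) -> tuple[EvalReport, list[ClockModel]]:
    """Leave-one-donor-out Lasso aging clock.

    One fold per donor: all of the donor's samples are held out together,
    the model is trained on the remaining samples with the L1 penalty
    tuned by internal cross-validation (minimum MSE over a 50-point
    logarithmic grid), and the held-out samples' ages are predicted.
    Donors with several samples receive their mean predicted age. The
    report carries the Pearson correlation between chronological and
    predicted donor ages with its regression p-value.

    Features enter the model unstandardized by default; set
    ``standardize=True`` to z-score them inside each training fold.
    """
    X = ft.matrix
    ages = np.asarray(ages, dtype=float)
    donors = np.asarray(donor_ids)
    unique_donors = pd.unique(donors)
    if len(unique_donors) < 3:
        raise ValueError("need at least three donors for leave-one-donor-out evaluation")
    if np.allclose(ages, ages[0]):
        raise ValueError("ages are constant; the correlation metric is undefined")
    logger.info(
        "LOOCV clock: %d donors, %d samples, %d features (standardize=%s)",
        len(unique_donors), X.shape[0], X.shape[1], standardize,
    )

    models: list[ClockModel] = []
    donor_true = np.empty(len(unique_donors))
    donor_pred = np.empty(len(unique_donors))
    for f, donor in enumerate(unique_donors):
        test = donors == donor
        train = ~test
        Xtr, ytr = X[train], ages[train]
        Xte = X[test]
        if standardize:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        alphas = _alpha_grid(Xtr, ytr, n_alphas)
        cv = LassoCV(alphas=alphas, cv=inner_cv, max_iter=50_000)
        cv.fit(Xtr, ytr)
        model = ClockModel(
            coefficients=cv.coef_,
            intercept=float(cv.intercept_),
            feature_names=list(ft.feature_names),
            penalty={"model": "lasso", "lambda": float(cv.alpha_)},
            age_unit=age_unit,
        )
        models.append(model)
        donor_true[f] = ages[test][0]
        donor_pred[f] = float(model.predict(Xte).mean())

    r, p = stats.pearsonr(donor_true, donor_pred)
    predictions = pd.DataFrame(
        {"donor_id": unique_donors, "age": donor_true, "predicted_age": donor_pred}
    )
    report = EvalReport(
        task="regression", predictions=predictions, pearson_r=float(r), p_value=float(p)
    )
    return report, models
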