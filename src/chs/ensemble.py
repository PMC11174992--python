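"""Climate suitability via a TSS-weighted ensemble of niche models.

The design follows common ensemble SDM practice: presences are paired with
several independently drawn pseudo-absence sets (3 sets of 500 background
points by default); each base algorithm is fitted on repeated random 80/20
train/test splits (10 runs by default) of each presence/pseudo-absence
dataset; members are scored on their held-out fold with TSS and AUC; only
members with TSS above a retention cutoff (0.7) enter the ensemble.  The
ensemble prediction for cell *i* is

    EM_i = sum_j W_j * X_ij,      W_j = r_j / sum_j r_j,

where r_j is member *j*'s TSS, so weights are TSS-proportional and sum to
one.  The continuous map is binarized at the threshold maximizing TSS on
the pooled held-out calibration scores.

Two base learners are implemented natively — the surface range envelope
(SRE, a per-variable 2.5–97.5 percentile rectangle) and a logistic GLM fit
by iteratively reweighted least squares.  The remaining registry entries
(RF, GBM, CTA, ANN, FDA, and a penalized-logistic MAXENT analogue) wrap
scikit-learn estimators behind the same score contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
import pandas as pd

from .metrics import auc_score, max_tss
from .occurrences import OccurrenceSet
from .raster import RasterStack

TSS_RETAIN_CUTOFF = 0.7
SRE_PERCENTILES = (2.5, 97.5)


@dataclass
class TrainingDesign:
    """Factorial training layout: algorithms × pseudo-absence sets × runs."""

    algorithms: list[str] = field(default_factory=lambda: ["SRE", "GLM"])
    n_pa_sets: int = 3
    n_pa_points: int = 500
    train_fraction: float = 0.8
    n_runs: int = 10
    tss_retain_cutoff: float = TSS_RETAIN_CUTOFF
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not self.algorithms:
            raise ValueError("need at least one algorithm")
        unknown = [a for a in self.algorithms if a not in ALGORITHM_REGISTRY]
        if unknown:
            raise ValueError(f"unknown algorithms {unknown}; "
                             f"registry has {sorted(ALGORITHM_REGISTRY)}")

    @property
    def n_members(self) -> int:
        return len(self.algorithms) * self.n_pa_sets * self.n_runs


class ScorePredictor(Protocol):
    """Contract every base model satisfies: rows of predictor values in,
    suitability scores in [0, 1] out."""

    def fit(self, x: np.ndarray, y: np.ndarray) -> "ScorePredictor": ...
    def predict_score(self, x: np.ndarray) -> np.ndarray: ...


class SurfaceRangeEnvelope:
    """Rectangular climate envelope from presence percentiles.

    Scores 1 inside the per-variable [2.5, 97.5] percentile interval of the
    presence sample on every axis, 0 outside; absences are ignored at fit
    time, as in the classical BIOCLIM/SRE formulation.
    """

    def __init__(self, percentiles: tuple[float, float] = SRE_PERCENTILES):
        self.percentiles = percentiles

    def fit(self, x: np.ndarray, y: np.ndarray) -> "SurfaceRangeEnvelope":
        pres = np.asarray(x, float)[np.asarray(y).astype(bool)]
        if pres.size == 0:
            raise ValueError("SRE needs presence rows")
        self.lo_ = np.percentile(pres, self.percentiles[0], axis=0)
        self.hi_ = np.percentile(pres, self.percentiles[1], axis=0)
        return self

    def predict_score(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        inside = (x >= self.lo_) & (x <= self.hi_)
        return inside.all(axis=1).astype(float)


class IRLSLogistic:
    """Logistic regression on standardized predictors, fit by IRLS.

    A small ridge term keeps the Newton step well-posed on separable data.
    """

    def __init__(self, max_iter: int = 50, tol: float = 1e-8,
                 ridge: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol
        self.ridge = ridge

    def fit(self, x: np.ndarray, y: np.ndarray) -> "IRLSLogistic":
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if not np.isfinite(x).all():
            raise ValueError("non-finite predictor values")
        if len(np.unique(y)) < 2:
            raise ValueError("training data has a single class")
        self.mean_ = x.mean(axis=0)
        std = x.std(axis=0)
        self.std_ = np.where(std > 0, std, 1.0)
        z = (x - self.mean_) / self.std_
        design = np.hstack([np.ones((len(z), 1)), z])
        beta = np.zeros(design.shape[1])
        for _ in range(self.max_iter):
            eta = np.clip(design @ beta, -30, 30)
            mu = 1 / (1 + np.exp(-eta))
            w = np.maximum(mu * (1 - mu), 1e-10)
            grad = design.T @ (y - mu) - self.ridge * beta
            hess = (design * w[:, None]).T @ design + self.ridge * np.eye(len(beta))
            step = np.linalg.solve(hess, grad)
            beta = beta + step
            if np.abs(step).max() < self.tol:
                break
        self.coef_ = beta[1:]
        self.intercept_ = beta[0]
        return self

    def predict_score(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, float) - self.mean_) / self.std_
        eta = np.clip(z @ self.coef_ + self.intercept_, -30, 30)
        return 1 / (1 + np.exp(-eta))


class _SklearnScorer:
    """Adapter giving scikit-learn classifiers the score contract."""

    def __init__(self, factory: Callable, seed: int | None = None):
        self._factory = factory
        self._seed = seed

    def fit(self, x, y):
        if not np.isfinite(np.asarray(x, float)).all():
            raise ValueError("non-finite predictor values")
        if len(np.unique(y)) < 2:
            raise ValueError("training data has a single class")
        self.model_ = self._factory(self._seed)
        self.model_.fit(np.asarray(x, float), np.asarray(y).astype(int))
        return self

    def predict_score(self, x):
        return self.model_.predict_proba(np.asarray(x, float))[:, 1]


def _rf(seed):
    from sklearn.ensemble import RandomForestClassifier
    return RandomForestClassifier(n_estimators=100, random_state=seed)


def _gbm(seed):
    from sklearn.ensemble import GradientBoostingClassifier
    return GradientBoostingClassifier(random_state=seed)


def _cta(seed):
    from sklearn.tree import DecisionTreeClassifier
    return DecisionTreeClassifier(random_state=seed, min_samples_leaf=5)


def _ann(seed):
    from sklearn.neural_network import MLPClassifier
    return MLPClassifier(hidden_layer_sizes=(16,), max_iter=500,
                         random_state=seed)


def _fda(seed):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    return LinearDiscriminantAnalysis()


def _maxent_like(seed):
    from sklearn.linear_model import LogisticRegression
    return LogisticRegression(C=1.0, max_iter=1000)


ALGORITHM_REGISTRY: dict[str, Callable[[int | None], ScorePredictor]] = {
    "SRE": lambda seed: SurfaceRangeEnvelope(),
    "GLM": lambda seed: IRLSLogistic(),
    "RF": lambda seed: _SklearnScorer(_rf, seed),
    "GBM": lambda seed: _SklearnScorer(_gbm, seed),
    "CTA": lambda seed: _SklearnScorer(_cta, seed),
    "ANN": lambda seed: _SklearnScorer(_ann, seed),
    "FDA": lambda seed: _SklearnScorer(_fda, seed),
    "MAXENT": lambda seed: _SklearnScorer(_maxent_like, seed),
}


@dataclass
class FittedMember:
    """One trained base model with its held-out evaluation."""

    algorithm: str
    pa_set: int
    run: int
    tss: float
    auc: float
    threshold_used: float
    model: ScorePredictor
    predictors: list[str]

    def predict_score(self, x: np.ndarray) -> np.ndarray:
        return np.clip(self.model.predict_score(x), 0.0, 1.0)


@dataclass
class EnsembleModel:
    members: list[FittedMember]
    weights: np.ndarray
    predictors: list[str]

    def predict_score(self, x: np.ndarray) -> np.ndarray:
        scores = np.stack([m.predict_score(x) for m in self.members])
        return self.weights @ scores


@dataclass
class SuitabilityMap:
    values: np.ndarray  # EM_i in [0, 1]
    valid: np.ndarray
    georef: object


@dataclass
class BinaryMap:
    suitable: np.ndarray  # bool
    valid: np.ndarray
    georef: object
    threshold: float = np.nan

    def masked(self) -> np.ndarray:
        return self.suitable & self.valid


# ----------------------------------------------------------------- sampling

def _stream(master: int, *path: int) -> np.random.Generator:
    """Named substream of the master seed (documented derivation)."""
    return np.random.default_rng(np.random.SeedSequence([master, *path]))


def sample_pseudo_absences(stack: RasterStack, occ: OccurrenceSet,
                           design: TrainingDesign,
                           pa_set_index: int) -> pd.DataFrame:
    """Uniform background cells excluding presence cells and nodata.

    Deterministic per (design.seed, pa_set_index); returns cell-center
    lon/lat of the sampled background points.
    """
    georef = stack.georef
    row, col = georef.cell_index(occ.lon, occ.lat)
    presence_flat = set((row * georef.n_cols + col)[(row >= 0) & (col >= 0)])
    eligible = np.flatnonzero(stack.valid.ravel())
    eligible = eligible[~np.isin(eligible, list(presence_flat))]
    if eligible.size < design.n_pa_points:
        raise ValueError(
            f"only {eligible.size} eligible background cells for "
            f"{design.n_pa_points} pseudo-absences")
    rng = _stream(design.seed, 2, pa_set_index)
    chosen = rng.choice(eligible, size=design.n_pa_points, replace=False)
    r, c = np.unravel_index(chosen, georef.shape)
    lon, lat = georef.cell_center(r, c)
    return pd.DataFrame({"lon": lon, "lat": lat})


def build_training_table(stack: RasterStack, occ: OccurrenceSet,
                         pa_points: pd.DataFrame,
                         predictors: list[str]) -> pd.DataFrame:
    """Presence rows (label 1) stacked over pseudo-absence rows (label 0)."""
    pres = stack.values_at(occ.lon, occ.lat, predictors)
    absn = stack.values_at(pa_points["lon"].to_numpy(),
                           pa_points["lat"].to_numpy(), predictors)
    table = pd.DataFrame(np.vstack([pres, absn]), columns=predictors)
    table["label"] = np.r_[np.ones(len(pres)), np.zeros(len(absn))]
    table = table.dropna().reset_index(drop=True)
    return table


# ------------------------------------------------------------- fit/evaluate

def fit_member(algorithm: str, train_table: pd.DataFrame,
               pa_set: int = 0, run: int = 0,
               seed: int | None = None) -> FittedMember:
    predictors = [c for c in train_table.columns if c != "label"]
    x = train_table[predictors].to_numpy(float)
    y = train_table["label"].to_numpy(float)
    model = ALGORITHM_REGISTRY[algorithm](seed).fit(x, y)
    return FittedMember(algorithm=algorithm, pa_set=pa_set, run=run,
                        tss=np.nan, auc=np.nan, threshold_used=np.nan,
                        model=model, predictors=predictors)


def evaluate_member(member: FittedMember,
                    test_table: pd.DataFrame) -> tuple[float, float]:
    """Held-out (TSS, AUC); also records them on the member."""
    y = test_table["label"].to_numpy(float)
    scores = member.predict_score(test_table[member.predictors].to_numpy(float))
    auc = auc_score(y, scores)
    tss, thr = max_tss(y, scores)
    member.tss, member.auc, member.threshold_used = tss, auc, thr
    return tss, auc


def train_members(stack: RasterStack, occ: OccurrenceSet,
                  predictors: list[str], design: TrainingDesign
                  ) -> tuple[list[FittedMember], pd.DataFrame]:
    """Run the full factorial: algorithms × PA sets × train/test runs.

    Returns all fitted members (a × n_pa_sets × n_runs of them) plus the
    pooled held-out rows, which later calibrate the binarization threshold.
    """
    members: list[FittedMember] = []
    pooled_test: list[pd.DataFrame] = []
    for pa_set in range(design.n_pa_sets):
        pa = sample_pseudo_absences(stack, occ, design, pa_set)
        table = build_training_table(stack, occ, pa, predictors)
        n = len(table)
        n_train = int(round(design.train_fraction * n))
        for run in range(design.n_runs):
            rng = _stream(design.seed, 3, pa_set, run)
            perm = rng.permutation(n)
            train = table.iloc[perm[:n_train]]
            test = table.iloc[perm[n_train:]]
            if train["label"].nunique() < 2 or test["label"].nunique() < 2:
                raise ValueError("a split lost one of the classes; "
                                 "increase sample sizes")
            pooled_test.append(test)
            for ai, algo in enumerate(design.algorithms):
                seed = int(_stream(design.seed, 4, pa_set, run, ai)
                           .integers(2**31))
                member = fit_member(algo, train, pa_set, run, seed)
                evaluate_member(member, test)
                members.append(member)
    calibration = pd.concat(pooled_test, ignore_index=True)
    return members, calibration


def member_ledger(members: list[FittedMember]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"algorithm": m.algorithm, "pa_set": m.pa_set, "run": m.run,
          "tss": m.tss, "auc": m.auc} for m in members])


# ---------------------------------------------------------------- ensemble

def build_ensemble(members: list[FittedMember],
                   cutoff: float = TSS_RETAIN_CUTOFF) -> EnsembleModel:
    """Retain members with TSS > cutoff and weight them by TSS share."""
    retained = [m for m in members if m.tss > cutoff]
    if not retained:
        best = max((m.tss for m in members), default=np.nan)
        raise ValueError(
            f"no member exceeds the TSS cutoff {cutoff} (best {best:.3f}); "
            "review the cutoff or the training data")
    tss = np.array([m.tss for m in retained])
    weights = tss / tss.sum()
    return EnsembleModel(members=retained, weights=weights,
                         predictors=retained[0].predictors)


def predict_ensemble(ens: EnsembleModel, stack: RasterStack) -> SuitabilityMap:
    """Cellwise weighted mean of member scores over all valid cells."""
    missing = [p for p in ens.predictors if p not in stack.layers]
    if missing:
        raise ValueError(f"stack lacks predictor layers {missing}")
    flat_valid = stack.valid.ravel()
    x = np.column_stack([stack.layers[p].ravel()[flat_valid]
                         for p in ens.predictors])
    em = ens.predict_score(x)
    values = np.zeros(stack.georef.shape).ravel()
    values[flat_valid] = em
    return SuitabilityMap(values=values.reshape(stack.georef.shape),
                          valid=stack.valid.copy(), georef=stack.georef)


def binarize_max_tss(suit: SuitabilityMap, ens: EnsembleModel,
                     calibration: pd.DataFrame) -> BinaryMap:
    """Threshold the EM map at the max-TSS point of the calibration scores."""
    y = calibration["label"].to_numpy(float)
    scores = ens.predict_score(calibration[ens.predictors].to_numpy(float))
    _, thr = max_tss(y, scores)
    return BinaryMap(suitable=(suit.values >= thr) & suit.valid,
                     valid=suit.valid.copy(), georef=suit.georef,
                     threshold=thr)
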