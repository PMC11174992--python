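"""Distribution limitation models for soil classes and UV-B.

Non-climate constraints (categorical soil types, continuous UV-B) are
modelled presence-vs-background with a penalized logistic scorer — the
standard maximum-entropy-equivalent GLM formulation of presence-background
estimation.  Categorical layers are one-hot encoded so class labels never
act as magnitudes.  Model skill is reported as the mean test AUC over ten
75/25 train/test repeats; the final scorer is refit on all calibration
points and binarized at the threshold maximizing training sensitivity +
specificity (whose argmax coincides with the max-TSS threshold).

Soil and UV-B are fitted as two separate models, each contributing its own
binary mask to the comprehensive suitability intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .ensemble import BinaryMap, SuitabilityMap, _stream
from .metrics import auc_score, max_sens_plus_spec
from .occurrences import OccurrenceSet
from .raster import RasterStack

log = logging.getLogger(__name__)

DEFAULT_BACKGROUND_N = 10_000
TRAIN_FRACTION = 0.75
N_REPEATS = 10


@dataclass
class LimitationResult:
    continuous_map: SuitabilityMap
    binary_map: BinaryMap
    threshold: float
    train_auc: float            # mean test AUC over the repeats
    repeat_aucs: np.ndarray
    degenerate: bool
    layers: list[str]
    threshold_rule: str = "max train sensitivity plus specificity"


def _encode(stack: RasterStack, values: pd.DataFrame,
            layers: list[str]) -> np.ndarray:
    """One-hot categorical columns (category levels taken from the full
    layer so train and map encodings align); continuous columns pass
    through."""
    cols = []
    for name in layers:
        col = values[name].to_numpy(float)
        if name in stack.categorical:
            levels = np.unique(stack.layers[name][stack.valid])
            cols.append((col[:, None] == levels[None, :]).astype(float))
        else:
            cols.append(col[:, None])
    return np.hstack(cols)


def sample_background(stack: RasterStack, n: int, seed: int) -> pd.DataFrame:
    """Uniform background cells (nodata excluded); all cells if fewer than n."""
    eligible = np.flatnonzero(stack.valid.ravel())
    rng = _stream(seed, 5)
    if eligible.size > n:
        eligible = rng.choice(eligible, size=n, replace=False)
    r, c = np.unravel_index(eligible, stack.georef.shape)
    lon, lat = stack.georef.cell_center(r, c)
    return pd.DataFrame({"lon": lon, "lat": lat})


def threshold_max_ss(labels: np.ndarray, scores: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity (ties -> smallest)."""
    _, thr = max_sens_plus_spec(labels, scores)
    return thr


def fit_limitation(stack: RasterStack, occ: OccurrenceSet,
                   layers: list[str],
                   background_n: int = DEFAULT_BACKGROUND_N,
                   seed: int = 0) -> LimitationResult:
    """Presence-background limitation model over the given layer subset."""
    kinds = {name in stack.categorical for name in layers}
    if len(kinds) > 1:
        raise ValueError("mixing categorical and continuous layers in one "
                         "limitation model is not supported")
    if len(occ) < 10:
        raise ValueError("need at least 10 presences")

    bg = sample_background(stack, background_n, seed)
    pres_vals = pd.DataFrame(stack.values_at(occ.lon, occ.lat, layers),
                             columns=layers).dropna()
    bg_vals = pd.DataFrame(
        stack.values_at(bg["lon"].to_numpy(), bg["lat"].to_numpy(), layers),
        columns=layers).dropna()
    x = _encode(stack, pd.concat([pres_vals, bg_vals], ignore_index=True),
                layers)
    y = np.r_[np.ones(len(pres_vals)), np.zeros(len(bg_vals))]

    degenerate = bool((x.std(axis=0) == 0).all())
    if degenerate:
        log.warning("limitation model is degenerate: no feature varies "
                    "between presences and background")

    def _fit(xa, ya):
        return LogisticRegression(C=1.0, max_iter=1000).fit(xa, ya)

    # 75/25 split x 10 repeats -> mean held-out AUC
    aucs = []
    n = len(y)
    n_train = int(round(TRAIN_FRACTION * n))
    for rep in range(N_REPEATS):
        rng = _stream(seed, 6, rep)
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            continue
        if degenerate:
            aucs.append(0.5)
            continue
        model = _fit(x[tr], y[tr])
        aucs.append(auc_score(y[te], model.predict_proba(x[te])[:, 1]))
    repeat_aucs = np.asarray(aucs)

    if degenerate:
        train_scores = np.full(n, 0.5)
        thr = 0.5
        score_flat = np.full(int(stack.valid.sum()), 0.5)
    else:
        final = _fit(x, y)
        train_scores = final.predict_proba(x)[:, 1]
        thr = threshold_max_ss(y, train_scores)
        flat_valid = stack.valid.ravel()
        cells = pd.DataFrame(
            {name: stack.layers[name].ravel()[flat_valid] for name in layers})
        score_flat = final.predict_proba(_encode(stack, cells, layers))[:, 1]

    values = np.zeros(stack.georef.shape).ravel()
    values[stack.valid.ravel()] = score_flat
    values = values.reshape(stack.georef.shape)
    cont = SuitabilityMap(values=values, valid=stack.valid.copy(),
                          georef=stack.georef)
    binary = BinaryMap(suitable=(values >= thr) & stack.valid,
                       valid=stack.valid.copy(), georef=stack.georef,
                       threshold=thr)
    return LimitationResult(
        continuous_map=cont, binary_map=binary, threshold=thr,
        train_auc=float(repeat_aucs.mean()) if repeat_aucs.size else np.nan,
        repeat_aucs=repeat_aucs, degenerate=degenerate, layers=list(layers))
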