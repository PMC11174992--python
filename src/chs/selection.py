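"""Predictor screening: PCA ranking plus pairwise Pearson filtering.

Bioclim-style predictor sets are strongly collinear.  Screening happens on
the values extracted at the occurrence points (the niche is delimited where
the species actually occurs, not over the whole raster): variables are
ranked by their maximum absolute PCA loading over the leading components
that reach a cumulative explained-variance target, then traversed in rank
order keeping a variable only if its |Pearson r| with every already-kept
variable stays below a threshold (0.6 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .occurrences import OccurrenceSet
from .raster import RasterStack

log = logging.getLogger(__name__)

R_THRESHOLD = 0.6
VARIANCE_TARGET = 0.9


@dataclass
class SelectionReport:
    candidate_layers: list[str]
    pca_loadings: pd.DataFrame  # variables x components
    explained_variance: np.ndarray
    correlation_matrix: pd.DataFrame
    selected_layers: list[str]
    r_threshold: float = R_THRESHOLD

    def write_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.pca_loadings.to_csv(path / "pca_loadings.csv")
        self.correlation_matrix.to_csv(path / "correlations.csv")
        pd.Series(self.explained_variance, name="explained_variance").to_csv(
            path / "explained_variance.csv", index_label="component")
        (path / "selected_layers.txt").write_text(
            "\n".join(self.selected_layers) + "\n")


def extract_at_points(stack: RasterStack, occ: OccurrenceSet,
                      layer_names: list[str] | None = None) -> pd.DataFrame:
    """Value table (records × layers) at occurrence locations.

    Rows falling on nodata or outside the extent are dropped (count logged).
    """
    if layer_names is None:
        layer_names = stack.continuous_names
    vals = stack.values_at(occ.lon, occ.lat, layer_names)
    table = pd.DataFrame(vals, columns=layer_names)
    ok = table.notna().all(axis=1)
    n_bad = int((~ok).sum())
    if n_bad:
        log.info("dropped %d occurrence rows on nodata/out-of-extent", n_bad)
    table = table[ok].reset_index(drop=True)
    if table.empty:
        raise ValueError("no occurrence falls on valid raster cells")
    return table


def select_predictors(values: pd.DataFrame, r_threshold: float = R_THRESHOLD,
                      variance_target: float = VARIANCE_TARGET) -> SelectionReport:
    """Rank variables by PCA loading, then greedily enforce |r| < threshold."""
    if len(values) < 3:
        raise ValueError("need at least 3 rows for PCA screening")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 candidate variables")
    candidates = list(values.columns)

    variances = values.var(axis=0, ddof=1)
    usable = [c for c in candidates if variances[c] > 0]
    dropped = sorted(set(candidates) - set(usable))
    if dropped:
        log.info("excluded zero-variance columns before PCA: %s", dropped)

    x = values[usable].to_numpy(float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    pca = PCA()
    pca.fit(x)
    explained = pca.explained_variance_ratio_
    n_comp = int(np.searchsorted(np.cumsum(explained), variance_target) + 1)
    n_comp = min(n_comp, len(explained))
    loadings = pd.DataFrame(
        pca.components_.T, index=usable,
        columns=[f"PC{i + 1}" for i in range(pca.components_.shape[0])],
    )

    score = loadings.iloc[:, :n_comp].abs().max(axis=1)
    # ties broken lexicographically by layer name for reproducibility
    ranked = sorted(usable, key=lambda c: (-score[c], c))

    corr = values[usable].corr(method="pearson")
    selected: list[str] = []
    for cand in ranked:
        if all(abs(corr.loc[cand, kept]) < r_threshold for kept in selected):
            selected.append(cand)

    return SelectionReport(
        candidate_layers=candidates,
        pca_loadings=loadings,
        explained_variance=explained,
        correlation_matrix=corr,
        selected_layers=selected,
        r_threshold=r_threshold,
    )
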