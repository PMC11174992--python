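"""Comprehensive habitat suitability, habitat typology, and change accounting.

The comprehensive suitability of a cell is the intersection of its three
binary suitabilities,

    CHS_i = TM_i ∩ S_i ∩ U_i,

for climate (TM), soil (S) and UV-B (U).  The 2³ combinations define eight
habitat types; type II (all three suitable) is the comprehensively suitable
— "core" — habitat.  Across a set of future scenario/GCM runs, the
certainty index C_i is the fraction of runs in which a cell is
CHS-suitable; cells with C_i strictly greater than 0.5 form the consensus
suitable range.  Areas are accumulated on the sphere (per-cell spherical
quadrangle areas in km²) and range change decomposes into unchanged, gained
and lost area, which is conservative: unchanged + loss equals the baseline
suitable area and unchanged + gain equals the future one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import BinaryMap, EnsembleModel
from .metrics import auc_score
from .raster import GridGeoref, RasterStack, cell_areas

# (climate, soil, uv) suitable -> habitat type code
TYPE_CODES: dict[tuple[bool, bool, bool], int] = {
    (False, False, False): 1,  # I    nothing suitable
    (True, True, True): 2,     # II   comprehensively suitable (CHS)
    (True, True, False): 3,    # III  UV-B unsuitable
    (True, False, True): 4,    # IV   soil unsuitable
    (False, True, True): 5,    # V    climate unsuitable
    (True, False, False): 6,   # VI   soil and UV-B unsuitable
    (False, True, False): 7,   # VII  climate and UV-B unsuitable
    (False, False, True): 8,   # VIII climate and soil unsuitable
}
ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI", 7: "VII",
         8: "VIII"}
CHS_CODE = 2
CI_CONSENSUS = 0.5  # strict: a cell suitable in exactly half the runs is out


@dataclass
class HabitatTypeMap:
    codes: np.ndarray  # int 1..8, 0 on nodata
    valid: np.ndarray
    georef: GridGeoref

    @property
    def chs(self) -> np.ndarray:
        """CHS_i: comprehensively suitable cells (type II)."""
        return (self.codes == CHS_CODE) & self.valid


@dataclass
class CertaintyMap:
    ci: np.ndarray     # fraction of runs suitable, in [0, 1]
    m: int             # number of scenario members
    valid: np.ndarray
    georef: GridGeoref

    @property
    def final_suitable(self) -> np.ndarray:
        return (self.ci > CI_CONSENSUS) & self.valid

    @property
    def merge(self) -> np.ndarray:
        """Intersection of all runs (suitable everywhere, Ci = 1)."""
        return (self.ci >= 1.0) & self.valid


@dataclass
class ChangeSummary:
    unchanged_km2: float
    gain_km2: float
    loss_km2: float

    @property
    def baseline_km2(self) -> float:
        return self.unchanged_km2 + self.loss_km2

    @property
    def future_km2(self) -> float:
        return self.unchanged_km2 + self.gain_km2


def _check_aligned(*maps) -> None:
    g = maps[0].georef
    for m in maps[1:]:
        if m.georef != g:
            raise ValueError("grids are not aligned")


def classify_types(tm: BinaryMap, s: BinaryMap, u: BinaryMap) -> HabitatTypeMap:
    """Code every cell I–VIII from its (climate, soil, UV-B) binary triple."""
    _check_aligned(tm, s, u)
    valid = tm.valid & s.valid & u.valid
    codes = np.zeros(tm.suitable.shape, dtype=int)
    for (c, so, uv), code in TYPE_CODES.items():
        mask = (tm.suitable == c) & (s.suitable == so) & (u.suitable == uv)
        codes[mask & valid] = code
    return HabitatTypeMap(codes=codes, valid=valid, georef=tm.georef)


def certainty_index(chs_masks: list[np.ndarray], valid: np.ndarray,
                    georef: GridGeoref) -> CertaintyMap:
    """C_i = mean suitability indicator over scenario members."""
    if not chs_masks:
        raise ValueError("need at least one CHS mask")
    arr = np.stack([np.asarray(m, bool) for m in chs_masks])
    return CertaintyMap(ci=arr.mean(axis=0), m=len(chs_masks),
                        valid=np.asarray(valid, bool), georef=georef)


def area_by_type(types: HabitatTypeMap,
                 areas: np.ndarray | None = None) -> pd.Series:
    """km² per habitat type code; sums to the total non-nodata area."""
    if areas is None:
        areas = cell_areas(types.georef)
    out = {}
    for code, numeral in ROMAN.items():
        out[numeral] = float(areas[types.valid & (types.codes == code)].sum())
    return pd.Series(out, name="area_km2")


def suitable_area(binary: BinaryMap, areas: np.ndarray | None = None) -> float:
    if areas is None:
        areas = cell_areas(binary.georef)
    return float(areas[binary.masked()].sum())


def change_statistics(baseline: BinaryMap, future: BinaryMap,
                      areas: np.ndarray | None = None) -> ChangeSummary:
    """Unchanged/gain/loss areas between two aligned binary maps."""
    _check_aligned(baseline, future)
    if areas is None:
        areas = cell_areas(baseline.georef)
    valid = baseline.valid & future.valid
    b = baseline.suitable & valid
    f = future.suitable & valid
    return ChangeSummary(
        unchanged_km2=float(areas[b & f].sum()),
        gain_km2=float(areas[~b & f].sum()),
        loss_km2=float(areas[b & ~f].sum()),
    )


def percent_change(current_area: float, future_area: float) -> float:
    """Percent contraction from current to future, rounded to 2 decimals.

    Positive values mean loss (future smaller than current).
    """
    if current_area <= 0:
        raise ValueError("current area must be positive")
    return round(100.0 * (current_area - future_area) / current_area, 2)


# --------------------------------------------------- variable interpretation

def contribution_analysis(ens: EnsembleModel, calibration: pd.DataFrame,
                          n_perm: int = 10, seed: int = 0) -> pd.Series:
    """Permutation importance of each predictor, normalized to sum 100%.

    A predictor's raw importance is the mean drop in ensemble AUC when its
    calibration column is shuffled; negative drops clip to zero before
    normalizing.  Predictors above 10% are conventionally called dominant.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    y = calibration["label"].to_numpy(float)
    x = calibration[ens.predictors].to_numpy(float)
    base = auc_score(y, ens.predict_score(x))
    drops = {}
    for j, name in enumerate(ens.predictors):
        acc = 0.0
        for _ in range(n_perm):
            xp = x.copy()
            xp[:, j] = rng.permutation(xp[:, j])
            acc += base - auc_score(y, ens.predict_score(xp))
        drops[name] = max(acc / n_perm, 0.0)
    s = pd.Series(drops)
    total = s.sum()
    return (100 * s / total) if total > 0 else s * 0.0


def dominant_variables(contrib: pd.Series, cutoff: float = 10.0) -> list[str]:
    return [n for n, v in contrib.items() if v > cutoff]


def dominant_variable_ranges(stack: RasterStack, suitable_mask: np.ndarray,
                             layers: list[str], mass: float = 0.5,
                             grid_points: int = 512
                             ) -> dict[str, tuple[float, float]]:
    """Highest-density interval of each layer over the suitable cells.

    A Gaussian kernel density over the layer values in suitable cells is
    evaluated on a regular grid; the interval grows outward from the mode,
    always toward the denser side, until it holds ``mass`` of the total
    density.  ``mass=1.0`` spans the full observed range.
    """
    suitable_mask = np.asarray(suitable_mask, bool) & stack.valid
    if suitable_mask.sum() < 30:
        raise ValueError("need at least 30 suitable cells")
    out = {}
    for name in layers:
        vals = stack.layers[name][suitable_mask]
        if np.ptp(vals) == 0:
            raise ValueError(f"layer {name!r} is constant over suitable cells")
        kde = stats.gaussian_kde(vals)
        grid = np.linspace(vals.min(), vals.max(), grid_points)
        dens = kde(grid)
        total = dens.sum()
        lo = hi = int(np.argmax(dens))
        acc = dens[lo]
        while acc < mass * total and (lo > 0 or hi < grid_points - 1):
            left = dens[lo - 1] if lo > 0 else -np.inf
            right = dens[hi + 1] if hi < grid_points - 1 else -np.inf
            if left >= right:
                lo -= 1
                acc += dens[lo]
            else:
                hi += 1
                acc += dens[hi]
        out[name] = (float(grid[lo]), float(grid[hi]))
    return out


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and its chi-squared p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    if flat.size < 3:
        raise ValueError("need at least 3 values in total")
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
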