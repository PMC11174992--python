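"""End-to-end run orchestration with provenance logging.

One config (TOML or an in-memory :class:`RunConfig`) drives the whole
chain: simulate → thin → select → fit → ensemble → limitation models →
habitat typing → certainty → change accounting.  Every stage is a pure
function of its inputs and the master seed; the run ledger records
parameters, derived seeds, output checksums and timings so a rerun with
the same config and seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assessment, limitation, simulate
from .ensemble import (BinaryMap, TrainingDesign, binarize_max_tss,
                       build_ensemble, member_ledger, predict_ensemble,
                       train_members)
from .occurrences import DEFAULT_MIN_KM, dedupe_and_gridify, thin_by_distance
from .raster import cell_areas, write_asc
from .selection import extract_at_points, select_predictors
from .simulate import SOIL_LAYER, UV_LAYER, LandscapeSpec, VirtualSpecies

log = logging.getLogger(__name__)


@dataclass
class ScenarioSpec:
    name: str
    deltas: dict[str, float]
    period: str = "future"


@dataclass
class RunConfig:
    landscape: LandscapeSpec = field(default_factory=LandscapeSpec)
    species_variables: list[str] = field(default_factory=lambda: ["bio1"])
    species_kind: str = "envelope"
    # one-sided envelope on the first climate axis; ~16% of the landscape
    # is suitable, a realistic prevalence for a habitat specialist
    species_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"bio1": (1.0, 99.0)})
    species_coefficients: dict[str, float] = field(default_factory=dict)
    species_intercept: float = 0.0
    n_occurrences: int = 200
    detection_prob: float = 1.0
    thin_min_km: float = DEFAULT_MIN_KM
    design: TrainingDesign = field(default_factory=TrainingDesign)
    background_n: int = limitation.DEFAULT_BACKGROUND_N
    scenarios: list[ScenarioSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.landscape.seed = self.seed
        self.design.seed = self.seed

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        kw: dict = {}
        if "landscape" in raw:
            kw["landscape"] = LandscapeSpec(**raw["landscape"])
        sp = raw.get("species", {})
        if sp:
            kw["species_variables"] = sp.get("variables", ["bio1"])
            kw["species_kind"] = sp.get("kind", "envelope")
            kw["species_bounds"] = {k: tuple(v)
                                    for k, v in sp.get("bounds", {}).items()}
            kw["species_coefficients"] = sp.get("coefficients", {})
            kw["species_intercept"] = sp.get("intercept", 0.0)
        samp = raw.get("sampling", {})
        kw["n_occurrences"] = samp.get("n", 200)
        kw["detection_prob"] = samp.get("detection_prob", 1.0)
        kw["thin_min_km"] = raw.get("thin", {}).get("min_km", DEFAULT_MIN_KM)
        if "design" in raw:
            kw["design"] = TrainingDesign(**raw["design"])
        kw["background_n"] = raw.get("limitation", {}).get(
            "background_n", limitation.DEFAULT_BACKGROUND_N)
        kw["scenarios"] = [
            ScenarioSpec(name=s["name"], deltas=s.get("deltas", {}),
                         period=s.get("period", "future"))
            for s in raw.get("scenario", [])]
        kw["seed"] = raw.get("seed", 0)
        return cls(**kw)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class RunLedger:
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, t0: float, **info) -> None:
        self.stages[stage] = {"seconds": round(time.perf_counter() - t0, 4),
                              **info}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.stages, indent=2, default=str))


@dataclass
class RunResult:
    ledger: RunLedger
    baseline_types: assessment.HabitatTypeMap
    scenario_types: dict[str, assessment.HabitatTypeMap]
    certainty: dict[str, assessment.CertaintyMap]
    change_by_scenario: pd.DataFrame
    type_areas: pd.DataFrame
    members: pd.DataFrame
    ensemble_weights: np.ndarray
    contributions: pd.Series


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None
                 ) -> RunResult:
    """Execute all stages in order; fail fast naming the broken stage."""
    ledger = RunLedger()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage %s", name)
        return time.perf_counter()

    # -- simulate -----------------------------------------------------------
    t0 = stage("simulate")
    stack = simulate.generate_stack(config.landscape)
    species = simulate.generate_species(
        stack,
        VirtualSpecies(response_variables=config.species_variables,
                       response_kind=config.species_kind,
                       envelope_bounds=config.species_bounds,
                       logistic_coefficients=config.species_coefficients,
                       logistic_intercept=config.species_intercept),
    )
    occ_raw = simulate.sample_occurrences(
        species, stack, config.n_occurrences,
        detection_prob=config.detection_prob, seed=config.seed)
    ledger.record("simulate", t0, n_raw_occurrences=len(occ_raw),
                  layer_checksums={n: _checksum(a)
                                   for n, a in stack.layers.items()})

    # -- thin ---------------------------------------------------------------
    t0 = stage("thin")
    occ = dedupe_and_gridify(occ_raw, stack)
    occ = thin_by_distance(occ, config.thin_min_km)
    if len(occ) < 10:
        raise RuntimeError("stage thin: fewer than 10 occurrences survive "
                           "cleaning; enlarge the sample or the grid")
    ledger.record("thin", t0, n_retained=len(occ))

    # -- select -------------------------------------------------------------
    t0 = stage("select")
    climate_layers = [n for n in stack.continuous_names if n != UV_LAYER]
    values = extract_at_points(stack, occ, climate_layers)
    report = select_predictors(values)
    predictors = report.selected_layers
    ledger.record("select", t0, candidates=climate_layers,
                  selected=predictors)

    # -- fit + ensemble -----------------------------------------------------
    t0 = stage("fit")
    members, calibration = train_members(stack, occ, predictors,
                                         config.design)
    ledger.record("fit", t0, n_members=len(members),
                  expected_members=config.design.n_members)
    t0 = stage("ensemble")
    ens = build_ensemble(members, config.design.tss_retain_cutoff)
    em_map = predict_ensemble(ens, stack)
    tm_baseline = binarize_max_tss(em_map, ens, calibration)
    ledger.record("ensemble", t0, n_retained=len(ens.members),
                  threshold=tm_baseline.threshold,
                  em_checksum=_checksum(em_map.values))

    # -- scenarios: same ensemble, same unified threshold -------------------
    t0 = stage("project")
    tm_future: dict[str, BinaryMap] = {}
    for sc in config.scenarios:
        shifted = simulate.shift_scenario(stack, sc.deltas)
        fmap = predict_ensemble(ens, shifted)
        tm_future[sc.name] = BinaryMap(
            suitable=(fmap.values >= tm_baseline.threshold) & fmap.valid,
            valid=fmap.valid, georef=fmap.georef,
            threshold=tm_baseline.threshold)
    ledger.record("project", t0, scenarios=[s.name for s in config.scenarios])

    # -- limitation models (soil categorical, UV continuous) ---------------
    t0 = stage("limit")
    soil_res = limitation.fit_limitation(stack, occ, [SOIL_LAYER],
                                         config.background_n, config.seed)
    uv_res = limitation.fit_limitation(stack, occ, [UV_LAYER],
                                       config.background_n, config.seed + 1)
    ledger.record("limit", t0, soil_auc=soil_res.train_auc,
                  uv_auc=uv_res.train_auc)

    # -- assessment ---------------------------------------------------------
    t0 = stage("assess")
    areas = cell_areas(stack.georef)
    base_types = assessment.classify_types(tm_baseline, soil_res.binary_map,
                                           uv_res.binary_map)
    scen_types = {
        name: assessment.classify_types(tm, soil_res.binary_map,
                                        uv_res.binary_map)
        for name, tm in tm_future.items()}

    periods: dict[str, list[str]] = {}
    for sc in config.scenarios:
        periods.setdefault(sc.period, []).append(sc.name)
    certainty = {
        period: assessment.certainty_index(
            [scen_types[n].chs for n in names], stack.valid, stack.georef)
        for period, names in periods.items()}

    rows = []
    for sc in config.scenarios:
        ch = assessment.change_statistics(
            BinaryMap(base_types.chs, stack.valid, stack.georef),
            BinaryMap(scen_types[sc.name].chs, stack.valid, stack.georef),
            areas)
        rows.append({"scenario": sc.name, "period": sc.period,
                     "unchanged_km2": ch.unchanged_km2,
                     "gain_km2": ch.gain_km2, "loss_km2": ch.loss_km2})
    change = pd.DataFrame(rows)

    type_areas = pd.DataFrame(
        {"baseline": assessment.area_by_type(base_types, areas),
         **{n: assessment.area_by_type(t, areas)
            for n, t in scen_types.items()}})

    contributions = assessment.contribution_analysis(
        ens, calibration, n_perm=5, seed=config.seed)
    ledger.record("assess", t0,
                  type_checksum=_checksum(base_types.codes),
                  chs_area_km2=float(areas[base_types.chs].sum()))

    # -- outputs ------------------------------------------------------------
    if out is not None:
        t0 = stage("write")
        write_asc(out / "em_baseline.asc", em_map.values, stack.georef,
                  stack.valid)
        write_asc(out / "types_baseline.asc", base_types.codes.astype(float),
                  stack.georef, base_types.valid, integer=True)
        for name, t in scen_types.items():
            write_asc(out / f"types_{name}.asc", t.codes.astype(float),
                      stack.georef, t.valid, integer=True)
        for period, cmap in certainty.items():
            write_asc(out / f"certainty_{period}.asc", cmap.ci, stack.georef,
                      cmap.valid)
        member_ledger(members).to_csv(out / "members.csv", index=False)
        change.to_csv(out / "change_by_scenario.csv", index=False)
        type_areas.to_csv(out / "type_areas_km2.csv")
        contributions.rename("contribution_pct").to_csv(
            out / "contributions.csv")
        report.write_dir(out / "selection")
        ledger.record("write", t0, out_dir=str(out))
        ledger.write(out / "run_ledger.json")

    return RunResult(ledger=ledger, baseline_types=base_types,
                     scenario_types=scen_types, certainty=certainty,
                     change_by_scenario=change, type_areas=type_areas,
                     members=member_ledger(members),
                     ensemble_weights=ens.weights,
                     contributions=contributions)
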