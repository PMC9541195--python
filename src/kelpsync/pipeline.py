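"""End-to-end orchestration: ingest -> clean -> transform -> synchrony ->
model -> attribution, per region, driven by a single YAML config.

Every output is written atomically (temp file + rename) so an aborted run
leaves no partial files, and a run manifest records the config hash,
package version and every seed, which suffices to reproduce the run
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (
    DEFAULT_BOUNDARY_LATITUDE,
    assign_regions,
    atomic_write_csv,
    filter_persistent_locations,
    read_index_series,
    read_quarterly_dataset,
    write_attribution_table,
)
from .preprocess import CleaningOptions, clean_series, impute_missing
from .synchrony import (
    STANDARD_BANDS,
    BandDef,
    mean_squared_synchrony,
    wavelet_phasor_mean_field,
    wpmf_significance,
)
from .wavelets import make_timescale_grid, normalize_power, transform_set
from .wlm import AttributionTable, attribute_synchrony, fit_wlm, index_coherence_model

log = logging.getLogger("kelpsync")

__all__ = ["PipelineConfig", "PipelineError", "run_analysis"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and context."""


@dataclass
class PipelineConfig:
    inputs: dict = field(default_factory=dict)  # variable -> csv path
    schema: dict = field(default_factory=dict)
    cleaning: dict = field(default_factory=dict)  # variable -> CleaningOptions kwargs
    grid: dict = field(default_factory=dict)
    bands: list[BandDef] = field(default_factory=lambda: list(STANDARD_BANDS))
    boundary_latitude: float = DEFAULT_BOUNDARY_LATITUDE
    max_absent_years: int = 3
    impute_max_run: int = 4
    n_surrogates: int = 10_000
    seed: int | None = None
    output_dir: str = "results"
    response: str = "kelp"
    predictors: list[str] = field(default_factory=lambda: ["waves", "nutrients"])
    index: str | None = None  # key in inputs, optional

    @staticmethod
    def from_yaml(path: str | os.PathLike) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        bands_raw = raw.pop("bands", None)
        cfg = PipelineConfig(**raw)
        if bands_raw is not None:
            cfg.bands = [BandDef(**b) for b in bands_raw]
        return cfg

    def validate(self) -> list[str]:
        """Return a list of problems (empty = valid)."""
        problems = []
        if not self.inputs:
            problems.append("inputs: no input files configured")
        for var, path in self.inputs.items():
            if not os.path.exists(path):
                problems.append(f"inputs.{var}: file not found: {path}")
        needed = [self.response] + list(self.predictors)
        for var in needed:
            if var not in self.inputs:
                problems.append(f"inputs: missing entry for variable {var!r}")
        for a, b in zip(self.bands, self.bands[1:]):
            lo = max(a.min_period_years, b.min_period_years)
            hi = min(a.max_period_years, b.max_period_years)
            if lo < hi:
                problems.append(f"bands: {a.name!r} and {b.name!r} overlap on ({lo}, {hi}) years")
        if self.seed is None:
            problems.append("seed: required (significance testing is Monte-Carlo)")
        for var, opts in self.cleaning.items():
            try:
                CleaningOptions(**opts)
            except (TypeError, ValueError) as e:
                problems.append(f"cleaning.{var}: {e}")
        return problems

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                **{k: v for k, v in self.__dict__.items() if k != "bands"},
                "bands": [b.__dict__ for b in self.bands],
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"stage {name!r}: {e}") from e

        return wrapped

    return deco


@_stage("ingest")
def _ingest(cfg: PipelineConfig) -> dict:
    mats = {}
    for var in [cfg.response] + list(cfg.predictors):
        mats[var] = read_quarterly_dataset(cfg.inputs[var], cfg.schema or None, variable_name=var)
    idx = None
    if cfg.index and cfg.index in cfg.inputs:
        idx = read_index_series(cfg.inputs[cfg.index], name=cfg.index)
    return {"matrices": mats, "index": idx}


@_stage("filter")
def _filter(cfg: PipelineConfig, data: dict) -> pd.DataFrame:
    mats = data["matrices"]
    resp = mats[cfg.response]
    filtered, report = filter_persistent_locations(resp, cfg.max_absent_years)
    if filtered is None:
        raise ValueError("persistence filter removed every location")
    keep_ids = set(filtered.location_ids())
    for var, m in list(mats.items()):
        ids = m.location_ids()
        missing = keep_ids - set(ids)
        if missing:
            raise ValueError(f"variable {var!r} lacks locations {sorted(missing)[:5]}")
        keep = [i for i, lid in enumerate(ids) if lid in keep_ids]
        mats[var] = m.subset_locations(keep)
    # common region assignment
    for var, m in mats.items():
        m.locations = assign_regions(m.locations, cfg.boundary_latitude)
    return report


@_stage("clean")
def _clean(cfg: PipelineConfig, data: dict) -> dict:
    cleaned = {}
    for var, m in data["matrices"].items():
        opts = CleaningOptions(**cfg.cleaning.get(var, {}))
        cleaned[var] = clean_series(impute_missing(m, cfg.impute_max_run), opts)
    return cleaned


@_stage("transform")
def _transform(cfg: PipelineConfig, cleaned: dict):
    T = next(iter(cleaned.values())).n_quarters
    grid = make_timescale_grid(T, **cfg.grid)
    sets = {var: normalize_power(transform_set(c, grid)) for var, c in cleaned.items()}
    return grid, sets


def run_analysis(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns a dict of in-memory results and writes
    all tabular outputs plus a manifest under ``cfg.output_dir``."""
    problems = cfg.validate()
    if problems:
        raise PipelineError("invalid config: " + "; ".join(problems))
    out = cfg.output_dir

    data = _ingest(cfg)
    filter_report = _filter(cfg, data)
    cleaned = _clean(cfg, data)
    grid, sets = _transform(cfg, cleaned)

    regions = sorted({loc.region for loc in sets[cfg.response].locations or []})
    tables, index_tables = [], []
    results: dict = {"grid": grid, "regions": {}, "filter_report": filter_report}
    for rix, region in enumerate(regions):
        try:
            yset = sets[cfg.response]
            fit = fit_wlm(
                yset,
                [sets[p] for p in cfg.predictors],
                region_subset=region,
                predictor_names=list(cfg.predictors),
            )
            observed = mean_squared_synchrony(fit.response_meanfield)
            predicted = mean_squared_synchrony(fit.model_meanfield)
            table = attribute_synchrony(fit, observed, cfg.bands, region=region)
            tables.append(table)

            y_region = yset.subset_locations(
                [i for i, loc in enumerate(yset.locations) if loc.region == region]
            )
            wpmf = wavelet_phasor_mean_field(y_region)
            sig = wpmf_significance(y_region, cfg.n_surrogates, seed=cfg.seed + rix)

            idx_table = None
            if data["index"] is not None:
                _, idx_table = index_coherence_model(
                    y_region, data["index"], cfg.bands, region=region
                )
                index_tables.append(idx_table)

            results["regions"][region] = {
                "fit": fit,
                "observed": observed,
                "predicted": predicted,
                "attribution": table,
                "wpmf": wpmf,
                "significance": sig,
                "index_attribution": idx_table,
            }

            prof = pd.DataFrame(
                {
                    "timescale_quarters": grid.timescales,
                    "observed": observed.values,
                    "predicted": predicted.values,
                }
            )
            atomic_write_csv(prof, os.path.join(out, f"profile_{region}.csv"))
            heat = pd.DataFrame(np.abs(fit.response_meanfield.values) ** 2)
            atomic_write_csv(heat, os.path.join(out, f"wmf_sq_{region}.csv"), header=False)
            atomic_write_csv(
                pd.DataFrame(sig.p_values), os.path.join(out, f"wpmf_p_{region}.csv"), header=False
            )
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(f"stage 'model' (region {region!r}): {e}") from e

    full = AttributionTable.concat(tables)
    write_attribution_table(full, os.path.join(out, "attribution.csv"))
    if index_tables:
        write_attribution_table(
            AttributionTable.concat(index_tables), os.path.join(out, "index_attribution.csv")
        )
    atomic_write_csv(filter_report, os.path.join(out, "filter_report.csv"))

    manifest = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "region_significance_seeds": {r: cfg.seed + i for i, r in enumerate(regions)},
        "n_locations": sets[cfg.response].n_locations,
        "n_quarters": sets[cfg.response].n_times,
        "timescales": [float(s) for s in grid.timescales],
        "config": yaml.safe_load(
            json.dumps(
                {**{k: v for k, v in cfg.__dict__.items() if k != "bands"},
                 "bands": [b.__dict__ for b in cfg.bands]},
                default=str,
            )
        ),
    }
    os.makedirs(out, exist_ok=True)
    tmp = os.path.join(out, ".manifest.tmp")
    with open(tmp, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    os.replace(tmp, os.path.join(out, "manifest.yaml"))

    results["attribution"] = full
    results["manifest"] = manifest
    return results
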