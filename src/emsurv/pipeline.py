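"""End-to-end pipeline: materialise inputs, run scenarios, write results.

Thin orchestration over the library modules.  All outputs are atomic (written
to a temporary file, then renamed), so a failed run never leaves a partial
results file behind.  Stage progress is logged to stderr; results are never
mixed into logs.
"""

from __future__ import annotations

import json
import logging
import pathlib
import tempfile
import time
from typing import Any

from .config import ScenarioConfig
from .curves import HazardCurves, generate_curves, read_curves, write_curves
from .drivetime import write_reach_curve
from .region import RegionScenario, generate_region, read_region, write_region
from .survival import marginal_effects, run_scenario

log = logging.getLogger("emsurv")


def _atomic_write_text(path: pathlib.Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd = tempfile.NamedTemporaryFile("w", dir=path.parent, delete=False,
                                     prefix=path.name, suffix=".tmp")
    try:
        fd.write(text)
        fd.close()
        pathlib.Path(fd.name).replace(path)
    except BaseException:
        fd.close()
        pathlib.Path(fd.name).unlink(missing_ok=True)
        raise


def materialise_region(config: ScenarioConfig, seed: int) -> RegionScenario:
    if config.region_source.source == "load":
        log.info("region: loading from %s", config.region_source.path)
        return read_region(config.region_source.path)
    log.info("region: generating (seed=%d, %d nodes, %d homes)",
             seed, config.region.n_nodes, config.region.n_homes)
    return generate_region(config.region, seed)


def materialise_curves(config: ScenarioConfig, seed: int) -> HazardCurves:
    if config.curves_source.source == "load":
        log.info("curves: loading from %s", config.curves_source.path)
        return read_curves(config.curves_source.path)
    log.info("curves: generating (shape=%s)", config.curve_params.shape)
    return generate_curves(config.curve_params, seed)


def cmd_generate(config: ScenarioConfig, seed: int,
                 outdir: str | pathlib.Path) -> dict[str, Any]:
    """Write region CSVs, curves.csv, the resolved config and a manifest."""
    outdir = pathlib.Path(outdir)
    t0 = time.perf_counter()
    region = materialise_region(config, seed)
    curves = materialise_curves(config, seed)
    files = [p.name for p in write_region(region, outdir)]
    files.append(write_curves(curves, outdir / "curves.csv").name)
    config.write_yaml(outdir / "scenario.yaml")
    files.append("scenario.yaml")
    manifest = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),   # every defaulted parameter, resolved
        "files": sorted(files),
    }
    _atomic_write_text(outdir / "manifest.json", json.dumps(manifest, indent=2) + "\n")
    log.info("generate: wrote %d files to %s in %.2fs",
             len(files) + 1, outdir, time.perf_counter() - t0)
    return manifest


def cmd_run(config: ScenarioConfig, seed: int,
            outdir: str | pathlib.Path) -> dict[str, Any]:
    """Run every configured resource set and the shift grid; write
    results.json, marginal_effects.csv and per-set reach curves."""
    outdir = pathlib.Path(outdir)
    t0 = time.perf_counter()
    region = materialise_region(config, seed)
    curves = materialise_curves(config, seed)

    log.info("scenarios: %d resource set(s), shifts %s",
             len(config.resource_sets), list(config.shifts))
    scenario_results = []
    cache: dict = {}
    for kinds in config.resource_sets:
        t1 = time.perf_counter()
        res = run_scenario(region, curves, config.statics, config.incidence,
                           set(kinds), tail=config.tail, field_cache=cache)
        log.info("scenario %-18s beta=%.2f S=%.4f (%.2fs)",
                 res.scenario, res.beta, res.s, time.perf_counter() - t1)
        scenario_results.append(res)
        write_reach_curve(res.reach, outdir / f"reach_{res.scenario.replace('+', '_')}.csv")

    table = marginal_effects(region, curves, config.statics, config.incidence,
                             [set(k) for k in config.resource_sets],
                             list(config.shifts), tail=config.tail)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "marginal_effects.csv", index=False)

    payload: dict[str, Any] = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "pop": region.pop,
        "scenarios": [
            {
                "label": r.scenario,
                "resource_set": sorted(r.kinds),
                "r": r.r,
                "s": r.s,
                "beta": r.beta,
                "survival_pct": r.survival_pct,
                "beta_over_incidence_pct": r.beta_over_incidence_pct,
                "per_bin": list(r.per_bin),
                "unreached": r.reach.unreached,
            }
            for r in scenario_results
        ],
    }
    if len(scenario_results) >= 2:
        betas = {r.scenario: r.beta for r in scenario_results}
        labels = [r.scenario for r in scenario_results]
        payload["delta_beta"] = {
            f"{b}-{a}": betas[b] - betas[a]
            for i, a in enumerate(labels) for b in labels[i + 1:]
        }
    _atomic_write_text(outdir / "results.json", json.dumps(payload, indent=2) + "\n")
    log.info("run: finished in %.2fs -> %s", time.perf_counter() - t0,
             outdir / "results.json")
    return payload


def load_results(path: str | pathlib.Path) -> dict[str, Any]:
    path = pathlib.Path(path)
    if path.is_dir():
        path = path / "results.json"
    if not path.exists():
        raise FileNotFoundError(f"no results file at {path}")
    return json.loads(path.read_text())
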