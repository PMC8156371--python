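"""End-to-end orchestration: simulate -> metrics -> nulls -> functional ->
hotspots -> overlap -> ecosystem services, as one reproducible run.

A single top-level seed fans out to per-stage sub-seeds (stage-name
hashing, :mod:`spatdiv.seeding`), so any stage can be re-run in isolation
and still reproduce.  Every run writes a manifest with the config hash,
output checksums and per-stage timings: enough to verify a re-run is
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .crosswalk import builtin_crosswalk, facet_flags, relevant_es
from .errors import ConfigError
from .functional import flag_most_diverse, regional_share, trait_richness
from .hotspots import all_inside, bin_classes, hotspot_l1, pa_overlap
from .io import write_surfaces_long
from .phylo import classify_pdses, faith_pd, pd_ses, phylogenetic_endemism, ses_surface
from .seeding import derive_seed
from .synth import ScenarioConfig, PlantedCenter, simulate_dataset, write_dataset
from .taxonomic import (
    corrected_weighted_endemism,
    cwe_significance,
    species_richness,
    weighted_endemism,
)

log = logging.getLogger("spatdiv")

DEFAULT_CONFIG = {
    "seed": 42,
    "scenario": {
        "n_taxa": 120,
        "grid_rows": 12,
        "grid_cols": 12,
        "endemic_fraction": 0.55,
        "logseries_p": 0.95,
        "cohesion": 0.8,
        "trait_coverage": 0.8,
    },
    "nulls": {
        "n_perm": 199,
        "cwe_algorithm": "curveball",
        "pd_null": "uniform_tip_draw",
        "alpha": 0.05,
    },
    "hotspots": {"level": 0.99},
    "functional": {"denominator": "covered"},
}

_SECTION_KEYS = {
    "seed": None,
    "scenario": None,  # validated by ScenarioConfig itself
    "nulls": {"n_perm", "cwe_algorithm", "pd_null", "alpha"},
    "hotspots": {"level"},
    "functional": {"denominator"},
}


def load_config(path_or_dict) -> dict:
    """Load and validate a YAML config, merged over the defaults."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict or {})
    unknown = set(raw) - set(_SECTION_KEYS)
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for section, value in raw.items():
        if section == "seed":
            config["seed"] = int(value)
            continue
        if not isinstance(value, dict):
            raise ConfigError(f"config section '{section}' must be a mapping")
        allowed = _SECTION_KEYS[section]
        if allowed is not None:
            bad = set(value) - allowed
            if bad:
                raise ConfigError(
                    f"unknown key(s) in '{section}': {sorted(bad)}"
                )
        config[section] = {**config.get(section, {}), **value}
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config=None, outdir="out") -> dict:
    """Execute every stage in dependency order; returns the run manifest.

    Partial outputs are preserved on failure (the manifest then records
    the failing stage).
    """
    config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
        "outputs": [],
        "status": "running",
    }
    outputs: list[Path] = []

    def _stage(name):
        manifest["stages"][name] = {"seed": derive_seed(seed, name)}
        return time.perf_counter()

    def _done(name, t0):
        manifest["stages"][name]["seconds"] = round(time.perf_counter() - t0, 3)

    try:
        # -- simulate -----------------------------------------------------
        t0 = _stage("simulate")
        scenario = dict(config["scenario"])
        if "planted" in scenario and scenario["planted"] is not None:
            scenario["planted"] = PlantedCenter(**scenario["planted"])
        ds = simulate_dataset(
            ScenarioConfig(seed=derive_seed(seed, "simulate"), **scenario)
        )
        data_paths = write_dataset(ds, outdir / "data")
        outputs += list(data_paths.values())
        _done("simulate", t0)

        # -- metrics ------------------------------------------------------
        t0 = _stage("metrics")
        sr = species_richness(ds.occ)
        we = weighted_endemism(ds.occ)
        cwe = corrected_weighted_endemism(ds.occ)
        pd_surface = faith_pd(ds.occ, ds.tree)
        pe = phylogenetic_endemism(ds.occ, ds.tree)
        surfaces_path = outdir / "surfaces.csv"
        write_surfaces_long([sr, we, cwe, pd_surface, pe], surfaces_path)
        outputs.append(surfaces_path)
        _done("metrics", t0)

        # -- nulls --------------------------------------------------------
        t0 = _stage("nulls")
        nulls_cfg = config["nulls"]
        cwe_ens = cwe_significance(
            ds.occ, n_perm=nulls_cfg["n_perm"],
            algorithm=nulls_cfg["cwe_algorithm"],
            seed=derive_seed(seed, "nulls_cwe"),
        )
        pd_ens = pd_ses(
            ds.occ, ds.tree, n_perm=nulls_cfg["n_perm"],
            null_model=nulls_cfg["pd_null"],
            seed=derive_seed(seed, "nulls_pd"),
        )
        ses = ses_surface(pd_ens)
        ses_classes = classify_pdses(ses)
        nulls_frame = pd.concat(
            [cwe_ens.to_frame(), pd_ens.to_frame()], ignore_index=True
        )
        nulls_path = outdir / "nulls.csv"
        nulls_frame.to_csv(nulls_path, index=False)
        pd.DataFrame(
            sorted(ses_classes.items()), columns=["cell", "pdses_class"]
        ).to_csv(outdir / "pdses_classes.csv", index=False)
        outputs += [nulls_path, outdir / "pdses_classes.csv"]
        _done("nulls", t0)

        # -- functional ---------------------------------------------------
        t0 = _stage("functional")
        diverse = {}
        func_rows, share_rows = [], []
        for trait in sorted(ds.traits.traits):
            surface = trait_richness(ds.occ, ds.traits, trait)
            flagged = flag_most_diverse(
                surface, denominator=config["functional"]["denominator"]
            )
            diverse[trait] = flagged
            for cell in surface.cells:
                func_rows.append(
                    {
                        "trait": trait,
                        "cell": cell,
                        "count": surface.counts[cell],
                        "most_diverse": cell in flagged.flagged,
                    }
                )
            if flagged.flagged:
                for region, share in regional_share(flagged, ds.regions).items():
                    share_rows.append(
                        {"trait": trait, "region": region, "share": share}
                    )
        func_path = outdir / "functional.csv"
        pd.DataFrame(func_rows).to_csv(func_path, index=False)
        shares_path = outdir / "functional_regional.csv"
        pd.DataFrame(
            share_rows, columns=["trait", "region", "share"]
        ).to_csv(shares_path, index=False)
        outputs += [func_path, shares_path]
        _done("functional", t0)

        # -- hotspots -----------------------------------------------------
        t0 = _stage("hotspots")
        level = config["hotspots"]["level"]
        hotspot_sets = {
            s.name: hotspot_l1(s, level=level)
            for s in (sr, cwe, pd_surface, pe)
        }
        hs_rows = [
            {"metric": m, "level": h.level, "threshold": h.threshold,
             "cell": c}
            for m, h in hotspot_sets.items() for c in sorted(h.members)
        ]
        hs_path = outdir / "hotspots.csv"
        pd.DataFrame(hs_rows).to_csv(hs_path, index=False)
        classes = {name: bin_classes(s) for name, s in
                   (("CWE", cwe), ("PE", pe))}
        cls_rows = [
            {"metric": m, "cell": c, "class": k}
            for m, d in classes.items() for c, k in sorted(d.items())
        ]
        classes_path = outdir / "classes.csv"
        pd.DataFrame(cls_rows).to_csv(classes_path, index=False)
        outputs += [hs_path, classes_path]
        _done("hotspots", t0)

        # -- overlap ------------------------------------------------------
        t0 = _stage("overlap")
        overlap_frames = []
        headlines = {}
        for metric, classed in classes.items():
            rep = pa_overlap(classed, ds.pa)
            rep.insert(0, "metric", metric)
            overlap_frames.append(rep)
            headlines[f"{metric}_medium_plus_all_inside"] = all_inside(rep)
        for metric, hs in hotspot_sets.items():
            rep = pa_overlap(hs, ds.pa)
            rep.insert(0, "metric", f"{metric}_L1")
            overlap_frames.append(rep)
        overlap_path = outdir / "overlap.csv"
        pd.concat(overlap_frames, ignore_index=True).to_csv(
            overlap_path, index=False
        )
        manifest["headlines"] = headlines
        outputs.append(overlap_path)
        _done("overlap", t0)

        # -- ecosystem services -------------------------------------------
        t0 = _stage("es")
        xwalk = builtin_crosswalk()
        xwalk_path = outdir / "crosswalk.csv"
        xwalk.to_csv(xwalk_path)
        es_rows = []
        for cell in ds.occ.cells:
            flags = facet_flags(cell, hotspots=hotspot_sets,
                                diverse_flags=diverse)
            codes = relevant_es(flags, xwalk)
            es_rows.append(
                {
                    "cell": cell,
                    "flags": "|".join(l for l, v in flags.items() if v),
                    "relevant_codes": "|".join(codes),
                    "n_relevant": len(codes),
                }
            )
        es_path = outdir / "es_relevance.csv"
        pd.DataFrame(es_rows).to_csv(es_path, index=False)
        outputs += [xwalk_path, es_path]
        _done("es", t0)

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed: {type(exc).__name__}: {exc}"
        raise
    finally:
        manifest["outputs"] = [
            {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for p in outputs
        ]
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("run complete: %d outputs in %s", len(outputs), outdir)
    return manifest
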