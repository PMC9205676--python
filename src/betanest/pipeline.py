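"""End-to-end orchestration: simulate → rarefy → incidence → partition →
permutation tests → gradient regressions → model averaging.

One YAML config drives the whole run.  A top-level seed deterministically
derives per-stage seeds through ``numpy.random.SeedSequence``, so the
full report is bit-reproducible and any stage can be re-run on the
retained intermediate TSVs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .averaging import (
    all_subsets_aicc,
    average_parameters,
    environmental_deltas,
    explained_variability,
    standardize,
    vif,
)
from .community import rarefy, to_incidence, write_count_table
from .gradient import compare_slopes, fit_dissimilarity_gradient
from .multivariate import nmds, permanova, permdisp
from .partition import (
    partition_matrix,
    species_pool_accounting,
    treatment_vs_ambient,
)
from .simulate import SyntheticConfig, generate_species_pool, simulate_experiment

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

#: default per-group assembly regimes: plants dominated by ordered species
#: loss, bacteria by niche replacement, fungi weakly structured; microbial
#: groups get amplicon-scale read depths and the matching rarefaction depth
DEFAULT_GROUPS: dict[str, dict] = {
    "plant": {"filtering_strength": 0.8, "replacement_rate": 0.15,
              "pool_size": 60, "depth_mean": 4000, "rarefy_depth": None},
    "bacteria": {"filtering_strength": 0.1, "replacement_rate": 0.45,
                 "pool_size": 400, "depth_mean": 25000, "rarefy_depth": 18877},
    "fungi": {"filtering_strength": 0.1, "replacement_rate": 0.2,
              "pool_size": 300, "depth_mean": 30000, "rarefy_depth": 24945},
}

_CONFIG_KEYS = {"seed", "groups", "n_perm", "nmds", "delta_aicc",
                "simulate"}


def load_config(path) -> dict:
    """Load a YAML pipeline config and fill in defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return normalize_config(raw)


def normalize_config(raw: dict | None = None) -> dict:
    raw = dict(raw or {})
    cfg = {
        "seed": int(raw.get("seed", 0)),
        "n_perm": int(raw.get("n_perm", 999)),
        "delta_aicc": float(raw.get("delta_aicc", 4.0)),
        "nmds": {"k": 2, "n_starts": 20, "max_iter": 300, "tol": 1e-7},
        "simulate": dict(raw.get("simulate", {})),
        "groups": {},
    }
    cfg["nmds"].update(raw.get("nmds", {}))
    groups = raw.get("groups") or {k: {} for k in DEFAULT_GROUPS}
    for name, overrides in groups.items():
        base = dict(DEFAULT_GROUPS.get(name, {}))
        base.update(cfg["simulate"])
        base.update(overrides or {})
        cfg["groups"][name] = base
    return cfg


def _simulate_group(name: str, params: dict, seed: int):
    params = dict(params)
    rarefy_depth = params.pop("rarefy_depth", None)
    config = SyntheticConfig(group=name, seed=seed, **params)
    pool = generate_species_pool(config)
    counts, meta, env = simulate_experiment(pool, config)
    return config, counts, meta, env, rarefy_depth


def run_all(config: dict | None = None, out_dir=None, seed: int | None = None) -> dict:
    """Run the full synthetic analysis and return the machine-readable report.

    Parameters
    ----------
    config : normalised pipeline config (see :func:`normalize_config`)
    out_dir : if given, intermediate TSVs and ``report.json`` are written there
    seed : overrides the config seed
    """
    cfg = normalize_config(config) if not _is_normalized(config) else dict(config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(cfg["seed"])
    group_names = sorted(cfg["groups"])
    children = ss.spawn(len(group_names) + 1)
    stat_seed = children[-1].generate_state(1)[0] % (2 ** 31)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software_version": __version__,
        "seed": cfg["seed"],
        "config": _jsonable(cfg),
        "groups": {},
    }
    comparisons_all = []
    deltas_all = {}

    for gi, (gname, child) in enumerate(zip(group_names, children)):
        t0 = time.monotonic()
        gseed = child.generate_state(1)[0] % (2 ** 31)
        config_g, counts, meta, env, rarefy_depth = _simulate_group(
            gname, cfg["groups"][gname], gseed
        )
        if rarefy_depth:
            counts = rarefy(counts, rarefy_depth, seed=gseed + 1)
            meta = meta[meta["sample"].isin(counts.columns)].reset_index(drop=True)
        inc = to_incidence(counts)
        inc = inc.loc[:, inc.any(axis=0)]
        sor, sim, nes = partition_matrix(inc)
        meta_idx = meta.set_index("sample").loc[list(inc.index)]
        groups_lvl = meta_idx["n_level"]
        rng_stat = np.random.default_rng([stat_seed, gi])
        perma = permanova(sor, groups_lvl, n_perm=cfg["n_perm"], seed=rng_stat)
        disp = permdisp(sor, groups_lvl, n_perm=cfg["n_perm"], seed=rng_stat)
        nm = cfg["nmds"]
        ordn = nmds(sor, k=nm["k"], n_starts=nm["n_starts"],
                    max_iter=nm["max_iter"], tol=nm["tol"], seed=rng_stat)
        comp = treatment_vs_ambient(inc, meta)
        pool_acc = species_pool_accounting(inc, meta)
        deltas = environmental_deltas(env, meta, comp)
        comparisons_all.append(comp)
        deltas_all[gname] = (comp, deltas)

        report["groups"][gname] = {
            "n_samples": int(inc.shape[0]),
            "n_species_observed": int(inc.shape[1]),
            "permanova": {
                "pseudo_F": perma.pseudo_F, "R2": perma.R2, "p": perma.p,
                "n_perm": perma.n_perm,
            },
            "permdisp": {"F": disp.F, "p": disp.p},
            "nmds_stress": ordn.stress,
            "comparison_summary": _summarize_comparisons(comp),
        }
        if out is not None:
            write_count_table(counts, out / f"{gname}_counts.tsv")
            meta.to_csv(out / f"{gname}_metadata.tsv", sep="\t", index=False)
            env.to_csv(out / f"{gname}_env.tsv", sep="\t", index=False)
            sor.to_csv(out / f"{gname}_beta_sor.tsv", sep="\t")
            sim.to_csv(out / f"{gname}_beta_sim.tsv", sep="\t")
            nes.to_csv(out / f"{gname}_beta_nes.tsv", sep="\t")
            comp.to_csv(out / f"{gname}_comparisons.tsv", sep="\t", index=False)
            pool_acc.to_csv(out / f"{gname}_pool_accounting.tsv", sep="\t",
                            index=False)
            ordn.coordinates.to_csv(out / f"{gname}_nmds.tsv", sep="\t")
        logger.info("group %s finished in %.1fs", gname,
                    time.monotonic() - t0)

    comp_all = pd.concat(comparisons_all, ignore_index=True)
    fits = fit_dissimilarity_gradient(comp_all, "beta_sor")
    report["gradient_fits"] = fits.to_dict("records")
    if len(group_names) >= 2:
        contrasts = compare_slopes(comp_all, "beta_sor")
        report["slope_comparison"] = contrasts.to_dict("records")
    if out is not None:
        comp_all.to_csv(out / "comparisons.tsv", sep="\t", index=False)
        fits.to_csv(out / "gradient_fits.tsv", sep="\t", index=False)

    report["model_averaging"] = {}
    for gname, (comp, deltas) in deltas_all.items():
        entry = {}
        Z, _, _ = standardize(deltas)
        entry["vif"] = vif(Z).to_dict()
        for component in ("beta_sim", "beta_nes"):
            ms = all_subsets_aicc(comp[component].to_numpy(), Z)
            avg = average_parameters(ms, delta_threshold=cfg["delta_aicc"])
            ev = explained_variability(ms)
            entry[component] = {
                "averaged": avg.table.reset_index(names="predictor")
                .to_dict("records"),
                "n_models": avg.n_models,
                "explained_variability": ev,
            }
            if out is not None:
                avg.table.to_csv(
                    out / f"{gname}_{component}_averaged.tsv", sep="\t"
                )
                ms.table.to_csv(
                    out / f"{gname}_{component}_models.tsv", sep="\t",
                    index=False,
                )
        report["model_averaging"][gname] = entry

    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report


def _is_normalized(config) -> bool:
    return isinstance(config, dict) and _CONFIG_KEYS <= set(config or {})


def _summarize_comparisons(comp: pd.DataFrame) -> list[dict]:
    agg = (comp.groupby("n_level")[["beta_sor", "beta_sim", "beta_nes"]]
           .mean().reset_index())
    return agg.to_dict("records")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
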