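"""End-to-end analysis driver with run manifests.

One YAML config describes a full run: the input tables (or a
``simulate`` block), the networks to analyze, the model (1 = age + sex;
2 adds annual income; 3 adds parental education), the distance metric,
permutation counts B and K, and a master seed.  Every stochastic stage
draws its own seed from the master via ``numpy.random.SeedSequence``
spawning in a fixed order, so a manifest (config hash, input hashes,
seeds, B, K, version) uniquely determines every output: re-running a
manifest reproduces the result files bit-identically.

Stage order per network: normalize -> MDMR (omnibus + pairwise +
interaction) -> jack-knife effect sizes -> dbRDA ordination -> post-hoc
regressions; a cohort summary is written once.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import build_design
from .effect_size import jackknife_effect_sizes, rank_regions
from .mdmr import (gower_center, interaction_test, mdmr_fit,
                   pairwise_distances, pairwise_group_contrasts)
from .networks import load_network_spec
from .normalize import to_proportions, to_tscores
from .ordination import dbrda
from .posthoc import cohort_summary, posthoc_table
from .simulate import SimulationConfig, simulate_cohort
from .tabular import align, read_cohort, validate_volumes

log = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "run_full_analysis"]

DEFAULT_CONFIG: dict = {
    "networks": ["FPN", "DMN"],
    "model": 1,
    "metric": "manhattan",
    "n_perm": 999,
    "K": 200,
    "seed": 0,
    "simulate": {},
    "skip_proportions": False,
}

_MODEL_COVARIATES = {1: (), 2: ("income",), 3: ("education",)}
_MODEL_COLUMNS = {2: "income_bracket", 3: "parental_education"}


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _jsonable(obj):
    """Canonical JSON-compatible view of a config (tuple keys stringified)."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj if isinstance(obj, (str, int, float, bool, type(None))) else str(obj)


def _stage_seeds(master: int, stages: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(stages))
    return {s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(stages, children)}


def run_full_analysis(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute the full pipeline; returns the output directory.

    Any stage failure aborts with a stage-tagged error; partial outputs
    stay on disk next to a ``.partial`` marker.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.touch()

    model = int(cfg["model"])
    if model not in (1, 2, 3):
        raise ValueError(f"model must be 1, 2 or 3, got {model}")
    metric = cfg["metric"]
    n_perm, K = int(cfg["n_perm"]), int(cfg["K"])
    networks = [str(n).upper() for n in cfg["networks"]]

    stage_names = ["simulate"] + [f"{s}:{n}" for n in networks
                                  for s in ("mdmr", "effect_size")]
    seeds = _stage_seeds(int(cfg["seed"]), stage_names)
    manifest: dict = {
        "version": __version__,
        "config_hash": _sha256(json.dumps(_jsonable(cfg), sort_keys=True).encode()),
        "seeds": seeds,
        "n_perm": n_perm, "K": K, "metric": metric, "model": model,
        "defaults_log": {
            "t_score": "mean 50, SD 10, sample (n-1) SD",
            "permutation_scheme": "freedman_lane",
            "p_estimator": "(1 + #{>= observed}) / (1 + B)",
        },
        "inputs": {}, "stages": {},
    }

    def run_stage(name: str, fn):
        try:
            result = fn()
            manifest["stages"][name] = "ok"
            return result
        except Exception as exc:
            manifest["stages"][name] = f"error: {exc}"
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    def load_inputs():
        if cfg.get("cohort") and cfg.get("volumes"):
            for p in (cfg["cohort"], cfg["volumes"]):
                manifest["inputs"][str(p)] = _sha256(Path(p).read_bytes())
            cohort = read_cohort(cfg["cohort"], schema=cfg.get("cohort_schema"))
            raw = pd.read_csv(cfg["volumes"],
                              float_precision="round_trip").set_index("participant_id")
            raw.index = raw.index.astype(str)
            return cohort, raw
        sim_cfg = SimulationConfig(**cfg.get("simulate") or {})
        cohort, volumes, truth = simulate_cohort(sim_cfg, seed=seeds["simulate"])
        (out / "truth.json").write_text(json.dumps(truth, indent=2, default=str))
        cohort.to_csv(out / "cohort.csv", index=False)
        volumes.to_csv(out / "volumes.csv")
        return cohort, volumes

    cohort, raw_volumes = run_stage("load", load_inputs)

    if model in _MODEL_COLUMNS:
        col = _MODEL_COLUMNS[model]
        if col not in cohort.columns or cohort[col].isna().all():
            raise ValueError(f"model {model} requires cohort column {col!r}")

    summary = cohort_summary(cohort)
    summary["counts"].to_csv(out / "cohort_counts.csv")
    (out / "cohort_summary.json").write_text(json.dumps(
        {k: v for k, v in summary.items() if k in ("n", "anova", "chi2", "ols_contrasts")},
        indent=2, default=str))

    covariates = ("age", "sex", *_MODEL_COVARIATES[model])
    for net in networks:
        spec = load_network_spec(net)
        coh, vols = align(cohort, validate_volumes(raw_volumes, spec))

        props = vols if cfg["skip_proportions"] else to_proportions(vols, coh)
        Y = to_tscores(props)
        Y.to_csv(out / f"tscores_{net}.csv")

        D = pairwise_distances(Y, metric=metric)
        G = gower_center(D)
        design = build_design(coh, terms=("group", *covariates))

        def mdmr_stage(D=D, G=G, coh=coh, design=design, net=net):
            seed = seeds[f"mdmr:{net}"]
            omnibus = mdmr_fit(G, design, n_perm=n_perm, seed=seed, metric=metric)
            omnibus.to_frame().to_csv(out / f"mdmr_omnibus_{net}.csv", index=False)
            pairs = pairwise_group_contrasts(D, coh, covariates=covariates,
                                             n_perm=n_perm, seed=seed, metric=metric)
            rows = [{"contrast": f"{a} vs {b}", **vars(r.terms["group"])}
                    for (a, b), r in pairs.items()]
            pd.DataFrame(rows).to_csv(out / f"mdmr_pairwise_{net}.csv", index=False)
            inter = interaction_test(G, coh, covariates=("age", *_MODEL_COVARIATES[model]),
                                     n_perm=n_perm, seed=seed)
            inter.to_frame().to_csv(out / f"mdmr_interaction_{net}.csv", index=False)
            return pairs

        pairs = run_stage(f"mdmr:{net}", mdmr_stage)

        def delta_stage(Y=Y, coh=coh, net=net):
            seed = seeds[f"effect_size:{net}"]
            groups = coh["group"].astype(str).to_numpy()
            tables = []
            for (a, b) in pairs:
                mask = np.isin(groups, [a, b])
                sub_design = build_design(coh.loc[mask].reset_index(drop=True),
                                          terms=("group", *covariates))
                tab = jackknife_effect_sizes(Y.loc[mask], sub_design, "group",
                                             metric=metric, K=K, seed=seed)
                tab["contrast"] = f"{a} vs {b}"
                tables.append(tab)
            full_design = build_design(coh, terms=("group", *covariates))
            sex_tab = jackknife_effect_sizes(Y, full_design, "sex",
                                             metric=metric, K=K, seed=seed)
            sex_tab["contrast"] = "sex"
            tables.append(sex_tab)
            all_tab = pd.concat(tables)
            all_tab.to_csv(out / f"effect_sizes_{net}.csv")
            return all_tab

        deltas = run_stage(f"effect_size:{net}", delta_stage)

        ord_res = dbrda(G, design, constraint="group",
                        covariates=covariates, groups=coh["group"].astype(str),
                        index=Y.index)
        ord_res.scores.to_csv(out / f"dbrda_scores_{net}.csv")
        ord_res.centroids.to_csv(out / f"dbrda_centroids_{net}.csv")
        ord_res.centroid_se.to_csv(out / f"dbrda_centroid_se_{net}.csv")
        ord_res.centroid_distances.to_csv(out / f"centroid_distances_{net}.csv", index=False)

        # post-hoc OLS on the top-2 delta regions of each pairwise contrast
        ph_rows = []
        for (a, b) in pairs:
            tab = deltas[deltas["contrast"] == f"{a} vs {b}"]
            top = rank_regions(tab, top_k=2).index.tolist()
            ph_rows.append(posthoc_table(Y, coh, top, [(a, b)], ("age", "sex")))
        pd.concat(ph_rows).to_csv(out / f"posthoc_{net}.csv", index=False)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    marker.unlink(missing_ok=True)
    return out
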