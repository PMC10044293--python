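"""End-to-end pipeline: generate -> design -> fit -> preprocess -> PLS ->
cluster -> Monte Carlo -> MFA -> PLS-PM.

A single config dict (seedable, serializable) drives every stage;
re-running with the same config reproduces all outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cluster_mod
from . import design as design_mod
from . import io as io_mod
from . import mfa as mfa_mod
from . import montecarlo as mc_mod
from . import pls as pls_mod
from . import plspm as plspm_mod
from . import preprocess as pre_mod
from . import rsm as rsm_mod
from .components import COMPONENT_ORDER, default_component_specs
from .simulate import (
    assign_bulls,
    default_true_model,
    simulate_bull_effects,
    simulate_responses,
)

logger = logging.getLogger(__name__)

X_COLUMNS = list(COMPONENT_ORDER)
Y_COLUMNS = ["tm", "pm"]


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "design": {
            "n_runs": 122,
            "n_replicates": 4,
            "n_starts": 1,
            "tol": 1e-6,
            "max_sweeps": 10,
        },
        "generator": {
            "noise_sd": None,  # None -> published residual mean squares
            "between_group_sd": 5.0,
            "within_group_sd": 2.0,
        },
        "preprocess": {"k_outliers": 88, "calibration_fraction": 0.75},
        "pls": {"n_components": 3, "max_cv_components": 6},
        "cluster": {"n_groups": 4},
        "monte_carlo": {"n_draws": 10_000, "top_k": 10},
        "mfa": {"n_dims": 5},
        "plspm": {"scheme": "centroid"},
    }


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute every stage; write stage outputs and a run manifest.

    Returns a dict of in-memory stage results keyed by stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    rng = np.random.default_rng(seed)
    results: dict = {}
    stages: list[str] = []

    def done(name: str) -> None:
        stages.append(name)
        logger.info("stage complete: %s", name)

    # 1. design
    dcfg = config["design"]
    specs = default_component_specs()
    model_spec = design_mod.quadratic_model(list(COMPONENT_ORDER))
    dm = design_mod.coordinate_exchange(
        dcfg["n_runs"],
        model_spec,
        n_starts=dcfg["n_starts"],
        tol=dcfg["tol"],
        seed=int(rng.integers(2**31)),
        max_sweeps=dcfg["max_sweeps"],
    )
    design_tbl = design_mod.decode(dm, specs, n_replicates=dcfg["n_replicates"])
    results["design"] = dm
    done("design")

    # 2. generate
    gcfg = config["generator"]
    effects = simulate_bull_effects(
        between_group_sd=gcfg["between_group_sd"],
        within_group_sd=gcfg["within_group_sd"],
        seed=int(rng.integers(2**31)),
    )
    design_tbl = assign_bulls(design_tbl, list(effects), seed=int(rng.integers(2**31)))
    tm_model = default_true_model("tm", bull_effects=effects, noise_sd=gcfg["noise_sd"])
    pm_model = default_true_model("pm", bull_effects=effects, noise_sd=gcfg["noise_sd"])
    table = simulate_responses(design_tbl, tm_model, pm_model, seed=int(rng.integers(2**31)))
    io_mod.write_experiment_table(table, out / "experiment.csv")
    results["table"] = table
    done("generate")

    # 3. response-surface fit + ANOVA
    lin = design_mod.linear_model(X_COLUMNS)
    fit = rsm_mod.fit_ols(table, lin, "tm")
    anova = rsm_mod.type3_anova(table, lin, "tm")
    anova.to_csv(out / "anova_tm.csv", index=False)
    results["anova"] = anova
    done("anova")

    # 4. preprocess
    pcfg = config["preprocess"]
    kept, removed = pre_mod.remove_top_residual_outliers(
        table, fit.residuals, pcfg["k_outliers"]
    )
    split = pre_mod.shuffle_split(
        kept, pcfg["calibration_fraction"], seed=int(rng.integers(2**31))
    )
    split.calibration.to_csv(out / "calibration.csv", index=False)
    split.validation.to_csv(out / "validation.csv", index=False)
    removed.to_csv(out / "removed.csv", index=False)
    results["split"] = split
    done("preprocess")

    # 5. PLS
    plscfg = config["pls"]
    pls_model = pls_mod.fit_nipals(
        split.calibration, X_COLUMNS, Y_COLUMNS,
        n_components=plscfg["n_components"],
    )
    pred_val = pls_model.predict(split.validation[X_COLUMNS].to_numpy(float))
    val_metrics = {
        col: vars(pls_mod.metrics(split.validation[col], pred_val[:, j]))
        for j, col in enumerate(Y_COLUMNS)
    }
    coef_tbl = pd.DataFrame(pls_model.coef_, index=X_COLUMNS, columns=Y_COLUMNS)
    coef_tbl.loc["intercept"] = pls_model.intercept_
    coef_tbl.to_csv(out / "pls_coefficients.csv")
    results["pls"] = pls_model
    results["validation_metrics"] = val_metrics
    done("pls")

    # 6. cluster bulls on t1-t3
    scores = cluster_mod.bull_scores(pls_model, table, X_COLUMNS)
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(scores.to_numpy()))
    dend = cluster_mod.upgma(D, labels=list(scores.index))
    groups = cluster_mod.cut_tree(dend, config["cluster"]["n_groups"])
    (out / "bulls.nwk").write_text(cluster_mod.to_newick(dend))
    groups.rename_axis("bull_id").to_frame().to_csv(out / "bull_groups.csv")
    results["cluster"] = groups
    done("cluster")

    # 7. Monte Carlo screening with the fitted equations
    mcfg = config["monte_carlo"]
    sim_spec = mc_mod.default_simulation_spec(
        specs, n_draws=mcfg["n_draws"], seed=int(rng.integers(2**31))
    )
    draws = mc_mod.simulate_formulations(sim_spec)
    preds = pls_model.predict(draws[X_COLUMNS].to_numpy(float))
    sens = mc_mod.sensitivity(
        draws[X_COLUMNS], {"tm": preds[:, 0], "pm": preds[:, 1]}
    )
    sens.to_csv(out / "sensitivity.csv")
    top_tm = mc_mod.top_k(draws, preds[:, 0], k=mcfg["top_k"], response_name="tm")
    top_pm = mc_mod.top_k(draws, preds[:, 1], k=mcfg["top_k"], response_name="pm")
    top_tm.to_csv(out / "top_tm.csv", index=False)
    top_pm.to_csv(out / "top_pm.csv", index=False)
    results["sensitivity"] = sens
    results["top_tm"], results["top_pm"] = top_tm, top_pm
    done("monte_carlo")

    # 8. MFA
    mfa_res = mfa_mod.fit_mfa(table, mfa_mod.default_groups(), n_dims=config["mfa"]["n_dims"])
    mfa_res.group_contributions_.to_csv(out / "mfa_group_contributions.csv")
    mfa_res.variable_coordinates_.to_csv(out / "mfa_variable_coords.csv")
    results["mfa"] = mfa_res
    done("mfa")

    # 9. PLS-PM
    pm = plspm_mod.fit_plspm(table, scheme=config["plspm"]["scheme"])
    pm.path_coefficients_.to_csv(out / "plspm_paths.csv")
    pd.DataFrame(
        {"dg_rho": pm.dg_rho_, "communality": pm.communality_}
    ).to_csv(out / "plspm_fit.csv")
    results["plspm"] = pm
    done("plspm")

    manifest = {
        "seed": seed,
        "stages": stages,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "config": config,
        "gof": pm.gof_,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
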