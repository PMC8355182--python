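"""Shared simulation harness for the acceptance checks: run the full
analysis chain on one synthetic dataset and collect per-dataset metrics."""

import numpy as np
import pandas as pd

from remap_rsa import (SimConfig, align_scores, build_timepoints,
                       compute_learned_rounds, eligibility, generate_dataset,
                       lr_asymmetry, permutation_test_ip, quartile_analysis,
                       rm_anova, scene_object_scores, similarity_tensor,
                       structure_correlation)
from remap_rsa.data_model import ValidationError


def analyze_simulation(config: SimConfig, perm_seed: int,
                       with_scene_object: bool = False) -> dict:
    """Generate one dataset and reduce it to group-level summary metrics."""
    sim = generate_dataset(config, with_recognition=False)
    ds = sim.dataset
    lr = compute_learned_rounds(ds.trials, ds.catalog)
    tensor = similarity_tensor(ds)
    aligned = align_scores(tensor, eligibility(lr), lr)
    pam = (aligned.groupby(["participant", "region", "alignment"])["score"]
           .mean().unstack("alignment"))
    tps = build_timepoints(tensor)
    lag1 = structure_correlation(tps, tps, 1)
    lag2 = structure_correlation(tps, tps, 2)
    out = {}
    for region in ds.regions:
        sub = pam.xs(region, level="region")
        m = {"ip_mean": sub["IP"].mean(), "preip_mean": sub["pre-IP"].mean()}
        both = sub[["IP", "pre-IP"]].dropna()
        m["ip_minus_preip"] = (both["IP"] - both["pre-IP"]).mean()
        asym = lr_asymmetry(aligned[aligned["region"] == region]).dropna(
            subset=["preceding_mean", "succeeding_mean"])
        m["prec_minus_succ"] = (asym["preceding_mean"]
                                - asym["succeeding_mean"]).mean()
        for lag, table in ((1, lag1), (2, lag2)):
            z = table[(table["region_a"] == region)
                      & (table["region_b"] == region)]["z"]
            m[f"lag{lag}"] = z.mean()
        quart = quartile_analysis(aligned[aligned["region"] == region])
        qm = quart.groupby("quartile")["mean_ip_score"].mean()
        m["q4_lowest"] = bool(len(qm) == 4 and qm.idxmin() == 4)
        m["perm_p"] = permutation_test_ip(tensor, lr, n_iter=1000,
                                          seed=perm_seed,
                                          region=region).p
        out[region] = m
    if with_scene_object:
        sos = scene_object_scores(ds, lr)
        for region in ds.regions:
            sub = sos[sos["region"] == region]
            m = out[region]
            try:
                an = rm_anova(sub, "relative_similarity",
                              ["state", "relevance"],
                              listwise=True).set_index("effect")
                m["so_interaction_p"] = an.loc["state*relevance", "p"]
            except ValidationError:
                m["so_interaction_p"] = np.nan
            wide = sub.pivot_table(index="participant",
                                   columns=["state", "relevance"],
                                   values="relative_similarity")
            m["so_pre_comp_minus_target"] = (
                wide[("pre-learned", "competitor")]
                - wide[("pre-learned", "target")]).mean()
            m["so_post_target_minus_comp"] = (
                wide[("learned", "target")]
                - wide[("learned", "competitor")]).mean()
    return out


def collect(configs_and_seeds, **kw) -> dict[str, pd.DataFrame]:
    """Run many simulations; returns {region: metrics DataFrame}."""
    per_region: dict[str, list] = {}
    for cfg, perm_seed in configs_and_seeds:
        res = analyze_simulation(cfg, perm_seed, **kw)
        for region, m in res.items():
            per_region.setdefault(region, []).append(m)
    return {r: pd.DataFrame(rows) for r, rows in per_region.items()}
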