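"""Representational structure across calendar timepoints.

The six learning rounds define five *timepoints*, one per consecutive
round pair ({1,2} ... {5,6}).  The vector of per-pairmate similarity
scores at a timepoint is the representational structure there; Spearman
rank correlations (Fisher z-transformed) between timepoint vectors measure
whether that structure is preserved (positive), lost (zero), or inverted
(negative — the signature of overlap-triggered repulsion).  Lag-1 averages
the timepoint pairs (1,2), (2,3), (3,4); lag-2 averages (1,3), (2,4),
(3,5), so both lags rest on three comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .data_model import SCENE_ROUNDS, ValidationError
from .pattern_similarity import fisher_z

N_TIMEPOINTS = len(SCENE_ROUNDS) - 1
LAG_PAIRS = {1: ((1, 2), (2, 3), (3, 4)), 2: ((1, 3), (2, 4), (3, 5))}


def build_timepoints(tensor: pd.DataFrame) -> pd.DataFrame:
    """Timepoint table from a similarity tensor.

    Timepoint t carries the scores at round pair {t, t+1}; all five
    consecutive round pairs must be present.  Columns: participant, region,
    timepoint, pair_index, score.
    """
    cons = tensor[tensor["round_j"] == tensor["round_i"] + 1].copy()
    present = set(zip(cons["round_i"], cons["round_j"]))
    needed = {(t, t + 1) for t in range(1, N_TIMEPOINTS + 1)}
    if not needed <= present:
        raise ValidationError(
            f"tensor missing consecutive round pairs {sorted(needed - present)}")
    cons["timepoint"] = cons["round_i"].astype(int)
    return cons[["participant", "region", "timepoint", "pair_index",
                 "score"]].reset_index(drop=True)


def _spearman_z(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3:
        raise ValidationError(
            "structure correlation needs at least 3 pairmates")
    rho = spearmanr(x, y).statistic  # average ranks on ties
    return fisher_z(rho)


def _rank_rows(X: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata
    return rankdata(X, axis=-1)  # average ranks on ties


def structure_correlation(tp_a: pd.DataFrame, tp_b: pd.DataFrame,
                          lag: int) -> pd.DataFrame:
    """Lagged rank correlation of representational structure.

    ``tp_a`` supplies timepoint N and ``tp_b`` timepoint N+lag (pass the
    same table for within-region correlations; for the cross-region control
    ``tp_a`` is the sensory region and ``tp_b`` the remapping region).
    Pairmates are matched by pair_index; per participant the Fisher-z
    Spearman values of the lag's three timepoint pairs are averaged.
    """
    if lag not in LAG_PAIRS:
        raise ValueError(f"lag must be 1 or 2, got {lag}")
    rows = []
    for ra in tp_a["region"].unique():
        wa = tp_a[tp_a["region"] == ra].pivot_table(
            index="participant", columns=["timepoint", "pair_index"],
            values="score")
        for rb in tp_b["region"].unique():
            wb = tp_b[tp_b["region"] == rb].pivot_table(
                index="participant", columns=["timepoint", "pair_index"],
                values="score")
            participants = wa.index.intersection(wb.index)
            pairs = (wa.columns.get_level_values("pair_index").unique()
                     .intersection(
                         wb.columns.get_level_values("pair_index").unique()))
            if len(pairs) < 3:
                raise ValidationError(
                    "structure correlation needs at least 3 pairmates")
            zs = np.zeros(len(participants))
            for (ta, tb) in LAG_PAIRS[lag]:
                Xa = wa.loc[participants, ta][pairs].to_numpy()
                Xb = wb.loc[participants, tb][pairs].to_numpy()
                if np.isnan(Xa).any() or np.isnan(Xb).any():
                    raise ValidationError(
                        "structure correlation requires complete "
                        "timepoint vectors")
                Ra, Rb = _rank_rows(Xa), _rank_rows(Xb)
                Ra = Ra - Ra.mean(axis=1, keepdims=True)
                Rb = Rb - Rb.mean(axis=1, keepdims=True)
                denom = (np.linalg.norm(Ra, axis=1)
                         * np.linalg.norm(Rb, axis=1))
                if (denom == 0).any():
                    raise ValidationError(
                        "structure correlation undefined for a constant "
                        "timepoint vector")
                rho = np.clip((Ra * Rb).sum(axis=1) / denom, -1.0, 1.0)
                zs = zs + fisher_z(rho)
            zs = zs / len(LAG_PAIRS[lag])
            for p, z in zip(participants, zs):
                rows.append({"participant": p, "region_a": ra,
                             "region_b": rb, "lag": lag, "z": float(z)})
    return pd.DataFrame(rows)


def quartile_analysis(aligned: pd.DataFrame,
                      binning: str = "quantile") -> pd.DataFrame:
    """Mean IP score per within-participant quartile of pre-IP score.

    Pairmates contributing both a pre-IP and an IP score are binned, within
    participant, by their pre-IP score: ``binning='quantile'`` (default)
    uses quartile breaks so bins are equally populated; ``'width'`` uses
    equal-width intervals over the observed range.  Bin 4 holds the highest
    pre-IP similarity.  Participants with fewer than 4 eligible pairmates
    are omitted.
    """
    if binning not in ("quantile", "width"):
        raise ValueError(f"unknown binning {binning!r}")
    wide = aligned.pivot_table(index=["participant", "region", "pair_index"],
                               columns="alignment", values="score")
    if "pre-IP" not in wide.columns or "IP" not in wide.columns:
        return pd.DataFrame(
            columns=["participant", "region", "quartile", "mean_ip_score", "n"])
    wide = wide.dropna(subset=["pre-IP", "IP"])
    rows = []
    for (p, region), g in wide.groupby(["participant", "region"]):
        if len(g) < 4:
            continue
        pre = g["pre-IP"]
        if binning == "quantile":
            bins = pd.qcut(pre.rank(method="first"), 4, labels=False)
        else:
            bins = pd.cut(pre, 4, labels=False)
        for q in range(4):
            sel = g.loc[bins == q, "IP"]
            rows.append({"participant": p, "region": region, "quartile": q + 1,
                         "mean_ip_score": sel.mean() if len(sel) else np.nan,
                         "n": int(len(sel))})
    return pd.DataFrame(rows)
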