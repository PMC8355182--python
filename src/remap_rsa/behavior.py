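"""Behavioral scoring: round accuracy, learned rounds, alignment eligibility.

The *learned round* (LR) of a scene pairmate is the first test round from
which, in that round and every subsequent round, the participant chose the
target object with high confidence for BOTH scenes of the pair.  Pairs for
which no such round exists are "never learned" (encoded as NaN).  The
*inflection point* (IP) is the LR-1 -> LR transition; the pre-IP reference
is the LR-2 -> LR-1 non-transition.  Alignment eligibility follows from the
round bounds: IP needs LR >= 2, pre-IP needs LR >= 3, LR-k needs
LR-k >= 1, LR+k needs LR+k <= 6.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import SCENE_ROUNDS, StimulusCatalog, ValidationError

#: Sentinel for "never learned" in learned-round tables (float NaN; test with
#: pandas.isna, never with equality).
NEVER = float("nan")

ALIGNMENTS = ("pre-IP", "IP", "LR-3", "LR-2", "LR+1", "LR+2", "LR+3")


def _high_conf_correct(trials: pd.DataFrame) -> pd.Series:
    return (trials["choice"] == "target") & (trials["confidence"] == "high")


def score_rounds(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x round accuracy and high-confidence-correct rate.

    No-response trials count as incorrect.  Every participant must have the
    same set of scenes in every round (a missing cell is an error).
    """
    n_scenes = trials.groupby(["participant", "round"])["scene_id"].nunique()
    if n_scenes.nunique() != 1 or len(trials) != n_scenes.sum():
        bad = n_scenes[n_scenes != n_scenes.max()]
        raise ValidationError(
            f"incomplete trial table; short cells: {list(bad.index)[:5]}")
    rounds_per = trials.groupby("participant")["round"].nunique()
    if rounds_per.nunique() != 1:
        raise ValidationError("participants differ in number of test rounds")
    df = trials.copy()
    df["correct"] = (df["choice"] == "target").astype(float)
    df["hc_correct"] = _high_conf_correct(df).astype(float)
    out = (df.groupby(["participant", "round"], as_index=False)
           [["correct", "hc_correct"]].mean()
           .rename(columns={"correct": "accuracy",
                            "hc_correct": "high_conf_correct_rate"}))
    return out


def compute_learned_rounds(trials: pd.DataFrame,
                           catalog: StimulusCatalog) -> pd.DataFrame:
    """Derive the learned round for every (participant, pair).

    Returns columns participant, pair_index, learned_round (NaN = never).
    """
    df = trials.copy()
    df["pair_index"] = df["scene_id"].map(catalog.pair_index)
    if df["pair_index"].isna().any():
        bad = df.loc[df["pair_index"].isna(), "scene_id"].iloc[0]
        raise ValidationError(f"scene {bad!r} not in catalog")
    df["hc"] = _high_conf_correct(df)
    # both scenes of the pair high-confidence-correct in a given round
    both = (df.groupby(["participant", "pair_index", "round"])["hc"]
            .agg(lambda s: bool(s.all()) and len(s) == 2))
    wide = both.unstack("round")
    missing = [c for c in SCENE_ROUNDS if c not in wide.columns]
    if missing or wide.isna().any().any():
        raise ValidationError(f"trials missing rounds {missing or 'cells'}")
    flags = wide[list(SCENE_ROUNDS)].to_numpy(dtype=bool)
    lr = learned_round_from_flags(flags)
    out = wide.index.to_frame(index=False)
    out["learned_round"] = lr
    return out.sort_values(["participant", "pair_index"]).reset_index(drop=True)


def learned_round_from_flags(flags: np.ndarray) -> np.ndarray:
    """LR from boolean both-scenes-high-confidence-correct flags.

    ``flags`` is (n, 6); LR is the smallest k such that flags[k-1:] are all
    True, NaN if none (vectorized suffix scan).
    """
    flags = np.atleast_2d(np.asarray(flags, dtype=bool))
    n, n_rounds = flags.shape
    suffix_all = np.flip(np.cumprod(np.flip(flags, axis=1), axis=1), axis=1)
    lr = np.full(n, np.nan)
    any_true = suffix_all.any(axis=1)
    lr[any_true] = np.argmax(suffix_all[any_true], axis=1) + 1
    return lr


def eligibility(lr_table: pd.DataFrame) -> pd.DataFrame:
    """Alignment eligibility flags per (participant, pair).

    Never-learned pairs are eligible for nothing.
    """
    lr = lr_table["learned_round"].to_numpy(dtype=float)
    out = lr_table[["participant", "pair_index"]].copy()
    with np.errstate(invalid="ignore"):
        out["IP"] = lr >= 2
        out["pre-IP"] = lr >= 3
        for k in (2, 3):
            out[f"LR-{k}"] = lr - k >= 1
        for k in (1, 2, 3):
            out[f"LR+{k}"] = lr + k <= max(SCENE_ROUNDS)
    # NaN comparisons are False, so never-learned rows are already all-False
    return out


def dprime(hit_rate: float, fa_rate: float, n_old: int | None = None,
           n_new: int | None = None) -> float:
    """Signal-detection d' = Phi^-1(hit) - Phi^-1(fa).

    Extreme rates (0 or 1) are replaced by 1/(2N) and 1 - 1/(2N) when trial
    counts are supplied; without counts, extreme rates are an error because
    d' would be infinite.
    """
    def adjust(rate: float, n: int | None, label: str) -> float:
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{label} rate {rate} outside [0, 1]")
        if rate in (0.0, 1.0):
            if n is None:
                raise ValueError(
                    f"{label} rate of {rate} needs a trial count for the "
                    "1/(2N) correction")
            rate = min(max(rate, 1.0 / (2 * n)), 1.0 - 1.0 / (2 * n))
        return rate

    hit = adjust(hit_rate, n_old, "hit")
    fa = adjust(fa_rate, n_new, "false-alarm")
    return float(norm.ppf(hit) - norm.ppf(fa))


def recognition_dprime(recog: pd.DataFrame) -> pd.DataFrame:
    """Per-participant d' from old/new recognition responses.

    No-response trials are dropped; extreme rates use the 1/(2N) correction.
    """
    rows = []
    for p, g in recog.groupby("participant"):
        g = g[g["response"] != "none"]
        old = g[g["is_old"]]
        new = g[~g["is_old"]]
        if not len(old) or not len(new):
            continue
        hit = (old["response"] == "old").mean()
        fa = (new["response"] == "old").mean()
        rows.append({"participant": p,
                     "dprime": dprime(hit, fa, len(old), len(new))})
    return pd.DataFrame(rows)


def exclude_low_performers(trials: pd.DataFrame,
                           min_final_high_conf_rate: float | None = None
                           ) -> pd.DataFrame:
    """Optionally drop participants below a final-round high-confidence
    threshold.  Off by default (threshold None returns the table unchanged)."""
    if min_final_high_conf_rate is None:
        return trials
    scores = score_rounds(trials)
    final = scores[scores["round"] == scores["round"].max()]
    keep = set(final.loc[final["high_conf_correct_rate"]
                         >= min_final_high_conf_rate, "participant"])
    return trials[trials["participant"].isin(keep)].reset_index(drop=True)
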