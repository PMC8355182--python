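"""Group-level inference: t-tests, within-subject ANOVA, permutation test.

Statistics mirror standard cognitive-neuroscience reporting: one-sample
and paired t-tests with Cohen's d and a 95% CI on the mean; classical
sums-of-squares repeated-measures ANOVA (no sphericity correction) with
classical eta-squared (SS_effect / SS_total); and a within-participant
permutation test that shuffles the mapping between behavioral inflection
points and scene pairmates.  No multiple-comparison correction is applied
anywhere; every p is reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ValidationError


@dataclass(frozen=True)
class StatResult:
    """One test: point estimate, 95% CI half-width, statistic, df, p, effect
    size (Cohen's d or classical eta^2)."""

    estimate: float
    ci_halfwidth: float
    statistic: float
    df: tuple[float, ...]
    p: float
    effect_size: float
    effect_size_name: str
    tails: int
    test: str

    def to_dict(self) -> dict:
        return {"estimate": self.estimate, "ci_halfwidth": self.ci_halfwidth,
                "statistic": self.statistic, "df": list(self.df), "p": self.p,
                "effect_size": self.effect_size,
                "effect_size_name": self.effect_size_name,
                "tails": self.tails, "test": self.test}


def one_sample_t(values, mu0: float = 0.0, tails: int = 2) -> StatResult:
    """One-sample t-test of the mean against mu0 (Cohen's d = mean/sd).

    A zero-variance sample is an error, except for the degenerate case of a
    constant sample exactly at mu0, which is reported as t = 0, p = 1 (the
    limit of a vanishing effect).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        raise ValidationError("one_sample_t needs at least 2 finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        if x[0] == mu0:
            return StatResult(float(mu0), 0.0, 0.0, (float(n - 1),), 1.0,
                              0.0, "cohen_d", tails, "one-sample t")
        raise ValidationError("one_sample_t: zero variance")
    mean = x.mean()
    se = sd / np.sqrt(n)
    t = (mean - mu0) / se
    df = n - 1
    p_two = 2.0 * stats.t.sf(abs(t), df)
    p = p_two if tails == 2 else p_two / 2.0
    ci = stats.t.ppf(0.975, df) * se
    return StatResult(float(mean), float(ci), float(t), (float(df),),
                      float(min(p, 1.0)), float((mean - mu0) / sd),
                      "cohen_d", tails, "one-sample t")


def paired_t(a, b, tails: int = 2) -> StatResult:
    """Paired-samples t-test (one-sample t on the differences a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired_t needs equal-length samples")
    res = one_sample_t(a - b, 0.0, tails)
    return StatResult(res.estimate, res.ci_halfwidth, res.statistic, res.df,
                      res.p, res.effect_size, res.effect_size_name, tails,
                      "paired t")


def _effect_label(factors: tuple[str, ...]) -> str:
    return "*".join(factors)


def rm_anova(data: pd.DataFrame, dv: str, within: list[str],
             subject: str = "participant",
             listwise: bool = False) -> pd.DataFrame:
    """Classical within-subject ANOVA for 1-3 fully crossed factors.

    Each subject must contribute every factor-level cell (several rows per
    cell are averaged first).  Missing cells raise unless ``listwise=True``
    drops incomplete subjects.  Each within effect is tested against its
    interaction with subject; effect size is classical eta^2 =
    SS_effect / SS_total.  No sphericity correction is applied.
    """
    if not 1 <= len(within) <= 3:
        raise ValidationError("rm_anova supports 1-3 within factors")
    cell = (data.groupby([subject] + within, observed=True)[dv]
            .mean().unstack(within))
    if listwise:
        cell = cell.dropna()
    if cell.isna().any().any() or cell.size == 0:
        missing = cell.stack(list(range(cell.columns.nlevels)),
                             future_stack=True)
        missing = missing[missing.isna()].index.tolist()[:5]
        raise ValidationError(f"rm_anova: missing cells, e.g. {missing}")
    levels = ([list(cell.columns.get_level_values(i).unique())
               for i in range(cell.columns.nlevels)]
              if len(within) > 1 else [list(cell.columns)])
    shape = [len(cell.index)] + [len(lv) for lv in levels]
    if np.prod(shape[1:]) != cell.shape[1]:
        raise ValidationError("rm_anova: design is not fully crossed")
    Y = cell.to_numpy().reshape(shape)
    n_subj = shape[0]
    if n_subj < 2:
        raise ValidationError("rm_anova needs at least 2 subjects")
    axes = tuple(range(Y.ndim))      # axis 0 = subject, 1.. = factors
    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())
    # inclusion-exclusion decomposition over subsets of axes (subject is a
    # factor here; effects containing it provide the error strata)
    effects: dict[frozenset, np.ndarray] = {frozenset(): np.array(grand)}
    ss: dict[frozenset, float] = {}
    df: dict[frozenset, float] = {}
    for size in range(1, Y.ndim + 1):
        for subset in combinations(axes, size):
            A = frozenset(subset)
            other = tuple(ax for ax in axes if ax not in A)
            m = Y.mean(axis=other, keepdims=True)
            e = m.copy()
            for B, eb in effects.items():
                if B < A:
                    e = e - eb.reshape([shape[ax] if ax in B else 1
                                        for ax in axes] if B else [1] * Y.ndim)
            effects[A] = e.reshape([shape[ax] if ax in A else 1 for ax in axes])
            mult = int(np.prod([shape[ax] for ax in other])) if other else 1
            ss[A] = float((e ** 2).sum()) * mult
            df[A] = float(np.prod([shape[ax] - 1 for ax in A]))
    rows = []
    for size in range(1, len(within) + 1):
        for subset in combinations(range(1, Y.ndim), size):
            A = frozenset(subset)
            err = A | {0}
            ms_eff = ss[A] / df[A]
            ms_err = ss[err] / df[err]
            if ms_err == 0:
                if ss[A] == 0:      # flat data: no effect, by convention F=0
                    F = 0.0
                else:
                    raise ValidationError("rm_anova: zero error variance")
            else:
                F = ms_eff / ms_err
            p = float(stats.f.sf(F, df[A], df[err]))
            rows.append({
                "effect": _effect_label(tuple(within[ax - 1] for ax in subset)),
                "ss": ss[A], "df1": df[A], "df2": df[err], "F": float(F),
                "p": p, "eta2": ss[A] / ss_total if ss_total else 0.0,
                "n_subjects": n_subj})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PermutationResult:
    """Within-participant IP-shuffle permutation test (one-tailed)."""

    observed: float
    null_means: np.ndarray
    n_iterations: int
    p: float
    p_rule: str
    seed: int

    def to_dict(self) -> dict:
        return {"observed": self.observed,
                "n_iterations": self.n_iterations, "p": self.p,
                "p_rule": self.p_rule, "seed": self.seed,
                "null_mean": float(np.mean(self.null_means)),
                "null_sd": float(np.std(self.null_means, ddof=1))}


def permutation_test_ip(tensor: pd.DataFrame, lr_table: pd.DataFrame,
                        n_iter: int = 1000, seed: int | None = None,
                        region: str | None = None,
                        p_rule: str = "plain") -> PermutationResult:
    """Permutation test of the group-mean pairmate similarity score at the IP.

    Each iteration shuffles, within each participant, the assignment of IP
    round pairs across that participant's IP-eligible pairmates (uniform
    permutation, fixed points allowed), recomputes each pairmate's score at
    its permuted round pair, averages within then across participants.  The
    one-tailed p is the fraction of permuted group means at or below the
    observed mean (``p_rule='plain'``: k/n; ``'add-one'``: (k+1)/(n+1)).
    """
    if seed is None:
        raise ValidationError("permutation test requires an explicit seed")
    if p_rule not in ("plain", "add-one"):
        raise ValueError(f"unknown p_rule {p_rule!r}")
    t = tensor
    if region is not None:
        t = t[t["region"] == region]
    if t["region"].nunique() != 1:
        raise ValidationError("tensor spans several regions; pass region=")
    cons = t[t["round_j"] == t["round_i"] + 1]
    score = cons.pivot_table(index=["participant", "pair_index"],
                             columns="round_i", values="score")
    if score.isna().any().any() or score.shape[1] != 5:
        raise ValidationError("tensor must cover all consecutive round pairs")
    lr = lr_table.set_index(["participant", "pair_index"])["learned_round"]
    rng = np.random.default_rng(seed)
    per_obs, per_null = [], []
    for p, g in score.groupby(level="participant"):
        lrs = lr.loc[[(p, k) for k in g.index.get_level_values("pair_index")]]
        with np.errstate(invalid="ignore"):
            elig = (lrs.to_numpy(dtype=float) >= 2)
        if not elig.any():
            continue
        S = g.to_numpy()[elig]                       # (n_e, 5)
        ip_col = lrs.to_numpy(dtype=float)[elig].astype(int) - 2  # 0-based
        per_obs.append(S[np.arange(len(S)), ip_col].mean())
        perm_cols = rng.permuted(
            np.broadcast_to(ip_col, (n_iter, len(ip_col))).copy(), axis=1)
        per_null.append(S[np.arange(len(S))[None, :], perm_cols].mean(axis=1))
    if not per_obs:
        raise ValidationError("no participant has IP-eligible pairmates")
    observed = float(np.mean(per_obs, axis=0))
    null_means = np.mean(per_null, axis=0)
    k = int((null_means <= observed).sum())
    p_val = k / n_iter if p_rule == "plain" else (k + 1) / (n_iter + 1)
    return PermutationResult(observed, null_means, n_iter, float(p_val),
                             p_rule, seed)
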