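"""Cross-run pattern correlation and pairmate similarity scoring.

Pattern similarity is the Fisher z-transformed Pearson correlation between
per-stimulus response patterns (t-maps), always computed across different
scans (never within one scan).  The *pairmate similarity score* for a pair
at an unordered round pair {i, j} is

    score = mean[z(A1_i, A2_j), z(A2_i, A1_j)]
            - mean of all cross-item z's between either pairmate and every
              non-pairmate scene, both directions (2 x 2 x (n_scenes - 2)
              entries; self-correlations of a scene with itself across
              rounds are excluded).

A negative score means the pairmates are less similar than unrelated
scenes — the signature of repulsion.  Behavior-aligned scores re-index the
tensor at per-pair learned rounds: IP = {LR-1, LR}, pre-IP = {LR-2, LR-1},
LR+-k = {LR, LR+-k}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (OBJECT, OBJECT_ROUNDS, SCENE, SCENE_ROUNDS, Dataset,
                         PatternSet, StimulusCatalog, ValidationError)

#: Correlations are clamped to +-(1 - 1e-7) before the z-transform so that
#: degenerate identities stay finite.
R_CLAMP = 1.0 - 1e-7


def fisher_z(r):
    """Fisher z-transform arctanh(r), clamping |r| to 1 - 1e-7.

    Accepts scalars or arrays; |r| > 1 is an error.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0):
        raise ValueError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(arr, -R_CLAMP, R_CLAMP))
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def _standardized_rows(values: np.ndarray, stimulus_ids, what: str) -> np.ndarray:
    """Rows centered and scaled to unit norm; zero-variance rows are errors."""
    X = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    bad = norms == 0
    if bad.any():
        sid = list(stimulus_ids)[int(np.flatnonzero(bad)[0])]
        raise ValidationError(f"zero-variance pattern for stimulus {sid!r} in {what}")
    return X / norms[:, None]


@dataclass(frozen=True)
class CrossRunMatrix:
    """Stimulus x stimulus Fisher-z correlations between two scans."""

    participant: str
    region: str
    phase_a: str
    round_a: int
    phase_b: str
    round_b: int
    stimuli_a: tuple[str, ...]
    stimuli_b: tuple[str, ...]
    values: np.ndarray  # z units, rows = scan-a stimuli, cols = scan-b

    def entry(self, stim_a: str, stim_b: str) -> float:
        return float(self.values[self.stimuli_a.index(stim_a),
                                 self.stimuli_b.index(stim_b)])


def cross_run_correlation(set_a: PatternSet, set_b: PatternSet) -> CrossRunMatrix:
    """Correlate every stimulus of one scan with every stimulus of another.

    The two pattern sets must share participant and region and come from
    different scans (different round, or different phase).
    """
    if set_a.participant != set_b.participant or set_a.region != set_b.region:
        raise ValidationError("cross-run correlation requires matching "
                              "participant and region")
    if (set_a.phase, set_a.round) == (set_b.phase, set_b.round):
        raise ValidationError("within-scan correlation forbidden")
    A = _standardized_rows(set_a.values, set_a.stimulus_ids, f"scan {set_a.key}")
    B = _standardized_rows(set_b.values, set_b.stimulus_ids, f"scan {set_b.key}")
    r = np.clip(A @ B.T, -1.0, 1.0)
    return CrossRunMatrix(set_a.participant, set_a.region, set_a.phase,
                          set_a.round, set_b.phase, set_b.round,
                          set_a.stimulus_ids, set_b.stimulus_ids, fisher_z(r))


def pairmate_score(matrix: CrossRunMatrix, catalog: StimulusCatalog,
                   pair_index: int) -> dict[str, float]:
    """Pairmate similarity score for one pair from a scene x scene z-matrix."""
    if matrix.phase_a != SCENE or matrix.phase_b != SCENE:
        raise ValidationError("pairmate scores are defined on scene patterns")
    s1, s2 = catalog.scenes_of_pair(pair_index)
    ia1, ia2 = matrix.stimuli_a.index(s1), matrix.stimuli_a.index(s2)
    ib1, ib2 = matrix.stimuli_b.index(s1), matrix.stimuli_b.index(s2)
    Z = matrix.values
    pair_sim = 0.5 * (Z[ia1, ib2] + Z[ia2, ib1])
    others_b = [j for j, s in enumerate(matrix.stimuli_b) if s not in (s1, s2)]
    others_a = [i for i, s in enumerate(matrix.stimuli_a) if s not in (s1, s2)]
    pool = np.concatenate([Z[[ia1, ia2]][:, others_b].ravel(),
                           Z[others_a][:, [ib1, ib2]].ravel()])
    non_pair_sim = float(pool.mean())
    return {"pairmate_sim": float(pair_sim), "non_pairmate_sim": non_pair_sim,
            "score": float(pair_sim) - non_pair_sim}


def pairmate_scores_from_z(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pairmate/non-pairmate similarity for all pairs at once.

    ``Z`` is a (2K, 2K) z-matrix whose rows/columns follow catalog order
    (pair k occupies slots 2k and 2k+1).  Returns (pairmate_sim,
    non_pairmate_sim), each length K.
    """
    n = Z.shape[0]
    K = n // 2
    e, o = np.arange(0, n, 2), np.arange(1, n, 2)
    pair_sim = 0.5 * (Z[e, o] + Z[o, e])
    row_tot = Z[e].sum(axis=1) + Z[o].sum(axis=1)
    col_tot = Z[:, e].sum(axis=0) + Z[:, o].sum(axis=0)
    block = Z[e, e] + Z[e, o] + Z[o, e] + Z[o, o]
    non_pair = (row_tot + col_tot - 2 * block) / (4 * (n - 2))
    return pair_sim, non_pair


def similarity_tensor(dataset: Dataset, regions=None,
                      round_pairs=None) -> pd.DataFrame:
    """Pairmate similarity scores for every pair and unordered round pair.

    Returns a tidy frame with columns participant, region, pair_index,
    round_i, round_j (i < j), pairmate_sim, non_pairmate_sim, score.
    """
    catalog = dataset.catalog
    regions = list(regions) if regions is not None else list(dataset.regions)
    if round_pairs is None:
        round_pairs = [(i, j) for i in SCENE_ROUNDS for j in SCENE_ROUNDS if i < j]
    K = catalog.n_pairs
    rows = {c: [] for c in ("participant", "region", "round_i", "round_j")}
    sims, nons = [], []
    for p in dataset.participants:
        for region in regions:
            S = np.stack([
                _standardized_rows(
                    dataset.pattern(p, region, SCENE, r).reindexed(
                        catalog.scene_ids),
                    catalog.scene_ids, f"({p}, {region}, scene, {r})")
                for r in SCENE_ROUNDS])
            for (i, j) in round_pairs:
                Z = fisher_z(np.clip(S[i - 1] @ S[j - 1].T, -1.0, 1.0))
                ps, nps = pairmate_scores_from_z(Z)
                sims.append(ps)
                nons.append(nps)
                rows["participant"].append(p)
                rows["region"].append(region)
                rows["round_i"].append(i)
                rows["round_j"].append(j)
    n_blocks = len(sims)
    out = pd.DataFrame({
        "participant": np.repeat(rows["participant"], K),
        "region": np.repeat(rows["region"], K),
        "pair_index": np.tile(np.arange(1, K + 1), n_blocks),
        "round_i": np.repeat(rows["round_i"], K).astype(int),
        "round_j": np.repeat(rows["round_j"], K).astype(int),
        "pairmate_sim": np.concatenate(sims) if sims else [],
        "non_pairmate_sim": np.concatenate(nons) if nons else [],
    })
    out["score"] = out["pairmate_sim"] - out["non_pairmate_sim"]
    return out


def _alignment_round_pair(alignment: str, lr: int) -> tuple[int, int] | None:
    """Unordered round pair measured by an alignment for learned round lr."""
    if alignment == "IP":
        lo, hi = lr - 1, lr
    elif alignment == "pre-IP":
        lo, hi = lr - 2, lr - 1
    elif alignment.startswith("LR-"):
        lo, hi = lr - int(alignment[3:]), lr
    elif alignment.startswith("LR+"):
        lo, hi = lr, lr + int(alignment[3:])
    else:
        raise ValueError(f"unknown alignment {alignment!r}")
    if lo < min(SCENE_ROUNDS) or hi > max(SCENE_ROUNDS):
        return None
    return lo, hi


def align_scores(tensor: pd.DataFrame, elig: pd.DataFrame,
                 lr_table: pd.DataFrame) -> pd.DataFrame:
    """Re-index similarity scores to behavioral alignments.

    Ineligible (participant, pair, alignment) cells are absent from the
    output, never zero-filled.  A missing tensor entry for an eligible cell
    is an error.
    """
    from .behavior import ALIGNMENTS

    lookup = tensor.set_index(
        ["participant", "region", "pair_index", "round_i", "round_j"])[
        "score"].to_dict()
    regions = tensor["region"].unique()
    lr_map = lr_table.set_index(["participant", "pair_index"])[
        "learned_round"].to_dict()
    elig_idx = elig.set_index(["participant", "pair_index"])
    recs = []
    for (p, k), row in elig_idx.iterrows():
        lr = lr_map[(p, k)]
        if pd.isna(lr):
            continue
        lr = int(lr)
        for alignment in ALIGNMENTS:
            if not row[alignment]:
                continue
            rp = _alignment_round_pair(alignment, lr)
            if rp is None:  # defensive; eligibility already enforces bounds
                continue
            for region in regions:
                key = (p, region, k, rp[0], rp[1])
                if key not in lookup:
                    raise ValidationError(
                        f"similarity tensor missing round pair {rp} for "
                        f"eligible pair (participant={p}, region={region}, "
                        f"pair={k})")
                recs.append((p, region, k, alignment, lookup[key]))
    return pd.DataFrame(recs, columns=["participant", "region", "pair_index",
                                       "alignment", "score"])


def lr_asymmetry(aligned: pd.DataFrame) -> pd.DataFrame:
    """Mean score of LR-vs-preceding vs LR-vs-succeeding rounds.

    Preceding pools the {LR-1, LR-2, LR-3} cells (the LR-1 pair is the IP),
    succeeding pools {LR+1, LR+2, LR+3}; cells are averaged within
    participant across pairmates.  A side with no eligible cells is NaN.
    """
    preceding = {"IP", "LR-2", "LR-3"}
    succeeding = {"LR+1", "LR+2", "LR+3"}
    rows = []
    for (p, region), g in aligned.groupby(["participant", "region"]):
        pre = g.loc[g["alignment"].isin(preceding), "score"]
        suc = g.loc[g["alignment"].isin(succeeding), "score"]
        rows.append({"participant": p, "region": region,
                     "preceding_mean": pre.mean() if len(pre) else np.nan,
                     "succeeding_mean": suc.mean() if len(suc) else np.nan})
    return pd.DataFrame(rows)


def scene_object_scores(dataset: Dataset, lr_table: pd.DataFrame,
                        regions=None, mode: str = "averaged") -> pd.DataFrame:
    """Scene-object similarity by behavioral state and object relevance.

    Object patterns are averaged voxelwise across the two object-exposure
    rounds before correlation (``mode='averaged'``, the default); with
    ``mode='per-round'`` each object round is scored separately and tagged
    in an ``object_round`` column.  For each pair with LR >= 2, scene
    patterns from LR-1 (pre-learned) and LR (learned) are correlated with
    the target object (the scene's own associate) and the competitor object
    (the pairmate's associate); both are expressed relative to the mean
    correlation with all across-pairmate objects and averaged over the two
    scenes of the pair.
    """
    if mode not in ("averaged", "per-round"):
        raise ValueError(f"unknown scene-object mode {mode!r}")
    catalog = dataset.catalog
    regions = list(regions) if regions is not None else list(dataset.regions)
    obj_ids = list(catalog.object_ids)
    obj_col = {o: i for i, o in enumerate(obj_ids)}
    lr_map = lr_table.set_index(["participant", "pair_index"])[
        "learned_round"].to_dict()
    recs = []
    for p in dataset.participants:
        pair_lrs = {k: lr_map.get((p, k)) for k in range(1, catalog.n_pairs + 1)}
        included = {k: int(lr) for k, lr in pair_lrs.items()
                    if not pd.isna(lr) and int(lr) >= 2}
        if not included:
            continue
        for region in regions:
            try:
                omats = {r: dataset.pattern(p, region, OBJECT, r).reindexed(obj_ids)
                         for r in OBJECT_ROUNDS}
            except KeyError as exc:
                raise ValidationError(
                    f"missing object round for participant {p}, region "
                    f"{region}: {exc}") from None
            if mode == "averaged":
                object_sets = {"avg": sum(omats.values()) / len(omats)}
            else:
                object_sets = {str(r): omats[r] for r in OBJECT_ROUNDS}
            needed_rounds = sorted({lr + d for lr in included.values()
                                    for d in (-1, 0)})
            scene_std = {
                r: _standardized_rows(
                    dataset.pattern(p, region, SCENE, r).reindexed(
                        catalog.scene_ids),
                    catalog.scene_ids, f"({p}, {region}, scene, {r})")
                for r in needed_rounds}
            for orange, omat in object_sets.items():
                O = _standardized_rows(omat, obj_ids,
                                       f"({p}, {region}, object, {orange})")
                zmats = {r: fisher_z(np.clip(scene_std[r] @ O.T, -1.0, 1.0))
                         for r in needed_rounds}
                for k, lr in included.items():
                    s1, s2 = catalog.scenes_of_pair(k)
                    for state, rnd in (("pre-learned", lr - 1), ("learned", lr)):
                        vals = {"target": 0.0, "competitor": 0.0}
                        for s in (s1, s2):
                            srow = zmats[rnd][catalog.scene_ids.index(s)]
                            t_col = obj_col[catalog.assoc_object[s]]
                            c_col = obj_col[catalog.competitor_object(s)]
                            base_cols = [j for j in range(len(obj_ids))
                                         if j not in (t_col, c_col)]
                            base = srow[base_cols].mean()
                            vals["target"] += 0.5 * (srow[t_col] - base)
                            vals["competitor"] += 0.5 * (srow[c_col] - base)
                        for relevance, v in vals.items():
                            rec = {"participant": p, "region": region,
                                   "pair_index": k, "state": state,
                                   "relevance": relevance,
                                   "relative_similarity": float(v)}
                            if mode == "per-round":
                                rec["object_round"] = orange
                            recs.append(rec)
    return pd.DataFrame(recs)
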