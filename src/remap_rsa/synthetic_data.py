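"""Generative model for behavior and multi-round voxel patterns.

Each scene's latent pattern is a unit-variance mixture of (i) a component
shared with its pairmate (loading sqrt(c_pre)), (ii) a scene-unique
component, and (iii) the latent of an associated object: before learning
the *competitor* object's latent enters with loading ``beta_comp_pre``;
from the learned round (LR) onward the *target* object's latent enters
with ``beta_target_post``.  All components are iid standard normal across
voxels; an observed round adds fresh iid Gaussian noise of scale ``sigma``.

Learning is a single absorbing per-pair transition with constant per-round
``hazard``; with the default degenerate response probabilities the
behaviorally derived LR equals the generative one.

Region types:

* ``remap`` — from a pair's LR onward the shared component's sign is
  flipped for both pairmates and rescaled by
  ``kappa * (1 + gamma * overlap)``, where ``overlap`` is that pair's
  realized (noiseless) pairmate similarity score just before learning.
  Cross-IP pairmate correlation is then negative (repulsion below the
  non-pairmate baseline), and stronger for initially more overlapping
  pairs.  The flipped loading decays geometrically (``kappa_decay`` per
  round) after the transition: repulsion is strongest at the inflection
  point, after which the two codes relax toward independence — the
  remapping endpoint.
* ``stable`` — no flip; structure persists apart from drift.
* ``sensory`` — no flip, larger shared loading ``c_pre_sensory``, and no
  drift: pairmates stay more similar than non-pairmates throughout.

In remap and stable regions the pairmate-shared and scene-unique
components drift across rounds as stationary AR(1) processes
(round-to-round autocorrelations ``rho_drift`` and ``rho_unique``), i.e.
representational drift: accidental per-pair overlap decays over calendar
time instead of persisting indefinitely.  Object-association components
do not drift, and the sensory-type region is fully time-invariant.  Pairs
also differ genuinely in how similar they are: each pair's shared
covariance is drawn uniformly from ``c_pre * [1 - s, 1 + s]``
(``s = c_pre_spread``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (OBJECT, OBJECT_ROUNDS, SCENE, SCENE_ROUNDS, Dataset,
                         PatternSet, StimulusCatalog)
from .pattern_similarity import fisher_z, pairmate_scores_from_z

REGION_TYPES = ("remap", "stable", "sensory")
DEFAULT_REGIONS = {"CA3DG": "remap", "CA1": "stable", "EVC": "sensory"}


class ConfigError(ValueError):
    """Invalid generative-model configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generative model (defaults = study conditions)."""

    n_participants: int = 31
    n_pairmates: int = 18
    n_voxels: int = 300
    c_pre: float = 0.15          # mean pre-learning pairmate latent covariance
    c_pre_spread: float = 0.15   # relative half-width of per-pair covariance
    c_pre_sensory: float = 0.5   # shared loading in the sensory-type region
    sigma: float = 0.55          # run-noise scale (fresh per round)
    kappa: float = 1.1           # repulsion strength (0 = no remapping)
    kappa_decay: float = 0.3     # per-round decay of the flipped component
    gamma: float = 22.0          # overlap -> repulsion coupling
    rho_drift: float = 0.6       # AR(1) persistence of the shared component
    rho_unique: float = 0.15     # AR(1) persistence of the unique component
    beta_comp_pre: float = 0.15  # competitor-object loading before learning
    beta_target_post: float = 0.15  # target-object loading from LR onward
    hazard: float = 0.25         # per-round P(not-yet-learned pair learns)
    p_highconf_learned: float = 1.0
    p_highconf_prelearned: float = 0.0
    p_recog_hit: float = 0.99
    p_recog_fa: float = 0.02
    regions: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS))
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {"hazard": self.hazard,
                 "p_highconf_learned": self.p_highconf_learned,
                 "p_highconf_prelearned": self.p_highconf_prelearned,
                 "p_recog_hit": self.p_recog_hit,
                 "p_recog_fa": self.p_recog_fa}
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name, v in (("c_pre", self.c_pre),
                        ("c_pre_sensory", self.c_pre_sensory)):
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1)")
        for name, v in (("sigma", self.sigma), ("kappa", self.kappa),
                        ("gamma", self.gamma)):
            if v < 0:
                raise ConfigError(f"{name}={v} must be >= 0")
        for name, v in (("rho_drift", self.rho_drift),
                        ("rho_unique", self.rho_unique)):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.c_pre_spread <= 1.0:
            raise ConfigError(
                f"c_pre_spread={self.c_pre_spread} outside [0, 1]")
        if not 0.0 <= self.kappa_decay <= 1.0:
            raise ConfigError(
                f"kappa_decay={self.kappa_decay} outside [0, 1]")
        beta_max = max(self.beta_comp_pre, self.beta_target_post)
        for name, c in (("c_pre", self.c_pre * (1 + self.c_pre_spread)),
                        ("c_pre_sensory", self.c_pre_sensory)):
            if c + beta_max ** 2 > 1.0:
                raise ConfigError(
                    f"loadings whose squares sum > 1 ({name}={c} + "
                    f"beta^2={beta_max ** 2:.4f})")
        bad = set(self.regions.values()) - set(REGION_TYPES)
        if bad:
            raise ConfigError(f"unknown region types {sorted(bad)}")
        if self.n_pairmates < 2 or self.n_voxels < 4 or self.n_participants < 1:
            raise ConfigError("need >=2 pairmates, >=4 voxels, >=1 participant")

    def null(self) -> "SimConfig":
        """Structureless variant: no shared covariance, no remapping, no
        object-association loadings, and no cross-round persistence (fresh
        latents every round), so every similarity score is pure noise."""
        return replace(self, c_pre=0.0, c_pre_sensory=0.0, kappa=0.0,
                       gamma=0.0, beta_comp_pre=0.0, beta_target_post=0.0,
                       rho_drift=0.0, rho_unique=0.0)


@dataclass
class SyntheticDataset:
    """Generated dataset plus its ground truth.

    ``truth`` has one row per (participant, pair): the generative learned
    round, the realized pre-learning overlap in the remap-type region, and
    the effective repulsion scale kappa_eff = kappa * (1 + gamma * overlap)
    applied there.
    """

    config: SimConfig
    dataset: Dataset
    truth: pd.DataFrame


def _participant_ids(n: int) -> list[str]:
    return [f"p{i:02d}" for i in range(1, n + 1)]


def generate_behavior(config: SimConfig, rng: np.random.Generator
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw learned rounds and per-trial test responses.

    Returns (trials, true_lr).  Each pair transitions once (absorbing) from
    pre-learned to learned with constant per-round hazard; from its LR
    onward each scene is high-confidence-correct with probability
    ``p_highconf_learned`` (otherwise correct at low confidence), before it
    with probability ``p_highconf_prelearned`` (otherwise a coin flip
    between target and competitor at low confidence).
    """
    P, K = config.n_participants, config.n_pairmates
    n_rounds = len(SCENE_ROUNDS)
    participants = _participant_ids(P)
    catalog = StimulusCatalog.default(K)

    transitions = rng.random((P, K, n_rounds)) < config.hazard
    any_learn = transitions.any(axis=2)
    lr = np.full((P, K), np.nan)
    lr[any_learn] = np.argmax(transitions[any_learn], axis=1) + 1

    pair_of_scene = np.repeat(np.arange(K), 2)        # catalog order
    lr_scene = lr[:, pair_of_scene]                   # (P, 2K)
    rounds = np.array(SCENE_ROUNDS)
    with np.errstate(invalid="ignore"):
        learned = rounds[None, None, :] >= lr_scene[:, :, None]  # (P, 2K, R)
    p_hc = np.where(learned, config.p_highconf_learned,
                    config.p_highconf_prelearned)
    hc = rng.random((P, 2 * K, n_rounds)) < p_hc
    guess_target = rng.random((P, 2 * K, n_rounds)) < 0.5
    choice_target = hc | learned | guess_target
    rt = 0.6 + rng.exponential(0.5, size=(P, 2 * K, n_rounds))

    idx_p, idx_s, idx_r = np.meshgrid(np.arange(P), np.arange(2 * K),
                                      np.arange(n_rounds), indexing="ij")
    trials = pd.DataFrame({
        "participant": np.array(participants)[idx_p.ravel()],
        "round": rounds[idx_r.ravel()],
        "scene_id": np.array(catalog.scene_ids)[idx_s.ravel()],
        "choice": np.where(choice_target.ravel(), "target", "competitor"),
        "confidence": np.where(hc.ravel(), "high", "low"),
        "rt": np.round(rt.ravel(), 3),
    })
    true_lr = pd.DataFrame({
        "participant": np.repeat(participants, K),
        "pair_index": np.tile(np.arange(1, K + 1), P),
        "true_lr": lr.ravel(),
    })
    return trials, true_lr


def generate_recognition(config: SimConfig, rng: np.random.Generator,
                         catalog: StimulusCatalog) -> pd.DataFrame:
    """Old/new judgments for exposure-phase scenes plus three novel lures
    per round (supports the d' summary)."""
    rows = {"participant": [], "round": [], "stimulus_id": [], "is_old": []}
    for p in _participant_ids(config.n_participants):
        for r in SCENE_ROUNDS:
            for sid in catalog.scene_ids:
                rows["participant"].append(p)
                rows["round"].append(r)
                rows["stimulus_id"].append(sid)
                rows["is_old"].append(True)
            for i in range(3):
                rows["participant"].append(p)
                rows["round"].append(r)
                rows["stimulus_id"].append(f"lure_r{r}_{i + 1}")
                rows["is_old"].append(False)
    recog = pd.DataFrame(rows)
    p_old = np.where(recog["is_old"], config.p_recog_hit, config.p_recog_fa)
    recog["response"] = np.where(rng.random(len(recog)) < p_old, "old", "new")
    return recog


def _overlap_scores(latents: np.ndarray) -> np.ndarray:
    """Noiseless pairmate similarity scores per pair for each consecutive
    round pair; ``latents`` is (n_rounds, 2K, V).  Returns (n_rounds-1, K)."""
    n_rounds = latents.shape[0]
    X = latents - latents.mean(axis=2, keepdims=True)
    X /= np.linalg.norm(X, axis=2, keepdims=True)
    out = []
    for r in range(n_rounds - 1):
        Z = fisher_z(np.clip(X[r] @ X[r + 1].T, -1.0, 1.0))
        ps, nps = pairmate_scores_from_z(Z)
        out.append(ps - nps)
    return np.stack(out)


def generate_patterns(config: SimConfig, true_lr: pd.DataFrame,
                      rng: np.random.Generator
                      ) -> tuple[dict, pd.DataFrame]:
    """Generate pattern sets for every region/phase/round.

    Returns (patterns dict keyed like Dataset.patterns, truth table).
    """
    K, V = config.n_pairmates, config.n_voxels
    n_rounds = len(SCENE_ROUNDS)
    catalog = StimulusCatalog.default(K)
    participants = _participant_ids(config.n_participants)
    lr_map = true_lr.set_index(["participant", "pair_index"])["true_lr"]
    pair_of_scene = np.repeat(np.arange(K), 2)
    # column index of each scene's target / competitor object (catalog order
    # puts object k-a/k-b in slots 2k/2k+1, matching the scenes)
    targ = np.arange(2 * K)
    comp = targ ^ 1
    patterns: dict = {}
    truth_rows = []
    for p in participants:
        lr_vec = np.array([lr_map[(p, k)] for k in range(1, K + 1)])
        truth_ov = np.full(K, np.nan)
        truth_keff = np.full(K, np.nan)
        for region, rtype in config.regions.items():
            c_mean = (config.c_pre_sensory if rtype == "sensory"
                      else config.c_pre)
            b_pre, b_post = config.beta_comp_pre, config.beta_target_post
            # per-pair shared covariance: pairs genuinely differ in how
            # similar they are (uniform on c_mean * [1-s, 1+s])
            c_k = c_mean * (1.0 + config.c_pre_spread
                            * (2.0 * rng.random(K) - 1.0))
            u_k = 1.0 - c_k - b_pre ** 2            # per-pair unique variance
            # shared and unique components drift across rounds (AR(1));
            # the sensory-type region is time-invariant
            sensory = rtype == "sensory"

            def ar1_walk(n_items: int, a: float) -> np.ndarray:
                x = np.empty((n_rounds, n_items, V))
                x[0] = rng.standard_normal((n_items, V))
                for r in range(1, n_rounds):
                    fresh = rng.standard_normal((n_items, V))
                    x[r] = a * x[r - 1] + np.sqrt(1.0 - a ** 2) * fresh
                return x

            shared = ar1_walk(K, 1.0 if sensory else config.rho_drift)
            U = ar1_walk(2 * K, 1.0 if sensory else config.rho_unique)
            O = rng.standard_normal((2 * K, V))
            sc = np.sqrt(c_k)[pair_of_scene, None]
            su = np.sqrt(u_k)[pair_of_scene, None]
            lam_pre = (sc * shared[:, pair_of_scene, :]
                       + su * U
                       + b_pre * O[None, comp, :])
            lam = lam_pre
            if rtype == "remap":
                ov_cons = _overlap_scores(lam_pre)       # (n_rounds-1, K)
                with np.errstate(invalid="ignore"):
                    ov_round = np.where(np.isnan(lr_vec) | (lr_vec < 3),
                                        1, lr_vec - 2).astype(int)
                ov = ov_cons[ov_round - 1, np.arange(K)]
                kappa_eff = config.kappa * np.maximum(
                    0.0, 1.0 + config.gamma * ov)
                truth_ov, truth_keff = ov, kappa_eff
                # flipped shared loading, strongest at the transition round
                # and decaying geometrically afterwards (repulsion relaxes
                # into near-independent codes); unique loading unchanged
                # across the flip (scene identity persists); renormalized
                # to unit voxel variance
                lr_scene = lr_vec[pair_of_scene]
                with np.errstate(invalid="ignore"):
                    since_lr = (np.array(SCENE_ROUNDS, dtype=float)[:, None]
                                - lr_scene[None, :])
                    is_post = since_lr >= 0
                flip = np.where(is_post, -kappa_eff[pair_of_scene][None, :]
                                * config.kappa_decay
                                ** np.where(is_post, since_lr, 0.0), 0.0)
                u_scene = u_k[pair_of_scene]
                norm = np.sqrt(flip ** 2 * c_k[pair_of_scene][None, :]
                               + u_scene[None, :] + b_post ** 2)
                lam_post = ((flip[:, :, None] * sc[None, :, :]
                             * shared[:, pair_of_scene, :]
                             + su[None, :, :] * U
                             + b_post * O[None, targ, :])
                            / norm[:, :, None])
                lam = np.where(is_post[:, :, None], lam_post, lam_pre)
            for r in SCENE_ROUNDS:
                obs = lam[r - 1] + config.sigma * rng.standard_normal((2 * K, V))
                patterns[(p, region, SCENE, r)] = PatternSet(
                    p, region, SCENE, r, catalog.scene_ids, obs)
            for r in OBJECT_ROUNDS:
                obs = O + config.sigma * rng.standard_normal((2 * K, V))
                patterns[(p, region, OBJECT, r)] = PatternSet(
                    p, region, OBJECT, r, catalog.object_ids, obs)
        for k in range(1, K + 1):
            truth_rows.append({"participant": p, "pair_index": k,
                               "true_lr": lr_vec[k - 1],
                               "overlap_realized": truth_ov[k - 1],
                               "kappa_eff": truth_keff[k - 1]})
    return patterns, pd.DataFrame(truth_rows)


def generate_dataset(config: SimConfig, with_recognition: bool = True
                     ) -> SyntheticDataset:
    """Compose behavior and pattern generation; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    catalog = StimulusCatalog.default(config.n_pairmates)
    trials, true_lr = generate_behavior(config, rng)
    patterns, truth = generate_patterns(config, true_lr, rng)
    recognition = (generate_recognition(config, rng, catalog)
                   if with_recognition else None)
    dataset = Dataset(catalog, patterns, trials, recognition)
    return SyntheticDataset(config, dataset, truth)
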