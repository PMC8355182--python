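"""Core domain types, validation, and file I/O.

The unit of analysis is a *pattern set*: one stimulus x voxel matrix of
response estimates (t-statistic-like, one per-scan GLM estimate per
stimulus) for a single participant, region, exposure phase, and learning
round.  Scenes come in 18 highly similar *pairmates* (36 scenes total),
each scene associated with one of 36 objects such that pairmate scenes map
to pairmate objects.

On disk a dataset is a JSON manifest indexing one TSV matrix per pattern
set plus tidy CSV behavior tables.  All values are written at full float
precision so that write -> load is an exact identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SCENE = "scene"
OBJECT = "object"
PHASES = (SCENE, OBJECT)
SCENE_ROUNDS = (1, 2, 3, 4, 5, 6)
OBJECT_ROUNDS = (1, 6)

CHOICES = ("target", "competitor", "none")
CONFIDENCES = ("high", "low", "none")

TRIAL_COLUMNS = ("participant", "round", "scene_id", "choice", "confidence", "rt")
RECOGNITION_COLUMNS = ("participant", "round", "stimulus_id", "is_old", "response")


class ValidationError(ValueError):
    """A dataset invariant was violated; the message names the offending item."""


@dataclass(frozen=True)
class StimulusCatalog:
    """Pairmate structure over scenes/objects and scene->object associations.

    ``pairmate_of`` is a symmetric involution without fixed points over the
    36 scenes (18 disjoint pairs); ``assoc_object`` is a bijection from
    scenes to objects that maps pairmate scenes onto pairmate objects;
    ``pair_index`` labels each scene with its pair number (1..18).
    """

    scene_ids: tuple[str, ...]
    object_ids: tuple[str, ...]
    pairmate_of: Mapping[str, str]
    assoc_object: Mapping[str, str]
    pair_index: Mapping[str, int]

    def __post_init__(self) -> None:
        scenes, objects = set(self.scene_ids), set(self.object_ids)
        if len(self.scene_ids) != len(scenes):
            raise ValidationError("duplicate scene ids")
        if len(self.object_ids) != len(objects):
            raise ValidationError("duplicate object ids")
        if len(self.scene_ids) % 2 or not self.scene_ids:
            raise ValidationError("number of scenes must be even and positive")
        if len(self.object_ids) != len(self.scene_ids):
            raise ValidationError("need one object per scene")
        if set(self.pairmate_of) != scenes:
            raise ValidationError("pairmate_of must be defined exactly on the scenes")
        for s, m in self.pairmate_of.items():
            if m not in scenes:
                raise ValidationError(f"pairmate of {s!r} is not a catalog scene")
            if m == s:
                raise ValidationError(f"scene {s!r} is its own pairmate")
            if self.pairmate_of[m] != s:
                raise ValidationError(f"pairmate_of is not symmetric at {s!r}")
        if set(self.assoc_object) != scenes:
            raise ValidationError("assoc_object must be defined exactly on the scenes")
        if set(self.assoc_object.values()) != objects:
            raise ValidationError("assoc_object must be a bijection onto the objects")
        if set(self.pair_index) != scenes:
            raise ValidationError("pair_index must be defined exactly on the scenes")
        n_pairs = len(self.scene_ids) // 2
        if sorted(set(self.pair_index.values())) != list(range(1, n_pairs + 1)):
            raise ValidationError(f"pair_index values must cover 1..{n_pairs}")
        for s, m in self.pairmate_of.items():
            if self.pair_index[s] != self.pair_index[m]:
                raise ValidationError(f"pairmates {s!r}/{m!r} disagree on pair_index")

    @property
    def n_pairs(self) -> int:
        return len(self.scene_ids) // 2

    def scenes_of_pair(self, pair_index: int) -> tuple[str, str]:
        scenes = sorted(s for s, k in self.pair_index.items() if k == pair_index)
        if len(scenes) != 2:
            raise ValidationError(f"pair {pair_index} not in catalog")
        return scenes[0], scenes[1]

    def competitor_object(self, scene: str) -> str:
        """Object associated with this scene's pairmate."""
        return self.assoc_object[self.pairmate_of[scene]]

    def stimuli(self, phase: str) -> tuple[str, ...]:
        if phase == SCENE:
            return self.scene_ids
        if phase == OBJECT:
            return self.object_ids
        raise ValidationError(f"unknown phase {phase!r}")

    @classmethod
    def default(cls, n_pairs: int = 18) -> "StimulusCatalog":
        """Canonical catalog: pair k holds scenes ``scene<k>a/b`` associated
        with objects ``object<k>a/b``."""
        scene_ids, object_ids = [], []
        pairmate_of, assoc_object, pair_index = {}, {}, {}
        for k in range(1, n_pairs + 1):
            sa, sb = f"scene{k:02d}a", f"scene{k:02d}b"
            oa, ob = f"object{k:02d}a", f"object{k:02d}b"
            scene_ids += [sa, sb]
            object_ids += [oa, ob]
            pairmate_of[sa], pairmate_of[sb] = sb, sa
            assoc_object[sa], assoc_object[sb] = oa, ob
            pair_index[sa] = pair_index[sb] = k
        return cls(tuple(scene_ids), tuple(object_ids), pairmate_of,
                   assoc_object, pair_index)

    def to_dict(self) -> dict:
        return {
            "scene_ids": list(self.scene_ids),
            "object_ids": list(self.object_ids),
            "pairmate_of": dict(self.pairmate_of),
            "assoc_object": dict(self.assoc_object),
            "pair_index": dict(self.pair_index),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusCatalog":
        return cls(tuple(d["scene_ids"]), tuple(d["object_ids"]),
                   dict(d["pairmate_of"]), dict(d["assoc_object"]),
                   {k: int(v) for k, v in d["pair_index"].items()})


@dataclass(frozen=True)
class PatternSet:
    """One stimulus x voxel response-estimate matrix.

    Rows are keyed by stimulus id via ``stimulus_ids`` (canonical catalog
    order in files, but consumers key by id, never position).  Values are
    unitless t-statistic-like response estimates from a single scan.
    """

    participant: str
    region: str
    phase: str
    round: int
    stimulus_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        rounds = SCENE_ROUNDS if self.phase == SCENE else OBJECT_ROUNDS
        if self.round not in rounds:
            raise ValidationError(
                f"round {self.round} invalid for phase {self.phase!r}")
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != len(self.stimulus_ids):
            raise ValidationError(
                f"values must be (n_stimuli, n_voxels); got {v.shape}")
        if v.shape[1] < 4:
            raise ValidationError("pattern sets need at least 4 voxels")
        if len(set(self.stimulus_ids)) != len(self.stimulus_ids):
            raise ValidationError("duplicate stimulus ids in pattern set")
        bad = ~np.isfinite(v).all(axis=1)
        if bad.any():
            which = [self.stimulus_ids[i] for i in np.flatnonzero(bad)]
            raise ValidationError(
                f"non-finite values in pattern set "
                f"({self.participant}, {self.region}, {self.phase}, "
                f"{self.round}) for stimuli {which}")

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.participant, self.region, self.phase, self.round)

    def row(self, stimulus_id: str) -> np.ndarray:
        try:
            i = self.stimulus_ids.index(stimulus_id)
        except ValueError:
            raise ValidationError(
                f"stimulus {stimulus_id!r} not in pattern set {self.key}") from None
        return self.values[i]

    def reindexed(self, stimulus_ids: Iterable[str]) -> np.ndarray:
        """Rows in the requested id order (keying by id, not position)."""
        ids = list(stimulus_ids)
        index = {s: i for i, s in enumerate(self.stimulus_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise ValidationError(
                f"pattern set {self.key} is missing stimuli {missing}")
        return self.values[[index[s] for s in ids]]


def validate_trials(trials: pd.DataFrame, catalog: StimulusCatalog,
                    participants: Iterable[str] | None = None) -> None:
    """Check the per-trial test-phase table against its invariants."""
    missing_cols = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing_cols:
        raise ValidationError(f"trials table missing columns {sorted(missing_cols)}")
    bad_choice = set(trials["choice"]) - set(CHOICES)
    if bad_choice:
        raise ValidationError(f"invalid choice values {sorted(bad_choice)}")
    bad_conf = set(trials["confidence"]) - set(CONFIDENCES)
    if bad_conf:
        raise ValidationError(f"invalid confidence values {sorted(bad_conf)}")
    # confidence is 'none' exactly when no response was made
    mism = trials[(trials["choice"] == "none") != (trials["confidence"] == "none")]
    if len(mism):
        r = mism.iloc[0]
        raise ValidationError(
            "confidence must be 'none' iff choice is 'none' "
            f"(participant {r['participant']}, round {r['round']}, "
            f"scene {r['scene_id']})")
    bad_scene = set(trials["scene_id"]) - set(catalog.scene_ids)
    if bad_scene:
        raise ValidationError(f"unknown scenes in trials: {sorted(bad_scene)}")
    if trials.duplicated(["participant", "round", "scene_id"]).any():
        raise ValidationError("duplicate (participant, round, scene) trials")
    if participants is None:
        participants = sorted(trials["participant"].unique())
    expected = len(catalog.scene_ids) * len(SCENE_ROUNDS)
    counts = trials.groupby("participant").size()
    for p in participants:
        if counts.get(p, 0) != expected:
            raise ValidationError(
                f"participant {p} has {counts.get(p, 0)} trials, expected {expected}")


def validate_recognition(recog: pd.DataFrame, catalog: StimulusCatalog) -> None:
    missing_cols = set(RECOGNITION_COLUMNS) - set(recog.columns)
    if missing_cols:
        raise ValidationError(
            f"recognition table missing columns {sorted(missing_cols)}")
    known = set(catalog.scene_ids) | set(catalog.object_ids)
    lures = recog[~recog["stimulus_id"].isin(known)]
    if lures["is_old"].any():
        bad = lures.loc[lures["is_old"], "stimulus_id"].iloc[0]
        raise ValidationError(f"lure stimulus {bad!r} marked is_old=True")


@dataclass
class Dataset:
    """A validated in-memory dataset: catalog + pattern sets + behavior."""

    catalog: StimulusCatalog
    patterns: dict[tuple[str, str, str, int], PatternSet]
    trials: pd.DataFrame
    recognition: pd.DataFrame | None = None
    regions: tuple[str, ...] = field(init=False)
    participants: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        keys = set(self.patterns)
        for key, ps in self.patterns.items():
            if key != ps.key:
                raise ValidationError(f"pattern set stored under wrong key {key}")
            want = set(self.catalog.stimuli(ps.phase))
            have = set(ps.stimulus_ids)
            if have != want:
                raise ValidationError(
                    f"pattern set {key} stimuli do not match catalog "
                    f"(missing {sorted(want - have)}, extra {sorted(have - want)})")
        self.participants = tuple(sorted({k[0] for k in keys}))
        self.regions = tuple(sorted({k[1] for k in keys}))
        for p in self.participants:
            for r in self.regions:
                for phase, rounds in ((SCENE, SCENE_ROUNDS), (OBJECT, OBJECT_ROUNDS)):
                    for rnd in rounds:
                        if (p, r, phase, rnd) not in keys:
                            raise ValidationError(
                                f"missing pattern set (participant={p}, "
                                f"region={r}, phase={phase}, round={rnd})")
        validate_trials(self.trials, self.catalog, self.participants)
        if self.recognition is not None:
            validate_recognition(self.recognition, self.catalog)

    def pattern(self, participant: str, region: str, phase: str,
                round: int) -> PatternSet:
        return self.patterns[(participant, region, phase, round)]


def _pattern_filename(key: tuple[str, str, str, int]) -> str:
    p, region, phase, rnd = key
    return f"patterns/{p}_{region}_{phase}_r{rnd}.tsv"


def write_pattern_tsv(ps: PatternSet, path: Path) -> None:
    header = "stimulus_id\t" + "\t".join(
        f"v{i}" for i in range(ps.values.shape[1]))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for sid, row in zip(ps.stimulus_ids, ps.values):
            fh.write(sid + "\t" + "\t".join(f"{x:.17g}" for x in row) + "\n")


def read_pattern_tsv(path: Path, key: tuple[str, str, str, int]) -> PatternSet:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "stimulus_id":
            raise ValidationError(f"{path}: first column must be stimulus_id")
        ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    p, region, phase, rnd = key
    return PatternSet(p, region, phase, rnd, tuple(ids), np.array(rows))


def write_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write a dataset to ``out_dir``; returns the manifest path.

    Layout is deterministic: ``catalog.json``, ``trials.csv``, optional
    ``recognition.csv``, one TSV per pattern set under ``patterns/``, and a
    ``manifest.json`` indexing everything.
    """
    if not dataset.patterns:
        raise ValidationError("refusing to write an empty dataset")
    out = Path(out_dir)
    (out / "patterns").mkdir(parents=True, exist_ok=True)
    with open(out / "catalog.json", "w") as fh:
        json.dump(dataset.catalog.to_dict(), fh, indent=1, sort_keys=True)
    trials = dataset.trials.sort_values(
        ["participant", "round", "scene_id"], kind="stable")
    trials.to_csv(out / "trials.csv", index=False, float_format="%.17g")
    entries = []
    for key in sorted(dataset.patterns):
        rel = _pattern_filename(key)
        write_pattern_tsv(dataset.patterns[key], out / rel)
        p, region, phase, rnd = key
        entries.append({"participant": p, "region": region, "phase": phase,
                        "round": rnd, "path": rel})
    manifest = {"catalog": "catalog.json", "trials": "trials.csv",
                "patterns": entries}
    if dataset.recognition is not None:
        dataset.recognition.sort_values(
            ["participant", "round", "stimulus_id"], kind="stable").to_csv(
            out / "recognition.csv", index=False)
        manifest["recognition"] = "recognition.csv"
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest_path


def load_dataset(manifest_path: str | Path) -> Dataset:
    """Load and fully validate a dataset from its JSON manifest."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    catalog = StimulusCatalog.from_dict(
        json.loads((root / manifest["catalog"]).read_text()))
    trials = pd.read_csv(root / manifest["trials"],
                         dtype={"participant": str, "scene_id": str})
    patterns = {}
    for e in manifest["patterns"]:
        key = (str(e["participant"]), e["region"], e["phase"], int(e["round"]))
        path = root / e["path"]
        if not path.exists():
            raise ValidationError(f"manifest references missing file {e['path']}")
        patterns[key] = read_pattern_tsv(path, key)
    recognition = None
    if "recognition" in manifest:
        recognition = pd.read_csv(root / manifest["recognition"],
                                  dtype={"participant": str, "stimulus_id": str})
    return Dataset(catalog, patterns, trials, recognition)
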