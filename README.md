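# remap-rsa

Learning-aligned representational similarity analysis (RSA) of
hippocampal *remapping*: abrupt decorrelation of the activity patterns
representing highly similar memories, time-locked to the moment the
memories stop interfering.

The package is written for cognitive-neuroimaging researchers studying
memory interference with multivoxel pattern analysis.  It implements the
full analysis chain for a 6-round paired-associate paradigm in which 36
scenes form 18 highly similar *pairmates* (e.g., two lighthouses), each
scene is associated with one of 36 objects (pairmate scenes map to
pairmate objects), and per-round, per-stimulus voxel patterns (t-maps
from per-scan GLMs) are available for several regions of interest.  A
synthetic-data generator with the same statistical structure lets the
whole pipeline run, and be validated, without any scanner data.

## The core quantities

**Pairmate similarity score.** Pattern similarity is the Fisher
z-transformed Pearson correlation between t-maps, always computed across
different scans.  For pairmates A1/A2 at round pair {i, j}:

    pairmate_sim  = mean[ z(r(A1_i, A2_j)), z(r(A2_i, A1_j)) ]
    score         = pairmate_sim − mean of all cross-item z's between
                    either pairmate and the 34 non-pairmate scenes
                    (both items x both directions, 136 entries)

A *negative* score means two highly similar scenes are represented as
*less* similar than unrelated scenes — the signature of repulsion
between competing memory representations.

**Learned round (LR) and inflection point (IP).** From the associative
test behavior, the LR of a pair is the first round from which both
scenes' objects are retrieved with sustained high-confidence accuracy.
The IP is the LR−1 → LR transition, measured by the score at round pair
{LR−1, LR}; the pre-IP reference is the non-transition {LR−2, LR−1}.
Pairs with LR = 1 or never learned are excluded; LR = 2 contributes an
IP but no pre-IP.

**Permutation test.** The group-mean IP score is compared against a null
built by shuffling, within each participant, the assignment of IP round
pairs across that participant's eligible pairmates (1000 iterations,
one-tailed p = fraction of permuted means at or below the observed).

**Structure correlations.** The six rounds define five timepoints (round
pairs {1,2} … {5,6}).  Per participant, the per-pairmate score vectors at
timepoints N and N+lag are rank-correlated (Spearman, Fisher-z); lag 1
averages timepoint pairs (1,2), (2,3), (3,4) and lag 2 averages (1,3),
(2,4), (3,5).  A negative lag-1 correlation means the representational
structure *inverts* from one timepoint to the next — high-overlap pairs
become low-overlap — which is what overlap-triggered repulsion predicts
and what regression to the mean cannot produce.

## Worked example

```python
from remap_rsa import RunConfig, run_pipeline

config = RunConfig(seed=7)      # 31 participants, 18 pairs, 300 voxels
report = run_pipeline(config, "out")
t = report["tests"]
for name in ("CA3DG_IP_score_vs_0", "CA3DG_pre-IP_score_vs_0",
             "CA3DG_structure_lag1_vs_0", "EVC_IP_score_vs_0"):
    r = t[name]
    print(f"{name}: {r['estimate']:+.4f} (t = {r['statistic']:.2f}, "
          f"p = {r['p']:.2g})")
print("CA3DG permutation p =", t["CA3DG_IP_permutation"]["p"])
```

prints (exactly reproducible with the same seed):

```
CA3DG_IP_score_vs_0: -0.1296 (t = -49.86, p = 2e-30)
CA3DG_pre-IP_score_vs_0: +0.0719 (t = 27.20, p = 1.1e-22)
CA3DG_structure_lag1_vs_0: -0.2200 (p = 6.2e-10)
EVC_IP_score_vs_0: +0.4144 (p = 2.2e-42)
CA3DG permutation p = 0.0
```

Reading: in the simulated remapping region (CA3/dentate gyrus analogue)
pairmate similarity is small-positive just before learning (+0.07) and
drops *below zero* exactly at the inflection point (−0.13) — pairmates
end up less similar than unrelated scenes, and the permutation test
confirms the effect is locked to each pair's own IP.  The negative lag-1
structure correlation (−0.22) shows that the most-overlapping pairs at
one timepoint are the least-overlapping at the next.  Early visual
cortex shows the opposite, purely visual structure (+0.41): the
hippocampal inversion is not inherited from sensory input.

The same run writes tidy CSVs (`similarity_tensor.csv`,
`aligned_scores.csv`, `structure_correlations.csv`,
`quartile_means.csv`, `scene_object_scores.csv`, …), a
`stats_report.json` with every test, and a log of seeds and eligible
pairmate counts.

The pipeline can also be driven from the shell:

```bash
remap-rsa all --config config.yaml --out out/
remap-rsa simulate --seed 3 --out sim/      # dataset + truth.csv only
```

Datasets are plain text on disk (one TSV matrix per participant x region
x phase x round, tidy CSV behavior tables, a JSON manifest), so real
t-map exports can be analyzed by writing them in the same layout and
running `remap-rsa analyze`.

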