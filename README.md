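# cav — dictionary-of-motions activity classification

`cav` classifies complex human activities from body-pose time series (nine
body-segment orientations as unit quaternions per frame). It is built for
activities with wide within-class variation: instead of matching whole
recordings, it learns a *dictionary of motions* — short, recurring movement
fragments — and recognizes activities from which motions occur and how they
follow one another.

## Method overview

**Training.** Each labeled recording is tiled with windows of 0.5, 1, 1.5 and
2 s at start offsets of 0%, 25% and 50% of the window size; every window is
sub-sampled to a common base length and flattened. Windows are clustered per
activity with k-means (Euclidean distance), clusters with five or fewer
members are dropped, and overlapping retained windows are resolved
largest-size-first. A second k-means over all cluster centers merges similar
motions from different activities into a single motion ID, with provenance
kept throughout. Each training example is then encoded as a motion-ID
sequence and represented by (a) a log-normalized tf-idf weighted motion
histogram, with a stop list covering the top 5% most frequent motions, and
(b) a Laplace-smoothed first-order transition matrix plus initial-motion
probabilities.

**Inference.** An observation (one pre-segmented activity) is scanned
greedily, longest window first; windows within a radius threshold of a
dictionary centroid emit that motion ID. The observation is scored against
every training example with `cost = histDiff / seqProb` — histogram Euclidean
distance divided by the sequence probability under that example's Markov
model — costs are averaged per activity, and the lowest-cost activity wins.

The package also provides the two dataset-profiling metrics (per-activity
**Complexity**, a circular-shift autocorrelation distance, and per-set
**Variation**, the mean pairwise distance between length-normalized
examples), the evaluation protocols (leave-one-out, narrowed-variation split,
repeated subject holdout), and a deterministic synthetic generator that
plants motion primitives with controllable variation so the whole pipeline is
testable without motion-capture data.

## Command line

```sh
# generate a synthetic dataset (pose CSVs + manifest.json + ground_truth.json)
cav simulate --n-activities 8 --n-subjects 15 --variation 0.5 --seed 1 --out data/

# per-activity Complexity / Variation table
cav metrics --dataset data/manifest.json

# train and serialize a model
cav train --dataset data/ --config config.yaml --out model.json

# classify recordings
cav infer --model model.json --dataset data/ --out predictions.csv

# evaluation protocols (report embeds the full config for provenance)
cav eval loocv    --dataset data/ --seed 1 --out report.json
cav eval narrowed --dataset data/ --seed 1 --out report.json
cav eval holdout  --dataset data/ --seed 1 --repeats 20 --out report.json
```

The config YAML accepts any `RunConfig` field (window sizes, increments,
cluster-count rules, pruning threshold, matching threshold `tau`, smoothing
`alpha`, stop-list fraction, seed, ...); all values have sensible defaults.

## Data format

One CSV per recording with header `frame,seg1_w,seg1_x,...,seg9_z` (nine
segments x quaternion w,x,y,z per row) plus a `manifest.json` listing
`{id, file, subject, label, frame_rate}` per recording and the segment label
list. Quaternions are canonicalized on load: unit norm, `w >= 0`.

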