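"""Generate the default synthetic study collection and build the combined matrix.

Three studies of 10 / 22 / 39 samples on two platforms (negative-binomial
counts and log-scale intensities) share a planted labor signature of 100
up- and 30 down-regulated genes. Count studies are log2(x+1)-transformed,
every study is restricted to the shared genes and z-scored over genes then
samples, and the columns are concatenated into the matrix the SVD and
classification stages consume.
"""

from laborsig import preprocess, simulate

config = simulate.SimConfig(seed=1)
studies, truth = simulate.generate_study_collection(config)
for study in studies:
    groups = study.labels().value_counts().to_dict()
    print(f"{study.study_id}: {study.platform:9s} {study.values.shape[0]} genes, {groups}")

processed = [preprocess.log_transform(preprocess.filter_genes(s)) for s in studies]
combined = preprocess.merge_studies(processed)
print(f"combined matrix: {combined.values.shape[0]} genes x {combined.values.shape[1]} samples")
print(f"planted signature: {len(truth.up_genes)} up, {len(truth.down_genes)} down")
print(f"mislabeled (ambiguous) samples: {sorted(truth.ambiguous_sample_ids)}")
# the combined matrix is fully normalized: every sample column is mean 0, sd 1,
# so downstream pattern extraction compares studies on one scale
col_sd = combined.values.std(ddof=1).round(6)
print(f"column sd after normalization: min={col_sd.min()}, max={col_sd.max()}")
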