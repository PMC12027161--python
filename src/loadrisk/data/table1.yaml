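# Seven-model experiment matrix: sampling strategies and distance
# metrics on the per-SNP feature set (models 1-5), then the combined
# genetic + phenotypic feature set at the default and the
# sensitivity-tuned decision threshold (models 6-7).
models:
  - model_id: model1
    feature_set: snps_only
    sampling: none
    metric: euclidean
    threshold: 0.50
    observations: per-SNP dosages
  - model_id: model2
    feature_set: snps_only
    sampling: oversample
    metric: euclidean
    threshold: 0.50
    observations: per-SNP dosages
  - model_id: model3
    feature_set: snps_only
    sampling: subsample
    metric: euclidean
    threshold: 0.50
    observations: per-SNP dosages
  - model_id: model4
    feature_set: snps_only
    sampling: subsample
    metric: manhattan
    threshold: 0.50
    observations: per-SNP dosages
  - model_id: model5
    feature_set: snps_only
    sampling: subsample
    metric: cosine
    threshold: 0.50
    observations: per-SNP dosages
  - model_id: model6
    feature_set: combined
    sampling: subsample
    metric: euclidean
    threshold: 0.50
    observations: z-score, APOE and phenotypes
  - model_id: model7
    feature_set: combined
    sampling: subsample
    metric: euclidean
    threshold: 0.42
    observations: z-score, APOE and phenotypes
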