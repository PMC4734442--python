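"""Preprocess a small synthetic corpus and merge it into one fold-change matrix.

Builds three microarray-like studies (replicate-level log2 intensities,
probe annotation, matched controls), runs the per-study chain (median
collapse of replicates and probes, control centring) and merges the
studies on their shared gene symbols.
"""

from bimaxgsea import CorpusSpec, PlantedBlock, generate_corpus, merge_studies, preprocess_study

spec = CorpusSpec(
    n_studies=3,
    total_conditions=12,
    universe_size=500,
    planted_blocks=[PlantedBlock(n_genes=15, n_conditions=5, effect=1.5)],
    compression_range=(0.8, 1.0),
    seed=1,
)
studies, registry = generate_corpus(spec)
print(f"{len(studies)} studies; first study: "
      f"{studies[0].n_probes} probes x {studies[0].n_samples} samples")

fold_changes = {s.study_id: preprocess_study(s) for s in studies}
merged = merge_studies(fold_changes)
print(f"merged matrix: {merged.shape[0]} gene symbols x {merged.shape[1]} conditions")
print(merged.iloc[:3, :4].round(3))
# Each cell is the log2 fold change of a gene in one study:condition
# versus that condition's matched control; the row set is the
# intersection of the three studies' gene symbols.
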