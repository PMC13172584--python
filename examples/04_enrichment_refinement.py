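"""Refine a candidate list by annotation enrichment.

Each candidate set is tested per annotation term (hypergeometric against the
full-network background, BH-corrected within category); terms passing all
four retention thresholds define the refinement: a candidate survives only
if every active category covers it. Surviving candidates are the ones whose
annotations consistently point at the enriched biology.
"""

from punet import enrich, losses, synth, train

inst = synth.generate_instance(synth.SynthConfig(seed=42))
res = train.run_cv(inst.network, inst.features, inst.labels,
                   loss_cfg=losses.PULossConfig(loss_name="nnpu"),
                   train_cfg=train.TrainConfig(seed=42))
candidates = set(res.consensus.top(100))

background = set(inst.network.node_ids)
table = enrich.enrich_all(candidates, inst.annotations, background)
retained = table[table["retained"]]
print(f"{len(retained)} retained terms across "
      f"{retained['category'].nunique()} categories")
print(retained[["category", "term", "fg_count", "bg_count",
                "fold_enrichment", "fdr"]].to_string(index=False))

refined, coverage = enrich.refine_candidates(candidates, table,
                                             inst.annotations)
module = {inst.network.node_ids[i] for i in inst.true_positives}
print(f"\nrefined candidates: {len(refined)} of {len(candidates)}; "
      f"{len(refined & module)} are true module members")
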