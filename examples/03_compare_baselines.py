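"""Compare a PU-trained graph model against the three non-PU baselines.

Recall@K against the hidden module members shows what each signal source
contributes: RWR sees only the graph, the MLP only the features, the
graph-only model only topology descriptors; the PU graph model sees both.
"""

from punet import baselines, losses, synth, train

inst = synth.generate_instance(synth.SynthConfig(seed=42))
held = {inst.network.node_ids[i] for i in inst.held_out_positives}
tc = train.TrainConfig(seed=42)
K = 120

pu = train.run_cv(inst.network, inst.features, inst.labels,
                  loss_cfg=losses.PULossConfig(loss_name="nnpu"), train_cfg=tc)
rwr = baselines.rwr_ranking(inst.network, inst.labels)
mlp = baselines.feature_only_scores(inst.features, inst.labels, inst.network,
                                    train_cfg=tc)
topo = baselines.graph_only_scores(inst.network, inst.labels, train_cfg=tc)

for name, ranking in [("nnPU graph model", pu.consensus), ("RWR", rwr),
                      ("feature-only MLP", mlp.consensus),
                      ("graph-only GCN", topo.consensus)]:
    print(f"Recall@{K} {name:18s} {train.recall_at_k(ranking, held, K):.2f}")
print(f"random expectation: {K / len(inst.labels.unlabeled):.3f}")
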