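# actnet

Detection of drug-response networks from dynamic multi-omics time courses,
with downstream physiological and clinical evaluation — exercised end to end
on synthetic data with planted ground truth.

## The problem

When cells are exposed to a drug over days to weeks, the response is not a
single pathway switching on but a coordinated drift of many proteins and
transcripts. Given longitudinal expression measurements (treated vs
time-matched control, several drugs, several doses, two omics layers), the
question is: **which connected part of the protein interaction network
carries the common response?** This package implements that inference chain
for the anthracycline-cardiotoxicity setting (four drugs, 7 time points over
14 days, 3 replicates), plus the downstream analyses used to interpret the
resulting network.

## The method

1. **Longitudinal regression** (`actnet.longitudinal`). Each feature is fit
   with the two-condition quadratic model in raw hours

   y = (β₀,C + β₀,TvsC·D) + (β₁,C + β₁,TvsC·D)·t + (β₂,C + β₂,TvsC·D)·t² + ε,

   D = 1 for treated samples. A feature is *dynamic* when the BH q-value of
   the joint F-test of the three TvsC terms is ≤ 0.05, R² ≥ 0.7 and at least
   10 observations were used. Proteome matrices are first normalized by
   median-of-medians shifting onto the control arm.

2. **Node scoring and network propagation** (`actnet.propagation`). Dynamic
   features get the score Sᵢ = −Σⱼ log₁₀ p(j,TvsC) (j ∈ {0,1,2}; zero
   otherwise); proteome and transcriptome scores are summed. Scores diffuse
   over the interactome with a random walk with restart (insulated heat
   diffusion): F = β(I − (1−β)W)⁻¹ with column-stochastic W and restart
   probability β = 0.4, and E = F·diag(S) is the exchanged-heat matrix.
   Thresholding E's off-diagonal at δ and keeping strongly connected
   components (≥ 3 nodes) yields a per-drug subnetwork; of four candidate δ
   the minimal is used. Nodes and interactions present in ≥ 2 of the
   per-drug subnetworks form the **consensus response network**.

3. **Downstream evaluation**: set overlap and hypergeometric
   over-representation with an explicit background universe
   (`actnet.set_statistics`); 75-bin metagene methylation profiles by
   expression class and TFBS-in-DMR odds ratios
   (`actnet.methylation_profile`); a reduced 11-reaction mass-action ODE
   model of mitochondrial energetics (TCA / ETC / ROS subsystems) with
   fold-change rate scaling and two sensitivity analyses
   (`actnet.mitochondrial_model`); correlation of network proteins with
   left-ventricular ejection fraction in a biopsy cohort
   (`actnet.clinical`).

4. **Synthetic data** (`actnet.synthetic_data`). Every input the pipeline
   consumes is generated with known ground truth — a preferential-attachment
   interactome with densified planted modules, treated/control time courses
   with polynomial treatment effects confined to the planted module,
   genomic intervals with a controllable TFBS-in-DMR odds ratio, a patient
   cohort with planted expression–LVEF correlations — so every stage is
   testable without downloads.

## Worked example

```python
from actnet import *
from actnet import synthetic_data as synth

# a 300-protein interactome with one planted 15-protein response module,
# perturbed (terminal effect 2.0 log2 units at noise SD 0.25) by 3 of 4 drugs
net = generate_network(n_nodes=300, mean_degree=4, n_modules=1,
                       module_size=15, intra_module_edge_prob=0.6, seed=1)
truth = plant_module_effects(net, affected={"DOX": [0], "EPI": [0], "IDA": [0]}, seed=2)

W, nodes = build_transition(net.graph)
subnetworks = []
for i, drug in enumerate(("DOX", "EPI", "IDA", "DAU")):
    layer_scores = []
    for j, layer in enumerate(synth.LAYERS):
        tc = generate_timecourse(net, truth, drug, "therapeutic", layer, seed=100 + 10*i + j)
        fits = fit_timecourse(tc)
        call_dynamic_features(fits)                      # BH q <= 0.05, R2 >= 0.7, n >= 10
        layer_scores.append(score_nodes(fits, (drug, "therapeutic", layer)))
    scores = integrate_scores(*layer_scores)             # proteome + transcriptome
    E = diffuse(W, nodes, scores, restart_prob=0.4)      # insulated heat diffusion
    sub = extract_subnetworks(E, nodes, None, drug, "therapeutic")
    subnetworks.append(sub)
    print(f"{drug}: {len(sub.nodes):3d} subnetwork proteins (delta = {sub.chosen_delta:.3f})")

consensus = build_consensus(subnetworks, min_occurrence=2)
planted = net.module_nodes(0)
tp = len(consensus.nodes & planted)
print(f"consensus: {len(consensus.nodes)} proteins, "
      f"precision {tp/len(consensus.nodes):.2f}, recall {tp/len(planted):.2f}")
```

prints

```
DOX:  15 subnetwork proteins (delta = 0.053)
EPI:  15 subnetwork proteins (delta = 0.046)
IDA:  14 subnetwork proteins (delta = 0.053)
DAU:   0 subnetwork proteins (delta = nan)
consensus: 15 proteins, precision 1.00, recall 1.00
```

The three perturbed drugs each yield a subnetwork concentrated on the
planted module; the unperturbed drug (DAU) has no dynamic features, hence no
heat to diffuse and an empty subnetwork; the ≥ 2-drug consensus recovers the
planted module exactly.

The same chain runs from the shell, one subcommand per stage:

```sh
actnet all --seed 3 --outdir out          # simulate -> fit -> propagate ->
                                          # consensus -> enrich -> methprofile
                                          # -> mito -> clinical
```

Each stage writes TSV/BED/GMT/JSON artifacts plus a manifest with input
checksums, parameters and seeds; deterministic stages reproduce
byte-identical output on re-run.

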