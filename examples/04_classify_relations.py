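"""Classify epigenetic marks and genes as upstream / downstream /
independent, with the cross-phenotype consensus rule.

Runs the pipeline on 50 genes with four phenotype contexts, labels every
mark against its gene's mRNA (path rule) and every gene against the
phenotype (direct-edge rule for upstream), keeps labels identical in at
least 3 of the 4 contexts, and annotates upstream marks as activators or
suppressors from their expression-correlation sign.
"""

import pandas as pd

from lrnkit.pipeline import infer_gene_networks
from lrnkit.relations import (
    call_upstream_genes,
    consensus_across_phenotypes,
    sign_of_regulation,
)
from lrnkit.synthetic import CascadeConfig, simulate_lrn_cascade

# 50 genes: composite covariates need a reasonably sized layer to estimate
# hidden factors well; tiny cohorts give unreliable edge orientations
ds = simulate_lrn_cascade(CascadeConfig(n_genes=50, n_phenotypes=4, seed=7))
res = infer_gene_networks(ds, contexts=[0, 1, 2, 3], n_steps=15_000, seed=8)

rel = res["relations"]
print("single-context relation calls (head):")
print(rel.head(8).to_string(index=False))

per_ctx = [rel[rel.phenotype == str(c)][["gene", "source", "reference", "label"]]
           for c in range(4)]
cons = consensus_across_phenotypes(per_ctx, min_support=3)
print(f"\nrelations consistent in ≥3 of 4 phenotype contexts: "
      f"{len(cons)} of {len(per_ctx[0])} pairs")
print(cons.head(8).to_string(index=False))

# regulation sign for upstream marks, from the eQTM correlation sign
eqtm = res["mapping"].eqtm
signs = []
for r in cons[cons.reference == "e"].itertuples():
    ns = res["node_sets"][(r.gene, 0)]
    feature = ns.feature_map.get(r.source, r.source)
    hit = eqtm[(eqtm.gene == r.gene) & (eqtm.peak == feature)]
    corr = float(hit.iloc[0]["r"]) if len(hit) else 0.0
    signs.append((r.gene, r.source, r.label, round(corr, 2),
                  sign_of_regulation(r.label, corr)))
print("\nregulation signs (upstream + negative correlation ⇒ suppressor):")
print(pd.DataFrame(signs, columns=["gene", "mark", "label", "r", "sign"])
      .head(8).to_string(index=False))

up = call_upstream_genes(res["networks"])
print("\ngene-vs-phenotype calls (upstream requires the direct e→p edge):")
print(up["label"].value_counts().to_string())
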