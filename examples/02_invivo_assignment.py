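"""Train the in vivo assignment layer and run all-versus-all prediction.

The in vivo layer nests the Naive Bayes+ posterior with functional
association evidence (GO-like semantic similarities, coexpression and
experimental association channels) in one monolithic Random Forest,
trained on annotated positive pairs plus an equally sized, type-matched
random negative set.
"""

import pandas as pd

from kinassign import invivo
from kinassign import pipeline as pl
from kinassign import synthetic as syn
from kinassign import windows as win

# half the kinome sits in isozyme families with near-identical motifs,
# so many sites are genuinely phosphorylated by more than one kinase
kinome = syn.generate_kinome(n_kinases=10, motif_sharpness=0.9,
                             family_fraction=0.5, seed=3)
assay, truth = syn.simulate_assay(kinome, pool_size=1000,
                                  substrates_per_kinase_range=(40, 100), seed=4)
bundle = syn.simulate_association_and_quant(truth, signal_strength=1.0, seed=5)
graph = pl.graph_from_edges(bundle.edges)
features, _ = pl.compute_context_features(
    assay, truth.sites, graph, bundle.protein_domains,
    bundle.domain_annotations)
models, background = pl.fit_invitro_models(assay, truth.sites,
                                           features_by_kinase=features)
scores = pl.score_sites(models, truth.sites, background,
                        features_by_kinase=features)

# positives = true pairs; negatives = random type-matched pairs
site_info = truth.sites[["site_id", "residue"]].copy()
site_info["site_class"] = site_info["residue"].map(win.residue_site_class)
pos = (truth.labels.reset_index(names="site_id")
       .melt(id_vars="site_id", var_name="kinase_id", value_name="lab"))
pos = pos[pos["lab"]].drop(columns="lab").merge(
    site_info[["site_id", "site_class"]], on="site_id")
pos["label"] = 1
neg = invivo.sample_negatives(pos, site_info[["site_id", "site_class"]], seed=6)
neg["label"] = 0
pairs = pd.concat([pos, neg], ignore_index=True)[["kinase_id", "site_id", "label"]]
ftable = pl.attach_pair_features(pairs, truth.sites, scores,
                                 bundle.association, kinome.registry())
clf, importances = invivo.train(ftable, ftable["label"], n_trees=200, seed=7)
print("feature importances (Gini impurity):")
print(importances.sort_values(ascending=False).round(3).to_string())

# all-versus-all assignment over the full pool
allpairs = invivo.all_vs_all_pairs(
    kinome.ids(), truth.sites.assign(
        site_class=truth.sites["residue"].map(win.residue_site_class)))
fall = pl.attach_pair_features(allpairs, truth.sites, scores,
                               bundle.association, kinome.registry())
result = invivo.predict(clf, fall)
per_site = result[result["assigned"]].groupby("site_id").size()
print(f"\n{result['assigned'].sum()} assignments over "
      f"{result['site_id'].nunique()} sites x {len(kinome)} kinases")
print("kinases per assigned site:",
      per_site.value_counts().sort_index().to_dict())
# multi-label by design: one site may be assigned to several kinases
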