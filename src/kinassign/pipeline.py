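"""End-to-end glue: fit in vitro models, score pools, assemble in vivo data.

These helpers wire the per-module operations into the standard workflow:

1. extract windows for a phosphosite pool,
2. fit a Naive Bayes(+) sub-model per kinase from a shared-pool assay
   (phosphoproteome-positional background, Henikoff weighting,
   sqrt-pseudocounts),
3. score any site set with Naive Bayes, Naive Bayes+ and the
   phosphoproteome-backed PSSM,
4. compute binary context features from interaction and domain data,
5. assemble (kinase, site) feature tables for the in vivo classifier.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from . import invivo
from . import naive_bayes as nb
from . import specificity as spec
from . import windows as win
from .errors import InputError

logger = logging.getLogger(__name__)


def site_windows_from_table(sites: pd.DataFrame) -> dict:
    """site_id -> SequenceWindow from a sites table with a window column."""
    return {sid: win.window_from_string(w)
            for sid, w in zip(sites["site_id"], sites["window"])}


def windows_from_fasta(sequences: dict, phosphosites: pd.DataFrame,
                       flank: int = 7, strict: bool = True) -> pd.DataFrame:
    """Extract windows for a phosphosite table against a FASTA proteome.

    Returns the sites table (site_id, protein_id, position, residue,
    window); in permissive mode, sites whose recorded acceptor mismatches
    the sequence are kept but flagged in a ``residue_mismatch`` column.
    """
    rows = []
    for i, r in phosphosites.iterrows():
        seq = sequences.get(r["protein_id"])
        if seq is None:
            logger.warning("protein %s absent from FASTA; site skipped",
                           r["protein_id"])
            continue
        site = win.Phosphosite(r["protein_id"], int(r["position"]), r["residue"])
        ok = site.validate(seq, strict=strict)
        w = win.extract_window(seq, int(r["position"]), flank)
        rows.append({
            "site_id": f"{r['protein_id']}@{r['position']}",
            "protein_id": r["protein_id"],
            "position": int(r["position"]),
            "residue": r["residue"],
            "window": w.residues,
            "residue_mismatch": not ok,
        })
    return pd.DataFrame(rows)


def fit_invitro_models(assay: pd.DataFrame, sites: pd.DataFrame,
                       features_by_kinase: dict | None = None,
                       pseudocount_mass="sqrt",
                       kinase_types: dict | None = None):
    """Fit one Naive Bayes(+) sub-model per kinase in the assay.

    Returns ``(models, background)``; the background is the
    position-specific (phosphoproteome) frequency model of all pool
    windows, shared across kinases.  Kinases with no positives are
    skipped with a warning.
    """
    site_windows = site_windows_from_table(sites)
    background = spec.BackgroundModel.from_windows(list(site_windows.values()))
    models = {}
    for kinase_id in sorted(assay["kinase_id"].unique()):
        feats = (features_by_kinase or {}).get(kinase_id)
        try:
            models[kinase_id] = nb.fit_nb_model(
                assay, site_windows, kinase_id, background=background,
                pseudocount_mass=pseudocount_mass, features=feats,
                kinase_type=(kinase_types or {}).get(kinase_id))
        except nb.UnmodellableKinase as exc:
            logger.warning("skipping kinase: %s", exc)
    if not models:
        raise InputError("no kinase could be modelled from the assay")
    return models, background


def score_sites(models: dict, sites: pd.DataFrame,
                background: spec.BackgroundModel | None = None,
                features_by_kinase: dict | None = None) -> pd.DataFrame:
    """Score every (kinase, site) pair with NB, NB+ and PSSM models.

    Returns a long frame (kinase_id, site_id, nb_posterior,
    nbplus_posterior, pssm_score); the PSSM column is the min-max
    normalized phosphoproteome-backed PSSM score of the kinase's
    foreground PFM (requires ``background``); the NB+ column requires both
    Bernoulli parameters and per-kinase feature tables.
    """
    site_windows = site_windows_from_table(sites)
    site_ids = sites["site_id"].tolist()
    encoded = win.encode_windows([site_windows[s] for s in site_ids])
    frames = []
    for kinase_id, model in models.items():
        out = pd.DataFrame({"kinase_id": kinase_id, "site_id": site_ids})
        out["nb_posterior"] = nb.nb_posterior_many(model, encoded)
        feats = (features_by_kinase or {}).get(kinase_id)
        if model.bernoulli_params is not None and feats is not None:
            aligned = feats.reindex(site_ids).fillna(False)
            out["nbplus_posterior"] = nb.nb_plus_posterior_many(
                model, encoded, aligned)
        if background is not None:
            pssm = spec.build_pssm(model.fg_pfm, background)
            out["pssm_score"] = pssm.score_normalized_many(encoded)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def compute_context_features(assay: pd.DataFrame, sites: pd.DataFrame,
                             graph: nx.Graph, protein_domains: dict,
                             domain_annotations: pd.DataFrame,
                             kinase_ids=None, max_distance: int = 2,
                             alpha: float = 0.05):
    """Per-kinase binary context feature tables for every pool site.

    Returns ``(features_by_kinase, enriched_by_kinase)``:
    ``features_by_kinase[k]`` is a site_id-indexed boolean frame with
    columns interactor, domain_enriched_substrates,
    domain_enriched_interactors, in_domain;
    ``enriched_by_kinase[k]`` the pair of enriched-domain sets.
    """
    if kinase_ids is None:
        kinase_ids = sorted(assay["kinase_id"].unique())
    pool_proteins = list(dict.fromkeys(sites["protein_id"]))

    # site-level in_domain flag: any interval containing the position
    ann = domain_annotations.merge(
        sites[["site_id", "protein_id", "position"]], on="protein_id")
    covered = ann[(ann["start"] <= ann["position"])
                  & (ann["position"] <= ann["end"])]["site_id"]
    in_domain = sites["site_id"].isin(set(covered))
    in_domain.index = sites["site_id"]

    pos_by_kinase = (assay[assay["phosphorylated"].astype(bool)]
                     .groupby("kinase_id")["protein_id"].apply(set))
    features_by_kinase = {}
    enriched_by_kinase = {}
    pool_set = set(pool_proteins)
    for kinase_id in kinase_ids:
        substrates = pos_by_kinase.get(kinase_id, set())
        interactors = nb.interactors_within(graph, kinase_id, max_distance)
        enriched_sub = nb.domain_enrichment(substrates & pool_set,
                                            protein_domains, pool_proteins,
                                            alpha)
        enriched_int = nb.domain_enrichment(interactors & pool_set,
                                            protein_domains, pool_proteins,
                                            alpha)
        proteins = sites["protein_id"]
        feats = pd.DataFrame({
            "interactor": proteins.isin(interactors).to_numpy(),
            "domain_enriched_substrates": np.array(
                [bool(protein_domains.get(p, set()) & enriched_sub)
                 for p in proteins]),
            "domain_enriched_interactors": np.array(
                [bool(protein_domains.get(p, set()) & enriched_int)
                 for p in proteins]),
            "in_domain": in_domain.to_numpy(),
        }, index=pd.Index(sites["site_id"], name="site_id"))
        features_by_kinase[kinase_id] = feats
        enriched_by_kinase[kinase_id] = (enriched_sub, enriched_int)
    return features_by_kinase, enriched_by_kinase


def attach_pair_features(pairs: pd.DataFrame, sites: pd.DataFrame,
                         scores: pd.DataFrame, association: pd.DataFrame,
                         registry: pd.DataFrame,
                         posterior_column: str = "nbplus_posterior") -> pd.DataFrame:
    """Assemble the in vivo 8-feature table for (kinase, site) pairs.

    ``pairs`` needs kinase_id and site_id (extra columns pass through);
    protein and site class come from ``sites``; the in vitro posterior
    from ``scores`` (pairs whose kinase has no model are dropped with a
    warning, per the skip contract).
    """
    site_info = sites[["site_id", "protein_id", "residue"]].copy()
    site_info["site_class"] = site_info["residue"].map(win.residue_site_class)
    pairs = pairs.drop(columns=[c for c in ("protein_id", "site_class")
                                if c in pairs.columns])
    out = pairs.merge(site_info.drop(columns="residue"), on="site_id")
    post = scores[["kinase_id", "site_id", posterior_column]].rename(
        columns={posterior_column: "nbplus_posterior"})
    n_before = len(out)
    out = out.merge(post, on=["kinase_id", "site_id"], how="inner")
    if len(out) < n_before:
        logger.warning("dropped %d pairs whose kinase lacks an in vitro model",
                       n_before - len(out))
    return invivo.build_feature_table(out, association, registry)


def graph_from_edges(edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from(zip(edges["protein_a"], edges["protein_b"]))
    return g
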