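"""Standard synthetic benchmark experiments.

Each function builds a self-contained study on synthetic data with known
ground truth and returns the summary quantities the package's validation
rests on: in vitro assignment recovery, cutoff behaviour, score-posterior
calibration, the in vivo classifier's benefit over the sequence-only
model, negative-sampling checks, and kinase-activity inference under
simulated inhibition.  All randomness is derived from a single integer
seed per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import activity as act
from . import evaluation as ev
from . import invivo
from . import naive_bayes as nb
from . import pipeline as pl
from . import specificity as spec
from . import synthetic as syn
from . import windows as win


@dataclass
class SyntheticStudy:
    """A complete synthetic data set plus fitted in vitro models."""

    kinome: syn.SyntheticKinome
    assay: pd.DataFrame
    truth: syn.GroundTruth
    bundle: syn.AssociationBundle | None
    models: dict
    background: spec.BackgroundModel
    scores: pd.DataFrame
    features_by_kinase: dict | None


def build_study(seed: int, n_kinases: int = syn.DEFAULT_N_KINASES,
                motif_sharpness=syn.DEFAULT_SHARPNESS,
                family_fraction: float = 0.4,
                pool_size: int = syn.DEFAULT_POOL_SIZE,
                substrates_per_kinase_range: tuple | None = None,
                signal_strength: float | None = None) -> SyntheticStudy:
    """Generate a kinome + assay (+ optional association data) and fit models."""
    kinome = syn.generate_kinome(n_kinases=n_kinases,
                                 motif_sharpness=motif_sharpness,
                                 family_fraction=family_fraction,
                                 seed=seed)
    assay, truth = syn.simulate_assay(
        kinome, pool_size=pool_size,
        substrates_per_kinase_range=substrates_per_kinase_range, seed=seed + 1)
    bundle = None
    features = None
    if signal_strength is not None:
        bundle = syn.simulate_association_and_quant(truth, signal_strength,
                                                    seed=seed + 2)
        graph = pl.graph_from_edges(bundle.edges)
        features, _ = pl.compute_context_features(
            assay, truth.sites, graph, bundle.protein_domains,
            bundle.domain_annotations)
    models, background = pl.fit_invitro_models(assay, truth.sites,
                                               features_by_kinase=features)
    scores = pl.score_sites(models, truth.sites, background,
                            features_by_kinase=features)
    return SyntheticStudy(kinome, assay, truth, bundle, models, background,
                          scores, features)


def invitro_macro_metrics(study: SyntheticStudy, column: str,
                          cutoff: float = 0.5,
                          min_substrates: int = 0) -> ev.MacroMetrics:
    """Macro metrics of an in vitro score column against the assay labels."""
    m = study.assay.merge(study.scores, on=["kinase_id", "site_id"])
    if min_substrates:
        keep = [k for k, mod in study.models.items()
                if mod.n_substrates >= min_substrates]
        m = m[m["kinase_id"].isin(keep)]
    m["label"] = m["phosphorylated"]
    m["assigned"] = m[column] > cutoff
    return ev.macro_metrics(ev.counts_from_predictions(m))


def cutoff_behaviour(study: SyntheticStudy,
                     cutoffs=None, min_substrates: int = 20) -> dict:
    """F1-vs-cutoff ranges and score bimodality (S/T kinases) for NB vs PSSM."""
    if cutoffs is None:
        cutoffs = np.linspace(0.1, 0.9, 17)
    keep = [k for k, mod in study.models.items()
            if mod.n_substrates >= min_substrates]
    m = study.assay.merge(study.scores, on=["kinase_id", "site_id"])
    m = m[m["kinase_id"].isin(keep)]
    m["label"] = m["phosphorylated"]
    out = {}
    for name, col in (("nb", "nb_posterior"), ("pssm", "pssm_score")):
        df = m.rename(columns={col: "score"})[["kinase_id", "score", "label"]]
        curve = ev.curve_over_cutoffs(df, cutoffs=cutoffs)
        out[f"{name}_f1_range"] = float(curve["f1"].max() - curve["f1"].min())
        out[f"{name}_f1_max"] = float(curve["f1"].max())
    st = {k.kinase_id for k in study.kinome if k.kinase_type == "S/T"} & set(keep)
    sub = m[m["kinase_id"].isin(st)]
    for name, col in (("nb", "nb_posterior"), ("pssm", "pssm_score")):
        s = sub[col].to_numpy()
        out[f"{name}_frac_outside"] = float(((s < 0.1) | (s > 0.9)).mean())
    return out


def calibration_trend(seed: int, n_kinases: int = 15, pool_size: int = 12000,
                      count_range: tuple = (20, 500),
                      motif_sharpness: float = 0.9) -> dict:
    """Logistic inflection of min-max PSSM scores versus substrate count.

    A kinome of equally promiscuous kinases is simulated on a shared pool;
    each kinase's *detected* substrates are thinned to a log-spaced ladder
    of counts (shotgun-detection emulation), models are refit, and per
    kinase a logistic curve is fit to min-max PSSM score versus Naive
    Bayes posterior over probe windows with graded motif match.  Returns
    the Spearman correlation of inflection with substrate count.
    """
    base = 600
    kinome = syn.generate_kinome(
        n_kinases=n_kinases, motif_sharpness=motif_sharpness,
        family_fraction=0.0,
        prior_range=((base - 50) / pool_size, (base + 50) / pool_size),
        seed=seed)
    assay, truth = syn.simulate_assay(kinome, pool_size=pool_size, seed=seed + 1)
    targets = np.round(np.exp(np.linspace(np.log(count_range[0]),
                                          np.log(count_range[1]), n_kinases)))
    assay, truth = syn.thin_detected_substrates(
        assay, truth, dict(zip(truth.labels.columns, targets)), seed=seed + 2)
    models, background = pl.fit_invitro_models(assay, truth.sites)
    fits = []
    for kinase in kinome:
        model = models.get(kinase.kinase_id)
        if model is None:
            continue
        probes = syn.calibration_probe_windows(kinase, seed=seed + 3)
        enc = win.encode_windows(probes)
        pssm = spec.build_pssm(model.fg_pfm, background)
        fit = ev.fit_logistic_calibration(
            pssm.score_normalized_many(enc), nb.nb_posterior_many(model, enc),
            n_substrates=model.n_substrates, kinase_id=kinase.kinase_id)
        fits.append(fit)
    ns = [f.n_substrates for f in fits]
    infl = [f.inflection for f in fits]
    rho, p = spearmanr(ns, infl)
    return {"rho": float(rho), "p": float(p), "fits": fits,
            "counts": (int(min(ns)), int(max(ns)))}


def _truth_pairs_long(truth: syn.GroundTruth) -> pd.DataFrame:
    long = truth.labels.reset_index(names="site_id").melt(
        id_vars="site_id", var_name="kinase_id", value_name="label")
    long["label"] = long["label"].astype(int)
    return long


def holdout_invivo_comparison(seed: int, signal_strength: float,
                              n_kinases: int = 30,
                              motif_sharpness: float = 0.95,
                              pool_size: int = 9000,
                              substrates_per_kinase_range: tuple = (150, 250),
                              n_trees: int = 500) -> dict:
    """In vivo classifier versus Naive Bayes+ on held-out sites.

    Sites are split in half; in vitro models and domain enrichment are fit
    on the training half only (mirroring per-fold refitting); the in vivo
    classifier is trained on the training half's true pairs plus sampled
    negatives; both methods are then evaluated all-versus-all on the
    held-out half at their nominal 0.5 cutoffs.
    """
    kinome = syn.generate_kinome(n_kinases=n_kinases,
                                 motif_sharpness=motif_sharpness,
                                 family_fraction=0.0, seed=seed)
    assay, truth = syn.simulate_assay(
        kinome, pool_size=pool_size,
        substrates_per_kinase_range=substrates_per_kinase_range, seed=seed + 1)
    bundle = syn.simulate_association_and_quant(truth, signal_strength,
                                                seed=seed + 2)
    graph = pl.graph_from_edges(bundle.edges)
    sites = truth.sites
    rng = np.random.default_rng(seed + 3)
    perm = rng.permutation(len(sites))
    half = len(sites) // 2
    tr_ids = set(sites["site_id"].iloc[perm[:half]])
    te_ids = set(sites["site_id"].iloc[perm[half:]])
    tr_assay = assay[assay["site_id"].isin(tr_ids)]
    feats_all, _ = pl.compute_context_features(
        tr_assay, sites, graph, bundle.protein_domains,
        bundle.domain_annotations)
    feats_tr = {k: v[v.index.isin(tr_ids)] for k, v in feats_all.items()}
    models, background = pl.fit_invitro_models(
        tr_assay, sites[sites["site_id"].isin(tr_ids)],
        features_by_kinase=feats_tr)
    scores = pl.score_sites(models, sites, background,
                            features_by_kinase=feats_all)

    long = _truth_pairs_long(truth)
    site_info = sites[["site_id", "residue"]].copy()
    site_info["site_class"] = site_info["residue"].map(win.residue_site_class)
    pos = (long[(long["label"] == 1) & long["site_id"].isin(tr_ids)]
           .merge(site_info[["site_id", "site_class"]], on="site_id"))
    pool_df = site_info.loc[site_info["site_id"].isin(tr_ids),
                            ["site_id", "site_class"]]
    neg = invivo.sample_negatives(pos, pool_df, seed=seed + 4)
    neg["label"] = 0
    pairs = pd.concat([pos[["kinase_id", "site_id", "label"]],
                       neg[["kinase_id", "site_id", "label"]]],
                      ignore_index=True)
    ftrain = pl.attach_pair_features(pairs, sites, scores, bundle.association,
                                     kinome.registry())
    clf, importances = invivo.train(ftrain, ftrain["label"], n_trees=n_trees,
                                    seed=seed + 5)

    test = long[long["site_id"].isin(te_ids)]
    ftest = pl.attach_pair_features(test, sites, scores, bundle.association,
                                    kinome.registry())
    res = ftest[["kinase_id", "site_id", "label", "nbplus_posterior"]].copy()
    res["assigned"] = invivo.predict(clf, ftest)["assigned"].to_numpy()
    rf = ev.macro_metrics(ev.counts_from_predictions(res))
    res["assigned"] = res["nbplus_posterior"] > 0.5
    nbp = ev.macro_metrics(ev.counts_from_predictions(res))
    mm = test.merge(scores, on=["kinase_id", "site_id"])
    mm["assigned"] = mm["nb_posterior"] > 0.5
    nbm = ev.macro_metrics(ev.counts_from_predictions(mm))
    return {"f1_invivo": rf.f1, "f1_nbplus": nbp.f1, "f1_nb": nbm.f1,
            "precision_invivo": rf.precision, "recall_invivo": rf.recall,
            "importances": importances}


def activity_rates(seed: int, effect: float = -1.0, noise_sd: float = 0.5,
                   m: int = 10, n_sites: int = 1000, n_runs: int = 40,
                   fp_fraction: float = 0.0) -> dict:
    """Signed-activity statistics over repeated simulated inhibitions.

    Each run draws a condition-wide fold-change vector N(0, noise_sd) over
    ``n_sites``, shifts ``m`` true-substrate sites by ``effect``, and
    infers the inhibited kinase's activity from an assigned set that mixes
    true substrates with a ``fp_fraction`` share of random (unshifted)
    sites.  Returns the fraction of runs with the expected (negative for
    inhibition) sign and the median |activity|.
    """
    rng = np.random.default_rng(seed)
    signs, mags = [], []
    for _ in range(n_runs):
        fcs = rng.normal(0.0, noise_sd, size=n_sites)
        true_idx = rng.choice(n_sites, size=m, replace=False)
        fcs[true_idx] += effect
        n_fp = int(round(m * fp_fraction / (1.0 - fp_fraction)))
        others = np.setdiff1d(np.arange(n_sites), true_idx)
        assigned = np.concatenate([
            true_idx, rng.choice(others, size=n_fp, replace=False)])
        score = act.infer_activity(fcs[assigned], fcs)
        signs.append(np.sign(score.activity))
        mags.append(abs(score.activity))
    expected = np.sign(effect)
    return {"frac_expected_sign": float(np.mean(np.array(signs) == expected)),
            "median_abs_activity": float(np.median(mags))}


def inhibition_study(seed: int, n_kinases: int = 12, pool_size: int = 1200,
                     effect: float = -1.0, noise_sd: float = 0.5) -> pd.DataFrame:
    """Full-pipeline activity inference on a simulated inhibitor experiment.

    Builds a synthetic assay, uses the *true* assignments at the nominal
    cutoff, filters the simulated quant table and returns the activity
    matrix with expectation tags.
    """
    kinome = syn.generate_kinome(n_kinases=n_kinases, motif_sharpness=0.9,
                                 family_fraction=0.0, seed=seed)
    assay, truth = syn.simulate_assay(kinome, pool_size=pool_size, seed=seed + 1)
    bundle = syn.simulate_association_and_quant(truth, 1.0, effect=effect,
                                                noise_sd=noise_sd, seed=seed + 2)
    assignments = _truth_pairs_long(truth).rename(columns={"label": "assigned"})
    assignments["assigned"] = assignments["assigned"].astype(bool)
    quant = act.filter_quant(bundle.quant)
    return act.activity_matrix(assignments, quant, kinome.ids(),
                               bundle.condition_targets,
                               bundle.regulatory_edges)
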