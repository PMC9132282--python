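"""In vivo kinase-site assignment layer.

Combines the in vitro Naive Bayes+ posterior with functional-association
evidence in a single monolithic (non-kinase-specific) classifier.  The
feature vector for a (kinase, site) pair has 8 entries:

* nbplus_posterior - in vitro Naive Bayes+ posterior probability,
* go_bp_semsim, go_cc_semsim - GO biological-process / cellular-component
  semantic similarity of kinase and substrate (ingested per-pair scores),
* string_coexpression, string_experimental - association-channel scores
  (rescaled from a 0-1000 dialect to [0, 1] when needed),
* substrate_is_kinase - whether the substrate protein is itself a kinase
  (association scores are symmetric, so enzymatic roles can be reversed),
* kinase_type, site_class - S/T (1) versus Y (0).

Training uses annotated positive pairs plus an equally sized random
negative set drawn from a phosphosite pool under type-matching
constraints.  The default classifier is a 500-tree Random Forest with Gini
splitting and impurity feature importances, exposed behind a
predict-probability contract so other learners can be substituted.
A kinase is assigned when the predicted probability exceeds 0.5 (strictly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import InputError, SamplingError

logger = logging.getLogger(__name__)

PROBABILITY_CUTOFF = 0.5

FEATURE_COLUMNS = [
    "nbplus_posterior",
    "go_bp_semsim",
    "go_cc_semsim",
    "string_coexpression",
    "string_experimental",
    "substrate_is_kinase",
    "kinase_type_st",
    "site_class_st",
]

_CHANNEL_TO_COLUMN = {
    "go_bp": "go_bp_semsim",
    "go_cc": "go_cc_semsim",
    "coexpression": "string_coexpression",
    "experimental": "string_experimental",
}


@dataclass(frozen=True)
class AssignmentResult:
    kinase_id: str
    site_id: str
    probability: float
    assigned: bool


def _rescale_scores(s: pd.Series) -> pd.Series:
    """Rescale a 0-1000 score dialect to [0, 1]; [0, 1] passes through."""
    if s.max() > 1.0:
        return s / 1000.0
    return s


def build_feature_table(pairs: pd.DataFrame, association: pd.DataFrame,
                        kinase_registry: pd.DataFrame) -> pd.DataFrame:
    """Assemble the 8-feature table for (kinase, site) pairs.

    ``pairs`` needs columns kinase_id, site_id, protein_id, site_class and
    nbplus_posterior (pairs whose kinase lacks a Naive Bayes+ model must be
    skipped upstream).  ``association`` is long (kinase_id, protein_id,
    channel, score); missing records are imputed as 0 and flagged in the
    ``imputed`` column (not a model feature).  ``kinase_registry`` has
    kinase_id, kinase_type and drives both the kinase-type feature and the
    substrate-is-kinase flag.
    """
    required = {"kinase_id", "site_id", "protein_id", "site_class",
                "nbplus_posterior"}
    if not required <= set(pairs.columns):
        raise InputError(f"pairs table must have columns {sorted(required)}")
    out = pairs.copy()
    wide = association.copy()
    wide["score"] = _rescale_scores(wide["score"].astype(float))
    wide = wide.pivot_table(index=["kinase_id", "protein_id"], columns="channel",
                            values="score", aggfunc="first").reset_index()
    out = out.merge(wide, on=["kinase_id", "protein_id"], how="left")
    assoc_cols = []
    for channel, col in _CHANNEL_TO_COLUMN.items():
        if channel in out.columns:
            out = out.rename(columns={channel: col})
        else:
            out[col] = np.nan
        assoc_cols.append(col)
    out["imputed"] = out[assoc_cols].isna().any(axis=1)
    n_imp = int(out["imputed"].sum())
    if n_imp:
        logger.warning("imputed missing association scores as 0 for %d pairs", n_imp)
    out[assoc_cols] = out[assoc_cols].fillna(0.0)

    kin_types = dict(zip(kinase_registry["kinase_id"],
                         kinase_registry["kinase_type"]))
    kinase_names = set(kinase_registry["kinase_id"])
    out["substrate_is_kinase"] = out["protein_id"].isin(kinase_names).astype(float)
    missing = set(out["kinase_id"]) - set(kin_types)
    if missing:
        raise InputError(f"kinases missing from registry: {sorted(missing)[:5]}")
    out["kinase_type_st"] = (out["kinase_id"].map(kin_types) == "S/T").astype(float)
    out["site_class_st"] = (out["site_class"] == "S/T").astype(float)
    return out


def build_feature_vector(kinase_id, site_id, protein_id, site_class,
                         nbplus_posterior, association, kinase_registry):
    """One-pair convenience wrapper around :func:`build_feature_table`."""
    pairs = pd.DataFrame([{
        "kinase_id": kinase_id, "site_id": site_id, "protein_id": protein_id,
        "site_class": site_class, "nbplus_posterior": nbplus_posterior,
    }])
    return build_feature_table(pairs, association, kinase_registry).iloc[0]


def sample_negatives(positives: pd.DataFrame, site_pool: pd.DataFrame,
                     exclusions: set | None = None, seed: int = 0) -> pd.DataFrame:
    """Random negative pairs mirroring the positive set's structure.

    For each kinase, the negative set contains exactly the kinase's
    positive count per site class (S/T positives get S/T negatives, Y get
    Y; annotated cross-type positives are mirrored in the same
    proportion), drawn without replacement per kinase from ``site_pool``
    (columns site_id, site_class and optionally is_kinase).  When the pool
    records which sites lie on kinase proteins, the proportion of
    substrate-kinase sites in each kinase's positives is maintained.
    Excluded pairs (positives, held-out test pairs) are never sampled.
    Deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    exclusions = set(exclusions or ())
    pos_pairs = set(zip(positives["kinase_id"], positives["site_id"]))
    forbidden = exclusions | pos_pairs
    has_kin_flag = "is_kinase" in site_pool.columns
    rows = []
    for kinase, grp in positives.groupby("kinase_id", sort=True):
        for site_class, sub in grp.groupby("site_class", sort=True):
            need = len(sub)
            cand = site_pool[site_pool["site_class"] == site_class]
            cand = cand[~cand["site_id"].map(
                lambda s, k=kinase: (k, s) in forbidden)]
            if len(cand) < need:
                raise SamplingError(
                    f"site pool exhausted for kinase {kinase} ({site_class}): "
                    f"need {need}, have {len(cand)}")
            if has_kin_flag and "is_kinase" in sub.columns:
                n_kin = int(sub["is_kinase"].astype(bool).sum())
                kin_cand = cand[cand["is_kinase"].astype(bool)]
                non_cand = cand[~cand["is_kinase"].astype(bool)]
                n_kin = min(n_kin, len(kin_cand))
                n_non = min(need - n_kin, len(non_cand))
                if n_kin + n_non < need:
                    raise SamplingError(
                        f"site pool exhausted for kinase {kinase} "
                        f"({site_class}, substrate-kinase stratum)")
                parts = []
                if n_kin:
                    parts.append(kin_cand.iloc[rng.choice(len(kin_cand), n_kin,
                                                          replace=False)])
                if n_non:
                    parts.append(non_cand.iloc[rng.choice(len(non_cand), n_non,
                                                          replace=False)])
                sel = pd.concat(parts)
            else:
                sel = cand.iloc[rng.choice(len(cand), need, replace=False)]
            for _, r in sel.iterrows():
                rows.append({"kinase_id": kinase, "site_id": r["site_id"],
                             "site_class": site_class, "label": 0})
    return pd.DataFrame(rows)


def train(features: pd.DataFrame, labels, n_trees: int = 500,
          split_criterion: str = "gini", seed: int | None = None):
    """Train the monolithic in vivo classifier.

    Returns ``(classifier, importances)`` where the classifier satisfies
    the predict-probability contract and importances are impurity (Gini)
    based, one per feature column.
    """
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise InputError("training set must contain both classes")
    clf = RandomForestClassifier(
        n_estimators=n_trees, criterion=split_criterion,
        random_state=seed, n_jobs=1)
    clf.fit(X, y)
    importances = pd.Series(clf.feature_importances_, index=FEATURE_COLUMNS)
    return clf, importances


def predict(classifier, features: pd.DataFrame) -> pd.DataFrame:
    """Assignment probabilities for feature rows; assigned iff p > 0.5.

    Returns a frame with kinase_id, site_id, probability, assigned.
    Probability exactly 0.5 is *not* assigned (strict inequality).
    """
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise InputError(f"feature table missing columns {missing}")
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    proba = classifier.predict_proba(X)[:, 1]
    return pd.DataFrame({
        "kinase_id": features["kinase_id"].to_numpy(),
        "site_id": features["site_id"].to_numpy(),
        "probability": proba,
        "assigned": proba > PROBABILITY_CUTOFF,
    })


def all_vs_all_pairs(kinase_ids, sites: pd.DataFrame) -> pd.DataFrame:
    """Expand a kinase set x site table into all (kinase, site) pairs."""
    sites = sites[["site_id", "protein_id", "site_class"]]
    return (pd.MultiIndex.from_product([sorted(kinase_ids), sites["site_id"]],
                                       names=["kinase_id", "site_id"])
            .to_frame(index=False)
            .merge(sites, on="site_id"))
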