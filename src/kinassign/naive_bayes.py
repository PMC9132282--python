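"""Multi-label Naive Bayes kinase-site assignment (in vitro layer).

Each kinase gets an independent binary sub-model built from a shared-pool
in vitro assay (every kinase exposed to approximately the same substrate
pool, so true negatives exist by design):

* a foreground PFM built from the kinase's substrates,
* a background PFM built from all substrates *not* phosphorylated by the
  kinase,
* empirical prior probabilities (fraction of assayed sites phosphorylated
  by the kinase or not).

The posterior for a kinase K and a window S is

    P(K|S) = s_K P(K) / (s_K P(K) + s_notK P(notK))

where s_K and s_notK are the min-max normalized PFM scores of the window
under the foreground and background models.  Note the score-as-likelihood
convention: normalized PFM scores are used as densities, not calibrated
probabilities.  A kinase is assigned to a site when P(K|S) > 0.5.

The "plus" variant multiplies Bernoulli likelihoods for binary context
features (physical interaction with the kinase, enriched domains, site
inside a domain) into both the foreground and background terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from . import specificity as spec
from . import windows as win
from .errors import InputError, UnmodellableKinase

logger = logging.getLogger(__name__)

PRIOR_EPS = 1e-6
POSTERIOR_CUTOFF = 0.5
MIN_SUBSTRATES_EVAL = 20

#: binary context features of the "plus" model
FEATURE_NAMES = (
    "interactor",
    "domain_enriched_substrates",
    "domain_enriched_interactors",
    "in_domain",
)


@dataclass(frozen=True)
class SiteFeatures:
    """Binary context features for one (kinase, site) pair."""

    interactor: bool = False
    domain_enriched_substrates: bool = False
    domain_enriched_interactors: bool = False
    in_domain: bool = False

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in FEATURE_NAMES}


@dataclass
class NaiveBayesModel:
    """Per-kinase Naive Bayes (optionally "+") sub-model.

    Both likelihood terms are scored under the *foreground* model's
    relative-entropy column weights: the weights define which positions
    carry specificity information for this kinase, and applying them
    symmetrically keeps the two normalized PFM scores commensurable in
    the posterior (each model's own weights would flatten the background
    score range, since the background PFM barely diverges from the pool).
    """

    kinase_id: str
    fg_pfm: spec.SpecificityMatrix
    bg_pfm: spec.SpecificityMatrix
    prior_fg: float
    prior_bg: float
    bernoulli_params: dict | None = None  # feature -> (theta_fg, theta_bg)
    n_substrates: int = 0
    kinase_type: str | None = None

    def __post_init__(self):
        if abs(self.prior_fg + self.prior_bg - 1.0) > 1e-9:
            raise InputError("priors must sum to 1")
        self._bg_scoring = None

    def bg_scoring_pfm(self) -> spec.SpecificityMatrix:
        """Background PFM under the foreground column weights (cached)."""
        if self._bg_scoring is None:
            self._bg_scoring = self.bg_pfm.with_column_weights(
                self.fg_pfm.column_weights)
        return self._bg_scoring


def estimate_priors(assay: pd.DataFrame, kinase_id: str) -> tuple[float, float]:
    """Empirical priors: fraction of assayed sites (not) phosphorylated by the kinase.

    Boundary values are smoothed into (eps, 1-eps).  A kinase with zero
    positives raises :class:`UnmodellableKinase`.
    """
    rows = assay.loc[assay["kinase_id"] == kinase_id, "phosphorylated"]
    if len(rows) == 0:
        raise InputError(f"kinase {kinase_id} not present in assay")
    n_pos = int(rows.sum())
    if n_pos == 0:
        raise UnmodellableKinase(f"kinase {kinase_id} has no positive substrates")
    p = n_pos / len(rows)
    p = min(max(p, PRIOR_EPS), 1.0 - PRIOR_EPS)
    return p, 1.0 - p


def _posterior(s_fg, s_bg, prior_fg, prior_bg, lr_fg=1.0, lr_bg=1.0):
    num = s_fg * lr_fg * prior_fg
    den = num + s_bg * lr_bg * prior_bg
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    zero = den == 0
    if np.any(zero):
        logger.warning("Naive Bayes posterior with zero numerator and denominator; "
                       "defining the posterior as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        post = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    return float(post) if post.ndim == 0 else post


def nb_posterior(model: NaiveBayesModel, window) -> float:
    """Posterior P(K|S) from normalized fg/bg PFM scores and priors."""
    s_fg = model.fg_pfm.score_normalized(window)
    s_bg = model.bg_scoring_pfm().score_normalized(window)
    return _posterior(s_fg, s_bg, model.prior_fg, model.prior_bg)


def nb_posterior_many(model: NaiveBayesModel, encoded: np.ndarray) -> np.ndarray:
    s_fg = model.fg_pfm.score_normalized_many(encoded)
    s_bg = model.bg_scoring_pfm().score_normalized_many(encoded)
    return _posterior(s_fg, s_bg, model.prior_fg, model.prior_bg)


def _bernoulli_ratios(params: dict, flags) -> tuple[float, float]:
    lr_fg = 1.0
    lr_bg = 1.0
    for feat, (theta_fg, theta_bg) in params.items():
        x = bool(flags[feat]) if not isinstance(flags, SiteFeatures) else bool(getattr(flags, feat))
        lr_fg *= theta_fg if x else (1.0 - theta_fg)
        lr_bg *= theta_bg if x else (1.0 - theta_bg)
    return lr_fg, lr_bg


def nb_plus_posterior(model: NaiveBayesModel, window, features) -> float:
    """Posterior with Bernoulli feature likelihoods multiplied into both terms."""
    if model.bernoulli_params is None:
        raise InputError("model has no Bernoulli parameters; fit them first")
    s_fg = model.fg_pfm.score_normalized(window)
    s_bg = model.bg_scoring_pfm().score_normalized(window)
    lr_fg, lr_bg = _bernoulli_ratios(model.bernoulli_params, features)
    return _posterior(s_fg, s_bg, model.prior_fg, model.prior_bg, lr_fg, lr_bg)


def nb_plus_posterior_many(model: NaiveBayesModel, encoded: np.ndarray,
                           features: pd.DataFrame) -> np.ndarray:
    """Vectorized "+" posterior; ``features`` rows align with ``encoded``."""
    if model.bernoulli_params is None:
        raise InputError("model has no Bernoulli parameters; fit them first")
    s_fg = model.fg_pfm.score_normalized_many(encoded)
    s_bg = model.bg_scoring_pfm().score_normalized_many(encoded)
    lik_fg = np.ones(len(encoded))
    lik_bg = np.ones(len(encoded))
    for feat, (theta_fg, theta_bg) in model.bernoulli_params.items():
        x = features[feat].to_numpy(dtype=bool)
        lik_fg *= np.where(x, theta_fg, 1.0 - theta_fg)
        lik_bg *= np.where(x, theta_bg, 1.0 - theta_bg)
    return _posterior(s_fg, s_bg, model.prior_fg, model.prior_bg, lik_fg, lik_bg)


def fit_bernoulli_params(assay: pd.DataFrame, kinase_id: str,
                         features: pd.DataFrame) -> dict:
    """Laplace-smoothed Bernoulli parameters per feature.

    ``features`` is indexed by site_id with one boolean column per feature.
    theta_fg is the smoothed fraction of the kinase's positive sites with
    the flag set ((k+1)/(n+2)); theta_bg likewise over negatives.
    """
    rows = assay[assay["kinase_id"] == kinase_id]
    pos_sites = rows.loc[rows["phosphorylated"].astype(bool), "site_id"]
    neg_sites = rows.loc[~rows["phosphorylated"].astype(bool), "site_id"]
    params = {}
    for feat in features.columns:
        fpos = features.loc[features.index.intersection(pos_sites), feat].astype(bool)
        fneg = features.loc[features.index.intersection(neg_sites), feat].astype(bool)
        theta_fg = (fpos.sum() + 1.0) / (len(fpos) + 2.0)
        theta_bg = (fneg.sum() + 1.0) / (len(fneg) + 2.0)
        params[feat] = (theta_fg, theta_bg)
    return params


def fit_nb_model(assay: pd.DataFrame, site_windows: dict, kinase_id: str,
                 background: spec.BackgroundModel | None = None,
                 pseudocount_mass="sqrt", henikoff: bool = True,
                 features: pd.DataFrame | None = None,
                 kinase_type: str | None = None) -> NaiveBayesModel:
    """Fit a Naive Bayes sub-model for one kinase from a shared-pool assay.

    ``assay`` is a long table with columns kinase_id, site_id,
    phosphorylated; ``site_windows`` maps site_id to a SequenceWindow.  The
    background defaults to position-specific frequencies of all assayed
    windows (phosphoproteome background).  Pass ``features`` (site_id-indexed
    boolean frame) to also fit Bernoulli parameters for the "+" model.
    Kinases with fewer than 20 substrates are modellable but flagged with a
    warning; evaluation conventionally restricts to >= 20.
    """
    prior_fg, prior_bg = estimate_priors(assay, kinase_id)
    rows = assay[assay["kinase_id"] == kinase_id]
    pos_sites = rows.loc[rows["phosphorylated"].astype(bool), "site_id"].tolist()
    neg_sites = rows.loc[~rows["phosphorylated"].astype(bool), "site_id"].tolist()
    if not neg_sites:
        raise UnmodellableKinase(f"kinase {kinase_id} has no negative substrates")
    if len(pos_sites) < MIN_SUBSTRATES_EVAL:
        logger.warning("kinase %s modelled from only %d substrates (< %d)",
                       kinase_id, len(pos_sites), MIN_SUBSTRATES_EVAL)
    if background is None:
        background = spec.BackgroundModel.from_windows(
            [site_windows[s] for s in rows["site_id"]])
    fg_windows = [site_windows[s] for s in pos_sites]
    bg_windows = [site_windows[s] for s in neg_sites]
    fg_w = spec.sequence_weights(fg_windows) if henikoff and len(fg_windows) > 1 else None
    bg_w = spec.sequence_weights(bg_windows) if henikoff and len(bg_windows) > 1 else None
    fg_pfm = spec.build_pfm(fg_windows, fg_w, pseudocount_mass, background, kinase_id)
    bg_pfm = spec.build_pfm(bg_windows, bg_w, pseudocount_mass, background, kinase_id)
    params = fit_bernoulli_params(assay, kinase_id, features) if features is not None else None
    return NaiveBayesModel(
        kinase_id=kinase_id, fg_pfm=fg_pfm, bg_pfm=bg_pfm,
        prior_fg=prior_fg, prior_bg=prior_bg,
        bernoulli_params=params, n_substrates=len(pos_sites),
        kinase_type=kinase_type,
    )


def domain_enrichment(fg_proteins, protein_domains: dict, pool_proteins,
                      alpha: float = 0.05) -> set:
    """Domains enriched in a foreground protein set versus the pool.

    One-sided Fisher exact (enrichment) per domain, domains deduplicated
    per protein (presence/absence), Benjamini-Hochberg adjustment across
    domains; returns domains with adjusted p < alpha.
    """
    fg = set(fg_proteins)
    pool = set(pool_proteins)
    if not fg:
        return set()
    if not fg <= pool:
        raise InputError("foreground proteins must be a subset of the pool")
    rest = pool - fg
    domains = sorted({d for p in pool for d in protein_domains.get(p, ())})
    if not domains:
        return set()
    pvals = []
    for d in domains:
        a = sum(1 for p in fg if d in protein_domains.get(p, ()))
        b = len(fg) - a
        c = sum(1 for p in rest if d in protein_domains.get(p, ()))
        dd = len(rest) - c
        _, p = fisher_exact([[a, b], [c, dd]], alternative="greater")
        pvals.append(p)
    _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    return {d for d, q in zip(domains, adjusted) if q < alpha}


def interactors_within(graph: nx.Graph, kinase_id: str, max_distance: int = 2) -> set:
    """Nodes within graph distance <= max_distance of the kinase."""
    if kinase_id not in graph:
        return set()
    lengths = nx.single_source_shortest_path_length(graph, kinase_id,
                                                    cutoff=max_distance)
    return set(lengths) - {kinase_id}


def compute_site_features(kinase_id: str, site: win.Phosphosite,
                          interactions: nx.Graph,
                          domain_intervals: pd.DataFrame,
                          enriched_substrate_domains: set,
                          enriched_interactor_domains: set,
                          protein_domains: dict | None = None,
                          max_distance: int = 2) -> SiteFeatures:
    """Binary context features for one (kinase, site) pair.

    ``domain_intervals`` has columns protein_id, domain_id, start, end
    (1-based, inclusive ends).  Unknown proteins yield all-false flags with
    a logged warning.
    """
    protein = site.protein_id
    rows = domain_intervals[domain_intervals["protein_id"] == protein]
    if protein_domains is not None:
        pdoms = set(protein_domains.get(protein, ()))
    else:
        pdoms = set(rows["domain_id"])
    known = protein in interactions or len(rows) > 0 or bool(pdoms)
    if not known:
        logger.warning("protein %s unknown to interaction/domain data; "
                       "features default to false", protein)
        return SiteFeatures()
    interactor = protein in interactors_within(interactions, kinase_id, max_distance)
    in_domain = bool(((rows["start"] <= site.position)
                      & (site.position <= rows["end"])).any())
    return SiteFeatures(
        interactor=interactor,
        domain_enriched_substrates=bool(pdoms & enriched_substrate_domains),
        domain_enriched_interactors=bool(pdoms & enriched_interactor_domains),
        in_domain=in_domain,
    )
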