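"""Kinase-activity inference from quantitative phosphoproteomics.

Given per-condition log2 fold changes of phosphosites and a set of
kinase-site assignments, a kinase's activity in a condition is scored by a
two-sided Z-test of its assigned substrates' mean fold change against the
condition-wide mean, signed by the direction of the shift:

    Z = (xbar_sub - xbar_all) * sqrt(m) / sd_all
    activity = -log10(p) * sgn(xbar_sub - xbar_all)

with m the number of assigned, quantified substrates.  This is the
one-sample KSEA-style form; a two-sample variant is selectable.  A kinase
whose substrates are significantly down-shifted gets a large negative
activity (expected under inhibition of that kinase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InputError, PipelineError

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300

TAG_DIRECT = "direct target"
TAG_ACTIVATED = "activated downstream"
TAG_INHIBITED = "inhibited downstream"
TAG_OTHER = "other"

#: expected sign of activity under inhibition of the condition's targets
EXPECTED_SIGN = {TAG_DIRECT: -1, TAG_ACTIVATED: -1, TAG_INHIBITED: +1, TAG_OTHER: 0}


@dataclass(frozen=True)
class ActivityScore:
    kinase_id: str | None
    condition: str | None
    n_substrates_used: int
    mean_fc: float
    p_value: float
    activity: float


def filter_quant(raw: pd.DataFrame) -> pd.DataFrame:
    """Reduce a long quant table to one complete peptide per phosphosite.

    ``raw`` has columns site_id, peptide_id, condition, log2fc.  Peptides
    missing any condition are dropped first; among a site's remaining
    peptides the one with the greatest dynamic range (max - min across
    conditions) is retained, ties broken lexicographically by peptide_id
    (logged).  Returns a wide frame indexed by site_id with one column per
    condition.
    """
    required = {"site_id", "peptide_id", "condition", "log2fc"}
    if not required <= set(raw.columns):
        raise InputError(f"quant table must have columns {sorted(required)}")
    wide = raw.pivot_table(index=["site_id", "peptide_id"], columns="condition",
                           values="log2fc", aggfunc="first", dropna=False)
    wide = wide.dropna(axis=0, how="any")
    if len(wide) == 0:
        raise PipelineError("no complete peptides after missing-data filtering")
    rng_ = wide.max(axis=1) - wide.min(axis=1)
    chosen = []
    for site, grp in rng_.groupby(level="site_id"):
        best = grp.max()
        cands = sorted(pid for (_, pid), v in grp.items() if v == best)
        if len(cands) > 1:
            logger.info("site %s: dynamic-range tie among peptides %s; "
                        "keeping %s", site, cands, cands[0])
        chosen.append((site, cands[0]))
    out = wide.loc[chosen]
    out.index = out.index.droplevel("peptide_id")
    out.columns.name = None
    return out


def infer_activity(assigned_fcs, all_fcs, kinase_id: str | None = None,
                   condition: str | None = None,
                   two_sample: bool = False) -> ActivityScore | None:
    """Signed -log10(p) activity of one kinase in one condition.

    ``assigned_fcs``: fold changes of the kinase's assigned substrates;
    ``all_fcs``: the condition-wide fold-change vector (reference).  With
    no quantified substrates the score is undefined and None is returned
    (reported as missing, never 0).
    """
    sub = np.asarray(assigned_fcs, dtype=float)
    allv = np.asarray(all_fcs, dtype=float)
    m = len(sub)
    if m == 0:
        logger.info("kinase %s / condition %s: no quantified substrates; "
                    "activity undefined", kinase_id, condition)
        return None
    sd_all = float(np.std(allv))
    if sd_all == 0:
        raise InputError("condition-wide fold changes have zero variance")
    mean_sub = float(sub.mean())
    mean_all = float(allv.mean())
    diff = mean_sub - mean_all
    if two_sample:
        se = sd_all * np.sqrt(1.0 / m + 1.0 / len(allv))
        z = diff / se
    else:
        z = diff * np.sqrt(m) / sd_all
    p = max(2.0 * norm.sf(abs(z)), P_FLOOR)
    activity = -np.log10(p) * np.sign(diff)
    return ActivityScore(kinase_id, condition, m, mean_sub, float(p), float(activity))


def tag_kinase(kinase_id: str, targets, regulatory_edges: pd.DataFrame | None) -> str:
    """Tag a kinase relative to a condition's inhibited target list.

    ``regulatory_edges`` has columns source, target, sign (+1 activating,
    -1 inhibiting); a kinase activated (inhibited) by an inhibited target
    is expected to lose (gain) activity.
    """
    if kinase_id in targets:
        return TAG_DIRECT
    if regulatory_edges is not None and len(regulatory_edges):
        down = regulatory_edges[(regulatory_edges["source"].isin(targets))
                                & (regulatory_edges["target"] == kinase_id)]
        if len(down):
            signs = set(down["sign"].astype(int))
            if signs == {1}:
                return TAG_ACTIVATED
            if signs == {-1}:
                return TAG_INHIBITED
            return TAG_OTHER  # conflicting consensus
    return TAG_OTHER


def activity_matrix(assignments: pd.DataFrame, quant: pd.DataFrame,
                    kinase_set, condition_targets: dict,
                    regulatory_edges: pd.DataFrame | None = None,
                    exclude_own_substrates: bool = False) -> pd.DataFrame:
    """Per-kinase, per-condition activity table with expectation tags.

    ``assignments`` has columns kinase_id, site_id, assigned (taken at each
    predictor's nominal cutoff); ``quant`` is the wide output of
    :func:`filter_quant`; ``condition_targets`` maps condition name to the
    kinases inhibited in it.  The reference distribution is the condition's
    full fold-change vector (optionally excluding the kinase's own
    substrates).  Kinases with no quantified substrates appear with NaN
    activity.
    """
    assigned = assignments[assignments["assigned"].astype(bool)]
    sub_sites = {k: set(g["site_id"]) & set(quant.index)
                 for k, g in assigned.groupby("kinase_id")}
    rows = []
    for condition in quant.columns:
        targets = set(condition_targets.get(condition, ()))
        allv = quant[condition].to_numpy(dtype=float)
        for kinase in kinase_set:
            sites = sorted(sub_sites.get(kinase, ()))
            tag = tag_kinase(kinase, targets, regulatory_edges)
            if exclude_own_substrates and sites:
                ref = quant.loc[~quant.index.isin(sites), condition].to_numpy(dtype=float)
            else:
                ref = allv
            score = infer_activity(quant.loc[sites, condition].to_numpy(dtype=float),
                                   ref, kinase, condition)
            rows.append({
                "kinase_id": kinase,
                "condition": condition,
                "tag": tag,
                "expected_sign": EXPECTED_SIGN[tag],
                "n_substrates_used": 0 if score is None else score.n_substrates_used,
                "mean_fc": np.nan if score is None else score.mean_fc,
                "p_value": np.nan if score is None else score.p_value,
                "activity": np.nan if score is None else score.activity,
            })
    return pd.DataFrame(rows)
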