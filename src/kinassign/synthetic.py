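"""Synthetic kinomes, in vitro assays, association data and inhibitor
phosphoproteomics with known ground truth.

The generator emulates a shared-pool in vitro specificity assay: a single
substrate pool is exposed to every kinase, so complete positive *and*
negative labels exist per kinase.  Kinase motifs are planted 15x20 PFMs
with a handful of informative flank columns (sharpness = probability mass
on the preferred residue); Y-kinase motifs put all center mass on Y,
S/T-kinase motifs split the center between S and T.  Some kinases are
grouped into families sharing informative columns, emulating isozymes with
highly similar specificities.  Per-kinase substrate counts follow planted
priors (default 0.01-0.1 of the pool, i.e. 20-200 substrates on the
default pool of 2000 - the reduced-scale analogue of an assay spanning
1-1700 substrates per kinase; the shared pool must be large enough to
hold every kinase's planted substrates plus background windows).

Association data (GO-like semantic similarities, coexpression/experimental
channels), an interaction graph, domain annotations and an
inhibitor-phosphoproteomics quant table are generated from the same ground
truth, with a single ``signal_strength`` dial that collapses every channel
to the null (truth-independent) at 0.

All randomness flows through one seeded numpy Generator; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import specificity as spec
from . import windows as win
from .errors import InputError, ValidationError

WINDOW_LENGTH = 15
CENTER = WINDOW_LENGTH // 2

#: default desk-scale profile
DEFAULT_N_KINASES = 30
DEFAULT_POOL_SIZE = 2000
DEFAULT_SHARPNESS = 0.8
DEFAULT_TYPE_MIX = 0.75  # fraction of S/T kinases
DEFAULT_PRIOR_RANGE = (0.005, 0.05)
DEFAULT_N_INFORMATIVE = 4

#: center-residue mix of background pool windows (S, T, Y)
POOL_CENTER_MIX = (0.50, 0.25, 0.25)

#: planted Bernoulli propensities at unit signal strength (theta_pos, theta_neg)
FEATURE_PROPENSITIES = {
    "interactor": (0.55, 0.08),
    "domain_enriched_substrates": (0.55, 0.10),
    "in_domain": (0.50, 0.20),
}

ASSOC_CHANNELS = ("go_bp", "go_cc", "coexpression", "experimental")


@dataclass
class SyntheticKinase:
    kinase_id: str
    kinase_type: str  # "S/T" | "Y"
    family: int | None
    motif: np.ndarray  # (15, 20) column-stochastic
    prior: float


@dataclass
class SyntheticKinome:
    kinases: list
    seed: int | None = None

    def __post_init__(self):
        for k in self.kinases:
            cols = k.motif.sum(axis=1)
            if not np.allclose(cols, 1.0, atol=1e-9):
                raise ValidationError(f"{k.kinase_id}: motif columns must sum to 1")
            center = k.motif[CENTER]
            y = center[win.AA_INDEX["Y"]]
            st = center[win.AA_INDEX["S"]] + center[win.AA_INDEX["T"]]
            if k.kinase_type == "Y" and not np.isclose(y, 1.0):
                raise ValidationError(f"{k.kinase_id}: Y kinase must center on Y")
            if k.kinase_type == "S/T" and not np.isclose(st, 1.0):
                raise ValidationError(f"{k.kinase_id}: S/T kinase must center on S/T")

    def __iter__(self):
        return iter(self.kinases)

    def __len__(self):
        return len(self.kinases)

    def ids(self):
        return [k.kinase_id for k in self.kinases]

    def registry(self) -> pd.DataFrame:
        """Kinase registry table (kinase_id, kinase_type)."""
        return pd.DataFrame({"kinase_id": self.ids(),
                             "kinase_type": [k.kinase_type for k in self.kinases]})


@dataclass
class GroundTruth:
    """Planted truth of a simulated assay."""

    labels: pd.DataFrame  # sites x kinases boolean
    sites: pd.DataFrame   # site_id, protein_id, position, residue, window
    kinome: SyntheticKinome
    seed_sites: dict      # kinase_id -> list of site_ids drawn from its motif

    @property
    def multiplicity(self) -> pd.Series:
        """Number of kinases truly assigned per site."""
        return self.labels.sum(axis=1)

    def pairs(self) -> set:
        arr = self.labels.to_numpy(dtype=bool)
        return {(self.labels.columns[j], self.labels.index[i])
                for i, j in zip(*np.nonzero(arr))}


def _informative_columns(rng, n_informative):
    flanks = np.array([i for i in range(WINDOW_LENGTH) if i != CENTER])
    return rng.choice(flanks, size=n_informative, replace=False)


def _build_motif(rng, kinase_type, cols, residues, sharpness):
    motif = np.tile(spec.PROTEOME_FREQS, (WINDOW_LENGTH, 1))
    for c, r in zip(cols, residues):
        column = spec.PROTEOME_FREQS * (1.0 - sharpness)
        column = column / column.sum() * (1.0 - sharpness)
        column[r] += sharpness
        motif[c] = column / column.sum()
    center = np.zeros(20)
    if kinase_type == "Y":
        center[win.AA_INDEX["Y"]] = 1.0
    else:
        center[win.AA_INDEX["S"]] = 0.7
        center[win.AA_INDEX["T"]] = 0.3
    motif[CENTER] = center
    return motif


def generate_kinome(n_kinases: int = DEFAULT_N_KINASES,
                    motif_sharpness: float = DEFAULT_SHARPNESS,
                    type_mix: float = DEFAULT_TYPE_MIX,
                    family_fraction: float = 0.4,
                    n_informative: int = DEFAULT_N_INFORMATIVE,
                    prior_range: tuple = DEFAULT_PRIOR_RANGE,
                    seed: int | None = None) -> SyntheticKinome:
    """Generate a kinome of planted motifs, priors and types.

    ``motif_sharpness`` in (0, 1] is the probability mass on the preferred
    residue at informative columns; ``type_mix`` the fraction of S/T
    kinases; roughly ``family_fraction`` of kinases are grouped into
    families of 2-3 members whose motifs share informative columns (small
    per-member perturbation), emulating isozymes.

    ``motif_sharpness`` may also be a ``(lo, hi)`` tuple: per-kinase
    sharpness is then anti-correlated with the planted prior, so kinases
    that phosphorylate a larger share of the common pool have more
    permissive motifs - the mechanistic coupling of a shared-pool assay,
    where substrate counts reflect specificity breadth.
    """
    if n_kinases < 1:
        raise InputError("n_kinases must be >= 1")
    sharpness_range = None
    if isinstance(motif_sharpness, (tuple, list)):
        sharpness_range = (float(motif_sharpness[0]), float(motif_sharpness[1]))
        if not 0 < sharpness_range[0] <= sharpness_range[1] <= 1:
            raise InputError("motif_sharpness range must satisfy 0 < lo <= hi <= 1")
    elif not 0 < motif_sharpness <= 1:
        raise InputError("motif_sharpness must be in (0, 1]")
    if not 0 <= type_mix <= 1:
        raise InputError("type_mix must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_st = int(round(n_kinases * type_mix))
    types = ["S/T"] * n_st + ["Y"] * (n_kinases - n_st)

    # carve family blocks of size 2-3 out of the kinase list
    families = [None] * n_kinases
    fam_id = 0
    i = 0
    n_in_families = int(round(family_fraction * n_kinases))
    while i < n_in_families - 1:
        size = int(rng.integers(2, 4))
        size = min(size, n_in_families - i)
        if size < 2:
            break
        for j in range(i, i + size):
            families[j] = fam_id
        fam_id += 1
        i += size

    kinases = []
    fam_proto = {}
    priors = np.exp(rng.uniform(np.log(prior_range[0]), np.log(prior_range[1]),
                                size=n_kinases))
    if sharpness_range is not None:
        lo, hi = sharpness_range
        ranks = np.argsort(np.argsort(priors))
        frac = ranks / max(n_kinases - 1, 1)
        sharpness_per_kinase = hi - (hi - lo) * frac  # permissive <=> promiscuous
    else:
        sharpness_per_kinase = np.full(n_kinases, float(motif_sharpness))
    for idx in range(n_kinases):
        ktype = types[idx]
        fam = families[idx]
        if fam is not None and (fam, ktype) in fam_proto:
            cols, residues = fam_proto[(fam, ktype)]
            # perturb one informative column's preferred residue
            residues = residues.copy()
            if rng.random() < 0.5:
                residues[int(rng.integers(len(residues)))] = int(rng.integers(20))
        else:
            cols = _informative_columns(rng, n_informative)
            residues = rng.integers(0, 20, size=n_informative)
            if fam is not None:
                fam_proto[(fam, ktype)] = (cols, residues.copy())
        motif = _build_motif(rng, ktype, cols, residues, sharpness_per_kinase[idx])
        kinases.append(SyntheticKinase(
            kinase_id=f"KIN{idx:03d}", kinase_type=ktype, family=fam,
            motif=motif, prior=float(priors[idx])))
    return SyntheticKinome(kinases=kinases, seed=seed)


def _sample_windows(rng, motif, n):
    """Draw n windows column-wise from a motif PFM."""
    out = np.empty((n, WINDOW_LENGTH), dtype=np.int8)
    for j in range(WINDOW_LENGTH):
        out[:, j] = rng.choice(20, size=n, p=motif[j])
    return out


def _pool_background_frequencies() -> np.ndarray:
    """(L, 20) planted background: proteome flanks, S/T/Y center mix."""
    bg = np.tile(spec.PROTEOME_FREQS, (WINDOW_LENGTH, 1))
    center = np.zeros(20)
    center[win.AA_INDEX["S"]], center[win.AA_INDEX["T"]], center[win.AA_INDEX["Y"]] = \
        POOL_CENTER_MIX
    bg[CENTER] = center
    return bg


def planted_posteriors(kinase: SyntheticKinase, encoded: np.ndarray,
                       prior: float) -> np.ndarray:
    """Ground-truth phosphorylation probabilities for pool windows.

    The acceptance model mirrors the assignment model exactly: the
    posterior combines the min-max normalized planted-motif PFM score,
    the normalized pool-background PFM score (both under the motif's
    relative-entropy column weights) and the planted prior.  Labels drawn
    from these probabilities make the nominal 0.5 posterior cutoff the
    Bayes rule for the assay, while sites near the acceptance margin get
    genuinely stochastic labels (the shotgun-detection limit).
    """
    bg_freqs = _pool_background_frequencies()
    background = spec.BackgroundModel("phosphoproteome", bg_freqs)
    fg = spec.matrix_from_frequencies(kinase.motif, background)
    bg = spec.matrix_from_frequencies(bg_freqs, background)
    s_fg = fg.score_normalized_many(encoded)
    s_bg = bg.with_column_weights(fg.column_weights).score_normalized_many(encoded)
    num = s_fg * prior
    den = num + s_bg * (1.0 - prior)
    return np.where(den == 0, 0.0, num / np.where(den == 0, 1.0, den))


def simulate_assay(kinome: SyntheticKinome, pool_size: int = DEFAULT_POOL_SIZE,
                   substrates_per_kinase_range: tuple | None = None,
                   seed: int | None = None):
    """Simulate a shared-pool in vitro assay.

    The pool mixes, per kinase, windows drawn from its planted motif with
    background windows (iid proteome residues, S/T/Y centers).  Each site
    is phosphorylated by a kinase independently with probability equal to
    its planted posterior (see :func:`planted_posteriors`): motif-matched
    windows are accepted at far higher rates than mismatched ones, family
    members cross-react, the expected positive count tracks
    prior * pool_size, and borderline matches get genuinely stochastic
    labels - emulating the random sampling limits of shotgun proteomics.

    Returns ``(assay, truth)``: a long label table (kinase_id, site_id,
    protein_id, position, residue, phosphorylated) complete over the pool,
    and a :class:`GroundTruth`.
    """
    rng = np.random.default_rng(seed)
    n_kin = len(kinome)
    if substrates_per_kinase_range is not None:
        lo, hi = substrates_per_kinase_range
        if not 1 <= lo <= hi <= pool_size:
            raise InputError("infeasible substrates_per_kinase_range")
        counts = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_kin))
        priors = counts / pool_size
    else:
        priors = np.array([k.prior for k in kinome])
    n_seed = np.maximum(np.round(priors * pool_size).astype(int), 1)
    # every kinase's planted substrates must fit in the shared pool with
    # room left for background windows
    if n_seed.sum() > 0.85 * pool_size:
        raise InputError(
            f"infeasible design: planted substrates ({int(n_seed.sum())}) "
            f"overfill the shared pool of {pool_size} sites; enlarge the "
            "pool or lower priors/substrate counts")

    blocks = []
    owners = []
    for k, ns in zip(kinome, n_seed):
        blocks.append(_sample_windows(rng, k.motif, int(ns)))
        owners.extend([k.kinase_id] * int(ns))
    n_bg = pool_size - int(n_seed.sum())
    if n_bg > 0:
        bg = np.empty((n_bg, WINDOW_LENGTH), dtype=np.int8)
        for j in range(WINDOW_LENGTH):
            bg[:, j] = rng.choice(20, size=n_bg, p=spec.PROTEOME_FREQS)
        centers = rng.choice([win.AA_INDEX["S"], win.AA_INDEX["T"], win.AA_INDEX["Y"]],
                             size=n_bg, p=POOL_CENTER_MIX)
        bg[:, CENTER] = centers
        blocks.append(bg)
        owners.extend([None] * n_bg)
    enc = np.vstack(blocks)
    perm = rng.permutation(pool_size)
    enc = enc[perm]
    owners = [owners[i] for i in perm]

    site_ids = [f"site{i:05d}" for i in range(pool_size)]
    protein_ids = [f"PROT{i:05d}" for i in range(pool_size)]
    windows = [win.decode_window(enc[i]) for i in range(pool_size)]
    sites = pd.DataFrame({
        "site_id": site_ids,
        "protein_id": protein_ids,
        "position": CENTER + 1,
        "residue": [w[CENTER] for w in windows],
        "window": windows,
    })
    seed_sites = {k.kinase_id: [] for k in kinome}
    for sid, owner in zip(site_ids, owners):
        if owner is not None:
            seed_sites[owner].append(sid)

    labels = pd.DataFrame(False, index=site_ids, columns=kinome.ids())
    for k, prior in zip(kinome, priors):
        p = planted_posteriors(k, enc, prior)
        labels[k.kinase_id] = rng.random(pool_size) < p

    long = labels.reset_index(names="site_id").melt(
        id_vars="site_id", var_name="kinase_id", value_name="phosphorylated")
    assay = long.merge(sites[["site_id", "protein_id", "position", "residue"]],
                       on="site_id")
    assay["phosphorylated"] = assay["phosphorylated"].astype(int)
    assay = assay[["kinase_id", "site_id", "protein_id", "position",
                   "residue", "phosphorylated"]]
    truth = GroundTruth(labels=labels, sites=sites, kinome=kinome,
                        seed_sites=seed_sites)
    return assay, truth


def thin_detected_substrates(assay: pd.DataFrame, truth: GroundTruth,
                             target_counts: dict, seed: int | None = None):
    """Randomly thin each kinase's detected substrates to a target count.

    Emulates the stochastic-detection limit of shotgun proteomics: a
    kinase's *detected* substrate set is a random subset of the sites it
    actually phosphorylated, so kinases end up with widely varying
    training-set sizes for identical underlying promiscuity.  Kinases
    whose current positive count is at or below the target are left
    untouched.  Returns a new (assay, truth) pair.
    """
    rng = np.random.default_rng(seed)
    labels = truth.labels.copy()
    assay = assay.copy()
    for kid, target in target_counts.items():
        pos = labels.index[labels[kid]].to_numpy()
        if len(pos) <= target:
            continue
        keep = set(rng.choice(pos, size=int(target), replace=False))
        dropped = [s for s in pos if s not in keep]
        labels.loc[dropped, kid] = False
        assay.loc[(assay["kinase_id"] == kid)
                  & (assay["site_id"].isin(dropped)), "phosphorylated"] = 0
    truth2 = GroundTruth(labels=labels, sites=truth.sites, kinome=truth.kinome,
                         seed_sites=truth.seed_sites)
    return assay, truth2


def calibration_probe_windows(kinase: SyntheticKinase, n_levels: int = 40,
                              n_per_level: int = 5,
                              seed: int | None = None) -> list:
    """Windows with graded motif match for score-calibration analyses.

    Samples windows from geometric interpolations motif^t * background^(1-t)
    for t on a grid in [0, 1], so scores and posteriors span the whole
    transition from background-like to fully motif-matched - the support a
    logistic calibration fit needs (a shared substrate pool contains almost
    no partially matched windows).
    """
    rng = np.random.default_rng(seed)
    bg = np.maximum(_pool_background_frequencies(), spec.BACKGROUND_FLOOR)
    bg = bg / bg.sum(axis=1, keepdims=True)
    motif = np.maximum(kinase.motif, spec.BACKGROUND_FLOOR)
    motif = motif / motif.sum(axis=1, keepdims=True)
    out = []
    for t in np.linspace(0.0, 1.0, n_levels):
        mix = np.exp(t * np.log(motif) + (1.0 - t) * np.log(bg))
        mix = mix / mix.sum(axis=1, keepdims=True)
        enc = np.empty((n_per_level, WINDOW_LENGTH), dtype=np.int8)
        for j in range(WINDOW_LENGTH):
            enc[:, j] = rng.choice(20, size=n_per_level, p=mix[j])
        out.extend(win.window_from_string(win.decode_window(enc[i]))
                   for i in range(n_per_level))
    return out


def validate_shared_pool(assay: pd.DataFrame) -> None:
    """Raise if kinases were not assayed on one shared substrate pool."""
    pools = assay.groupby("kinase_id")["site_id"].apply(frozenset)
    if len(set(pools)) != 1:
        raise ValidationError("assay violates the shared-pool contract: "
                              "kinases were assayed on different site sets")


@dataclass
class AssociationBundle:
    """Synthetic in vivo context generated from assay ground truth."""

    association: pd.DataFrame      # kinase_id, protein_id, channel, score
    edges: pd.DataFrame            # protein_a, protein_b interaction edges
    domain_annotations: pd.DataFrame  # protein_id, domain_id, start, end
    protein_domains: dict          # protein_id -> set of domain ids
    quant: pd.DataFrame            # site_id, peptide_id, condition, log2fc
    condition_targets: dict        # condition -> list of inhibited kinases
    regulatory_edges: pd.DataFrame  # source, target, sign
    signal_strength: float
    inhibition_effect: float
    feature_flags: pd.DataFrame | None = field(default=None)


def _theta(feature, strength):
    pos, neg = FEATURE_PROPENSITIES[feature]
    return neg + strength * (pos - neg), neg


def simulate_association_and_quant(truth: GroundTruth,
                                   signal_strength: float = 1.0,
                                   inhibition_design: list | None = None,
                                   effect: float = -1.0,
                                   noise_sd: float = 0.5,
                                   n_decoy_domains: int = 20,
                                   seed: int | None = None) -> AssociationBundle:
    """Generate association scores, interactions, domains and quant data.

    True (kinase, substrate) pairs receive stochastically elevated
    association scores and interaction/domain propensities controlled by
    ``signal_strength``; at 0 every channel is independent of the truth.
    The quant table simulates one inhibitor condition per designed target
    kinase: true substrates of inhibited kinases are shifted by ``effect``
    on top of Gaussian noise (sd ``noise_sd``).
    """
    if not 0 <= signal_strength <= 1:
        raise InputError("signal_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    kinome = truth.kinome
    labels = truth.labels
    sites = truth.sites
    kin_ids = list(labels.columns)
    proteins = sites["protein_id"].tolist()
    site_to_protein = dict(zip(sites["site_id"], sites["protein_id"]))
    truth_arr = labels.to_numpy(dtype=bool).T  # kinases x sites(==proteins)
    n_kin, n_prot = truth_arr.shape

    # association channels: Beta scores with strength-controlled separation
    a0, b0, gain = 1.5, 5.0, 8.0
    frames = []
    for channel in ASSOC_CHANNELS:
        a = a0 + gain * signal_strength * truth_arr
        scores = rng.beta(a, b0)
        frames.append(pd.DataFrame({
            "kinase_id": np.repeat(kin_ids, n_prot),
            "protein_id": np.tile(proteins, n_kin),
            "channel": channel,
            "score": scores.ravel(),
        }))
    association = pd.concat(frames, ignore_index=True)

    # interaction graph: kinase-protein edges with planted propensities
    th_pos, th_neg = _theta("interactor", signal_strength)
    edge_p = np.where(truth_arr, th_pos, th_neg)
    edge_mask = rng.random(edge_p.shape) < edge_p
    ka, pa = np.nonzero(edge_mask)
    edges = pd.DataFrame({"protein_a": [kin_ids[i] for i in ka],
                          "protein_b": [proteins[j] for j in pa]})

    # domains: one signature domain per kinase plus random decoys
    protein_domains = {p: set() for p in proteins}
    annotations = []
    th_pos, th_neg = _theta("domain_enriched_substrates", signal_strength)
    sig_p = np.where(truth_arr, th_pos, th_neg)
    sig_mask = rng.random(sig_p.shape) < sig_p
    for i, kid in enumerate(kin_ids):
        dom = f"DOM_SIG_{kid}"
        for j in np.nonzero(sig_mask[i])[0]:
            protein_domains[proteins[j]].add(dom)
    n_rand = rng.poisson(0.8, size=n_prot)
    for j, p in enumerate(proteins):
        for d in rng.integers(0, n_decoy_domains, size=n_rand[j]):
            protein_domains[p].add(f"DOM{d:03d}")

    # in-domain intervals: center position 8 covered or not
    th_pos, th_neg = _theta("in_domain", signal_strength)
    any_substrate = truth_arr.any(axis=0)
    p_in = np.where(any_substrate, th_pos, th_neg)
    in_mask = rng.random(n_prot) < p_in
    for j, p in enumerate(proteins):
        doms = sorted(protein_domains[p])
        if in_mask[j]:
            dom = doms[0] if doms else f"DOM{int(rng.integers(n_decoy_domains)):03d}"
            protein_domains[p].add(dom)
            annotations.append((p, dom, 4, 12))
        elif doms:
            annotations.append((p, doms[0], 1, 5))
    domain_annotations = pd.DataFrame(
        annotations, columns=["protein_id", "domain_id", "start", "end"])

    # regulatory edges among kinases (signed), sparse random
    reg_rows = []
    for i, src in enumerate(kin_ids):
        for tgt in rng.choice(kin_ids, size=2, replace=False):
            if tgt != src:
                reg_rows.append((src, tgt, int(rng.choice([1, 1, -1]))))
    regulatory_edges = pd.DataFrame(reg_rows, columns=["source", "target", "sign"])

    # inhibitor phosphoproteomics
    if inhibition_design is None:
        st = [k.kinase_id for k in kinome if k.kinase_type == "S/T"][:5]
        inhibition_design = [(f"inhib_{k}", [k], effect) for k in st]
    site_ids = sites["site_id"].tolist()
    quant_rows = []
    condition_targets = {}
    for condition, targets, eff in inhibition_design:
        condition_targets[condition] = list(targets)
        fc = rng.normal(0.0, noise_sd, size=n_prot)
        for t in targets:
            fc = fc + eff * labels[t].to_numpy(dtype=float)
        quant_rows.append(pd.DataFrame({
            "site_id": site_ids,
            "peptide_id": [f"pep_{s}_a" for s in site_ids],
            "condition": condition,
            "log2fc": fc,
        }))
        # second, noisier peptide for a subset of sites (exercises filtering)
        extra = rng.random(n_prot) < 0.1
        quant_rows.append(pd.DataFrame({
            "site_id": np.array(site_ids)[extra],
            "peptide_id": [f"pep_{s}_b" for s in np.array(site_ids)[extra]],
            "condition": condition,
            "log2fc": fc[extra] + rng.normal(0, 0.05, size=int(extra.sum())),
        }))
    quant = pd.concat(quant_rows, ignore_index=True)
    # MCAR dropout on the secondary peptides
    b_mask = quant["peptide_id"].str.endswith("_b")
    drop = b_mask & (rng.random(len(quant)) < 0.05)
    quant.loc[drop, "log2fc"] = np.nan

    return AssociationBundle(
        association=association, edges=edges,
        domain_annotations=domain_annotations, protein_domains=protein_domains,
        quant=quant, condition_targets=condition_targets,
        regulatory_edges=regulatory_edges,
        signal_strength=signal_strength, inhibition_effect=effect,
    )
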