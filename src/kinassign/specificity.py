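"""Position-specific kinase specificity models.

Builds weighted, pseudocounted position frequency matrices (PFMs) and
log-odds position-specific scoring matrices (PSSMs) from aligned substrate
windows, with relative-entropy column weights and min-max normalized
scores.

The construction pipeline is:

1. *Sequence weighting* (Henikoff position-based weights) down-weights
   redundant substrate windows so shared evolutionary history does not
   masquerade as specificity.
2. *Weighted counting* per column over the 20-letter alphabet.
3. *Position-specific pseudocounts* proportional to the background
   distribution at each column, with total mass ``B = sqrt(N_eff)`` per
   column by default; pad-symbol counts at a column (sites near protein
   termini) are redistributed as additional background-proportional
   pseudocount mass, so terminal sites are neither rewarded nor punished.
4. *Column weights*: the relative entropy (KL divergence, bits) of each
   PFM column versus the background, giving well-resolved positions more
   scoring weight than degenerate ones.
5. *Scoring*: PSSMs accumulate weighted log-odds; PFMs accumulate weighted
   log frequencies (equivalently a weighted product of frequencies).
   Scores are min-max normalized against the theoretical extremes so every
   kinase shares the [0, 1] range; PFM scores are normalized in the linear
   (probability) domain so they can serve as likelihoods, PSSM scores in
   the log-odds domain.

All logarithms are base 2 (bits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import windows as win
from .errors import InputError, NormalizationError

BACKGROUND_FLOOR = 1e-6
PROP_PSEUDOCOUNT_FRACTION = 0.05

ROLE_PFM = "pfm"
ROLE_PSSM_PROTEOME = "pssm-proteome"
ROLE_PSSM_PHOSPHO = "pssm-phospho"

# Typical eukaryotic proteome residue frequencies (order: ACDEFGHIKLMNPQRSTVWY)
PROTEOME_FREQS = np.array([
    0.0702, 0.0230, 0.0473, 0.0710, 0.0365, 0.0658, 0.0263, 0.0433,
    0.0573, 0.0996, 0.0213, 0.0359, 0.0631, 0.0477, 0.0564, 0.0833,
    0.0536, 0.0597, 0.0122, 0.0266,
])
PROTEOME_FREQS = PROTEOME_FREQS / PROTEOME_FREQS.sum()


def _smooth(freqs: np.ndarray) -> np.ndarray:
    """Floor frequencies at BACKGROUND_FLOOR and renormalize rows."""
    out = np.maximum(np.asarray(freqs, dtype=float), BACKGROUND_FLOOR)
    return out / out.sum(axis=-1, keepdims=True)


@dataclass
class BackgroundModel:
    """Residue background: global (proteome) or per-position (phosphoproteome).

    ``frequencies`` is a (20,) vector for a proteome background or an
    (L, 20) matrix of position-specific frequencies estimated from the full
    set of observed sequence windows.
    """

    kind: str  # "proteome" | "phosphoproteome"
    frequencies: np.ndarray

    def __post_init__(self):
        self.frequencies = _smooth(self.frequencies)

    @property
    def positional(self) -> bool:
        return self.frequencies.ndim == 2

    def column(self, i: int) -> np.ndarray:
        return self.frequencies[i] if self.positional else self.frequencies

    def matrix(self, length: int) -> np.ndarray:
        """Background as an (L, 20) matrix regardless of kind."""
        if self.positional:
            if self.frequencies.shape[0] != length:
                raise InputError("background length mismatch")
            return self.frequencies
        return np.tile(self.frequencies, (length, 1))

    @classmethod
    def presmoothed(cls, kind: str, frequencies: np.ndarray) -> "BackgroundModel":
        """Rebuild from already-smoothed frequencies without re-smoothing.

        Used by model persistence so that loading reproduces scores
        bit-identically (re-smoothing perturbs the last ulp).
        """
        obj = cls.__new__(cls)
        obj.kind = kind
        obj.frequencies = np.asarray(frequencies, dtype=float)
        return obj

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls("proteome", np.full(20, 1.0 / 20))

    @classmethod
    def proteome_default(cls) -> "BackgroundModel":
        return cls("proteome", PROTEOME_FREQS.copy())

    @classmethod
    def from_sequences(cls, sequences) -> "BackgroundModel":
        counts = np.zeros(20)
        for seq in sequences:
            for ch in win.sanitize_sequence(seq):
                idx = win.AA_INDEX.get(ch)
                if idx is not None:
                    counts[idx] += 1
        if counts.sum() == 0:
            raise InputError("no standard residues in background sequences")
        return cls("proteome", counts / counts.sum())

    @classmethod
    def from_windows(cls, windows) -> "BackgroundModel":
        """Position-specific frequencies from observed windows (phosphoproteome)."""
        enc = win.encode_windows(windows)
        L = enc.shape[1]
        counts = np.zeros((L, 20))
        for a in range(20):
            counts[:, a] = (enc == a).sum(axis=0)
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            # all-pad column: fall back to uniform
            counts[totals[:, 0] == 0] = 1.0
            totals = counts.sum(axis=1, keepdims=True)
        return cls("phosphoproteome", counts / totals)


def sequence_weights(windows) -> np.ndarray:
    """Henikoff position-based weights for a set of same-length windows.

    Each column contributes 1/(r*s) to a sequence's weight, where r is the
    number of distinct symbols in the column and s the count of the
    sequence's own symbol there.  Pad and unknown symbols participate as
    ordinary symbols.  Weights are normalized to sum to the number of
    windows, so identical windows all get weight 1.
    """
    enc = win.encode_windows(windows)
    n, L = enc.shape
    weights = np.zeros(n)
    for j in range(L):
        col = enc[:, j]
        symbols, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        r = len(symbols)
        weights += 1.0 / (r * counts[inverse])
    return weights * (n / weights.sum())


def column_relative_entropy(p: np.ndarray, q: np.ndarray, log_base: float = 2.0) -> float:
    """Kullback-Leibler divergence sum(p*log(p/q)); zero iff p == q."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise InputError("background column must be strictly positive (pre-smoothed)")
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(p[mask] / q[mask]) / np.log(log_base))))


def _column_weights(freqs: np.ndarray, bg: np.ndarray,
                    n_eff: np.ndarray | None) -> np.ndarray:
    """Relative-entropy column weights with small-sample bias correction.

    The plug-in KL divergence of an estimated frequency column versus its
    background is biased upward by about (k-1)/(2 n ln 2) bits for k
    residue categories and n observations (Miller-Madow), which would
    spuriously weight every column of a small training set.  The
    correction is subtracted (floored at zero); columns with no counts
    keep zero weight.
    """
    L = freqs.shape[0]
    kl = np.array([column_relative_entropy(freqs[i], bg[i]) for i in range(L)])
    if n_eff is None:
        return kl
    n = np.maximum(np.asarray(n_eff, dtype=float), 1.0)
    bias = (freqs.shape[1] - 1) / (2.0 * n * np.log(2.0))
    corrected = np.maximum(kl - bias, 0.0)
    # degenerate guard: an all-zero weight vector would collapse the
    # score range, so fall back to uncorrected weights
    return corrected if corrected.sum() > 0 else kl


@dataclass
class SpecificityMatrix:
    """A kinase specificity model: PFM (frequencies) or PSSM (log-odds).

    ``values`` is (L, 20): per-position residue frequencies for the PFM
    role, log2 odds versus background for PSSM roles.  ``column_weights``
    multiply columns at scoring time.  ``theoretical_min``/``max`` are the
    extreme raw scores (weighted log domain).  ``pad_base`` is the
    *unweighted* per-column contribution of a pad/unknown symbol (the
    column's expected log frequency under the background for PFMs, exactly
    zero log-odds for PSSMs); the effective pad score is
    ``column_weights * pad_base``, so terminal sites are neither rewarded
    nor punished.
    """

    kinase_id: str | None
    role: str
    values: np.ndarray
    column_weights: np.ndarray
    pad_base: np.ndarray
    theoretical_min: float
    theoretical_max: float
    n_substrates: int = 0
    effective_counts: np.ndarray | None = None
    _table: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def pad_scores(self) -> np.ndarray:
        return self.column_weights * self.pad_base

    def base_values(self) -> np.ndarray:
        """Unweighted per-column scores: log2 frequencies (PFM) or log-odds."""
        return np.log2(self.values) if self.role == ROLE_PFM else self.values

    def with_column_weights(self, column_weights: np.ndarray) -> "SpecificityMatrix":
        """Copy of this matrix scored under different column weights.

        Used by the Naive Bayes layer, which applies the *foreground*
        model's weights to both likelihood terms so the two normalized
        scores stay commensurable.  Theoretical extremes are recomputed.
        """
        column_weights = np.asarray(column_weights, dtype=float)
        if column_weights.shape != (self.length,) or np.any(column_weights < 0):
            raise InputError("column weights must be nonnegative, one per column")
        scored = column_weights[:, None] * self.base_values()
        return SpecificityMatrix(
            kinase_id=self.kinase_id, role=self.role, values=self.values,
            column_weights=column_weights, pad_base=self.pad_base,
            theoretical_min=float(scored.min(axis=1).sum()),
            theoretical_max=float(scored.max(axis=1).sum()),
            n_substrates=self.n_substrates,
            effective_counts=self.effective_counts,
        )

    def score_table(self) -> np.ndarray:
        """(L, 22) per-symbol raw score contributions (cached)."""
        if self._table is None:
            L = self.length
            table = np.empty((L, win.N_SYMBOLS))
            table[:, :20] = self.column_weights[:, None] * self.base_values()
            table[:, win.PAD_CODE] = self.pad_scores
            table[:, win.UNKNOWN_CODE] = self.pad_scores
            self._table = table
        return self._table

    def score(self, window) -> float:
        """Raw score of one window (weighted per-column accumulation)."""
        codes = window if isinstance(window, np.ndarray) else win.encode_window(window)
        if codes.shape[0] != self.length:
            raise InputError("window length does not match matrix")
        return float(self.score_table()[np.arange(self.length), codes].sum())

    def score_many(self, encoded: np.ndarray) -> np.ndarray:
        """Raw scores for an (n, L) array of encoded windows."""
        if encoded.ndim != 2 or encoded.shape[1] != self.length:
            raise InputError("encoded window array shape mismatch")
        return self.score_table()[np.arange(self.length)[None, :], encoded].sum(axis=1)

    def normalize(self, raw):
        """Min-max normalize raw score(s) into [0, 1].

        PSSM scores are normalized linearly in the log-odds domain.  PFM
        scores are normalized in the linear (probability) domain so that
        the result behaves as a likelihood: s = (2^raw - 2^min)/(2^max - 2^min),
        computed stably relative to the maximum.  Pad-containing windows
        are clipped into [0, 1].
        """
        tmin, tmax = self.theoretical_min, self.theoretical_max
        if not tmax > tmin:
            raise NormalizationError(
                f"degenerate matrix for {self.kinase_id}: min == max == {tmax}"
            )
        raw = np.asarray(raw, dtype=float)
        if self.role == ROLE_PFM:
            lo = np.exp2(tmin - tmax)
            s = (np.exp2(raw - tmax) - lo) / (1.0 - lo)
        else:
            s = (raw - tmin) / (tmax - tmin)
        return float(np.clip(s, 0.0, 1.0)) if s.ndim == 0 else np.clip(s, 0.0, 1.0)

    def score_normalized(self, window) -> float:
        return self.normalize(self.score(window))

    def score_normalized_many(self, encoded: np.ndarray) -> np.ndarray:
        return self.normalize(self.score_many(encoded))


def minmax_normalize(matrix: SpecificityMatrix, raw_score):
    """Min-max normalize a raw score against the matrix's theoretical range."""
    return matrix.normalize(raw_score)


def build_pfm(windows, weights=None, pseudocount_mass="sqrt",
              background: BackgroundModel | None = None,
              kinase_id: str | None = None) -> SpecificityMatrix:
    """Build a weighted, pseudocounted PFM from substrate windows.

    ``weights``: per-window positive weights (defaults to 1 each; use
    :func:`sequence_weights` for redundancy down-weighting).
    ``pseudocount_mass``: total background-proportional pseudocount mass
    per column; the string ``"sqrt"`` (default) uses sqrt of the column's
    effective (weighted, non-pad) count.  Pad and unknown counts at a
    column are redistributed as additional background-proportional
    pseudocount mass.
    """
    if len(windows) == 0:
        raise InputError("cannot build a PFM from zero windows")
    enc = win.encode_windows(windows)
    n, L = enc.shape
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w <= 0):
            raise InputError("weights must be positive, one per window")
    if background is None:
        background = BackgroundModel.uniform()
    bg = background.matrix(L)

    counts = np.zeros((L, 20))
    for a in range(20):
        counts[:, a] = ((enc == a) * w[:, None]).sum(axis=0)
    pad_mass = (((enc == win.PAD_CODE) | (enc == win.UNKNOWN_CODE))
                * w[:, None]).sum(axis=0)
    n_eff = counts.sum(axis=1)

    if pseudocount_mass == "sqrt":
        base_mass = np.sqrt(n_eff)
        # all-pad columns still need mass so the column falls back to background
        base_mass = np.where(n_eff > 0, base_mass, 1.0)
    elif pseudocount_mass == "prop":
        # mass proportional to the effective count keeps smoothed minimum
        # frequencies (hence theoretical score ranges) stable across
        # training-set sizes
        base_mass = 1.0 + PROP_PSEUDOCOUNT_FRACTION * n_eff
    else:
        base_mass = np.full(L, float(pseudocount_mass))
        if np.any(base_mass <= 0):
            raise InputError("pseudocount_mass must be > 0")
    pseudo = (base_mass + pad_mass)[:, None] * bg
    freqs = counts + pseudo
    freqs = freqs / freqs.sum(axis=1, keepdims=True)

    column_weights = _column_weights(freqs, bg, n_eff)
    logf = np.log2(freqs)
    scored = column_weights[:, None] * logf
    tmin = float(scored.min(axis=1).sum())
    tmax = float(scored.max(axis=1).sum())
    pad_base = (logf * bg).sum(axis=1)  # expected background log-frequency
    return SpecificityMatrix(
        kinase_id=kinase_id,
        role=ROLE_PFM,
        values=freqs,
        column_weights=column_weights,
        pad_base=pad_base,
        theoretical_min=tmin,
        theoretical_max=tmax,
        n_substrates=n,
        effective_counts=n_eff,
    )


def matrix_from_frequencies(freqs: np.ndarray, background: BackgroundModel,
                            kinase_id: str | None = None,
                            n_substrates: int = 0) -> SpecificityMatrix:
    """PFM-role matrix from known per-position frequencies (no counting).

    Frequencies are smoothed to be strictly positive; column weights,
    pad contributions and theoretical extremes follow the same rules as
    :func:`build_pfm`.  Used for planted ground-truth motifs.
    """
    freqs = _smooth(np.asarray(freqs, dtype=float))
    L = freqs.shape[0]
    bg = background.matrix(L)
    column_weights = np.array([
        column_relative_entropy(freqs[i], bg[i]) for i in range(L)
    ])
    logf = np.log2(freqs)
    scored = column_weights[:, None] * logf
    return SpecificityMatrix(
        kinase_id=kinase_id, role=ROLE_PFM, values=freqs,
        column_weights=column_weights, pad_base=(logf * bg).sum(axis=1),
        theoretical_min=float(scored.min(axis=1).sum()),
        theoretical_max=float(scored.max(axis=1).sum()),
        n_substrates=n_substrates,
    )


def build_pssm(pfm: SpecificityMatrix, background: BackgroundModel) -> SpecificityMatrix:
    """Log-odds PSSM of a PFM versus a (smoothed) background model.

    The role is ``pssm-proteome`` for a global background and
    ``pssm-phospho`` for a position-specific (phosphoproteome) background.
    Column weights are the relative entropy of the PFM column versus the
    same background; pad positions contribute exactly zero log-odds.
    """
    if pfm.role != ROLE_PFM:
        raise InputError("build_pssm expects a PFM-role matrix")
    L = pfm.length
    bg = background.matrix(L)
    values = np.log2(pfm.values / bg)
    column_weights = _column_weights(pfm.values, bg, pfm.effective_counts)
    scored = column_weights[:, None] * values
    tmin = float(scored.min(axis=1).sum())
    tmax = float(scored.max(axis=1).sum())
    role = ROLE_PSSM_PHOSPHO if background.positional else ROLE_PSSM_PROTEOME
    return SpecificityMatrix(
        kinase_id=pfm.kinase_id,
        role=role,
        values=values,
        column_weights=column_weights,
        pad_base=np.zeros(L),
        theoretical_min=tmin,
        theoretical_max=tmax,
        n_substrates=pfm.n_substrates,
        effective_counts=pfm.effective_counts,
    )


def score_window(matrix: SpecificityMatrix, window) -> float:
    """Raw score of a window under a specificity matrix."""
    return matrix.score(window)
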