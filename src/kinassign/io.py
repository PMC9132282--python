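"""Readers/writers for tabular and sequence formats, model persistence, config.

Tab-separated values ('#' comments, UTF-8) are the universal tabular
dialect, matching proteomics tooling convention.  Each table kind has a
declared schema (required typed columns plus validators); unknown columns
are preserved and passed through with a warning.  Models persist to an
HDF5 container with one group per kinase plus the trained in vivo
classifier and a schema hash.
"""

from __future__ import annotations

import hashlib
import logging
import pickle
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import naive_bayes as nb
from . import specificity as spec
from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"

#: required columns and dtypes per table kind
SCHEMAS = {
    "phosphosites": {"protein_id": str, "position": int, "residue": str},
    "assay": {"kinase_id": str, "site_id": str, "protein_id": str,
              "position": int, "residue": str, "phosphorylated": int},
    "annotations": {"kinase_id": str, "protein_id": str, "position": int,
                    "residue": str},
    "edges": {"protein_a": str, "protein_b": str},
    "domains": {"protein_id": str, "domain_id": str, "start": int, "end": int},
    "association": {"kinase_id": str, "protein_id": str, "channel": str,
                    "score": float},
    "quant": {"site_id": str, "peptide_id": str, "condition": str,
              "log2fc": float},
    "registry": {"kinase_id": str, "kinase_type": str},
    "regulatory": {"source": str, "target": str, "sign": int},
    "sites": {"site_id": str, "protein_id": str, "position": int,
              "residue": str, "window": str},
    "pairs": {"kinase_id": str, "site_id": str},
    "assignments": {"kinase_id": str, "site_id": str, "probability": float},
    "activity": {"kinase_id": str, "condition": str, "tag": str,
                 "activity": float},
}

_POSITION_COLUMNS = ("position", "start", "end")


def read_table(path, schema: str | None = None) -> pd.DataFrame:
    """Read a TSV table, validating against a declared schema.

    Violations raise :class:`SchemaError`/:class:`ValidationError` naming
    the offending column (and row where applicable).  Extra columns are
    preserved with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=True)
    if schema is None:
        return df
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    spec_cols = SCHEMAS[schema]
    missing = [c for c in spec_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in spec_cols]
    if extra:
        logger.warning("%s: unknown columns %s preserved", path, extra)
    for col, dtype in spec_cols.items():
        if dtype in (int, float):
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{path}: column {col!r} is not numeric: {exc}")
            if dtype is int:
                df[col] = df[col].astype(int)
        if col in _POSITION_COLUMNS:
            bad = df.index[df[col] < 1]
            if len(bad):
                raise ValidationError(
                    f"{path}: column {col!r} must be 1-based (>= 1); "
                    f"first violation at row {int(bad[0]) + 1}")
    return df


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> None:
    if schema is not None:
        missing = [c for c in SCHEMAS.get(schema, {}) if c not in df.columns]
        if missing:
            raise SchemaError(f"cannot write {schema}: missing columns {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict:
    """Protein sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def matrix_to_frame(matrix) -> pd.DataFrame:
    """Plain-TSV-exportable view of a specificity matrix.

    One row per (position, residue) with the stored value (frequency for
    PFMs, log2 odds for PSSMs) plus the column weight, for audit outside
    the HDF5 bundle.
    """
    from . import windows as win
    rows = []
    for i in range(matrix.length):
        for a, residue in enumerate(win.AMINO_ACIDS):
            rows.append({
                "kinase_id": matrix.kinase_id, "role": matrix.role,
                "position": i + 1, "residue": residue,
                "value": matrix.values[i, a],
                "column_weight": matrix.column_weights[i],
            })
    return pd.DataFrame(rows)


def export_matrix_tsv(matrix, path) -> None:
    write_table(matrix_to_frame(matrix), path)


@dataclass
class RunConfig:
    """Resolved run parameters; serialized next to every output."""

    alphabet: str = "ACDEFGHIKLMNPQRSTVWY"
    flank: int = 7
    pseudocount_mass: str | float = "sqrt"
    posterior_cutoff: float = 0.5
    min_substrates: int = 20
    cv_folds: int = 10
    cv_repeats: int = 10
    n_trees: int = 500
    split_criterion: str = "gini"
    seed: int = 0
    inputs: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class ModelBundle:
    """Everything needed to score new sites: NB models + in vivo classifier."""

    nb_models: dict                       # kinase_id -> NaiveBayesModel
    background: spec.BackgroundModel | None = None
    classifier: object | None = None
    feature_columns: list | None = None


def _schema_hash(feature_columns) -> str:
    payload = "|".join([FORMAT_VERSION, spec.ROLE_PFM,
                        *(feature_columns or []), "ACDEFGHIKLMNPQRSTVWY"])
    return hashlib.sha256(payload.encode()).hexdigest()


def _write_matrix(group: h5py.Group, m: spec.SpecificityMatrix) -> None:
    group.create_dataset("values", data=m.values)
    group.create_dataset("column_weights", data=m.column_weights)
    group.create_dataset("pad_base", data=m.pad_base)
    if m.effective_counts is not None:
        group.create_dataset("effective_counts", data=m.effective_counts)
    group.attrs["role"] = m.role
    group.attrs["theoretical_min"] = m.theoretical_min
    group.attrs["theoretical_max"] = m.theoretical_max
    group.attrs["n_substrates"] = m.n_substrates


def _read_matrix(group: h5py.Group, kinase_id: str | None) -> spec.SpecificityMatrix:
    return spec.SpecificityMatrix(
        kinase_id=kinase_id,
        role=str(group.attrs["role"]),
        values=group["values"][()],
        column_weights=group["column_weights"][()],
        pad_base=group["pad_base"][()],
        theoretical_min=float(group.attrs["theoretical_min"]),
        theoretical_max=float(group.attrs["theoretical_max"]),
        n_substrates=int(group.attrs["n_substrates"]),
        effective_counts=(group["effective_counts"][()]
                          if "effective_counts" in group else None),
    )


def save_models(bundle: ModelBundle, path) -> None:
    """Persist a model bundle to one HDF5 container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = FORMAT_VERSION
        h5.attrs["schema_hash"] = _schema_hash(bundle.feature_columns)
        if bundle.feature_columns:
            h5.attrs["feature_columns"] = list(bundle.feature_columns)
        kin = h5.create_group("kinases")
        for kid, model in bundle.nb_models.items():
            g = kin.create_group(kid)
            g.attrs["prior_fg"] = model.prior_fg
            g.attrs["n_substrates"] = model.n_substrates
            if model.kinase_type is not None:
                g.attrs["kinase_type"] = model.kinase_type
            _write_matrix(g.create_group("fg_pfm"), model.fg_pfm)
            _write_matrix(g.create_group("bg_pfm"), model.bg_pfm)
            if model.bernoulli_params is not None:
                feats = sorted(model.bernoulli_params)
                g.attrs["bernoulli_features"] = feats
                g.create_dataset("bernoulli_theta", data=np.array(
                    [model.bernoulli_params[f] for f in feats]))
        if bundle.background is not None:
            bg = h5.create_group("background")
            bg.attrs["kind"] = bundle.background.kind
            bg.create_dataset("frequencies", data=bundle.background.frequencies)
        if bundle.classifier is not None:
            blob = np.frombuffer(pickle.dumps(bundle.classifier), dtype=np.uint8)
            h5.create_dataset("classifier", data=blob)


def load_models(path) -> ModelBundle:
    """Load a model bundle; schema-hash mismatch or missing version fails."""
    try:
        h5 = h5py.File(path, "r")
    except OSError as exc:
        raise SchemaError(f"cannot open model bundle {path}: {exc}") from exc
    with h5:
        if "format_version" not in h5.attrs:
            raise SchemaError(
                "model bundle has no format version; re-export it with this "
                "version of the package")
        feature_columns = ([str(c) for c in h5.attrs["feature_columns"]]
                           if "feature_columns" in h5.attrs else None)
        if str(h5.attrs["schema_hash"]) != _schema_hash(feature_columns):
            raise SchemaError("model bundle schema hash mismatch")
        nb_models = {}
        for kid, g in h5["kinases"].items():
            params = None
            if "bernoulli_features" in g.attrs:
                feats = [str(f) for f in g.attrs["bernoulli_features"]]
                theta = g["bernoulli_theta"][()]
                params = {f: (float(t[0]), float(t[1]))
                          for f, t in zip(feats, theta)}
            prior_fg = float(g.attrs["prior_fg"])
            nb_models[kid] = nb.NaiveBayesModel(
                kinase_id=kid,
                fg_pfm=_read_matrix(g["fg_pfm"], kid),
                bg_pfm=_read_matrix(g["bg_pfm"], kid),
                prior_fg=prior_fg,
                prior_bg=1.0 - prior_fg,
                bernoulli_params=params,
                n_substrates=int(g.attrs["n_substrates"]),
                kinase_type=(str(g.attrs["kinase_type"])
                             if "kinase_type" in g.attrs else None),
            )
        background = None
        if "background" in h5:
            background = spec.BackgroundModel.presmoothed(
                kind=str(h5["background"].attrs["kind"]),
                frequencies=h5["background"]["frequencies"][()],
            )
        classifier = None
        if "classifier" in h5:
            classifier = pickle.loads(h5["classifier"][()].tobytes())
    return ModelBundle(nb_models=nb_models, background=background,
                       classifier=classifier, feature_columns=feature_columns)
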