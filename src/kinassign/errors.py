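"""Exception hierarchy for kinassign."""


class KinassignError(Exception):
    """Base class for all package-specific errors."""


class InputError(KinassignError):
    """Malformed or inconsistent input data."""


class ValidationError(KinassignError):
    """A domain invariant was violated (e.g. acceptor residue mismatch)."""


class NormalizationError(KinassignError):
    """Degenerate score range: theoretical min equals max."""


class UnmodellableKinase(KinassignError):
    """A kinase cannot be modelled (e.g. zero positive substrates)."""


class SamplingError(KinassignError):
    """Negative-set sampling could not satisfy its constraints."""


class FoldError(KinassignError):
    """Cross-validation fold constraints are unsatisfiable."""


class SchemaError(KinassignError):
    """Table or model-bundle schema violation."""


class PipelineError(KinassignError):
    """A pipeline stage produced an empty or unusable result."""
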