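"""Exception hierarchy shared by all atlaskit modules."""


class AtlasKitError(Exception):
    """Base class for all atlaskit errors."""


class ValidationError(AtlasKitError, ValueError):
    """Input violates a documented invariant (values, identifiers, labels)."""


class StructuralError(AtlasKitError, ValueError):
    """Files or arrays do not fit together (dimension / schema mismatch)."""


class EmptyResultError(AtlasKitError):
    """An operation produced no result and silence would be misleading,
    e.g. every pseudobulk group fell below the cell-count filter."""


class UnscorableError(AtlasKitError):
    """A signature cannot be scored on the given matrix (no signature gene
    present, or every present gene is constant across samples)."""
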