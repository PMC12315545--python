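"""Exception hierarchy.

Every error raised by the library derives from :class:`PeplearnError`, so
callers (and the CLI) can distinguish user/data errors from genuine bugs.
"""


class PeplearnError(Exception):
    """Base class for all library errors."""


class ChemistryError(PeplearnError):
    """Invalid SMILES, failed sanitization, or impossible chemistry."""


class LibraryError(PeplearnError):
    """Malformed or inconsistent monomer library."""


class UnknownMonomerError(PeplearnError):
    """Sequence references a monomer code absent from the library."""


class IntegrityError(PeplearnError):
    """A Fragmentation/HeteroGraph/MaskPlan is internally inconsistent."""


class EncodingError(PeplearnError):
    """A fragment key cannot be encoded with the given vocabulary."""


class MetricError(PeplearnError):
    """Metric undefined for the given input (constant ranks, one class)."""


class ConfigError(PeplearnError):
    """Invalid configuration value or schema violation."""
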