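"""Exception hierarchy shared across the pipeline stages."""


class HookjointError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(HookjointError):
    """Input file could not be parsed under the named standard."""


class EmptyAssemblyError(HookjointError):
    """A structure file contained no polymer chain with Cα atoms."""


class ConfigurationError(HookjointError):
    """Invalid domain definitions, overlapping ranges, or bad run options."""


class ValidationError(HookjointError):
    """A synthetic-assembly specification violates its invariants."""


class InsufficientDataError(HookjointError):
    """Too few subunits / vertices / pairs for the requested computation."""


class IndexingError(HookjointError):
    """The subunit arrangement is inconsistent with the assumed lattice."""


class DegenerateInputError(HookjointError):
    """Geometrically degenerate input (collinear points, zero-length segments)."""
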