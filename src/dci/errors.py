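"""Exception hierarchy shared across the package.

Every error a pipeline stage can raise derives from :class:`DciError`, so
callers (and the CLI) can catch one type and report a one-line diagnostic.
"""


class DciError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(DciError):
    """A structure file could not be parsed (message names the offending line)."""


class EmptySelectionError(DciError):
    """No C-alpha atoms remain after applying chain/residue/HETATM filters."""


class DisconnectedNetworkError(DciError):
    """The elastic network splits into several connected components."""

    def __init__(self, n_components: int, cutoff: float):
        self.n_components = n_components
        self.cutoff = cutoff
        super().__init__(
            f"elastic network is disconnected ({n_components} components at "
            f"cutoff {cutoff:g} A); increase the cutoff or analyse each "
            f"component separately"
        )


class DegenerateGeometryError(DciError):
    """Structure geometry is singular for the requested network model."""


class ConfigError(DciError):
    """Invalid parameter combination."""
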