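"""Exception hierarchy."""


class GnmflowError(Exception):
    """Base class for all package-specific errors."""


class InputError(GnmflowError):
    """Invalid user input (bad recipe name, residue out of range, ...)."""


class FormatError(GnmflowError):
    """Malformed structure file (duplicate residue identifiers, unparseable)."""


class EmptyStructureError(GnmflowError):
    """No C-alpha nodes remain after filtering."""


class DisconnectedNetworkError(GnmflowError):
    """Contact network has more than one connected component.

    Mode-space dynamics silently ignores inter-component transport, so a
    disconnected network is refused rather than analysed.
    """


class IntegrationError(GnmflowError):
    """Numerical integration became unstable (energy drift beyond tolerance)."""
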