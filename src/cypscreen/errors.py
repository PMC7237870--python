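"""Exception hierarchy shared across the package."""


class CypscreenError(Exception):
    """Base class for all package errors."""


class LibraryError(CypscreenError):
    """Compound table could not be loaded (all rows bad, duplicate names, ...)."""


class DescriptorError(CypscreenError):
    """Descriptor computation failed for a molecule."""


class ReceptorError(CypscreenError):
    """Receptor preparation failed (missing chain, missing heme, ...)."""


class MutationError(ReceptorError):
    """Point mutation spec does not match the structure."""


class PoseFormatError(CypscreenError):
    """Docked-pose file could not be parsed."""


class PlacementError(CypscreenError):
    """Synthetic pose/pocket placement is geometrically unreachable."""
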