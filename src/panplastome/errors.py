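"""Exception hierarchy shared across the toolkit."""


class PanPlastomeError(Exception):
    """Base class for all toolkit errors."""


class InputError(PanPlastomeError):
    """Malformed or inconsistent user input (exit code 1 in the CLI)."""


class NoQuadripartiteStructureError(PanPlastomeError):
    """No inverted repeat of the required minimum length was found."""


class StructuralAnomalyError(PanPlastomeError):
    """The best inverted-repeat pair cannot induce a valid LSC/IRb/SSC/IRa tiling."""


class UndefinedGCError(PanPlastomeError):
    """A region contains no unambiguous nucleotides, so GC is undefined."""


class AnnotationError(InputError):
    """Annotation file unparseable or inconsistent with the genome."""


class NoInformativeSitesError(PanPlastomeError):
    """Complete deletion removed every alignment column."""


class SaturationError(PanPlastomeError):
    """Distance undefined (saturation): a logarithm argument was <= 0."""


class ConfigError(InputError):
    """Invalid or infeasible configuration."""
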