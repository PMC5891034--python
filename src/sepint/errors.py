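"""Exception types shared across the package."""


class SepintError(Exception):
    """Base class for all package-specific errors."""


class SingularityError(SepintError, ValueError):
    """A pairwise law was evaluated at (or too close to) zero distance."""


class BasisMismatchError(SepintError, ValueError):
    """Two pose polynomials built over different primitive sets were combined."""


class SurrogateTargetError(SepintError, ValueError):
    """Surrogate target (shape of f vs shape of |f|/d) does not match the
    requested output kind."""


class UnsupportedFamilyError(SepintError, ValueError):
    """The requested pose family is not supported by this operation."""


class SeparabilityError(SepintError, ValueError):
    """An interaction law whose prefactor does not factor over the two
    particle properties was registered."""
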