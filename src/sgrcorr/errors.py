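"""Exception types shared across the package.

A *degenerate* condition (a constant column in a sample, a point-mass
marginal in a distribution) is distinguished from an *invalid* input
(a malformed parameter): the former can legitimately arise inside a
Monte Carlo run and is handled by the caller, the latter is a usage
error.
"""


class SGRError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SGRError, ValueError):
    """A parameter is outside its admissible range or malformed."""


class DegenerateDistributionError(SGRError):
    """A joint distribution has a zero-variance marginal, so a
    correlation is undefined for it."""


class DegenerateSampleError(SGRError):
    """A sample has a constant column, so a sample correlation is
    undefined.  Monte Carlo consumers catch this and record the
    replicate as excluded rather than aborting."""
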