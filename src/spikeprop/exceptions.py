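"""Exception hierarchy for spikeprop."""


class SpikePropError(Exception):
    """Base class for all spikeprop errors."""


class FormatError(SpikePropError):
    """An input file does not conform to the expected layout."""


class ValidationError(SpikePropError):
    """Input data violate a structural invariant (duplicate ids, bad values...)."""


class DegenerateInputError(SpikePropError):
    """A statistic is undefined for the given input (zero variance, no neighbors...)."""
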