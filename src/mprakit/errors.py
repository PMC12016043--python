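"""Exception hierarchy shared across mprakit modules."""


class MprakitError(Exception):
    """Base class for all mprakit errors."""


class InvalidParameterError(MprakitError, ValueError):
    """A parameter is outside its valid domain."""


class BoundsError(MprakitError, IndexError):
    """An interval falls outside the sequence it addresses."""


class AlleleMismatchError(MprakitError, ValueError):
    """The stated reference base does not match the sequence."""


class CapacityError(MprakitError, RuntimeError):
    """Barcode constraints could not be satisfied by rejection sampling."""


class StructureError(MprakitError, ValueError):
    """An oligo part has the wrong length or composition."""


class PairingError(MprakitError, KeyError):
    """No matched DNA sample exists for an RNA sample."""


class DegenerateNullError(MprakitError, ValueError):
    """The negative-control distribution has zero spread."""


class ConfigurationError(MprakitError, ValueError):
    """A sample sheet or config references something unknown."""
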