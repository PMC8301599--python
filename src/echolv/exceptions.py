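"""Exception hierarchy used across the package."""


class EchoLVError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(EchoLVError):
    """Raised for geometrically invalid inputs (e.g. epicardium inside endocardium)."""


class OutOfRangeError(EchoLVError, IndexError):
    """Requested coordinate lies outside the stored image stack."""


class MissingAnnotationError(EchoLVError):
    """The assisted model variant requires a user-supplied anchor radius."""


class InsufficientDataError(EchoLVError):
    """Not enough frames/samples/animals for the requested operation."""


class PairingError(EchoLVError):
    """Metric tables to be compared do not describe matched datasets."""
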