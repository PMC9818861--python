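"""Exception types shared across the package."""


class MsFingerprintError(Exception):
    """Base class for all package errors."""


class MzXMLParseError(MsFingerprintError):
    """The mzXML file could not be parsed."""


class EmptyRunError(MsFingerprintError):
    """A run contained no MS1 scans."""


class ContractError(MsFingerprintError, ValueError):
    """An operation was called outside its contract (e.g. double normalization)."""


class ShapeMismatchError(MsFingerprintError, ValueError):
    """Two spectral matrices (or a matrix and a model) disagree in shape."""


class DegenerateCalibrationError(MsFingerprintError, ValueError):
    """Class mean log odds coincide; the linear score transform is undefined."""
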