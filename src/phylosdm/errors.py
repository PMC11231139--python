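"""Exception hierarchy: input/metadata errors vs computation errors."""


class PhylosdmError(Exception):
    """Base class for all package errors."""


class InputError(PhylosdmError):
    """Malformed or empty input data (parse failures, illegal characters)."""


class AlignmentError(InputError):
    """Ragged alignments or otherwise invalid sequence sets."""


class MetadataError(InputError):
    """Sample/population metadata inconsistent with the sequence data."""


class DegenerateDataError(PhylosdmError):
    """Data too degenerate for the requested statistic (e.g. no usable sites)."""


class ParameterError(PhylosdmError):
    """Parameter outside its documented domain."""


class RasterError(InputError):
    """Raster layers failing to parse or to share a common geometry."""


class ProjectionError(PhylosdmError):
    """Model projected onto layers it was not trained on."""


class SelectionError(PhylosdmError):
    """No valid candidate model to select."""
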