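"""Exception hierarchy shared across the toolkit."""


class SnpsatError(Exception):
    """Base class for all toolkit errors."""


class InputError(SnpsatError):
    """Invalid or inconsistent input data (missing file, bad values)."""


class FormatError(SnpsatError):
    """A file does not conform to its declared format."""


class DegenerateInputError(InputError):
    """Input too small or too uniform for the requested model fit."""


class UndefinedMetricError(SnpsatError):
    """A requested statistic is undefined for the given data."""


class StateError(SnpsatError):
    """Operation requested on an object in the wrong state (e.g. untrained model)."""
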