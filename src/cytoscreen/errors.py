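"""Exception hierarchy.

``InputError`` covers malformed user inputs (bad rasters, bad CSVs, bad
config); ``ConsistencyError`` covers internally inconsistent intermediate
state (e.g. unpaired label masks); the remaining classes cover degenerate
statistical inputs. The CLI maps input errors and computation errors to
distinct exit codes.
"""


class CytoscreenError(Exception):
    """Base class for all package-specific errors."""


class InputError(CytoscreenError, ValueError):
    """A user-supplied input (raster, CSV, config value) is invalid."""


class ConsistencyError(CytoscreenError, ValueError):
    """Paired data structures disagree (e.g. nucleus/cell label sets)."""


class InsufficientDataError(CytoscreenError, ValueError):
    """Too few observations to compute the requested statistic."""


class DegenerateControlsError(CytoscreenError, ValueError):
    """Control populations do not separate (equal means or zero spread)."""
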