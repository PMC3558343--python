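"""Exception hierarchy for tilewave."""


class TilewaveError(Exception):
    """Base class for all tilewave errors."""


class InvalidDesignError(TilewaveError, ValueError):
    """A design specification or matrix violates its contract."""


class RankError(InvalidDesignError):
    """A custom design matrix is rank deficient."""


class ShapeError(TilewaveError, ValueError):
    """Array dimensions do not match the transform plan or model."""


class DataError(TilewaveError, ValueError):
    """Input data is malformed (non-finite values, unsorted probes, ...)."""


class ConfigurationError(TilewaveError, ValueError):
    """Mutually inconsistent analysis options."""


class StateError(TilewaveError, RuntimeError):
    """An operation was requested on an object in the wrong state."""


class SelectionError(TilewaveError, ValueError):
    """An effect / contrast selector is out of range for the fit."""
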