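"""Exception hierarchy shared across the pipeline."""


class PlasmidRBEError(Exception):
    """Base class for all package errors."""


class SchemaError(PlasmidRBEError):
    """A delimited-text table is missing a required column or has the wrong layout."""


class TableValidationError(PlasmidRBEError):
    """A table parsed but one or more rows violate an invariant."""


class EmptyLaneError(PlasmidRBEError):
    """A gel lane carries no integrable signal after baseline subtraction."""


class FitError(PlasmidRBEError):
    """Nonlinear fit failed to converge or the data cannot support a fit.

    Carries the best point found (if any) on the ``best`` attribute.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class UnitError(PlasmidRBEError):
    """Two quantities were combined with incompatible units or bases."""
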