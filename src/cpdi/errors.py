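"""Exception hierarchy for the cpdi package."""


class CPDIError(Exception):
    """Base class for all cpdi errors."""


class StandardSchemaError(CPDIError):
    """A standard-definition document violates the documented schema.

    Carries the offending component id and field name when known.
    """

    def __init__(self, message: str, component: str | None = None, field: str | None = None):
        self.component = component
        self.field = field
        prefix = ""
        if component is not None:
            prefix = f"[component={component}" + (f", field={field}] " if field else "] ")
        super().__init__(prefix + message)


class StandardInvariantError(CPDIError):
    """A parsed standard violates a structural invariant (e.g. lower > upper)."""


class AgeOutOfRangeError(CPDIError):
    """Age outside the index's domain of completed years 2-5."""


class DegenerateIntakeError(CPDIError):
    """Recall records cannot be densified (e.g. mean energy is zero)."""


class CategoryMismatchError(CPDIError):
    """A scoring rule was invoked with a component of the wrong category."""


class InsufficientDataError(CPDIError):
    """Too few subjects or components for a cohort statistic."""


class InputSchemaError(CPDIError):
    """A tabular input file is missing mandatory columns or is malformed."""
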