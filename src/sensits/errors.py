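"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input record or field violates a domain invariant.

    Messages always name the offending field and, when known, the record
    id or row number, so that failures in large panels are traceable.
    """

    def __init__(self, message: str, *, record_id: str | None = None,
                 field: str | None = None):
        self.record_id = record_id
        self.field = field
        prefix = ""
        if record_id is not None:
            prefix += f"[record {record_id}] "
        if field is not None:
            prefix += f"field '{field}': "
        super().__init__(prefix + message)


class MissingCallError(ValidationError):
    """Raised when a mixture component lacks an ingredient hazard call."""

    def __init__(self, missing_ids: list[str], *, mixture_id: str | None = None):
        self.missing_ids = list(missing_ids)
        super().__init__(
            f"no hazard call for ingredient(s): {', '.join(self.missing_ids)}",
            record_id=mixture_id,
        )
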