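"""Exception hierarchy for sulcmorph.

Measurement *failures* (e.g. an edge loop that cannot be closed) are values,
not exceptions — see :class:`sulcmorph.sulcus_mesh.LoopFailure`.  Exceptions
are reserved for malformed inputs and misconfiguration.
"""


class SulcmorphError(Exception):
    """Base class for all sulcmorph errors."""


class FormatError(SulcmorphError):
    """A file is not in the expected FreeSurfer binary dialect."""

    def __init__(self, path, message, offset=None):
        self.path = str(path)
        self.offset = offset
        loc = f"{self.path}" if offset is None else f"{self.path} (byte offset {offset})"
        super().__init__(f"{loc}: {message}")


class ValidationError(SulcmorphError):
    """In-memory data violates a type invariant (caught before any write)."""


class ConsistencyError(SulcmorphError):
    """Companion files disagree (e.g. overlay length vs mesh vertex count)."""


class UnknownLabelError(SulcmorphError):
    """A requested sulcus name is absent from the annotation's name table."""

    def __init__(self, name, available):
        self.name = name
        self.available = sorted(available)
        super().__init__(
            f"label {name!r} not found in annotation; available sulcus labels: "
            + ", ".join(self.available)
        )


class ConfigurationError(SulcmorphError):
    """A required input file or setting is missing."""
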