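"""Exception hierarchy shared across the pipeline."""


class CernetError(Exception):
    """Base class for all package errors."""


class ParseError(CernetError):
    """An input file could not be parsed (maps to CLI exit code 2)."""


class StageError(CernetError):
    """A pipeline stage failed (maps to CLI exit code 3).

    Carries the stage name so an end-to-end run can report where it aborted.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
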