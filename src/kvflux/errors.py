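"""Exception hierarchy.

All package errors derive from :class:`KvfluxError` so callers can catch one
type; subclasses distinguish bad physics inputs (``DomainError``), malformed
analysis arguments (``InvalidInputError``), protocol/data mismatches
(``ProtocolError``), file-format problems (``FormatError``) and calibration
problems in laser-Doppler traces (``CalibrationError``).
"""


class KvfluxError(Exception):
    """Base class for all kvflux errors."""


class DomainError(KvfluxError, ValueError):
    """A physical quantity is outside its mathematical domain (e.g. a
    non-positive ion concentration)."""


class InvalidInputError(KvfluxError, ValueError):
    """Arguments are individually valid but jointly inconsistent (e.g.
    macroscopic and single-channel currents of opposite sign)."""


class ProtocolError(KvfluxError):
    """Recorded data do not match the declared voltage protocol (missing
    sweep, missing tail segment, empty family)."""


class FormatError(KvfluxError):
    """A CSV/JSON/YAML input could not be parsed; the message names the file
    and, where possible, the offending row or column."""


class CalibrationError(KvfluxError):
    """A biological-zero calibration is inconsistent with the trace (zero at
    or above the resting flux)."""


class IncompleteRecordError(KvfluxError):
    """A pressure-diameter record lacks a matched active/passive pair."""


class StageError(KvfluxError):
    """A pipeline stage failed; carries the stage label."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
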