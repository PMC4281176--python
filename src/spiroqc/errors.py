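"""Exception hierarchy for spiroqc."""


class SpiroError(Exception):
    """Base class for all spiroqc errors."""


class InputError(SpiroError, ValueError):
    """Invalid argument values (length mismatch, bad order, unknown kind...)."""


class FormatError(SpiroError, ValueError):
    """Malformed curve, session or configuration file."""


class ParameterError(SpiroError, ValueError):
    """Infeasible generator or configuration parameters."""


class DegenerateCurveError(SpiroError, ValueError):
    """Maneuver too short, flat, or otherwise unanalysable."""
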