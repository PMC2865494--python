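"""Exception hierarchy; the CLI maps these onto exit codes."""


class CocaError(Exception):
    """Base class for package errors."""


class InputError(CocaError, ValueError):
    """Malformed user input: files, matrices, masks, labels. CLI exit code 2."""


class NumericalError(CocaError, RuntimeError):
    """Numerical failure during optimization or evaluation. CLI exit code 3."""
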