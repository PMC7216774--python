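"""Exception hierarchy; the CLI maps these onto distinct exit codes."""


class AsmevalError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(AsmevalError):
    """Invalid or incomplete run configuration (missing cost, bad YAML...)."""

    exit_code = 2


class InputError(AsmevalError):
    """Malformed or unreadable input data (FASTA/TSV format problems)."""

    exit_code = 3


class ConsistencyError(AsmevalError):
    """Inputs that are individually valid but mutually inconsistent,
    e.g. a coverage track whose length differs from its sequence."""

    exit_code = 4
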