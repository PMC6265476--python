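"""Exception hierarchy shared across the package."""


class GeneLinkerError(Exception):
    """Base class for all package errors."""


class InputError(GeneLinkerError):
    """Malformed or missing user input (FASTA, GFF, tables)."""


class ConfigError(GeneLinkerError):
    """Invalid configuration: unknown preset, bad override, bad table."""


class ToolError(GeneLinkerError):
    """A required external tool is unavailable or failed."""


class GenerationError(GeneLinkerError):
    """A synthetic fixture specification could not be realised."""
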