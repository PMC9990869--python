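"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class IntegrityError(ValueError):
    """A file parses but violates an internal consistency invariant."""


class ConfigError(ValueError):
    """A configuration is internally inconsistent or infeasible."""
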