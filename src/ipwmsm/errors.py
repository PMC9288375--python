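"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid simulation or analysis configuration (e.g. probability outside [0, 1])."""


class EstimationError(RuntimeError):
    """A model could not be estimated (separation, zero events, non-convergence)."""


class ArtefactError(FileNotFoundError):
    """A required pipeline artefact (table, weight file) is missing or malformed."""
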