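"""Exception types shared across the toolkit."""


class PPGFormatError(ValueError):
    """A signal or table file does not conform to the expected dialect."""


class QualityError(RuntimeError):
    """A signal is unusable for feature extraction (no landmarks, flat trace, ...)."""


class FitError(RuntimeError):
    """A model could not be trained on the given data."""
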