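"""Exception types shared across the toolkit."""


class InputError(ValueError):
    """Invalid user input (bad spec fields, empty tables, malformed files)."""


class SaturationError(ValueError):
    """A distance is too large for the substitution model to invert."""


class DegenerateDataError(ValueError):
    """Data technically valid but carrying no usable signal (e.g. all-zero tracks)."""
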