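"""Exception types shared across the toolkit."""


class MRNetError(ValueError):
    """Raised for invalid inputs, malformed files and contract violations."""
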