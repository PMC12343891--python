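"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """Raised when a run configuration is inconsistent with the data."""


class WidenKernel(Exception):
    """Internal control-flow signal: the current kernel bandwidth produced a
    grid partition too complex (or too pathological) to analyse; the caller
    should widen the kernel by sqrt(2) and restart from the weight array.
    """

    def __init__(self, reason: str = ""):
        super().__init__(reason)
        self.reason = reason
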