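"""Exception types raised by the simulator."""


class ConfigurationError(ValueError):
    """A parameter set, network description or structure size is invalid."""


class SimulationError(RuntimeError):
    """The simulation entered an invalid state (e.g. non-finite values)."""


class EdgeFileError(ValueError):
    """An edge-list or adjacency file could not be parsed."""
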