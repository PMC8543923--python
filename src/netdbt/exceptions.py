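"""Exception hierarchy for netdbt."""


class NetdbtError(Exception):
    """Base class for all netdbt errors."""


class NetworkFormatError(NetdbtError, ValueError):
    """The input file does not conform to the long-format CSV dialect."""


class NetworkValidationError(NetdbtError, ValueError):
    """The data are well-formed but violate a dataset invariant."""


class DisconnectedNetworkError(NetdbtError, ValueError):
    """The treatment graph is not connected."""


class EstimationError(NetdbtError, RuntimeError):
    """A variance component or model fit is not estimable."""


class ConfigError(NetdbtError, ValueError):
    """A simulation configuration violates its invariants."""
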