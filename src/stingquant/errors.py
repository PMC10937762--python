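"""Exception hierarchy for the stingquant pipeline."""


class StingQuantError(Exception):
    """Base class for all stingquant errors."""


class ConfigurationError(StingQuantError):
    """A run/stack configuration is inconsistent (e.g. missing nucleus channel)."""


class FormatError(StingQuantError):
    """An on-disk artifact does not match its declared layout."""


class PlacementError(StingQuantError):
    """The synthetic generator could not place the requested number of cells."""
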