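"""Exception hierarchy shared across the package."""


class SlidegridError(Exception):
    """Base class for all slidegrid errors."""


class GeometryError(SlidegridError, ValueError):
    """Invalid slide geometry (non-positive dimension, MPP, or grid edge)."""


class ShapeMismatchError(SlidegridError, ValueError):
    """Two grid maps (or a mask and a layout) do not share one geometry."""


class LevelError(SlidegridError, ValueError):
    """A map was passed at the wrong grid level (fine vs display)."""


class AdjudicationIncompleteError(SlidegridError):
    """A disputed grid has no chief-pathologist label to fall back on."""


class UndefinedMetricError(SlidegridError, ZeroDivisionError):
    """A proportion or AUC is undefined (zero denominator / single class)."""


class PairingError(SlidegridError, ValueError):
    """A paired reader analysis has missing (reader, slide, condition) cells."""


class ConfigError(SlidegridError, ValueError):
    """An infeasible or unknown configuration value."""


class FixtureLookupError(SlidegridError, KeyError):
    """Unknown printed-table fixture name."""
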