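"""Exception hierarchy.

``AmpligaugeError`` is the base for all data-level failures; ``ConfigError``
is raised for malformed run configurations (distinct CLI exit code).
"""


class AmpligaugeError(Exception):
    """Base class for all ampligauge data errors."""


class ConfigError(AmpligaugeError):
    """Invalid run configuration (unknown keys, bad values)."""


class TaxonomyError(AmpligaugeError):
    pass


class ParseError(TaxonomyError):
    pass


class AmpliconError(AmpligaugeError):
    pass


class ReadSimError(AmpligaugeError):
    pass


class ClassifierError(AmpligaugeError):
    pass


class LkoError(AmpligaugeError):
    pass


class CalibrationError(AmpligaugeError):
    pass


class CombineError(AmpligaugeError):
    pass


class FixtureError(AmpligaugeError):
    pass
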