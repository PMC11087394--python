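"""Typed error conditions used throughout the pipeline.

Row-level conditions (an exposure with no usable instruments, a mediation
leg that cannot be estimated) are represented as exceptions so that batch
drivers can catch them per item and keep the screen running; configuration
and file-format problems abort immediately.
"""


class MRScreenError(Exception):
    """Base class for all package errors."""


class SumStatsFormatError(MRScreenError):
    """A summary-statistics or LD file violates the expected format."""


class ConfigError(MRScreenError):
    """A run configuration is structurally invalid."""


class NoInstrumentsError(MRScreenError):
    """An estimator was asked to run with zero instruments."""


class NoHarmonizableInstrumentsError(MRScreenError):
    """Harmonization retained zero variants for an exposure-outcome pair.

    Batch drivers report this per exposure rather than aborting a screen.
    """


class DegenerateInstrumentError(MRScreenError):
    """A Wald ratio was requested for an instrument with zero exposure effect."""


class MediationLegError(MRScreenError):
    """One of the three MR legs of a mediation analysis is not estimable."""

    def __init__(self, leg: str, message: str = ""):
        self.leg = leg
        super().__init__(f"mediation leg '{leg}' not estimable" + (f": {message}" if message else ""))
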