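"""Exception and warning types shared across the package."""


class SampenmapError(Exception):
    """Base class for all package-specific errors."""


class DegenerateSeriesError(SampenmapError, ValueError):
    """A time series has zero variance (or too few points) so no tolerance
    can be derived from its standard deviation."""


class UndefinedCountsError(SampenmapError, ValueError):
    """No valid template positions exist, so match counts are undefined."""


class InsufficientWindowsError(SampenmapError, ValueError):
    """A window set is empty where at least one window is required."""


class SubjectExcludedError(SampenmapError):
    """The subject does not meet the inclusion rule (fewer usable low-motion
    windows than requested), so no entropy map can be produced for them.

    This is a structured exclusion, distinct from a processing failure.
    """

    def __init__(self, n_found: int, n_required: int, message: str | None = None):
        self.n_found = n_found
        self.n_required = n_required
        if message is None:
            message = (
                f"subject excluded: only {n_found} usable low-motion windows "
                f"found, {n_required} required; subjects without enough "
                "usable volumes must be excluded"
            )
        super().__init__(message)


class FormatError(SampenmapError, ValueError):
    """An input file does not conform to the expected on-disk format."""


class UndefinedSampEnWarning(UserWarning):
    """Emitted when sample entropy is not mathematically defined
    (no template matches at length m or m+1)."""
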