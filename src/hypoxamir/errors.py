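"""Exception types shared across the pipeline."""


class SizingError(ValueError):
    """Requested synthetic features do not fit on the requested contig."""


class ReferenceLookupError(ValueError):
    """A name referenced by a profile or query is absent from the reference."""


class ConfigurationError(ValueError):
    """Invalid or inconsistent pipeline parameters."""


class UndefinedLibraryError(ValueError):
    """Normalization requested against a library with zero clone count."""
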