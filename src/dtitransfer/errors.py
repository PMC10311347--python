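"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file or table does not conform to the expected layout."""


class IntegrityError(ValueError):
    """Logically inconsistent data, e.g. a compound listed in both split partitions."""


class DimensionError(ValueError):
    """Mismatched vector/fingerprint dimensions."""


class SamplingError(ValueError):
    """A requested subset cannot be drawn from the available pool."""


class SplitError(ValueError):
    """A cluster-disjoint train/test split cannot be constructed."""


class FeaturizationError(KeyError):
    """A compound id is missing from the embedding table."""
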