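"""Exception hierarchy shared across the package."""


class HepafrocError(Exception):
    """Base class for all package errors."""


class FormatError(HepafrocError):
    """A file does not conform to the expected schema (missing columns, bad YAML)."""


class ValidationError(HepafrocError):
    """A value violates a domain invariant (negative diameter, rating out of range)."""


class UndefinedMetricError(HepafrocError):
    """A metric has an empty denominator (e.g. LLF over an empty lesion subset)."""


class DegenerateStatisticError(HepafrocError):
    """A test statistic is undefined (e.g. paired t with zero-variance differences)."""


class PlacementError(HepafrocError):
    """Random geometric placement failed (infeasible packing, lesion outside liver)."""


class SegmentationError(HepafrocError):
    """Liver segmentation produced an empty mask."""
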