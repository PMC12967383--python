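"""Exception hierarchy.

Every failure mode callers are expected to branch on gets a named class;
all inherit from :class:`ShapeClustError` so a CLI can catch one type.
"""


class ShapeClustError(Exception):
    """Base class for all shapeclust errors."""


class ConstantSeriesError(ShapeClustError):
    """Series has (numerically) zero scatter; standardization is undefined."""

    def __init__(self, site: str, scatter: float):
        self.site = site
        self.scatter = scatter
        super().__init__(
            f"series {site!r} has zero scatter ({scatter!r}); it cannot be "
            "standardized and must be excluded or clustered unstandardized"
        )


class AxisMismatchError(ShapeClustError):
    """Two series do not share an identical year axis; align before comparing."""


class IncompleteSeriesError(ShapeClustError):
    """Series does not cover the full shared year axis (no imputation is done)."""


class OverlapError(ShapeClustError):
    """Cluster member sets passed to a linkage computation intersect."""


class UnknownLabelError(ShapeClustError):
    """A label is not present in the distance matrix / panel."""


class DegenerateMatrixError(ShapeClustError):
    """Distance matrix too small to cluster (fewer than 2 items)."""


class ClusterCountError(ShapeClustError):
    """Requested cluster count k outside [1, number of leaves]."""


class SchemaError(ShapeClustError):
    """Input table is missing required columns."""


class DuplicateKeyError(ShapeClustError):
    """Registry table contains duplicated (sex, site, age_group, year) keys."""


class EmptyPanelError(ShapeClustError):
    """No site qualifies for the requested panel."""


class ZeroBaselineError(ShapeClustError):
    """Percentage change from a zero baseline value is undefined."""


class WindowError(ShapeClustError):
    """Invalid year window for a trend statistic."""


class SpecError(ShapeClustError):
    """Invalid synthetic panel specification."""


class LeafMismatchError(ShapeClustError):
    """Two partitions being compared do not cover the same leaf set."""
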