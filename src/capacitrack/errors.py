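"""Exception hierarchy.

All package errors derive from :class:`CapacitrackError` so callers can
catch one type at the pipeline boundary; the CLI maps subtypes onto exit
codes (config errors, data/format errors, numerical failures).
"""


class CapacitrackError(Exception):
    """Base class for all package errors."""


class ConfigError(CapacitrackError, ValueError):
    """Invalid or incomplete pipeline configuration."""


class FormatError(CapacitrackError, ValueError):
    """Malformed input file or table (duplicates, missing cells, bad values)."""


class UnitError(CapacitrackError, ValueError):
    """Operation applied to an expression matrix in the wrong unit."""


class HarmonizationError(CapacitrackError, ValueError):
    """Cross-dataset gene harmonization produced an empty intersection."""


class FitError(CapacitrackError, RuntimeError):
    """A model fit could not be carried out (too few genes, degenerate data)."""


class LabelingError(CapacitrackError, RuntimeError):
    """Cluster centroid geometry does not admit an unambiguous semantic labeling."""


class PipelineStageError(CapacitrackError, RuntimeError):
    """A pipeline stage failed; carries the stage name for the manifest."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
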