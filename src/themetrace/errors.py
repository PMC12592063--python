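"""Exception hierarchy shared across the pipeline stages."""


class ThemetraceError(Exception):
    """Base class for all package-specific failures."""


class SchemaError(ThemetraceError):
    """An input table is missing a mapped column or violates the declared dialect."""


class EmptyCorpusError(ThemetraceError):
    """No records survived ingestion/filtering."""


class ConfigurationError(ThemetraceError):
    """Invalid configuration (overlapping phases, unknown keys, bad values)."""


class TrainingError(ThemetraceError):
    """A model could not be trained (e.g. empty effective vocabulary)."""


class CoverageError(ThemetraceError):
    """No evaluable item remained after out-of-vocabulary filtering."""


class FilterError(ThemetraceError):
    """Dictionary filtering removed the entire vocabulary."""


class FusionError(ThemetraceError):
    """A topic or document vector could not be constructed."""


class StructureError(ThemetraceError):
    """An output graph/structure is internally inconsistent (e.g. dangling link)."""
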