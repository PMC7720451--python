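"""Exception hierarchy shared across the pipeline.

Three error classes map onto the three failure modes a run can hit:
malformed input files, internally inconsistent counts, and invalid
analysis configuration. The CLI translates them into distinct exit codes.
"""


class CohortMinerError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CohortMinerError):
    """A cohort summary file (or config file) could not be parsed."""


class ConsistencyError(CohortMinerError):
    """Counts violate a structural invariant (e.g. frequency > cohort size)."""


class ConfigurationError(CohortMinerError):
    """An analysis was requested with invalid or incomplete parameters."""
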