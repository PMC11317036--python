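"""Exception hierarchy shared across the package."""


class DepcrsimError(Exception):
    """Base class for all package errors."""


class DesignError(DepcrsimError):
    """Invalid template/primer design space (bad offsets, duplicate keys, ...)."""


class ModelError(DepcrsimError):
    """Annealing-efficiency model cannot resolve a query (unknown temperature, ...)."""


class SimulationError(DepcrsimError):
    """Amplification simulation cannot proceed (e.g. all efficiencies zero)."""


class InputError(DepcrsimError):
    """Malformed external input (unpaired FASTQ streams, bad mapping file, ...)."""


class MetricError(DepcrsimError):
    """A metric is undefined for the given input (all-zero vectors, empty rows)."""


class StatsError(DepcrsimError):
    """A statistical test is undefined for the given input (degenerate variance)."""


class PipelineError(DepcrsimError):
    """End-to-end run failure, tagged with the stage that failed."""
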