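"""Exception hierarchy shared across the package."""


class FlaxPopGenError(Exception):
    """Base class for all package errors."""


class FormatError(FlaxPopGenError):
    """Malformed input file (FASTA dialect, panel TSV)."""


class AlignmentError(FlaxPopGenError):
    """Sequences that should form an alignment do not (ragged lengths)."""


class ConsistencyError(FlaxPopGenError):
    """Cross-file inconsistency: panel ids vs. alignment ids, missing samples."""


class InputError(FlaxPopGenError):
    """Invalid argument to a statistical operation (e.g. n < 2)."""


class EstimationError(FlaxPopGenError):
    """An estimator could not produce a usable result (degenerate likelihood)."""
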