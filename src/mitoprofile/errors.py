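"""Typed exceptions raised across the toolkit."""


class MitoprofileError(Exception):
    """Base class for all mitoprofile errors."""


class FastaError(MitoprofileError):
    """Malformed FASTA input (empty file, duplicate ids, ...)."""


class AlphabetError(MitoprofileError):
    """Sequence contains characters outside the accepted alphabet."""


class FeatureError(MitoprofileError):
    """Invalid feature record or feature table."""


class AlignmentError(MitoprofileError):
    """Invalid multiple alignment or alignment-based computation."""


class CodingSequenceError(MitoprofileError):
    """A protein-coding gene violates the genetic-code contract."""


class SimulationError(MitoprofileError):
    """Invalid simulation specification."""


class PipelineError(MitoprofileError):
    """A pipeline stage failed; the message names the stage."""
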