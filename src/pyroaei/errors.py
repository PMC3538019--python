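"""Exception hierarchy for the pyroaei pipeline."""


class PyroAeiError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PyroAeiError):
    """A file could not be parsed (bad columns, non-IUPAC characters, ragged matrices)."""


class ValidationError(PyroAeiError):
    """Parsed data violates an invariant (percent sums, duplicate keys, bad ranges)."""


class AssayError(PyroAeiError):
    """An RFLP assay cannot be constructed or interpreted."""


class NoAmplificationError(AssayError):
    """A primer pair found no product on the template."""


class AmbiguousAmplificationError(AssayError):
    """A primer pair found more than one candidate product."""


class UninformativeAssayError(AssayError):
    """The two allele fragment patterns are indistinguishable on a gel."""


class MissingReferenceError(PyroAeiError):
    """No heterozygous gDNA rows available to standardise a gene."""


class InsufficientDataError(PyroAeiError):
    """Too few observations for the requested statistic."""
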