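"""Typed exceptions shared across the package."""


class SplicePPIError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(SplicePPIError, ValueError):
    """A protein/CDS/genomic position fell outside the valid range."""


class LoadError(SplicePPIError):
    """Annotation or interaction input failed validation at load time.

    ``offenders`` lists the individual problems so the caller can report
    all of them at once instead of fixing the file one row at a time.
    """

    def __init__(self, message: str, offenders: list[str] | None = None):
        self.offenders = list(offenders or [])
        if self.offenders:
            message = message + "\n  - " + "\n  - ".join(self.offenders)
        super().__init__(message)


class ParseError(SplicePPIError, ValueError):
    """A source table row could not be interpreted (bad id, bad label)."""


class IdMappingError(SplicePPIError, KeyError):
    """An identifier could not be resolved through the id mapping table."""

    def __init__(self, identifier: str, target: str = "entrez"):
        self.identifier = identifier
        self.target = target
        super().__init__(f"cannot map id {identifier!r} to {target}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return f"cannot map id {self.identifier!r} to {self.target}"


class StructureError(SplicePPIError):
    """A PDB structure or chain lookup failed."""


class AmbiguousExonError(SplicePPIError, ValueError):
    """Exon coordinates matched zero or several annotated exons."""

    def __init__(self, message: str, candidates: list[str] | None = None):
        self.candidates = list(candidates or [])
        if self.candidates:
            message += f" (candidates: {', '.join(self.candidates)})"
        super().__init__(message)


class NoStructuralAnnotation(SplicePPIError):
    """A gene pair has a PPI but no joint (DDI-supported) edges.

    Deliberately distinct from an interaction score of 0.0: a score of 0
    means structural evidence exists and the isoform lost all of it, while
    this condition means there is nothing to score.
    """

    def __init__(self, gene_a: str, gene_b: str):
        self.gene_a, self.gene_b = gene_a, gene_b
        super().__init__(f"no joint DDI edges between genes {gene_a} and {gene_b}")
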