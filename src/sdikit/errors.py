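"""Exception hierarchy shared across the package."""


class SdikitError(Exception):
    """Base class for all package-specific errors."""


class OntologyError(SdikitError):
    """Malformed or unusable ontology input."""


class EmptyOntologyError(OntologyError):
    """No term of the requested namespace was found."""


class CyclicOntologyError(OntologyError):
    """The term graph contains a cycle."""

    def __init__(self, member: str):
        self.member = member
        super().__init__(f"ontology graph contains a cycle through {member!r}")


class UnknownTermError(SdikitError):
    """A term identifier could not be resolved in the ontology."""

    def __init__(self, term: str, gene_id: str | None = None):
        self.term = term
        self.gene_id = gene_id
        msg = f"unknown term {term!r}"
        if gene_id is not None:
            msg += f" (gene {gene_id!r})"
        super().__init__(msg)


class ContractViolationError(SdikitError):
    """A caller broke an operation precondition."""


class DomainError(SdikitError):
    """A numeric input fell outside its valid domain."""


class UndefinedStatisticError(SdikitError):
    """The requested statistic is undefined on this input (e.g. one-class AUC)."""


class FixtureSpecError(SdikitError):
    """An infeasible synthetic-fixture specification."""
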