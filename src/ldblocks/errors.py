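"""Exception and warning hierarchy for ldblocks."""


class LDBlocksError(Exception):
    """Base class for all ldblocks errors."""


class ContractError(LDBlocksError, ValueError):
    """An argument violates a documented precondition."""


class LinkageFormatError(LDBlocksError, ValueError):
    """Malformed PED/MAP/INFO or precomputed-LD input."""


class GeneTableError(LDBlocksError, ValueError):
    """Malformed gene-annotation table."""


class GeneLookupError(LDBlocksError, LookupError):
    """No gene record matches the query identifier."""


class AmbiguousGeneError(GeneLookupError):
    """More than one gene record matches the query identifier."""


class MarkerLookupError(LDBlocksError, LookupError):
    """A marker id is absent from the panel."""


class UndefinedLDError(LDBlocksError, ValueError):
    """An LD quantity is undefined (monomorphic locus, no overlapping samples)."""


class SimulationSpecError(LDBlocksError, ValueError):
    """An infeasible synthetic-panel specification."""


class NonCliqueWarning(UserWarning):
    """A connected component at the perfect-LD threshold is not a clique
    (possible only through missing-data artifacts)."""


class DuplicatePositionWarning(UserWarning):
    """Two cluster members share a base-pair position; their BED blocks collapse."""


class UndefinedDistanceWarning(UserWarning):
    """No defined cross-pair between two clusters; maximal distance substituted."""


class EmptyArchitectureWarning(UserWarning):
    """An architecture query matched no markers."""
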