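"""Exception types raised across the package."""


class PPAffinityError(Exception):
    """Base class for all package-specific errors."""


class ChainNotFoundError(PPAffinityError):
    """A chain named in a partner assignment is absent from the structure."""


class EmptyPartnerError(PPAffinityError):
    """A binding partner ends up with zero standard residues."""


class MissingBackboneError(PPAffinityError):
    """No usable backbone atoms for secondary-structure assignment."""


class UnknownElementError(PPAffinityError):
    """An atom's element has no configured van der Waals radius."""


class SASAInputError(PPAffinityError):
    """Inconsistent or invalid accessibility inputs (e.g. negative values,
    or a complex-context area exceeding the monomer-context area)."""


class MutationMismatchError(PPAffinityError):
    """A mutation's wild-type residue does not match the structure."""


class DegenerateDataError(PPAffinityError):
    """A dataset or sequence has no variance / too few points for the
    requested statistic or fit."""


class FixtureGeometryError(PPAffinityError):
    """An infeasible synthetic-structure geometry was requested."""
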