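"""Exception hierarchy for searchkin.

Every error raised on purpose by the package derives from
:class:`SearchkinError` so callers (and the CLI) can distinguish domain
errors from programming bugs.
"""


class SearchkinError(Exception):
    """Base class for all searchkin domain errors."""

    #: short machine-parsable category used by the CLI on stderr
    category = "error"


class InvalidParameterError(SearchkinError, ValueError):
    """A physical or model parameter violates its domain (sign, range)."""

    category = "invalid-parameter"


class ParameterRangeError(SearchkinError, ValueError):
    """An exponent or derived quantity left the numerically safe range."""

    category = "parameter-range"


class StructureParseError(SearchkinError, ValueError):
    """Input coordinates could not be parsed as PDB or mmCIF."""

    category = "structure-parse"


class NoProteinError(SearchkinError, ValueError):
    """The (selected part of the) structure contains no protein residues."""

    category = "no-protein"


class NoDNAError(SearchkinError, ValueError):
    """The (selected part of the) structure contains no DNA residues."""

    category = "no-dna"


class NoSpecificContactsError(SearchkinError, ValueError):
    """Specific-contact detection returned an empty set."""

    category = "no-specific-contacts"


class UndefinedSimilarityError(SearchkinError, ValueError):
    """chi_i is undefined: residue has no neighbors inside the cutoff."""

    category = "undefined-similarity"


class MutationError(SearchkinError, ValueError):
    """A mutation string is malformed or inconsistent with the structure."""

    category = "mutation"


class ChargeSchemeError(SearchkinError, KeyError):
    """Unknown residue charge scheme name."""

    category = "charge-scheme"


class NoAbsorptionError(SearchkinError, ValueError):
    """Simulation would never terminate (zero transition probability)."""

    category = "no-absorption"
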