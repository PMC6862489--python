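"""Exception hierarchy shared across the package.

Everything raised deliberately by grainlink derives from
:class:`GrainlinkError`, so callers (and the CLI, which maps these to exit
status 3) can catch one type.
"""


class GrainlinkError(Exception):
    """Base class for model, data and configuration errors."""


class InvalidGenotypeError(GrainlinkError, ValueError):
    """An allele is not legal for its locus, or haplotypes do not cover the map."""


class InvalidRuleError(GrainlinkError, ValueError):
    """A lethality rule or threshold rule violates its invariants."""


class IncompatibleGametesError(GrainlinkError, ValueError):
    """Gamete distributions defined over different locus sets cannot be united."""


class ClassificationError(GrainlinkError, ValueError):
    """A classifier is not total over the genotypes it was handed."""


class DegenerateExpectationError(GrainlinkError, ValueError):
    """An expected class count of zero makes the chi-square statistic undefined."""


class EmptyClassError(GrainlinkError, ValueError):
    """No individuals in the class an estimator or test needs."""


class MapDistanceError(GrainlinkError, ValueError):
    """Recombination fraction at or beyond 0.5 has no finite map distance."""


class DesignError(GrainlinkError, ValueError):
    """A cross design is internally inconsistent (bad references, sizes, cycles)."""


class SelectionError(GrainlinkError, RuntimeError):
    """A selection step matched no individual in its source population."""


class PlacementError(GrainlinkError, ValueError):
    """A marker cannot be placed on the simulated chromosome."""


class NonIdentifiableWarning(UserWarning):
    """The likelihood is flat in r; the estimate is arbitrary within the grid."""
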