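"""Transmission genetics of linked loci with gamete lethality.

This module models how a rice plant heterozygous for the large-grain allele
*GW2*, the semidwarfing allele *d60* and the complementary gametic-lethality
allele *gal* transmits alleles to its progeny.  Gametes carrying both *d60*
and *gal* are inviable in both sexes, so an F1 of genotype *D60d60Galgal*
sheds only three of its four gamete classes, its pollen and seed fertility
drop to 75%, and its selfed progeny segregate 6 fertile long-culm : 2
partially sterile long-culm : 1 semidwarf instead of a Mendelian 3 : 1.
When a second gene (*GW2*) rides on the same chromosome as *d60*, the same
lethality distorts its zygotic ratios in opposite directions in the
semidwarf and long-culm classes — the signal used to detect linkage.

The building blocks are small and composable:

* :class:`Locus` — a biallelic locus with a donor/recurrent allele pair;
* :class:`LinkageMap` — loci arranged into linkage groups, with a
  recombination fraction between each adjacent pair (groups assort
  independently; within a group crossovers occur without interference);
* :class:`PhasedGenotype` — an individual's two haplotypes over the map;
* :class:`LethalityRule` — allele combinations that kill a gamete;
* :func:`gamete_frequencies` / :func:`zygote_distribution` — exact gamete
  and offspring distributions;
* :class:`PhenotypeClassifier` and the :func:`culm_classifier` /
  :func:`grain_classifier` builders — map genotypes onto the phenotype
  classes scored in the field.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence, Union

from .errors import (
    ClassificationError,
    DesignError,
    GrainlinkError,
    IncompatibleGametesError,
    InvalidGenotypeError,
    InvalidRuleError,
)

Haplotype = tuple[str, ...]
AllelePair = tuple[str, str]
GenotypeKey = tuple[AllelePair, ...]

__all__ = [
    "Locus",
    "LinkageGroup",
    "LinkageMap",
    "PhasedGenotype",
    "LethalityRule",
    "GameteDistribution",
    "PhenotypeClassifier",
    "gamete_frequencies",
    "zygote_distribution",
    "zygote_phased_distribution",
    "expected_class_probabilities",
    "classify",
    "fertility_of",
    "culm_classifier",
    "grain_classifier",
    "joint_classifier",
]


# ---------------------------------------------------------------------------
# loci and maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Locus:
    """A biallelic locus.

    ``alleles`` is ordered (donor, recurrent): the donor allele is the one
    introgressed from the nonrecurrent parent (Inochinoichi for *GW2*,
    Hokuriku 100 via Koshihikari d60 for *d60*/*Gal*), coded ``A`` in
    genotype files; the recurrent allele is coded ``B``.
    """

    name: str
    alleles: AllelePair
    chromosome: str | None = None
    position_mb: float | None = None

    def __post_init__(self) -> None:
        if len(self.alleles) != 2 or len(set(self.alleles)) != 2:
            raise InvalidGenotypeError(
                f"locus {self.name!r} needs exactly two distinct alleles"
            )

    @property
    def donor(self) -> str:
        return self.alleles[0]

    @property
    def recurrent(self) -> str:
        return self.alleles[1]


@dataclass(frozen=True)
class LinkageGroup:
    """Ordered loci on one chromosome segment with adjacent-pair r values."""

    loci: tuple[Locus, ...]
    r: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "r", tuple(float(x) for x in self.r))
        if len(self.r) != len(self.loci) - 1:
            raise DesignError(
                f"linkage group needs {len(self.loci) - 1} recombination "
                f"fractions for {len(self.loci)} loci, got {len(self.r)}"
            )
        for x in self.r:
            if not 0.0 <= x <= 0.5:
                raise DesignError(f"recombination fraction {x} outside [0, 0.5]")


@dataclass(frozen=True)
class LinkageMap:
    """Loci partitioned into independently assorting linkage groups.

    Locus names and allele symbols must be unique across the whole map;
    allele uniqueness is what lets a lethality rule and a haplotype be
    compared as plain symbol sets.
    """

    groups: tuple[LinkageGroup, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise DesignError("locus names must be unique within a map")
        symbols = [a for loc in self.loci for a in loc.alleles]
        if len(set(symbols)) != len(symbols):
            raise DesignError("allele symbols must be unique across loci")

    @property
    def loci(self) -> tuple[Locus, ...]:
        return tuple(loc for g in self.groups for loc in g.loci)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(loc.name for loc in self.loci)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise DesignError(f"no locus named {name!r} in map") from None

    def locus(self, name: str) -> Locus:
        return self.loci[self.index(name)]

    def group_of(self, name: str) -> LinkageGroup:
        for g in self.groups:
            if any(loc.name == name for loc in g.loci):
                return g
        raise DesignError(f"no locus named {name!r} in map")

    def set_r(self, a: str, b: str, r: float) -> "LinkageMap":
        """Return a new map with r between adjacent loci ``a`` and ``b`` replaced."""
        new_groups = []
        done = False
        for g in self.groups:
            names = [loc.name for loc in g.loci]
            if a in names and b in names:
                i, j = sorted((names.index(a), names.index(b)))
                if j != i + 1:
                    raise DesignError(f"loci {a!r} and {b!r} are not adjacent")
                rs = list(g.r)
                rs[i] = r
                new_groups.append(LinkageGroup(g.loci, tuple(rs)))
                done = True
            else:
                new_groups.append(g)
        if not done:
            raise DesignError(f"loci {a!r} and {b!r} not in one linkage group")
        return LinkageMap(tuple(new_groups))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhasedGenotype:
    """Two haplotypes over every locus of a map, in map order.

    Phase matters for transmission (it decides which alleles travel
    together through a non-recombinant gamete) but the *genotype* — the
    unordered allele pair per locus — is what phenotype classifiers see.
    """

    lmap: LinkageMap
    haplotypes: tuple[Haplotype, Haplotype]

    def __post_init__(self) -> None:
        h1, h2 = (tuple(h) for h in self.haplotypes)
        object.__setattr__(self, "haplotypes", (h1, h2))
        loci = self.lmap.loci
        for h in (h1, h2):
            if len(h) != len(loci):
                raise InvalidGenotypeError(
                    f"haplotype length {len(h)} does not cover the "
                    f"{len(loci)}-locus map"
                )
            for allele, loc in zip(h, loci):
                if allele not in loc.alleles:
                    raise InvalidGenotypeError(
                        f"allele {allele!r} not legal for locus {loc.name!r} "
                        f"(alleles {loc.alleles})"
                    )

    @classmethod
    def from_haplotypes(
        cls, lmap: LinkageMap, h1: Sequence[str], h2: Sequence[str]
    ) -> "PhasedGenotype":
        return cls(lmap, (tuple(h1), tuple(h2)))

    @classmethod
    def homozygous(cls, lmap: LinkageMap, h: Sequence[str]) -> "PhasedGenotype":
        return cls(lmap, (tuple(h), tuple(h)))

    def pair(self, name: str) -> AllelePair:
        """Unordered allele pair at a locus, donor allele first."""
        i = self.lmap.index(name)
        loc = self.lmap.loci[i]
        return _canonical_pair(
            (self.haplotypes[0][i], self.haplotypes[1][i]), loc
        )

    def genotype(self) -> GenotypeKey:
        """Per-locus canonical allele pairs over the whole map."""
        return tuple(self.pair(n) for n in self.lmap.names)

    def pairs(self) -> dict[str, AllelePair]:
        return {n: self.pair(n) for n in self.lmap.names}

    def code(self, name: str) -> str:
        """File coding ``A/A`` (donor homozygote), ``A/B`` or ``B/B``."""
        loc = self.lmap.locus(name)
        p = self.pair(name)
        return "/".join("A" if a == loc.donor else "B" for a in p)

    def codes(self) -> dict[str, str]:
        return {n: self.code(n) for n in self.lmap.names}

    def is_heterozygous(self, name: str) -> bool:
        p = self.pair(name)
        return p[0] != p[1]


def _canonical_pair(pair: Iterable[str], locus: Locus) -> AllelePair:
    a, b = sorted(pair, key=lambda x: 0 if x == locus.donor else 1)
    return (a, b)


# ---------------------------------------------------------------------------
# lethality
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LethalityRule:
    """Allele combinations that render a gamete inviable.

    A gamete dies if it carries *all* alleles of any one combination.  The
    default rule of the package — ``{d60, gal}`` in both sexes — encodes
    complementary gametic lethality: only gametes uniting the semidwarfing
    allele with the lethality allele are lost.  ``sexes`` may restrict the
    rule to male or female gametes for reuse with sex-specific distorters.
    """

    combinations: tuple[frozenset[str], ...]
    sexes: str = "both"  # "both" | "male" | "female"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "combinations", tuple(frozenset(c) for c in self.combinations)
        )
        if self.sexes not in ("both", "male", "female"):
            raise InvalidRuleError(f"sexes must be both/male/female, not {self.sexes!r}")
        for c in self.combinations:
            if len(c) < 2:
                raise InvalidRuleError("a lethal combination needs >= 2 alleles")

    def applies_to(self, sex: str | None) -> bool:
        if self.sexes == "both":
            return True
        return sex == self.sexes

    def is_lethal(self, haplotype: Haplotype) -> bool:
        carried = set(haplotype)
        return any(c <= carried for c in self.combinations)

    def validate_against(self, lmap: LinkageMap) -> None:
        """Check that no combination names two alleles of the same locus."""
        owner = {a: loc.name for loc in lmap.loci for a in loc.alleles}
        for c in self.combinations:
            seen: dict[str, str] = {}
            for a in c:
                if a in owner:
                    if owner[a] in seen.values():
                        raise InvalidRuleError(
                            f"lethal combination {set(c)} names two alleles "
                            f"of locus {owner[a]!r}"
                        )
                    seen[a] = owner[a]


# ---------------------------------------------------------------------------
# gamete and zygote distributions
# ---------------------------------------------------------------------------


@dataclass
class GameteDistribution:
    """Haplotype frequencies among *surviving* gametes.

    ``fertility`` is the pre-lethality surviving fraction: the probability
    that a freshly formed gamete escapes the lethality rule.  Frequencies
    are renormalised to the survivors, so they always sum to one; a plant
    whose fertility is below one is scored "partially sterile" in the
    field.
    """

    lmap: LinkageMap
    frequencies: dict[Haplotype, float]
    fertility: float = 1.0

    def haplotypes(self) -> list[Haplotype]:
        return list(self.frequencies)

    def probabilities(self) -> list[float]:
        return list(self.frequencies.values())


def _group_gamete_freqs(
    parent: PhasedGenotype, group: LinkageGroup, offset: int
) -> dict[Haplotype, float]:
    """Exact gamete haplotype frequencies for one linkage group.

    Enumerates parental-origin vectors: the first locus takes either
    haplotype with probability 1/2, and each adjacent interval switches
    origin with its recombination fraction, independently (no
    interference).
    """
    k = len(group.loci)
    h = [parent.haplotypes[s][offset : offset + k] for s in (0, 1)]
    out: dict[Haplotype, float] = {}
    for origins in itertools.product((0, 1), repeat=k):
        p = 0.5
        for i in range(k - 1):
            r = group.r[i]
            p *= r if origins[i] != origins[i + 1] else 1.0 - r
        if p == 0.0:
            continue
        hap = tuple(h[origins[i]][i] for i in range(k))
        out[hap] = out.get(hap, 0.0) + p
    return out


def gamete_frequencies(
    parent: PhasedGenotype,
    lmap: LinkageMap | None = None,
    rule: LethalityRule | None = None,
    sex: str | None = None,
) -> GameteDistribution:
    """Surviving-gamete haplotype distribution of one parent.

    Linkage groups assort independently; within a group, crossovers occur
    between adjacent loci with the mapped recombination fraction and no
    interference.  Haplotypes hit by ``rule`` (when it applies to ``sex``)
    are removed and the remainder renormalised; the removed mass is
    reported as ``1 - fertility``.

    ``sex`` may be ``"female"``, ``"male"`` or ``None`` (a rule restricted
    to one sex is then not applied).
    """
    lmap = lmap or parent.lmap
    if lmap is not parent.lmap and lmap.names != parent.lmap.names:
        raise InvalidGenotypeError("parent is not defined over the map's loci")
    if rule is not None:
        rule.validate_against(lmap)

    full: dict[Haplotype, float] = {(): 1.0}
    offset = 0
    for group in lmap.groups:
        gf = _group_gamete_freqs(parent, group, offset)
        offset += len(group.loci)
        full = {
            h + gh: p * gp for h, p in full.items() for gh, gp in gf.items()
        }

    if rule is not None and rule.applies_to(sex):
        lethal_mass = sum(p for h, p in full.items() if rule.is_lethal(h))
        survivors = {h: p for h, p in full.items() if not rule.is_lethal(h)}
    else:
        lethal_mass = 0.0
        survivors = full

    fertility = 1.0 - lethal_mass
    if fertility <= 0.0:
        raise GrainlinkError("all gametes are lethal under this rule")
    freqs = {h: p / fertility for h, p in survivors.items()}
    return GameteDistribution(lmap, freqs, fertility)


def fertility_of(
    parent: PhasedGenotype,
    rule: LethalityRule | None,
    lmap: LinkageMap | None = None,
    sex: str | None = None,
) -> float:
    """Pre-lethality gamete survival fraction of one parent (1.0 if no rule)."""
    if rule is None:
        return 1.0
    return gamete_frequencies(parent, lmap, rule, sex=sex or rule.sexes).fertility


def _check_compatible(a: GameteDistribution, b: GameteDistribution) -> None:
    if a.lmap.names != b.lmap.names:
        raise IncompatibleGametesError(
            "gamete distributions are over different locus sets: "
            f"{a.lmap.names} vs {b.lmap.names}"
        )


def zygote_distribution(
    female: GameteDistribution, male: GameteDistribution
) -> dict[GenotypeKey, float]:
    """Offspring genotype distribution from two gamete distributions.

    The outer product of the surviving gamete frequencies, aggregated into
    unordered genotypes (reciprocal heterozygotes are not distinguished).
    """
    _check_compatible(female, male)
    loci = female.lmap.loci
    out: dict[GenotypeKey, float] = {}
    for hf, pf in female.frequencies.items():
        for hm, pm in male.frequencies.items():
            key = tuple(
                _canonical_pair((hf[i], hm[i]), loci[i]) for i in range(len(loci))
            )
            out[key] = out.get(key, 0.0) + pf * pm
    return out


def zygote_phased_distribution(
    female: GameteDistribution, male: GameteDistribution
) -> dict[tuple[Haplotype, Haplotype], float]:
    """Like :func:`zygote_distribution` but keyed by unordered haplotype pairs.

    Phase is retained (which alleles co-reside on one chromosome), so the
    result can seed another round of transmission; parental origin is not.
    """
    _check_compatible(female, male)
    out: dict[tuple[Haplotype, Haplotype], float] = {}
    for hf, pf in female.frequencies.items():
        for hm, pm in male.frequencies.items():
            key = tuple(sorted((hf, hm)))  # type: ignore[assignment]
            out[key] = out.get(key, 0.0) + pf * pm
    return out


# ---------------------------------------------------------------------------
# phenotype classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeClassifier:
    """Total mapping from multilocus genotypes to phenotype class labels."""

    trait: str
    labels: tuple[str, ...]
    loci: tuple[str, ...]
    fn: Callable[[Mapping[str, AllelePair]], str]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ClassificationError("class labels must be unique")

    def __call__(self, pairs: Mapping[str, AllelePair]) -> str:
        missing = [n for n in self.loci if n not in pairs]
        if missing:
            raise ClassificationError(
                f"genotype does not cover classifier loci {missing}"
            )
        label = self.fn(pairs)
        if label not in self.labels:
            raise ClassificationError(
                f"classifier {self.trait!r} produced unknown label {label!r}"
            )
        return label


GenotypeLike = Union[PhasedGenotype, Mapping[str, AllelePair]]


def classify(genotype: GenotypeLike, classifier: PhenotypeClassifier) -> str:
    """Deterministic phenotype class of a genotype under a classifier."""
    if isinstance(genotype, PhasedGenotype):
        pairs: Mapping[str, AllelePair] = genotype.pairs()
    else:
        pairs = genotype
    return classifier(pairs)


def grain_classifier(
    gw2: Locus, mode: str = "incomplete", trait: str = "grain"
) -> PhenotypeClassifier:
    """Grain-size classes from the *GW2* genotype.

    Incomplete dominance (the default, and what the field data show): the
    heterozygote is an intermediate "medium" class, so an F2 segregates
    1 large : 2 medium : 1 small.  Complete mode collapses carriers into
    "large", as in the early-generation 3 : 1 grain-diameter scoring.
    """
    if mode == "incomplete":
        labels = ("large", "medium", "small")

        def fn(pairs: Mapping[str, AllelePair]) -> str:
            n = pairs[gw2.name].count(gw2.donor)
            return {2: "large", 1: "medium", 0: "small"}[n]

    elif mode == "complete":
        labels = ("large", "small")

        def fn(pairs: Mapping[str, AllelePair]) -> str:
            return "large" if gw2.donor in pairs[gw2.name] else "small"

    else:
        raise ClassificationError(f"unknown dominance mode {mode!r}")
    return PhenotypeClassifier(trait, labels, (gw2.name,), fn)


def culm_classifier(
    d60: Locus, gal: Locus, trait: str = "culm"
) -> PhenotypeClassifier:
    """Culm classes: semidwarf / partially sterile / long-stem.

    * semidwarf — homozygous *d60d60* (necessarily *GalGal*, since *d60*
      gametes carrying *gal* never survive);
    * partially sterile — the F1-type double heterozygote *D60d60Galgal*,
      which loses a quarter of its gametes and sets seed at 75%;
    * long-stem — everything else.
    """
    labels = ("semidwarf", "partially sterile", "long-stem")

    def fn(pairs: Mapping[str, AllelePair]) -> str:
        nd = pairs[d60.name].count(d60.donor)
        if nd == 2:
            return "semidwarf"
        g = pairs[gal.name]
        if nd == 1 and g[0] != g[1]:
            return "partially sterile"
        return "long-stem"

    return PhenotypeClassifier(trait, labels, (d60.name, gal.name), fn)


def joint_classifier(
    a: PhenotypeClassifier, b: PhenotypeClassifier, sep: str = " & "
) -> PhenotypeClassifier:
    """Cartesian product of two classifiers (e.g. grain class x culm class)."""
    labels = tuple(f"{la}{sep}{lb}" for la in a.labels for lb in b.labels)

    def fn(pairs: Mapping[str, AllelePair]) -> str:
        return f"{a(pairs)}{sep}{b(pairs)}"

    return PhenotypeClassifier(
        f"{a.trait}{sep}{b.trait}", labels, tuple(dict.fromkeys(a.loci + b.loci)), fn
    )


# ---------------------------------------------------------------------------
# expected class probabilities
# ---------------------------------------------------------------------------


def _pairs_from_key(key, lmap: LinkageMap) -> dict[str, AllelePair]:
    """Interpret a distribution key as per-locus allele pairs.

    Keys may be unordered genotypes (a canonical allele pair per locus) or
    phased haplotype pairs; the two are told apart by which loci the
    symbols belong to, which is unambiguous because allele symbols are
    unique across a map.
    """
    loci = lmap.loci
    n = len(loci)
    if (
        len(key) == 2
        and all(len(h) == n for h in key)
        and all(key[s][i] in loci[i].alleles for s in (0, 1) for i in range(n))
    ):
        return {
            loci[i].name: _canonical_pair((key[0][i], key[1][i]), loci[i])
            for i in range(n)
        }
    if len(key) == n and all(
        len(p) == 2 and set(p) <= set(loci[i].alleles) for i, p in enumerate(key)
    ):
        return {loci[i].name: _canonical_pair(key[i], loci[i]) for i in range(n)}
    raise InvalidGenotypeError(f"cannot interpret distribution key {key!r}")


def expected_class_probabilities(
    distribution, classifier: PhenotypeClassifier, lmap: LinkageMap | None = None
) -> dict[str, float]:
    """Phenotype-class probabilities implied by a genotype distribution.

    ``distribution`` may be a dict from genotypes (or phased haplotype
    pairs) to probabilities, or any object with an ``analytic_distribution``
    method (a cross design).  Probabilities are returned for every label of
    the classifier, in label order, and sum to one.
    """
    if hasattr(distribution, "analytic_distribution"):
        design = distribution
        distribution = design.analytic_distribution()
        lmap = lmap or design.lmap
    if lmap is None:
        raise DesignError("a linkage map is required to interpret the distribution")
    probs = dict.fromkeys(classifier.labels, 0.0)
    for key, p in distribution.items():
        probs[classifier(_pairs_from_key(key, lmap))] += p
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise GrainlinkError(f"class probabilities sum to {total}, not 1")
    return probs
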