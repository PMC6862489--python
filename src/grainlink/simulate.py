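"""Breeding-scheme simulator: F2, BCnF2 and d60-combining populations.

The generator draws offspring under the same transmission model the
analytic code uses: one surviving gamete is sampled per parent per
offspring from its exact :class:`~grainlink.transmission.GameteDistribution`,
so gamete lethality, linkage and phase all propagate correctly through a
multi-step crossing scheme.  A :class:`CrossDesign` is a list of named
steps — ``cross``, ``self`` and ``select`` — over named founders; selection
picks the first individual matching a predicate (reproducible under the
seed) or, with ``keep="all"``, the whole matching subpopulation (e.g. all
small-grain homozygotes for marker mapping).

Random streams are spawned hierarchically, one per step, from a single
seed, so appending steps to a design never perturbs earlier draws.

Markers are attached by promoting them to ordinary loci on the augmented
linkage map (physical Mb positions converted to map distance at a
configurable cM/Mb factor, Haldane) and re-simulating the design under the
recorded seed: marker and trait genotypes then come from one joint gamete
sampling, so double-recombinant frequencies, marker-trait recombination
and the rest follow from the model with no separate marker machinery.

Phenotypes are class means plus Gaussian noise; fertility is not sampled —
it is a genotype property (the surviving-gamete fraction), 0.75 for the
F1-type double heterozygote under the default lethality rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    DesignError,
    GrainlinkError,
    PlacementError,
    SelectionError,
)
from .recomb import haldane_d_to_r
from .segregation import ClassCountTable, ThresholdRule
from .transmission import (
    GameteDistribution,
    Haplotype,
    LethalityRule,
    LinkageGroup,
    LinkageMap,
    Locus,
    PhasedGenotype,
    PhenotypeClassifier,
    classify,
    culm_classifier,
    fertility_of,
    gamete_frequencies,
    grain_classifier,
    zygote_phased_distribution,
)

__all__ = [
    "CrossStep",
    "SelfStep",
    "SelectStep",
    "CrossDesign",
    "PhenotypeModel",
    "SimulatedPopulation",
    "simulate_population",
    "sample_phenotypes",
    "attach_markers",
    "design_with_markers",
    "analytic_genotype_distribution",
    "default_loci",
    "default_map",
    "default_rule",
    "default_grain_rule",
    "builtin_design",
    "BUILTIN_DESIGNS",
]

CM_PER_MB_DEFAULT = 4.0  # toy rice chromosome-2 calibration, configurable


# ---------------------------------------------------------------------------
# design steps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossStep:
    name: str
    mother: str
    father: str
    n: int = 1


@dataclass(frozen=True)
class SelfStep:
    name: str
    parent: str
    n: int = 1


Predicate = Union[Mapping[str, object], Callable[[pd.Series], bool]]


@dataclass(frozen=True)
class SelectStep:
    """Pick individuals from an earlier population.

    ``where`` is either a mapping from locus name to a genotype code
    (``"A/A"``) or tuple of acceptable codes, or a callable over the
    individual's row (codes plus any sampled traits) — the latter enables
    phenotype-based selection with its attendant misclassification.
    ``keep`` is ``"first"`` (a single plant, the usual breeding choice) or
    ``"all"`` (the whole matching class).
    """

    name: str
    source: str
    where: Predicate = field(default_factory=dict)
    keep: str = "first"

    def __post_init__(self) -> None:
        if self.keep not in ("first", "all"):
            raise DesignError(f"keep must be 'first' or 'all', not {self.keep!r}")


Step = Union[CrossStep, SelfStep, SelectStep]


@dataclass
class CrossDesign:
    """Founders, ordered steps, the linkage map and the lethality rule."""

    name: str
    lmap: LinkageMap
    founders: dict[str, PhasedGenotype]
    steps: tuple[Step, ...]
    rule: LethalityRule | None = None

    def __post_init__(self) -> None:
        self.steps = tuple(self.steps)
        known = set(self.founders)
        for step in self.steps:
            refs = (
                (step.mother, step.father)
                if isinstance(step, CrossStep)
                else (step.parent,)
                if isinstance(step, SelfStep)
                else (step.source,)
            )
            for ref in refs:
                if ref not in known:
                    raise DesignError(
                        f"step {step.name!r} references unknown population {ref!r}"
                    )
            if step.name in known:
                raise DesignError(f"duplicate population name {step.name!r}")
            if not isinstance(step, SelectStep) and step.n < 1:
                raise DesignError(f"step {step.name!r}: population size must be >= 1")
            known.add(step.name)
        for g in self.founders.values():
            if g.lmap.names != self.lmap.names:
                raise DesignError("founder genotypes must cover the design's map")

    def analytic_distribution(self, upto: str | None = None):
        return analytic_genotype_distribution(self, upto=upto)


# ---------------------------------------------------------------------------
# phenotype model
# ---------------------------------------------------------------------------


def _default_grain_means() -> dict[str, float]:
    return {"small": 20.0, "medium": 22.0, "large": 24.6}


def _default_culm_means() -> dict[str, float]:
    return {"semidwarf": 49.0, "partially sterile": 64.0, "long-stem": 64.0}


@dataclass
class PhenotypeModel:
    """Gaussian trait model per genotype class.

    Grain area in mm² per *GW2* class (anchored to the parental means:
    ~20 mm² in the Koshihikari background, ~24.6 mm² with two donor
    alleles, heterozygote intermediate — incomplete dominance) and culm
    length in cm per culm class.  Partial sterility is not sampled: an
    individual is "partially sterile" when its genotypic gamete survival
    falls below ``fertility_threshold``.
    """

    grain_means: dict[str, float] = field(default_factory=_default_grain_means)
    grain_sd: float = 0.5
    culm_means: dict[str, float] = field(default_factory=_default_culm_means)
    culm_sd: float = 4.0
    fertility_threshold: float = 0.9
    grain_locus: str = "GW2"
    d60_locus: str = "D60"
    gal_locus: str = "Gal"

    def __post_init__(self) -> None:
        g = self.grain_means
        if not g["small"] < g["medium"] < g["large"]:
            raise DesignError("grain means must be ordered small < medium < large")
        c = self.culm_means
        if not c["semidwarf"] < c["long-stem"]:
            raise DesignError("semidwarf culm mean must be below long-stem")
        if self.grain_sd <= 0 or self.culm_sd <= 0:
            raise DesignError("trait standard deviations must be positive")


def default_grain_rule(model: PhenotypeModel | None = None) -> ThresholdRule:
    """Threshold classifier at the midpoints between grain-class means."""
    model = model or PhenotypeModel()
    m = model.grain_means
    return ThresholdRule(
        trait="grain_area",
        cuts=(
            (m["small"] + m["medium"]) / 2,
            (m["medium"] + m["large"]) / 2,
        ),
        labels=("small", "medium", "large"),
    )


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------


class SimulatedPopulation:
    """Individuals as sampled maternal/paternal haplotype indices.

    Haplotypes are stored once (``mother_haps`` / ``father_haps``) with one
    index pair per individual, so class-level operations (coding,
    classification, fertility) are computed per unique genotype and
    broadcast — populations of 10^5 individuals stay cheap.
    """

    def __init__(
        self,
        generation: str,
        lmap: LinkageMap,
        rule: LethalityRule | None,
        mother_haps: tuple[Haplotype, ...],
        father_haps: tuple[Haplotype, ...],
        idx_mother: np.ndarray,
        idx_father: np.ndarray,
        provenance: dict | None = None,
    ):
        self.generation = generation
        self.lmap = lmap
        self.rule = rule
        self.mother_haps = tuple(mother_haps)
        self.father_haps = tuple(father_haps)
        self.idx_mother = np.asarray(idx_mother, dtype=np.int64)
        self.idx_father = np.asarray(idx_father, dtype=np.int64)
        self.provenance = provenance or {}
        self.traits = pd.DataFrame(index=pd.RangeIndex(self.size))

    @property
    def size(self) -> int:
        return int(self.idx_mother.size)

    def genotype(self, i: int) -> PhasedGenotype:
        return PhasedGenotype(
            self.lmap,
            (self.mother_haps[self.idx_mother[i]], self.father_haps[self.idx_father[i]]),
        )

    # -- per-unique-genotype broadcasting -----------------------------------

    def _pair_ids(self) -> tuple[np.ndarray, list[tuple[int, int]]]:
        ids = self.idx_mother * len(self.father_haps) + self.idx_father
        uniq, inverse = np.unique(ids, return_inverse=True)
        pairs = [
            (int(u) // len(self.father_haps), int(u) % len(self.father_haps))
            for u in uniq
        ]
        return inverse, pairs

    def _per_genotype(self, fn: Callable[[PhasedGenotype], object]) -> np.ndarray:
        inverse, pairs = self._pair_ids()
        values = np.array(
            [
                fn(
                    PhasedGenotype(
                        self.lmap, (self.mother_haps[i], self.father_haps[j])
                    )
                )
                for i, j in pairs
            ],
            dtype=object,
        )
        return values[inverse]

    def codes_frame(self) -> pd.DataFrame:
        """One column per locus with ``A/A``-style genotype codes."""
        inverse, pairs = self._pair_ids()
        rows = [
            PhasedGenotype(self.lmap, (self.mother_haps[i], self.father_haps[j])).codes()
            for i, j in pairs
        ]
        base = pd.DataFrame(rows)
        return base.iloc[inverse].reset_index(drop=True)

    def frame(self) -> pd.DataFrame:
        df = self.codes_frame()
        for col in self.traits.columns:
            df[col] = self.traits[col].to_numpy()
        df.insert(0, "generation", self.generation)
        return df

    def fertility(self) -> np.ndarray:
        """Genotypic gamete-survival fraction per individual (not sampled)."""
        return self._per_genotype(
            lambda g: fertility_of(g, self.rule, self.lmap)
        ).astype(float)

    def classify(self, classifier: PhenotypeClassifier) -> np.ndarray:
        return self._per_genotype(lambda g: classify(g, classifier))

    def counts(
        self,
        classifier: PhenotypeClassifier,
        ratio: Sequence[float] | None = None,
    ) -> ClassCountTable:
        labels = self.classify(classifier)
        return ClassCountTable(
            labels=classifier.labels,
            observed=tuple(int((labels == l).sum()) for l in classifier.labels),
            ratio=tuple(ratio) if ratio is not None else None,
        )

    def marker_table(self) -> pd.DataFrame:
        """Single-letter marker genotypes (A/H/B) for attached markers."""
        markers = self.provenance.get("markers")
        if not markers:
            raise GrainlinkError("population has no attached markers")
        codes = self.codes_frame()[list(markers)]
        return codes.replace({"A/A": "A", "A/B": "H", "B/B": "B"})

    # -- subsetting ---------------------------------------------------------

    def _match(self, where) -> np.ndarray:
        if isinstance(where, np.ndarray) and where.dtype == bool:
            return where
        if callable(where):
            df = self.frame()
            return np.array([bool(where(row)) for _, row in df.iterrows()])
        codes = self.codes_frame()
        mask = np.ones(self.size, dtype=bool)
        for name, wanted in where.items():
            if name not in codes.columns:
                raise DesignError(f"predicate references unknown locus {name!r}")
            accept = (wanted,) if isinstance(wanted, str) else tuple(wanted)
            mask &= codes[name].isin(accept).to_numpy()
        return mask

    def filter(self, where: Predicate, generation: str | None = None):
        mask = self._match(where)
        sub = SimulatedPopulation(
            generation or self.generation,
            self.lmap,
            self.rule,
            self.mother_haps,
            self.father_haps,
            self.idx_mother[mask],
            self.idx_father[mask],
            dict(self.provenance),
        )
        sub.traits = self.traits[mask].reset_index(drop=True)
        return sub

    # -- output -------------------------------------------------------------

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write individuals as CSV plus a JSON provenance sidecar."""
        df = self.frame()
        df.insert(0, "id", [f"{self.generation}-{i + 1}" for i in range(self.size)])
        df.to_csv(path, index=False, lineterminator="\n", float_format="%.6g")
        if sidecar:
            meta = {
                "generation": self.generation,
                "n": self.size,
                "seed": self.provenance.get("seed"),
                "design": self.provenance.get("design_name"),
                "design_hash": self.provenance.get("design_hash"),
                "markers": list(self.provenance.get("markers", ())),
            }
            with open(str(path) + ".provenance.json", "w") as fh:
                json.dump(meta, fh, indent=2, sort_keys=True)
                fh.write("\n")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _founder_population(
    name: str, g: PhasedGenotype, lmap: LinkageMap, rule
) -> SimulatedPopulation:
    return SimulatedPopulation(
        name,
        lmap,
        rule,
        (g.haplotypes[0],),
        (g.haplotypes[1],),
        np.zeros(1, dtype=np.int64),
        np.zeros(1, dtype=np.int64),
    )


def _sample_gametes(
    g: PhasedGenotype,
    rule,
    sex: str,
    n: int,
    rng: np.random.Generator,
) -> tuple[tuple[Haplotype, ...], np.ndarray]:
    gd = gamete_frequencies(g, rule=rule, sex=sex)
    haps = tuple(gd.frequencies)
    probs = np.asarray(list(gd.frequencies.values()))
    probs = probs / probs.sum()  # exact renormalisation against fp drift
    idx = rng.choice(len(haps), size=n, p=probs)
    return haps, idx


def simulate_population(
    design: CrossDesign,
    n: int | None = None,
    seed: int = 0,
    phenomodel: PhenotypeModel | None = None,
    return_all: bool = False,
):
    """Run a cross design and return the final population.

    ``n`` overrides the size of the last cross/self step.  Every step owns
    one child stream of ``seed`` (spawned in step order), so results are
    reproducible per seed and extending a design leaves earlier
    generations' draws untouched.  When ``phenomodel`` is given, grain
    area, culm length and fertility are sampled for every generated
    population (phenotype-based selection predicates then see them).

    A selection step whose predicate matches nobody raises
    :class:`SelectionError` naming the step.
    """
    steps = list(design.steps)
    if n is not None:
        for i in range(len(steps) - 1, -1, -1):
            if not isinstance(steps[i], SelectStep):
                steps[i] = replace(steps[i], n=int(n))
                break
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(steps))
    prov_base = {
        "seed": int(seed),
        "design_name": design.name,
        "design": design,
        "phenomodel": phenomodel,
    }

    pops: dict[str, SimulatedPopulation] = {
        name: _founder_population(name, g, design.lmap, design.rule)
        for name, g in design.founders.items()
    }
    last = None
    for step, stream in zip(steps, streams):
        gam_stream, phen_stream = stream.spawn(2)
        rng = np.random.default_rng(gam_stream)
        if isinstance(step, (CrossStep, SelfStep)):
            if isinstance(step, CrossStep):
                mother = pops[step.mother].genotype(0)
                father = pops[step.father].genotype(0)
            else:
                mother = father = pops[step.parent].genotype(0)
            mh, mi = _sample_gametes(mother, design.rule, "female", step.n, rng)
            fh, fi = _sample_gametes(father, design.rule, "male", step.n, rng)
            pop = SimulatedPopulation(
                step.name, design.lmap, design.rule, mh, fh, mi, fi,
                dict(prov_base),
            )
            if phenomodel is not None:
                sample_phenotypes(pop, phenomodel, rng=np.random.default_rng(phen_stream))
        else:
            src = pops[step.source]
            mask = src._match(step.where)
            if not mask.any():
                raise SelectionError(
                    f"selection step {step.name!r}: no individual in "
                    f"{step.source!r} satisfies the predicate"
                )
            if step.keep == "first":
                first = int(np.flatnonzero(mask)[0])
                mask = np.zeros(src.size, dtype=bool)
                mask[first] = True
            pop = src.filter(mask, generation=step.name)
        pops[step.name] = pop
        last = pop
    if last is None:
        raise DesignError("design has no steps")
    return pops if return_all else last


def sample_phenotypes(
    population: SimulatedPopulation,
    phenomodel: PhenotypeModel,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedPopulation:
    """Attach grain area, culm length, fertility and true class labels.

    Traits are class mean + Gaussian noise, deterministic per seed.
    Fertility is the genotype's surviving-gamete fraction, not a random
    draw.  Culm traits are produced only when the map carries the d60 and
    Gal loci.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    lmap = population.lmap
    names = lmap.names
    if phenomodel.grain_locus in names:
        gcls = grain_classifier(lmap.locus(phenomodel.grain_locus))
        labels = population.classify(gcls)
        means = np.array([phenomodel.grain_means[l] for l in labels])
        population.traits["grain_class"] = labels
        population.traits["grain_area"] = means + rng.normal(
            0.0, phenomodel.grain_sd, population.size
        )
    if phenomodel.d60_locus in names and phenomodel.gal_locus in names:
        ccls = culm_classifier(
            lmap.locus(phenomodel.d60_locus), lmap.locus(phenomodel.gal_locus)
        )
        labels = population.classify(ccls)
        means = np.array([phenomodel.culm_means[l] for l in labels])
        population.traits["culm_class"] = labels
        population.traits["culm_length"] = means + rng.normal(
            0.0, phenomodel.culm_sd, population.size
        )
    population.traits["fertility"] = population.fertility()
    return population


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------


def _normalise_marker_map(marker_map) -> pd.DataFrame:
    if isinstance(marker_map, pd.DataFrame):
        df = marker_map.copy()
    elif isinstance(marker_map, Mapping):
        df = pd.DataFrame(
            {"marker": list(marker_map), "position_mb": list(marker_map.values())}
        )
    else:
        df = pd.DataFrame(marker_map, columns=["marker", "chromosome", "position_mb"])
    if "chromosome" not in df.columns:
        df["chromosome"] = None
    return df[["marker", "chromosome", "position_mb"]]


def design_with_markers(
    design: CrossDesign,
    marker_map,
    anchor: str = "GW2",
    cm_per_mb: float = CM_PER_MB_DEFAULT,
) -> tuple[CrossDesign, tuple[str, ...]]:
    """Augment a design's map and founders with marker loci.

    Markers become ordinary biallelic loci (alleles ``<name>.A`` donor /
    ``<name>.B`` recurrent) inserted into the anchor locus's linkage group
    at their physical position; every adjacent recombination fraction in
    that group is recomputed from physical distance via Haldane at
    ``cm_per_mb``.  Each founder, assumed inbred, receives the marker
    allele matching its homozygous genotype at the anchor locus.
    """
    mm = _normalise_marker_map(marker_map)
    anchor_locus = design.lmap.locus(anchor)
    group = design.lmap.group_of(anchor)
    for loc in group.loci:
        if loc.position_mb is None:
            raise PlacementError(
                f"locus {loc.name!r} has no physical position; cannot merge markers"
            )
    for _, row in mm.iterrows():
        if (
            row["chromosome"] is not None
            and anchor_locus.chromosome is not None
            and str(row["chromosome"]) != str(anchor_locus.chromosome)
        ):
            raise PlacementError(
                f"marker {row['marker']!r} is on chromosome {row['chromosome']}, "
                f"not {anchor_locus.chromosome}"
            )

    marker_loci = [
        Locus(
            str(row["marker"]),
            (f"{row['marker']}.A", f"{row['marker']}.B"),
            anchor_locus.chromosome,
            float(row["position_mb"]),
        )
        for _, row in mm.iterrows()
    ]
    merged = sorted(
        list(group.loci) + marker_loci, key=lambda loc: (loc.position_mb, loc.name)
    )
    rs = tuple(
        haldane_d_to_r(cm_per_mb * (b.position_mb - a.position_mb))
        for a, b in zip(merged, merged[1:])
    )
    new_groups = tuple(
        LinkageGroup(tuple(merged), rs) if g is group else g
        for g in design.lmap.groups
    )
    new_map = LinkageMap(new_groups)

    new_founders = {}
    for name, g in design.founders.items():
        pair = g.pair(anchor)
        if pair[0] != pair[1]:
            raise DesignError(
                f"founder {name!r} is heterozygous at the anchor locus "
                f"{anchor!r}; marker provenance is undefined"
            )
        donor_side = pair[0] == anchor_locus.donor
        old_by_name = {
            n: (g.haplotypes[0][i], g.haplotypes[1][i])
            for i, n in enumerate(design.lmap.names)
        }
        h1, h2 = [], []
        for loc in new_map.loci:
            if loc.name in old_by_name:
                a, b = old_by_name[loc.name]
            else:
                allele = loc.donor if donor_side else loc.recurrent
                a = b = allele
            h1.append(a)
            h2.append(b)
        new_founders[name] = PhasedGenotype(new_map, (tuple(h1), tuple(h2)))

    new_design = CrossDesign(
        design.name, new_map, new_founders, design.steps, design.rule
    )
    return new_design, tuple(loc.name for loc in marker_loci)


def attach_markers(
    population: SimulatedPopulation,
    marker_map,
    anchor: str = "GW2",
    cm_per_mb: float = CM_PER_MB_DEFAULT,
) -> SimulatedPopulation:
    """Re-simulate a population jointly with marker loci.

    The population must have been produced by :func:`simulate_population`
    (its design and seed travel in the provenance).  The design is
    augmented with the markers and re-run under the same seed, so marker
    and trait genotypes in the returned population stem from a single
    joint sampling of gametes — markers literally inherit from the same
    haplotypes as the trait loci.
    """
    design = population.provenance.get("design")
    seed = population.provenance.get("seed")
    if design is None or seed is None:
        raise GrainlinkError(
            "population carries no design/seed provenance; "
            "attach markers by simulating an augmented design instead"
        )
    new_design, markers = design_with_markers(design, marker_map, anchor, cm_per_mb)
    pop = simulate_population(
        new_design,
        seed=seed,
        phenomodel=population.provenance.get("phenomodel"),
    )
    pop.provenance["markers"] = markers
    return pop


# ---------------------------------------------------------------------------
# analytic propagation (exact expected distributions for a design)
# ---------------------------------------------------------------------------


def _mixture_gametes(
    dist: dict, lmap: LinkageMap, rule, sex: str
) -> dict[Haplotype, float]:
    out: dict[Haplotype, float] = {}
    for pair, p in dist.items():
        gd = gamete_frequencies(PhasedGenotype(lmap, pair), rule=rule, sex=sex)
        for h, q in gd.frequencies.items():
            out[h] = out.get(h, 0.0) + p * q
    return out


def analytic_genotype_distribution(
    design: CrossDesign, upto: str | None = None
) -> dict[tuple[Haplotype, Haplotype], float]:
    """Exact phased-genotype distribution after each design step.

    Selfing couples the two gametes through the same (random) parent;
    crossing treats the two parents as independent draws from their
    populations' distributions.  Selection steps condition the
    distribution on the predicate (genotype predicates only — phenotype
    callables have no analytic counterpart and raise
    :class:`DesignError`).  Returns the distribution after ``upto`` (or
    the final step).
    """
    lmap, rule = design.lmap, design.rule
    dists: dict[str, dict] = {
        name: {tuple(sorted(g.haplotypes)): 1.0}
        for name, g in design.founders.items()
    }
    result = None
    for step in design.steps:
        if isinstance(step, CrossStep):
            gm = _mixture_gametes(dists[step.mother], lmap, rule, "female")
            gf = _mixture_gametes(dists[step.father], lmap, rule, "male")
            dist: dict = {}
            for hm, pm in gm.items():
                for hf, pf in gf.items():
                    key = tuple(sorted((hm, hf)))
                    dist[key] = dist.get(key, 0.0) + pm * pf
        elif isinstance(step, SelfStep):
            dist = {}
            for pair, p in dists[step.parent].items():
                g = PhasedGenotype(lmap, pair)
                zf = gamete_frequencies(g, rule=rule, sex="female")
                zm = gamete_frequencies(g, rule=rule, sex="male")
                for key, q in zygote_phased_distribution(zf, zm).items():
                    dist[key] = dist.get(key, 0.0) + p * q
        else:
            if callable(step.where):
                raise DesignError(
                    f"selection step {step.name!r}: callable predicates have "
                    "no analytic counterpart"
                )
            src = dists[step.source]
            dist = {}
            for pair, p in src.items():
                g = PhasedGenotype(lmap, pair)
                codes = g.codes()
                ok = True
                for name, wanted in step.where.items():
                    accept = (wanted,) if isinstance(wanted, str) else tuple(wanted)
                    if codes.get(name) not in accept:
                        ok = False
                        break
                if ok:
                    dist[pair] = dist.get(pair, 0.0) + p
            total = sum(dist.values())
            if total == 0.0:
                raise SelectionError(
                    f"selection step {step.name!r}: predicate has probability 0"
                )
            dist = {k: v / total for k, v in dist.items()}
        dists[step.name] = dist
        result = dist
        if upto is not None and step.name == upto:
            return dist
    if upto is not None:
        raise DesignError(f"no step named {upto!r} in design")
    if result is None:
        raise DesignError("design has no steps")
    return result


# ---------------------------------------------------------------------------
# built-in loci, maps and designs
# ---------------------------------------------------------------------------


def default_loci() -> tuple[Locus, Locus, Locus]:
    """The three segregating loci of the material.

    *GW2* sits 8.1 Mb from the distal end of the short arm of chromosome 2.
    The *D60* locus is placed at a toy 13.5 Mb — back-calculated from the
    estimated r = 0.176 via inverse Haldane at the package's 4 cM/Mb
    default — purely so that marker attachment has a fully positioned map.
    *Gal* is unlinked to both by default.
    """
    gw2 = Locus("GW2", ("GW2", "gw2"), "2", 8.1)
    d60 = Locus("D60", ("d60", "D60"), "2", 13.5)
    gal = Locus("Gal", ("Gal", "gal"))
    return gw2, d60, gal


def default_map(r: float = 0.176) -> LinkageMap:
    gw2, d60, gal = default_loci()
    return LinkageMap((LinkageGroup((gw2, d60), (r,)), LinkageGroup((gal,))))


def default_rule() -> LethalityRule:
    """Both-sex lethality of gametes carrying d60 together with gal."""
    return LethalityRule((frozenset({"d60", "gal"}),), "both")


def _founders(lmap: LinkageMap) -> dict[str, PhasedGenotype]:
    hap = {
        # haplotype order: GW2 locus, D60 locus, Gal locus
        "Koshihikari": ("gw2", "D60", "gal"),
        "Koshihikari-d60": ("gw2", "d60", "Gal"),
        "Inochinoichi": ("GW2", "D60", "gal"),
        "Nipponbare": ("gw2", "D60", "gal"),
        # the selected large-grain semidwarf segregant, idealised as the
        # double-donor homozygote in coupling (GW2 d60 on one chromosome)
        "GW2-d60-segregant": ("GW2", "d60", "Gal"),
    }
    return {k: PhasedGenotype.homozygous(lmap, v) for k, v in hap.items()}


def _two_step(name, mother, father, f1_name, n) -> tuple[Step, ...]:
    return (
        CrossStep(f1_name, mother, father, 1),
        SelfStep(name, f1_name, n),
    )


def f2_design(n: int = 186, r: float = 0.176) -> CrossDesign:
    """F2 of Koshihikari x Inochinoichi (grain locus only segregates)."""
    lmap = default_map(r)
    return CrossDesign(
        "f2", lmap, _founders(lmap),
        _two_step("F2", "Koshihikari", "Inochinoichi", "F1", n),
        default_rule(),
    )


def d60_f2_design(n: int = 186, r: float = 0.176) -> CrossDesign:
    """F2 of Koshihikari d60 x Inochinoichi: culm classes segregate 6:2:1."""
    lmap = default_map(r)
    return CrossDesign(
        "d60-f2", lmap, _founders(lmap),
        _two_step("F2", "Koshihikari-d60", "Inochinoichi", "F1", n),
        default_rule(),
    )


def bcnf2_design(label: str = "BC1F2", n: int = 112, r: float = 0.176) -> CrossDesign:
    """Koshihikari backcross to the GW2-d60 segregant, selfed.

    The backcross F1 is the coupling double heterozygote
    GW2 d60 Gal / gw2 D60 gal; its selfed progeny show the 1:2:6 culm
    ratio and the deviated grain segregation per culm class.
    """
    lmap = default_map(r)
    return CrossDesign(
        label.lower(), lmap, _founders(lmap),
        _two_step(label, "Koshihikari", "GW2-d60-segregant", f"{label}-F1", n),
        default_rule(),
    )


def bc1f2_design(n: int = 112, r: float = 0.176) -> CrossDesign:
    return bcnf2_design("BC1F2", n, r)


def bc4f2_design(n: int = 157, r: float = 0.176) -> CrossDesign:
    return bcnf2_design("BC4F2", n, r)


def d60_background_bcnf2_design(
    label: str = "BC3F2", n: int = 94, r: float = 0.176
) -> CrossDesign:
    """Backcross to Koshihikari d60, selfed: fixed d60d60 GalGal background.

    With every gamete carrying d60 and Gal, the lethality rule never
    fires, the linkage distortion disappears and the grain locus
    segregates 1:2:1.
    """
    lmap = default_map(r)
    return CrossDesign(
        label.lower(), lmap, _founders(lmap),
        _two_step(label, "Koshihikari-d60", "GW2-d60-segregant", f"{label}-F1", n),
        default_rule(),
    )


def nipponbare_f2_design(n: int = 1484, r: float = 0.176) -> CrossDesign:
    """F2 of Nipponbare x Inochinoichi for recessive-class marker mapping."""
    lmap = default_map(r)
    return CrossDesign(
        "nipponbare-f2", lmap, _founders(lmap),
        _two_step("F2", "Nipponbare", "Inochinoichi", "F1", n),
        default_rule(),
    )


BUILTIN_DESIGNS: dict[str, Callable[..., CrossDesign]] = {
    "f2": f2_design,
    "d60-f2": d60_f2_design,
    "bc1f2": bc1f2_design,
    "bc4f2": bc4f2_design,
    "bc2f2-d60": lambda n=24, r=0.176: d60_background_bcnf2_design("BC2F2", n, r),
    "bc3f2-d60": lambda n=94, r=0.176: d60_background_bcnf2_design("BC3F2", n, r),
    "nipponbare-f2": nipponbare_f2_design,
}


def builtin_design(name: str, **kwargs) -> CrossDesign:
    key = name.removeprefix("builtin:")
    if key not in BUILTIN_DESIGNS:
        raise DesignError(
            f"unknown builtin design {name!r}; choose from {sorted(BUILTIN_DESIGNS)}"
        )
    return BUILTIN_DESIGNS[key](**kwargs)
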