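"""Shared fixtures and the independent gamete-enumeration oracle."""

from __future__ import annotations

import itertools
import math

import pytest
from hypothesis import strategies as st

import grainlink as gl


# ---------------------------------------------------------------------------
# brute-force oracle: start-strand x per-interval crossover indicators
# ---------------------------------------------------------------------------


def oracle_gamete_frequencies(parent, lmap, rule=None, sex=None):
    """Exhaustive enumeration of gamete formation, independent of the
    package's origin-vector implementation.

    For every linkage group, enumerate the starting strand (1/2 each) and
    every vector of per-interval crossover indicators (probability r or
    1 - r each, independent — no interference); multiply across groups;
    accumulate haplotype probabilities; then apply the lethality rule and
    renormalise.  Tractable for maps of a few loci.
    """
    per_group = []
    for g in lmap.groups:
        k = len(g.loci)
        opts = []
        for start in (0, 1):
            for xo in itertools.product((0, 1), repeat=k - 1):
                p = 0.5
                for flip, r in zip(xo, g.r):
                    p *= r if flip else 1.0 - r
                opts.append((start, xo, p))
        per_group.append(opts)

    freq: dict[tuple, float] = {}
    for combo in itertools.product(*per_group):
        p = math.prod(c[2] for c in combo)
        hap = []
        off = 0
        for (start, xo, _), g in zip(combo, lmap.groups):
            origin = start
            for i in range(len(g.loci)):
                if i > 0 and xo[i - 1]:
                    origin ^= 1
                hap.append(parent.haplotypes[origin][off + i])
            off += len(g.loci)
        if p == 0.0:
            continue
        key = tuple(hap)
        freq[key] = freq.get(key, 0.0) + p

    if rule is not None and rule.applies_to(sex):
        dead = sum(p for h, p in freq.items() if rule.is_lethal(h))
        freq = {h: p / (1.0 - dead) for h, p in freq.items() if not rule.is_lethal(h)}
        fertility = 1.0 - dead
    else:
        fertility = 1.0
    return freq, fertility


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def lmap():
    return gl.default_map()


@pytest.fixture
def rule():
    return gl.default_rule()


@pytest.fixture
def f1(lmap):
    """The coupling F1 of the d60-combining backcrosses: GW2 d60 Gal / gw2 D60 gal."""
    return gl.PhasedGenotype.from_haplotypes(
        lmap, ("GW2", "d60", "Gal"), ("gw2", "D60", "gal")
    )


@pytest.fixture
def two_locus_map():
    """D60 and Gal only, unlinked — the classic 6:2:1 configuration."""
    d60 = gl.Locus("D60", ("d60", "D60"))
    gal = gl.Locus("Gal", ("Gal", "gal"))
    return gl.LinkageMap((gl.LinkageGroup((d60,)), gl.LinkageGroup((gal,))))


@pytest.fixture
def d60_f1(two_locus_map):
    return gl.PhasedGenotype.from_haplotypes(
        two_locus_map, ("d60", "Gal"), ("D60", "gal")
    )


@pytest.fixture
def culm(lmap):
    return gl.culm_classifier(lmap.locus("D60"), lmap.locus("Gal"))


@pytest.fixture
def grain(lmap):
    return gl.grain_classifier(lmap.locus("GW2"))


# ---------------------------------------------------------------------------
# hypothesis strategies for random maps and parents
# ---------------------------------------------------------------------------


@st.composite
def random_map_and_parent(draw, max_loci=4):
    n = draw(st.integers(2, max_loci))
    split = draw(st.integers(0, n - 1))  # 0 -> single group
    loci = [gl.Locus(f"L{i}", (f"L{i}a", f"L{i}b")) for i in range(n)]
    rs = [
        draw(st.floats(0.0, 0.5, allow_nan=False, allow_infinity=False))
        for _ in range(n - 1)
    ]
    if split == 0:
        groups = (gl.LinkageGroup(tuple(loci), tuple(rs[: n - 1])),)
    else:
        groups = (
            gl.LinkageGroup(tuple(loci[:split]), tuple(rs[: split - 1])),
            gl.LinkageGroup(tuple(loci[split:]), tuple(rs[split - 1 : n - 2])),
        )
    lmap = gl.LinkageMap(groups)
    h1 = tuple(draw(st.sampled_from(loc.alleles)) for loc in lmap.loci)
    h2 = tuple(draw(st.sampled_from(loc.alleles)) for loc in lmap.loci)
    parent = gl.PhasedGenotype(lmap, (h1, h2))
    return lmap, parent


@st.composite
def random_lethality(draw, lmap):
    """A lethality rule over two distinct loci of the map (possibly harmless)."""
    loci = lmap.loci
    i, j = draw(
        st.tuples(
            st.integers(0, len(loci) - 1), st.integers(0, len(loci) - 1)
        ).filter(lambda t: t[0] != t[1])
    )
    a = draw(st.sampled_from(loci[i].alleles))
    b = draw(st.sampled_from(loci[j].alleles))
    return gl.LethalityRule((frozenset({a, b}),), "both")
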