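"""Reading and writing designs, maps, genotype tables and results.

Cross designs live in YAML: loci (with donor/recurrent alleles and
optional Mb positions), linkage groups with adjacent-pair recombination
fractions, the lethality rule, inbred founders as haplotype lists, and
the ordered cross/self/select steps.  Genotype and marker tables are
plain CSV, one row per individual, one column per locus/marker, codes
``A/A``/``A/B``/``B/B`` (or single-letter ``A``/``H``/``B`` for markers).
"""

from __future__ import annotations

import hashlib
import json
from typing import Mapping

import pandas as pd
import yaml

from .errors import DesignError, GrainlinkError
from .segregation import ClassCountTable
from .simulate import CrossDesign, CrossStep, SelectStep, SelfStep
from .transmission import (
    LethalityRule,
    LinkageGroup,
    LinkageMap,
    Locus,
    PhasedGenotype,
)

__all__ = [
    "load_design",
    "design_from_dict",
    "design_to_dict",
    "design_fingerprint",
    "load_marker_map",
    "load_marker_table",
    "load_counts_csv",
]


def design_from_dict(doc: Mapping) -> CrossDesign:
    try:
        loci = {
            d["name"]: Locus(
                d["name"],
                tuple(d["alleles"]),
                str(d["chromosome"]) if d.get("chromosome") is not None else None,
                float(d["position_mb"]) if d.get("position_mb") is not None else None,
            )
            for d in doc["loci"]
        }
        groups = tuple(
            LinkageGroup(
                tuple(loci[n] for n in g["loci"]),
                tuple(float(x) for x in g.get("r", [])),
            )
            for g in doc["map"]["groups"]
        )
        lmap = LinkageMap(groups)
        rule = None
        if doc.get("lethality"):
            rule = LethalityRule(
                tuple(frozenset(c) for c in doc["lethality"]["combinations"]),
                doc["lethality"].get("sexes", "both"),
            )
        founders = {
            name: PhasedGenotype(
                lmap, (tuple(f["haplotypes"][0]), tuple(f["haplotypes"][1]))
            )
            for name, f in doc["founders"].items()
        }
        steps = []
        for s in doc["steps"]:
            if "cross" in s:
                steps.append(
                    CrossStep(s["name"], s["cross"][0], s["cross"][1], int(s.get("n", 1)))
                )
            elif "self" in s:
                steps.append(SelfStep(s["name"], s["self"], int(s.get("n", 1))))
            elif "select" in s:
                steps.append(
                    SelectStep(
                        s["name"], s["select"],
                        {k: tuple(v) if isinstance(v, list) else v
                         for k, v in s.get("where", {}).items()},
                        s.get("keep", "first"),
                    )
                )
            else:
                raise DesignError(f"step {s.get('name')!r}: need cross/self/select")
    except (KeyError, TypeError, IndexError) as e:
        raise DesignError(f"malformed design config: {e!r}") from e
    return CrossDesign(str(doc.get("name", "design")), lmap, founders, tuple(steps), rule)


def load_design(path) -> CrossDesign:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise DesignError(f"{path}: not a design config")
    return design_from_dict(doc)


def design_to_dict(design: CrossDesign) -> dict:
    def step_dict(s):
        if isinstance(s, CrossStep):
            return {"name": s.name, "cross": [s.mother, s.father], "n": s.n}
        if isinstance(s, SelfStep):
            return {"name": s.name, "self": s.parent, "n": s.n}
        return {
            "name": s.name,
            "select": s.source,
            "where": {k: list(v) if isinstance(v, tuple) else v
                      for k, v in (s.where.items() if isinstance(s.where, Mapping)
                                   else ())},
            "keep": s.keep,
        }

    return {
        "name": design.name,
        "loci": [
            {
                "name": loc.name,
                "alleles": list(loc.alleles),
                "chromosome": loc.chromosome,
                "position_mb": loc.position_mb,
            }
            for loc in design.lmap.loci
        ],
        "map": {
            "groups": [
                {"loci": [loc.name for loc in g.loci], "r": list(g.r)}
                for g in design.lmap.groups
            ]
        },
        "lethality": (
            {
                "combinations": [sorted(c) for c in design.rule.combinations],
                "sexes": design.rule.sexes,
            }
            if design.rule
            else None
        ),
        "founders": {
            name: {"haplotypes": [list(h) for h in g.haplotypes]}
            for name, g in design.founders.items()
        },
        "steps": [step_dict(s) for s in design.steps],
    }


def design_fingerprint(design: CrossDesign) -> str:
    """Stable sha256 over the canonical design dictionary."""
    blob = json.dumps(design_to_dict(design), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def load_marker_map(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"marker", "position_mb"}
    if not required <= set(df.columns):
        raise GrainlinkError(
            f"marker map needs columns {sorted(required)}, got {list(df.columns)}"
        )
    return df


def load_marker_table(path) -> pd.DataFrame:
    """Marker genotype CSV: one row per individual, marker columns, 'id' optional."""
    df = pd.read_csv(path)
    if "id" in df.columns:
        df = df.set_index("id")
    return df


def load_counts_csv(path) -> ClassCountTable:
    """CSV with columns class,observed (optional ratio)."""
    df = pd.read_csv(path)
    if not {"class", "observed"} <= set(df.columns):
        raise GrainlinkError("counts CSV needs columns: class, observed")
    ratio = tuple(df["ratio"]) if "ratio" in df.columns else None
    return ClassCountTable(
        labels=tuple(df["class"].astype(str)),
        observed=tuple(int(x) for x in df["observed"]),
        ratio=ratio,
    )
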