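"""Recombination-fraction estimators for two-point linkage.

The headline estimator is recessive-class counting.  Selecting the class
homozygous for a recessive allele (the *d60d60* semidwarfs, or the small
grain *gw2gw2* F2 segregants in marker mapping) fixes both of the gametes
an individual received, so each individual contributes two independently
scoreable gametes at a second locus.  With the trait allele in coupling
with the donor allele, a recombinant gamete is one carrying the *other*
side's allele, and

    r̂ = (n_het + 2 · n_recombinant_homozygotes) / (2 N)

is simply the recombinant-gamete fraction — which is also the conditional
maximum-likelihood estimate, because the class genotype probabilities are
binomial in r: ((1−r)², 2r(1−r), r²).  Selection on the recessive class
removes the distortion that gamete lethality imposes on the rest of the
population: among surviving *d60*-bearing gametes the probability of
carrying *gw2* is exactly r.

A general multinomial maximum-likelihood estimator over any class-count
model, the Haldane map function, and a per-marker recessive-class scan
(:func:`marker_trait_recombination`) round out the module.  Recombination
values are reported ×100, to one decimal, as in "17.6".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import (
    EmptyClassError,
    GrainlinkError,
    MapDistanceError,
    NonIdentifiableWarning,
)
from .segregation import ClassCountTable

__all__ = [
    "RecombEstimate",
    "counting_estimator",
    "ml_estimator",
    "recessive_class_probs",
    "marker_trait_recombination",
    "haldane_d_to_r",
    "haldane_r_to_d",
]


@dataclass(frozen=True)
class RecombEstimate:
    """A recombination-fraction estimate with provenance.

    ``r_hat`` normally lies in [0, 0.5]; a counting estimate can exceed it
    when the assumed phase is wrong, in which case the estimate is kept as
    computed and flagged rather than silently clipped.  ``n_gametes`` is
    the number of independently scored gametes (2 per recessive-class
    individual).  ``support`` is the likelihood-based interval
    {r : logL(r) >= logL(r̂) − 1} when available.
    """

    r_hat: float
    estimator: str  # "counting" | "ML" | "marker-trait"
    n_gametes: int
    support: tuple[float, float] | None = None
    flags: tuple[str, ...] = ()
    phase: str = "coupling"

    def __post_init__(self) -> None:
        if self.n_gametes < 1:
            raise EmptyClassError("an estimate needs at least one scored gamete")

    @property
    def recombination_value(self) -> float:
        """r̂ scaled ×100, the conventional reporting unit."""
        return 100.0 * self.r_hat

    def __str__(self) -> str:
        s = (
            f"r = {self.r_hat:.3f} (recombination value "
            f"{self.recombination_value:.1f}; {self.estimator}, "
            f"{self.n_gametes} gametes)"
        )
        if self.support is not None:
            s += f", support [{self.support[0]:.3f}, {self.support[1]:.3f}]"
        if self.flags:
            s += " [" + "; ".join(self.flags) + "]"
        return s


def counting_estimator(
    n_donor_homo: int, n_het: int, n_other_homo: int
) -> RecombEstimate:
    """Recessive-class counting estimate of r.

    Counts are individuals of the selected recessive class that are
    homozygous for the coupled donor allele, heterozygous, and homozygous
    for the opposite (recombinant-side) allele at the second locus.  Each
    individual contributes two gametes, so
    r̂ = (n_het + 2 n_other_homo) / (2 N).

    An estimate above 0.5 (more recombinant than parental gametes) is
    flagged: the assumed coupling phase is then almost certainly wrong.
    """
    counts = (int(n_donor_homo), int(n_het), int(n_other_homo))
    if any(c < 0 for c in counts):
        raise GrainlinkError("counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise EmptyClassError("empty recessive class: cannot estimate r")
    r_hat = (counts[1] + 2 * counts[2]) / (2 * n)
    flags: tuple[str, ...] = ()
    if r_hat > 0.5:
        flags = (
            "estimate outside [0, 0.5]",
            "recombinants outnumber parentals: check the assumed phase",
        )
    return RecombEstimate(r_hat, "counting", 2 * n, flags=flags)


def recessive_class_probs(r: float) -> tuple[float, float, float]:
    """Genotype probabilities within a recessive class under coupling.

    (donor homozygote, heterozygote, recombinant homozygote) =
    ((1−r)², 2r(1−r), r²): each of the two gametes is independently
    recombinant with probability r.
    """
    return ((1.0 - r) ** 2, 2.0 * r * (1.0 - r), r * r)


def _log_likelihood(counts: np.ndarray, probs: np.ndarray) -> float:
    if np.any((probs <= 0) & (counts > 0)):
        return -math.inf
    mask = counts > 0
    return float(np.sum(counts[mask] * np.log(probs[mask])))


def ml_estimator(
    observed: ClassCountTable | Sequence[int],
    model: Callable[[float], Sequence[float]] | None = None,
    grid_step: float = 1e-4,
    phase: str = "known",
) -> RecombEstimate:
    """Multinomial maximum-likelihood estimate of r over [0, 0.5].

    ``model`` maps r to the class probabilities, in the order of the
    observed counts; it defaults to :func:`recessive_class_probs` for
    three-class recessive-class counts.  Optimisation is a dense grid
    (``grid_step``) followed by golden-section refinement; ties break
    toward smaller r.  With ``phase="unknown"`` the likelihood is also
    maximised under the reversed class order (the opposite coupling) and
    the better phase is reported.

    A flat likelihood (classes uninformative for r) triggers a
    :class:`NonIdentifiableWarning`.
    """
    if isinstance(observed, ClassCountTable):
        counts = np.asarray(observed.observed, dtype=float)
    else:
        counts = np.asarray([int(x) for x in observed], dtype=float)
    if counts.sum() == 0:
        raise EmptyClassError("no observations to fit")
    if model is None:
        if len(counts) != 3:
            raise GrainlinkError("default recessive-class model needs 3 classes")
        model = recessive_class_probs

    def fit_one(probe: Callable[[float], np.ndarray]) -> tuple[float, float, tuple]:
        grid = np.arange(0.0, 0.5 + grid_step / 2, grid_step)
        ll = np.array([_log_likelihood(counts, probe(r)) for r in grid])
        finite = ll[np.isfinite(ll)]
        if finite.size == 0:
            raise GrainlinkError("likelihood is -inf everywhere on the grid")
        if finite.max() - finite.min() < 1e-9:
            warnings.warn(
                "likelihood is flat in r: classes are uninformative",
                NonIdentifiableWarning,
                stacklevel=3,
            )
        i = int(np.argmax(ll))  # first max: ties break toward smaller r
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda r: -_log_likelihood(counts, probe(r)),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-10},
            )
            r_hat, ll_max = float(res.x), -float(res.fun)
            if ll[i] >= ll_max:  # keep the grid point on numerical ties
                r_hat, ll_max = float(grid[i]), float(ll[i])
        else:
            r_hat, ll_max = float(grid[i]), float(ll[i])
        inside = grid[ll >= ll_max - 1.0]
        support = (float(inside.min()), float(inside.max())) if inside.size else None
        return r_hat, ll_max, support

    def probe_known(r: float) -> np.ndarray:
        return np.asarray(model(r), dtype=float)

    r_hat, ll_max, support = fit_one(probe_known)
    used_phase = "coupling"
    if phase == "unknown":
        r_rep, ll_rep, support_rep = fit_one(
            lambda r: np.asarray(model(r), dtype=float)[::-1]
        )
        if ll_rep > ll_max:
            r_hat, ll_max, support = r_rep, ll_rep, support_rep
            used_phase = "repulsion"
    return RecombEstimate(
        r_hat,
        "ML",
        int(2 * counts.sum()),
        support=support,
        phase=used_phase,
    )


# ---------------------------------------------------------------------------
# marker-trait scan
# ---------------------------------------------------------------------------

_CODE_ALIASES = {
    "A": "A", "H": "H", "B": "B",
    "A/A": "A", "A/B": "H", "B/A": "H", "B/B": "B",
}


def marker_trait_recombination(
    table: pd.DataFrame,
    marker_map: pd.DataFrame | Mapping[str, float] | None = None,
    donor_code: str = "A",
) -> pd.DataFrame:
    """Per-marker recombination values from a recessive-class genotype table.

    ``table`` holds one row per trait-recessive individual and one column
    per marker, coded ``A`` (donor homozygote), ``H`` (heterozygote),
    ``B`` (recurrent homozygote); ``A/A``-style codes are accepted.  All
    individuals must belong to the recessive (recurrent-homozygous) trait
    class, so under complete linkage every marker would be ``B``: donor-side
    alleles are the recombinants, and per marker

        recombination value = 100 · (n_H + 2 n_A) / (2 N).

    Missing genotypes shrink that marker's N and are reported in the
    ``n_missing`` column.  ``marker_map`` (marker → position in Mb, or a
    frame with ``marker``/``position_mb`` columns) sorts the output along
    the chromosome.
    """
    if table.shape[0] == 0:
        raise EmptyClassError("no individuals in the recessive-class table")
    positions: dict[str, float] = {}
    chromosomes: dict[str, str] = {}
    if isinstance(marker_map, pd.DataFrame):
        for _, row in marker_map.iterrows():
            positions[str(row["marker"])] = float(row["position_mb"])
            if "chromosome" in marker_map.columns:
                chromosomes[str(row["marker"])] = str(row["chromosome"])
    elif isinstance(marker_map, Mapping):
        positions = {str(k): float(v) for k, v in marker_map.items()}

    rows = []
    for marker in table.columns:
        col = table[marker]
        codes = col[col.notna()].astype(str).map(_CODE_ALIASES)
        if codes.isna().any():
            bad = sorted(set(col[col.notna()].astype(str)) - set(_CODE_ALIASES))
            raise GrainlinkError(f"marker {marker!r}: unknown genotype codes {bad}")
        n_used = int(codes.size)
        n_missing = int(col.isna().sum())
        if n_used == 0:
            raise EmptyClassError(f"marker {marker!r}: all genotypes missing")
        n_a = int((codes == donor_code).sum())
        n_h = int((codes == "H").sum())
        est = counting_estimator(n_used - n_a - n_h, n_h, n_a)
        est = RecombEstimate(
            est.r_hat, "marker-trait", est.n_gametes, flags=est.flags
        )
        rows.append(
            {
                "marker": marker,
                "chromosome": chromosomes.get(marker),
                "position_mb": positions.get(marker),
                "n": n_used,
                "n_missing": n_missing,
                "r_hat": est.r_hat,
                "recombination_value": round(est.recombination_value, 1),
                "flags": "; ".join(est.flags),
            }
        )
    out = pd.DataFrame(rows)
    if positions:
        out = out.sort_values("position_mb", kind="stable", ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Haldane map function
# ---------------------------------------------------------------------------


def haldane_d_to_r(d_cm: float) -> float:
    """Map distance (cM) to recombination fraction, no interference."""
    if d_cm < 0:
        raise MapDistanceError("map distance must be non-negative")
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


def haldane_r_to_d(r: float) -> float:
    """Recombination fraction to map distance (cM); r must be below 0.5."""
    if not 0.0 <= r < 0.5:
        raise MapDistanceError(
            f"r = {r} has no finite map distance (needs 0 <= r < 0.5)"
        )
    return -50.0 * math.log(1.0 - 2.0 * r)
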