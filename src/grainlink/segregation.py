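"""Goodness-of-fit tests for phenotype-class counts.

Segregation analysis reduces to one question: do observed class counts fit
the ratio a genetic model predicts?  The workhorse is the uncorrected
Pearson chi-square statistic

    X² = Σ (obs − exp)² / exp,   exp = n · ratio / Σ ratio,

with k − 1 degrees of freedom (minus one per parameter estimated from the
data, when applicable).  Expectations may come from a plain Mendelian
ratio (3:1, 1:2:1) or from the gamete-lethality transmission model
(1:2:6 culm classes), via :func:`fit_vs_model`.

Continuous traits (grain diameter in mm, grain area in mm²) are brought
into class form by :func:`classify_counts` with a :class:`ThresholdRule`
of ordered cut points; values falling outside an explicitly bounded rule
are reported, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .errors import (
    DegenerateExpectationError,
    EmptyClassError,
    GrainlinkError,
    InvalidRuleError,
)
from .transmission import (
    LinkageMap,
    PhenotypeClassifier,
    expected_class_probabilities,
)

__all__ = [
    "ClassCountTable",
    "GoodnessOfFitResult",
    "ThresholdRule",
    "chi_square_gof",
    "classify_counts",
    "fit_vs_model",
    "p_bracket",
]


@dataclass
class ClassCountTable:
    """Observed counts per phenotype/genotype class, with the tested ratio.

    Exactly one of ``ratio`` (e.g. (1, 2, 1)) or ``probabilities`` (already
    normalised, e.g. from the transmission model) should be given when the
    table is destined for a goodness-of-fit test; a table built from raw
    measurements may carry neither.  ``unclassified`` counts measurements
    that fell outside a bounded threshold rule.
    """

    labels: tuple[str, ...]
    observed: tuple[int, ...]
    ratio: tuple[float, ...] | None = None
    probabilities: tuple[float, ...] | None = None
    unclassified: int = 0

    def __post_init__(self) -> None:
        self.labels = tuple(str(x) for x in self.labels)
        self.observed = tuple(int(x) for x in self.observed)
        if len(self.labels) < 2:
            raise GrainlinkError("need at least two classes")
        if len(self.observed) != len(self.labels):
            raise GrainlinkError("one observed count per class label required")
        if any(c < 0 for c in self.observed):
            raise GrainlinkError("observed counts must be non-negative")
        if self.ratio is not None:
            self.ratio = tuple(float(x) for x in self.ratio)
            if len(self.ratio) != len(self.labels):
                raise GrainlinkError("ratio length must match classes")
            if any(x <= 0 for x in self.ratio):
                raise DegenerateExpectationError("ratio entries must be positive")
        if self.probabilities is not None:
            self.probabilities = tuple(float(x) for x in self.probabilities)
            if len(self.probabilities) != len(self.labels):
                raise GrainlinkError("probabilities length must match classes")
            if abs(sum(self.probabilities) - 1.0) > 1e-9:
                raise GrainlinkError("probabilities must sum to 1")

    @property
    def n(self) -> int:
        return sum(self.observed)

    def probs(self) -> tuple[float, ...]:
        if self.probabilities is not None:
            return self.probabilities
        if self.ratio is not None:
            s = sum(self.ratio)
            return tuple(x / s for x in self.ratio)
        raise GrainlinkError("table carries no expected ratio or probabilities")

    def expected(self) -> tuple[float, ...]:
        return tuple(self.n * p for p in self.probs())


@dataclass(frozen=True)
class GoodnessOfFitResult:
    """Pearson chi-square result with per-class contributions."""

    statistic: float
    df: int
    pvalue: float
    contributions: tuple[float, ...]
    expected: tuple[float, ...]

    @property
    def p_bracket(self) -> str:
        return p_bracket(self.pvalue)

    def __str__(self) -> str:
        return (
            f"chi2 = {self.statistic:.2f}, df = {self.df}, {self.p_bracket} "
            f"(exact P = {self.pvalue:.4f})"
        )


# table-style P brackets: a fine probability ladder, reported as an interval,
# the way segregation tests are conventionally printed ("0.35 < P < 0.40")
_P_GRID = (
    [0.001, 0.005, 0.01, 0.025]
    + [i / 20 for i in range(1, 20)]
    + [0.975, 0.99, 0.995, 0.999]
)


def _fmt_p(x: float) -> str:
    s = f"{x:.3f}"
    return s[:-1] if s.endswith("0") else s


def p_bracket(p: float) -> str:
    """Bracket an exact p-value between neighbouring tabular probabilities."""
    grid = sorted(set(_P_GRID))
    if p < grid[0]:
        return f"P < {_fmt_p(grid[0])}"
    if p > grid[-1]:
        return f"P > {_fmt_p(grid[-1])}"
    lo = max(x for x in grid if x <= p)
    hi = min(x for x in grid if x >= p)
    if lo == hi:
        return f"P = {_fmt_p(lo)}"
    return f"{_fmt_p(lo)} < P < {_fmt_p(hi)}"


def chi_square_gof(
    table: ClassCountTable, df: int | None = None, n_fitted: int = 0
) -> GoodnessOfFitResult:
    """Uncorrected Pearson chi-square goodness of fit for a count table.

    ``df`` defaults to classes − 1 − ``n_fitted``; pass ``df`` explicitly
    to override (some published tables print unconventional df).  No Yates
    continuity correction is applied.
    """
    if table.n == 0:
        raise EmptyClassError("no observations: chi-square undefined")
    exp = table.expected()
    if any(e <= 0 for e in exp):
        raise DegenerateExpectationError("expected count of zero in some class")
    contrib = tuple((o - e) ** 2 / e for o, e in zip(table.observed, exp))
    statistic = float(sum(contrib))
    if df is None:
        df = len(table.labels) - 1 - n_fitted
    if df < 1:
        raise GrainlinkError(f"degrees of freedom {df} < 1")
    pvalue = float(stats.chi2.sf(statistic, df))
    return GoodnessOfFitResult(statistic, df, pvalue, contrib, exp)


@dataclass(frozen=True)
class ThresholdRule:
    """Ordered cut points turning a continuous trait into classes.

    ``cuts`` are the len(labels) − 1 inner boundaries; intervals are
    half-open ``[low, high)``.  Optional ``lower``/``upper`` bounds make the
    rule bounded: values outside are counted as unclassified rather than
    forced into the end classes.
    """

    trait: str
    cuts: tuple[float, ...]
    labels: tuple[str, ...]
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cuts", tuple(float(c) for c in self.cuts))
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.cuts) != len(self.labels) - 1:
            raise InvalidRuleError(
                f"{len(self.labels)} labels need {len(self.labels) - 1} cut points"
            )
        bounds = [self.lower, *self.cuts, self.upper]
        inner = [b for b in bounds if b is not None]
        if any(b >= a for b, a in zip(inner, inner[1:])):
            raise InvalidRuleError("cut points must be strictly increasing")

    def classify_value(self, x: float) -> str | None:
        if self.lower is not None and x < self.lower:
            return None
        if self.upper is not None and x >= self.upper:
            return None
        for cut, label in zip(self.cuts, self.labels):
            if x < cut:
                return label
        return self.labels[-1]


def classify_counts(
    values: Sequence[float],
    rule: ThresholdRule,
    ratio: Sequence[float] | None = None,
) -> ClassCountTable:
    """Count trait measurements per threshold class.

    Non-finite values are rejected; values outside a bounded rule are
    tallied in the table's ``unclassified`` field.  An expected ``ratio``
    may be attached for a subsequent goodness-of-fit test.
    """
    counts = dict.fromkeys(rule.labels, 0)
    unclassified = 0
    for x in values:
        if not math.isfinite(x):
            raise GrainlinkError(f"non-finite trait value {x!r}")
        label = rule.classify_value(float(x))
        if label is None:
            unclassified += 1
        else:
            counts[label] += 1
    return ClassCountTable(
        labels=rule.labels,
        observed=tuple(counts[l] for l in rule.labels),
        ratio=tuple(ratio) if ratio is not None else None,
        unclassified=unclassified,
    )


def fit_vs_model(
    observed: ClassCountTable | Sequence[int],
    model,
    classifier: PhenotypeClassifier | None = None,
    lmap: LinkageMap | None = None,
    df: int | None = None,
) -> GoodnessOfFitResult:
    """Test observed class counts against model-derived expectations.

    ``model`` may be a mapping from class label to probability, a genotype
    distribution (with ``classifier`` and ``lmap``), or a cross design
    exposing ``analytic_distribution`` (with ``classifier``).  Observed
    counts given as a bare sequence are taken in the model's label order.
    """
    if isinstance(model, Mapping) and all(isinstance(k, str) for k in model):
        # already a label -> probability mapping
        probs_by_label = dict(model)
    else:
        if classifier is None:
            raise GrainlinkError("a classifier is required with a distribution/design")
        probs_by_label = expected_class_probabilities(model, classifier, lmap)

    labels = tuple(probs_by_label)
    if isinstance(observed, ClassCountTable):
        if set(observed.labels) != set(labels):
            raise GrainlinkError(
                f"observed labels {observed.labels} do not match model classes {labels}"
            )
        counts = tuple(
            observed.observed[observed.labels.index(l)] for l in labels
        )
    else:
        counts = tuple(int(x) for x in observed)
        if len(counts) != len(labels):
            raise GrainlinkError(
                f"{len(counts)} counts for {len(labels)} model classes"
            )
    table = ClassCountTable(
        labels=labels,
        observed=counts,
        probabilities=tuple(probs_by_label[l] for l in labels),
    )
    return chi_square_gof(table, df=df)
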