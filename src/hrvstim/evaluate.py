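"""Classifier evaluation: standard agreement metrics plus a hierarchical
cost-sensitive metric for ordered stimulus classes.

Standard metrics (accuracy, F1, Cohen's kappa with the Landis–Koch verbal
scale, multiclass Matthews correlation) are computed straight from a
confusion matrix. The cost metric addresses a gap those metrics share: when
stimulus classes carry a natural order (e.g. harmonic intervals ranked by
consonance), confusing two adjacent intervals is a milder error than
confusing a consonance with broadband noise, yet accuracy and MCC score both
mistakes identically.

The cost construction works as follows. Classes form a two-level hierarchy:
general classes (consonant, dissonant, noise, ...), each holding an ordered
list of subclasses. The maximum total cost per true class is ``C`` (default
1). ``C`` is split evenly into a sub-cost budget ``SC = C / n_general`` per
general class. For a true subclass, predicting a subclass of a *different*
general class ``h`` costs ``SC / n_h`` (uniform over that class's
subclasses). Within the true general class, the budget ``SC`` is distributed
over the subclasses so that the correct prediction costs zero and cost grows
with hierarchical distance, using one of three allocation rules:

- ``linear``      — cost proportional to distance rank,
- ``inverse_square`` — weights proportional to ``1 − 1/i²`` (steep early
  growth, near-flat tail; for strict applications),
- ``gompertz``    — weights shaped by the Gompertz sigmoid
  ``exp(−β·exp(−γ·i))``, tunable between the two regimes via ``β`` (horizontal
  displacement) and ``γ`` (growth rate).

Every row of the resulting cost matrix sums to exactly ``C``. The total cost
of a classification run is the elementwise product of confusion and cost
matrices, summed; dividing by the worst attainable cost (every instance sent
to its row's most expensive prediction) normalizes it into [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ClassHierarchy",
    "CostScheme",
    "ConfusionMatrix",
    "CostMatrix",
    "EvaluationReport",
    "confusion_matrix",
    "basic_metrics",
    "cohen_kappa",
    "mcc",
    "subcost_weights",
    "build_cost_matrix",
    "total_cost",
    "normalized_cost",
    "evaluate_report",
]

#: Landis–Koch interpretation bands for Cohen's kappa (upper edge, label).
KAPPA_SCALE = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


@dataclass(frozen=True)
class ClassHierarchy:
    """Ordered general classes, each with an ordered list of subclasses.

    Subclass order within a general class encodes hierarchical rank (e.g.
    degree of consonance); adjacent ranks are "similar" and misclassifying
    between them is cheap relative to distant ranks.
    """

    groups: tuple[tuple[str, tuple[str, ...]], ...]

    def __init__(
        self, groups: Mapping[str, Sequence[str]] | Sequence[tuple[str, Sequence[str]]]
    ) -> None:
        if isinstance(groups, Mapping):
            items = list(groups.items())
        else:
            items = list(groups)
        if not items:
            raise ValueError("hierarchy must contain at least one general class")
        norm: list[tuple[str, tuple[str, ...]]] = []
        for name, subs in items:
            subs = tuple(subs)
            if not subs:
                raise ValueError(f"general class {name!r} has no subclasses")
            norm.append((str(name), tuple(str(s) for s in subs)))
        names = [n for n, _ in norm]
        leaves = [s for _, subs in norm for s in subs]
        if len(set(names)) != len(names):
            raise ValueError("general class names must be unique")
        if len(set(leaves)) != len(leaves):
            raise ValueError("subclass names must be unique across the hierarchy")
        object.__setattr__(self, "groups", tuple(norm))

    @property
    def general_classes(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.groups)

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(s for _, subs in self.groups for s in subs)

    @property
    def n_general(self) -> int:
        return len(self.groups)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def subclasses(self, general: str) -> tuple[str, ...]:
        for name, subs in self.groups:
            if name == general:
                return subs
        raise KeyError(general)

    def locate(self, leaf: str) -> tuple[int, int]:
        """Return (general-class index, rank within that class) of a leaf."""
        for g, (_, subs) in enumerate(self.groups):
            if leaf in subs:
                return g, subs.index(leaf)
        raise KeyError(leaf)

    def general_of(self, leaf: str) -> str:
        g, _ = self.locate(leaf)
        return self.groups[g][0]


@dataclass(frozen=True)
class CostScheme:
    """Cost-allocation rule for within-class errors.

    kind : 'linear' | 'inverse_square' | 'gompertz'
    beta, gamma : Gompertz shape constants (horizontal displacement and
        growth rate); required positive when kind == 'gompertz'.
    C : maximum total cost per true class, default 1.
    """

    kind: str = "gompertz"
    beta: float = 1.0
    gamma: float = 1.0
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "inverse_square", "gompertz"):
            raise ValueError(f"unknown cost scheme kind {self.kind!r}")
        if self.kind == "gompertz" and (self.beta <= 0 or self.gamma <= 0):
            raise ValueError("gompertz scheme requires beta > 0 and gamma > 0")
        if self.C <= 0:
            raise ValueError("maximum cost C must be positive")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of (true class, predicted class) pairs in a fixed label order."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.shape[0] != len(self.labels):
            raise ValueError("label count must match matrix size")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.round(counts)) or np.any(counts < 0):
                raise ValueError("counts must be non-negative integers")
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_instances(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class CostMatrix:
    """Per-(true, predicted) misclassification cost; zero diagonal, rows sum to C."""

    costs: np.ndarray
    labels: tuple[str, ...]
    C: float = 1.0

    def __post_init__(self) -> None:
        costs = np.asarray(self.costs, dtype=float)
        if costs.ndim != 2 or costs.shape[0] != costs.shape[1]:
            raise ValueError("cost matrix must be square")
        if np.any(costs < 0):
            raise ValueError("costs must be non-negative")
        if not np.allclose(np.diag(costs), 0.0, atol=1e-12):
            raise ValueError("diagonal (correct classification) cost must be zero")
        rowsums = costs.sum(axis=1)
        if not np.allclose(rowsums, self.C, atol=1e-9):
            raise ValueError("every cost-matrix row must sum to C")
        object.__setattr__(self, "costs", costs)
        object.__setattr__(self, "labels", tuple(self.labels))


def confusion_matrix(
    truth: Sequence[str], predicted: Sequence[str], label_order: Sequence[str]
) -> ConfusionMatrix:
    """Tally (true, predicted) label pairs into a matrix with fixed label order."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    labels = tuple(label_order)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, labels)


def basic_metrics(cm: ConfusionMatrix) -> tuple[float, dict[str, float], float]:
    """Accuracy, per-class F1 and macro-averaged F1.

    Classes absent from both truth and predictions get F1 = 0 with a warning
    (they still count toward the macro average).
    """
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(counts) / total)
    per_class: dict[str, float] = {}
    for i, lab in enumerate(cm.labels):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        if tp + fn + fp == 0:
            warnings.warn(
                f"class {lab!r} has no true or predicted instances; F1 set to 0",
                stacklevel=2,
            )
            per_class[lab] = 0.0
        elif tp == 0:
            per_class[lab] = 0.0
        else:
            per_class[lab] = float(2 * tp / (2 * tp + fp + fn))
    macro = float(np.mean(list(per_class.values())))
    return accuracy, per_class, macro


def cohen_kappa(cm: ConfusionMatrix) -> tuple[float, str]:
    """Cohen's kappa with its Landis–Koch verbal label.

    Returns (value, label). The conventional scale covers [0, 1]; negative
    values are reported verbatim and labelled ``"below scale"``. A degenerate
    matrix with chance agreement 1 yields (nan, "undefined").
    """
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(counts) / total
    p_e = float(np.sum(counts.sum(axis=0) * counts.sum(axis=1)) / total**2)
    if p_e >= 1.0 - 1e-15:
        return float("nan"), "undefined"
    kappa = float((p_o - p_e) / (1 - p_e))
    if kappa < 0:
        return kappa, "below scale"
    for upper, label in KAPPA_SCALE:
        if kappa <= upper + 1e-12:
            return kappa, label
    return kappa, KAPPA_SCALE[-1][1]


def mcc(cm: ConfusionMatrix) -> float:
    """Multiclass Matthews correlation coefficient (Gorodkin's R_K).

    Reduces to the familiar binary formula for 2x2 matrices. Ranges over
    [-1, 1]: 1 is perfect classification, -1 total discrepancy, 0 a random
    or uncorrelated prediction. A zero denominator (a degenerate margin)
    returns 0 by convention.
    """
    counts = cm.counts.astype(float)
    s = counts.sum()
    if s == 0:
        raise ValueError("empty confusion matrix")
    c = np.trace(counts)
    t = counts.sum(axis=1)  # true-class totals
    p = counts.sum(axis=0)  # predicted-class totals
    cov = c * s - np.dot(t, p)
    denom = np.sqrt((s**2 - np.dot(p, p)) * (s**2 - np.dot(t, t)))
    if denom == 0:
        warnings.warn("MCC denominator is zero; returning 0 by convention", stacklevel=2)
        return 0.0
    return float(cov / denom)


def subcost_weights(n: int, scheme: CostScheme, sc: float) -> np.ndarray:
    """Within-class cost weights by hierarchical distance index i = 1..n.

    ``weights[0]`` (the correct prediction) is always 0; weights are
    non-decreasing and sum to ``sc`` exactly.

    linear:          weight_i = (i-1) * sc / sum(1..n-1)
    inverse_square:  weight_i ∝ 1 - 1/i**2
    gompertz:        weight_i ∝ exp(-beta*exp(-gamma*i)) - exp(-beta*exp(-gamma))
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sc <= 0:
        raise ValueError("sub-cost budget must be positive")
    if n == 1:
        return np.zeros(1)
    i = np.arange(1, n + 1, dtype=float)
    if scheme.kind == "linear":
        cost_minimum = sc / np.sum(np.arange(1, n))
        weights = (i - 1) * cost_minimum
    elif scheme.kind == "inverse_square":
        raw = 1.0 - 1.0 / i**2
        weights = sc * raw / raw.sum()
    else:  # gompertz
        g = np.exp(-scheme.beta * np.exp(-scheme.gamma * i))
        raw = g - g[0]
        weights = sc * raw / raw.sum()
    return weights


def build_cost_matrix(hierarchy: ClassHierarchy, scheme: CostScheme) -> CostMatrix:
    """Construct the full hierarchical cost matrix over leaf classes.

    For a true subclass at rank ``r`` of general class ``g``:

    - predicting within ``g``: the class's subclasses, sorted by
      (hierarchical distance ``|r - r'|``, rank), receive the sorted
      within-class weights in order — the correct class gets 0, the most
      distant gets the largest share, and the row spends exactly the
      sub-cost budget ``SC``. Equidistant neighbours are tie-broken by
      rank so the budget is conserved exactly.
    - predicting in a different general class ``h``: uniform cost
      ``SC / n_h`` per subclass, regardless of rank.

    A singleton general class has no within-class wrong option to spend its
    sub-cost on; that share is redistributed uniformly over the row's
    cross-class options so the full budget is always spent. Every row
    therefore sums to ``C``.
    """
    leaves = hierarchy.leaf_labels
    if len(leaves) < 2:
        raise ValueError("cost matrix needs at least two leaf classes")
    if len(set(leaves)) != len(leaves):  # pragma: no cover - hierarchy enforces this
        raise ValueError("duplicate class names")
    n_general = hierarchy.n_general
    sc = scheme.C / n_general
    k = len(leaves)
    costs = np.zeros((k, k))
    # leaf index offsets per general class
    offsets = np.cumsum([0] + [len(subs) for _, subs in hierarchy.groups])
    weights_per_group = [
        subcost_weights(len(subs), scheme, sc) for _, subs in hierarchy.groups
    ]
    for g, (_, subs) in enumerate(hierarchy.groups):
        n_g = len(subs)
        w = weights_per_group[g]
        # singleton class: its within-class budget moves to the cross costs
        cross_scale = 1.0 if n_g > 1 else n_general / (n_general - 1)
        for r in range(n_g):
            row = offsets[g] + r
            order = sorted(range(n_g), key=lambda rp: (abs(r - rp), rp))
            for widx, rp in enumerate(order):
                costs[row, offsets[g] + rp] = w[widx]
            for h, (_, subs_h) in enumerate(hierarchy.groups):
                if h == g:
                    continue
                costs[row, offsets[h] : offsets[h] + len(subs_h)] = (
                    cross_scale * sc / len(subs_h)
                )
    return CostMatrix(costs, leaves, C=scheme.C)


def total_cost(cm: ConfusionMatrix, cost: CostMatrix) -> float:
    """Sum of count x cost over all cells of the classification run."""
    if cm.labels != cost.labels:
        raise ValueError("confusion and cost matrices must share label order")
    if cm.counts.shape != cost.costs.shape:
        raise ValueError("shape mismatch")
    return float(np.sum(cm.counts * cost.costs))


def normalized_cost(cm: ConfusionMatrix, cost: CostMatrix) -> float:
    """Total cost divided by the worst attainable cost, in [0, 1].

    The worst case sends every instance of each true class to that row's
    most expensive prediction, so a value of 1 is attainable and 0 means a
    perfect classification.
    """
    if cm.n_instances == 0:
        raise ValueError("confusion matrix has no instances")
    tc = total_cost(cm, cost)
    row_counts = cm.counts.sum(axis=1)
    row_max = cost.costs.max(axis=1)
    max_cost = float(np.dot(row_counts, row_max))
    if max_cost <= 0:
        raise ValueError("maximum possible cost is zero")
    return tc / max_cost


@dataclass(frozen=True)
class EvaluationReport:
    """Bundle of agreement and cost metrics for one classification run."""

    accuracy: float
    f1_per_class: dict[str, float]
    macro_f1: float
    kappa: float
    kappa_label: str
    mcc: float
    total_cost: float
    normalized_cost: float
    n_instances: int
    labels: tuple[str, ...] = field(default=())

    def summary(self) -> str:
        lines = [
            "Classification evaluation",
            "-" * 42,
            f"instances        {self.n_instances}",
            f"accuracy         {self.accuracy:.4f}",
            f"macro F1         {self.macro_f1:.4f}",
            f"Cohen's kappa    {self.kappa:.4f} ({self.kappa_label})",
            f"MCC              {self.mcc:.4f}",
            f"total cost       {self.total_cost:.4f}",
            f"normalized cost  {self.normalized_cost:.4f}",
            "",
            "per-class F1:",
        ]
        for lab, v in self.f1_per_class.items():
            lines.append(f"  {lab:<16s} {v:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1_per_class": dict(self.f1_per_class),
            "macro_f1": self.macro_f1,
            "kappa": self.kappa,
            "kappa_label": self.kappa_label,
            "mcc": self.mcc,
            "total_cost": self.total_cost,
            "normalized_cost": self.normalized_cost,
            "n_instances": self.n_instances,
            "labels": list(self.labels),
        }


def evaluate_report(
    truth: Sequence[str],
    predicted: Sequence[str],
    hierarchy: ClassHierarchy,
    scheme: CostScheme | None = None,
) -> EvaluationReport:
    """One-call evaluation: confusion matrix, agreement metrics and costs."""
    scheme = scheme or CostScheme()
    cm = confusion_matrix(truth, predicted, hierarchy.leaf_labels)
    cost = build_cost_matrix(hierarchy, scheme)
    accuracy, per_class, macro = basic_metrics(cm)
    kappa, kappa_label = cohen_kappa(cm)
    return EvaluationReport(
        accuracy=accuracy,
        f1_per_class=per_class,
        macro_f1=macro,
        kappa=kappa,
        kappa_label=kappa_label,
        mcc=mcc(cm),
        total_cost=total_cost(cm, cost),
        normalized_cost=normalized_cost(cm, cost),
        n_instances=cm.n_instances,
        labels=cm.labels,
    )
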