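"""Somatochart coordinates and the 13-category somatotype classifier.

The somatochart projects the component triple (endo, meso, ecto) onto the
plane with the conventional axes

    x = ecto - endo,    y = 2*meso - (endo + ecto)

so a perfectly balanced physique sits at the origin, mesomorphs plot high,
endomorphs left and ectomorphs right.

The 13-category scheme labels a triple by dominance:

* *central* — no component differs from any other by more than 1.0;
* co-dominant ``X–Y`` — the two largest components differ by at most 0.5
  and both exceed the third;
* *balanced X* — one component dominates and the other two differ by at
  most 0.5;
* ``Y-ic X`` (e.g. "mesomorphic endomorph") — X dominates and Y exceeds
  the remaining component by more than 0.5.

Ties exactly at a threshold resolve toward the more central / co-dominant
label (inclusive comparisons); thresholds are arguments so alternative
readings of the scheme can be tested.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ArgumentError, DomainError
from .records import COMPONENT_FLOOR

#: The closed label set, in conventional order around the chart.
CATEGORY_LABELS: tuple[str, ...] = (
    "central",
    "balanced endomorph",
    "mesomorphic endomorph",
    "mesomorph-endomorph",
    "endomorphic mesomorph",
    "balanced mesomorph",
    "ectomorphic mesomorph",
    "mesomorph-ectomorph",
    "mesomorphic ectomorph",
    "balanced ectomorph",
    "endomorphic ectomorph",
    "endomorph-ectomorph",
    "ectomorphic endomorph",
)

_NOUN = {"endo": "endomorph", "meso": "mesomorph", "ecto": "ectomorph"}
_ADJ = {"endo": "endomorphic", "meso": "mesomorphic", "ecto": "ectomorphic"}
# canonical member order inside a co-dominant pair label
_PAIR_LABEL = {
    frozenset({"endo", "meso"}): "mesomorph-endomorph",
    frozenset({"meso", "ecto"}): "mesomorph-ectomorph",
    frozenset({"endo", "ecto"}): "endomorph-ectomorph",
}


@dataclass(frozen=True)
class SomatotypeCategory:
    """One of the 13 somatotype categories."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in CATEGORY_LABELS:
            raise ArgumentError(f"unknown somatotype category {self.label!r}")


def _check_components(endo: float, meso: float, ecto: float) -> None:
    for name, v in (("endomorphy", endo), ("mesomorphy", meso), ("ectomorphy", ecto)):
        if not (v >= COMPONENT_FLOOR):
            raise DomainError(f"{name} must be >= {COMPONENT_FLOOR}, got {v}")


def somatochart_coordinates(endo: float, meso: float, ecto: float) -> tuple[float, float]:
    """Planar somatochart coordinates of a component triple."""
    _check_components(endo, meso, ecto)
    return (ecto - endo, 2.0 * meso - (endo + ecto))


def classify_13(
    endo: float,
    meso: float,
    ecto: float,
    *,
    codominance_tol: float = 0.5,
    central_tol: float = 1.0,
    rounded: bool = False,
) -> SomatotypeCategory:
    """Deterministic 13-category label for a component triple.

    ``rounded=True`` first rounds each component to the nearest integer
    (half away from zero is irrelevant at the floor), a coarser reading
    useful for sensitivity analysis; statistics in this package always
    classify unrounded values.
    """
    _check_components(endo, meso, ecto)
    if rounded:
        endo, meso, ecto = (round(endo), round(meso), round(ecto))
    values = {"endo": endo, "meso": meso, "ecto": ecto}

    spread = max(values.values()) - min(values.values())
    if spread <= central_tol:
        return SomatotypeCategory("central")

    # sort descending; stable name order breaks exact value ties so that
    # equal top-two values still yield the canonical pair label
    order = sorted(values, key=lambda k: values[k], reverse=True)
    v1, v2, v3 = (values[k] for k in order)
    first, second, third = order

    if v1 - v2 <= codominance_tol:
        # not central, so v1 - v3 > central_tol, hence both v1 and v2
        # exceed v3: a genuine co-dominant pair
        return SomatotypeCategory(_PAIR_LABEL[frozenset({first, second})])
    if v2 - v3 <= codominance_tol:
        return SomatotypeCategory(f"balanced {_NOUN[first]}")
    return SomatotypeCategory(f"{_ADJ[second]} {_NOUN[first]}")


def plot_somatochart(
    triples: Iterable[tuple[float, float, float]],
    *,
    labels: Iterable[str] | None = None,
    title: str = "Somatochart",
    path=None,
):
    """Scatter cohort component triples on the standard somatochart axes.

    Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = [somatochart_coordinates(*t) for t in triples]
    fig, ax = plt.subplots(figsize=(5, 5))
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    ax.scatter(xs, ys, s=18, alpha=0.7)
    if labels is not None:
        for (x, y), lab in zip(pts, labels):
            ax.annotate(lab, (x, y), fontsize=6, alpha=0.6)
    ax.axhline(0, color="gray", lw=0.5)
    ax.axvline(0, color="gray", lw=0.5)
    ax.set_xlabel("ectomorphy - endomorphy")
    ax.set_ylabel("2*mesomorphy - (endomorphy + ectomorphy)")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def category_agreement(
    paired_labels: Sequence[tuple[str, str]] | Iterable[tuple[str, str]],
) -> tuple[float, Counter]:
    """Percent agreement and per-category discrepancy tally.

    Takes ``(reference, candidate)`` label pairs; returns the percentage of
    exact matches and a Counter keyed by the *reference* category of each
    mismatch (the breakdown format used for reporting which somatotypes the
    candidate method misclassifies).
    """
    pairs = list(paired_labels)
    if not pairs:
        raise ArgumentError("category_agreement requires a non-empty pair list")
    mismatches = Counter(ref for ref, cand in pairs if ref != cand)
    n = len(pairs)
    matches = n - sum(mismatches.values())
    return 100.0 * matches / n, mismatches
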