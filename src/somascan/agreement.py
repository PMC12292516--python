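"""Method-comparison statistics for validating one measurement method
against another.

For each quantity measured by both a reference method and a candidate
method on the same subjects, the battery computes:

* Bland-Altman bias and 95% limits of agreement (mean difference
  +/- 1.96 * SD of differences, sample SD);
* intraclass correlation in two two-way single-measure forms — absolute
  agreement ICC(A,1), which penalises systematic offsets, and consistency
  ICC(C,1), which does not;
* standard error of estimate (SEE): residual SE of regressing candidate on
  reference, n-2 denominator;
* standard measurement error (SME, a.k.a. SEM): pooled SD * sqrt(1 - ICC),
  reported for both ICC forms;
* within-subject coefficient of variation:
  100 * (SD_diff / sqrt(2)) / grand mean;
* root mean square error of the paired differences.

Signed and absolute difference summaries are both reported, since the two
answer different questions (bias direction vs typical error size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, DomainError, SingularFitError, UndefinedStatisticError

Pairs = Sequence[tuple[float, float]]


def _as_arrays(pairs: Pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ArgumentError("pairs must be a sequence of (reference, candidate) tuples")
    return arr[:, 0], arr[:, 1]


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    #: per-pair (mean, difference) points for plotting
    points: tuple[tuple[float, float], ...]


def bland_altman(pairs: Pairs) -> BlandAltman:
    """Bias and 95% limits of agreement for candidate - reference.

    Differences are candidate minus reference; limits are mean +/- 1.96
    sample standard deviations (n-1 denominator, fixed 1.96 multiplier —
    no small-sample t correction).
    """
    ref, cand = _as_arrays(pairs)
    if len(ref) < 2:
        raise ArgumentError(f"bland_altman needs >= 2 pairs, got {len(ref)}")
    diff = cand - ref
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    points = tuple(zip(((ref + cand) / 2.0).tolist(), diff.tolist()))
    return BlandAltman(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd, points)


def _anova_mean_squares(ref: np.ndarray, cand: np.ndarray) -> tuple[float, float, float, int]:
    """Two-way (subjects x methods) ANOVA mean squares for n subjects, k=2."""
    data = np.column_stack([ref, cand])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((data - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)  # guard tiny negative rounding
    return msr, msc, mse, n


def icc(pairs: Pairs, form: str = "agreement") -> float:
    """Two-way mixed, single-measure intraclass correlation.

    ``form="agreement"`` gives ICC(A,1) (absolute agreement: a constant
    offset between methods lowers it); ``form="consistency"`` gives
    ICC(C,1) (offsets are ignored).  Both derive from the same two-way
    ANOVA decomposition.
    """
    if form not in ("agreement", "consistency"):
        raise ArgumentError(f"form must be 'agreement' or 'consistency', got {form!r}")
    ref, cand = _as_arrays(pairs)
    if len(ref) < 3:
        raise ArgumentError(f"icc needs >= 3 pairs, got {len(ref)}")
    msr, msc, mse, n = _anova_mean_squares(ref, cand)
    k = 2
    if msr == 0 and mse == 0:
        raise UndefinedStatisticError("zero between-subject variance; ICC undefined")
    if form == "consistency":
        denom = msr + (k - 1) * mse
    else:
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise UndefinedStatisticError("degenerate ANOVA decomposition; ICC undefined")
    return (msr - mse) / denom


def see(pairs: Pairs) -> float:
    """Standard error of estimate: residual SE of OLS of candidate on
    reference, n-2 denominator."""
    ref, cand = _as_arrays(pairs)
    n = len(ref)
    if n < 3:
        raise ArgumentError(f"see needs >= 3 pairs, got {n}")
    if np.ptp(ref) == 0:
        raise SingularFitError("reference values are constant; regression undefined")
    slope, intercept = np.polyfit(ref, cand, 1)
    resid = cand - (slope * ref + intercept)
    return float(np.sqrt(np.sum(resid**2) / (n - 2)))


def rmse(pairs: Pairs) -> float:
    """Root mean square of the paired differences."""
    ref, cand = _as_arrays(pairs)
    if len(ref) < 1:
        raise ArgumentError("rmse needs at least one pair")
    return float(np.sqrt(np.mean((cand - ref) ** 2)))


def pooled_sd(pairs: Pairs) -> float:
    """Pooled between-subject SD of the two methods: sqrt of the mean of the
    per-method sample variances."""
    ref, cand = _as_arrays(pairs)
    return float(np.sqrt((np.var(ref, ddof=1) + np.var(cand, ddof=1)) / 2.0))


def sme(pairs: Pairs, form: str = "agreement") -> float:
    """Standard measurement error: pooled SD * sqrt(1 - ICC_form)."""
    r = icc(pairs, form)
    return pooled_sd(pairs) * math.sqrt(max(1.0 - r, 0.0))


def cv(pairs: Pairs) -> float:
    """Within-subject coefficient of variation (%) for two methods:
    100 * (SD_diff / sqrt(2)) / grand mean of all measurements."""
    ref, cand = _as_arrays(pairs)
    if len(ref) < 2:
        raise ArgumentError(f"cv needs >= 2 pairs, got {len(ref)}")
    grand = float(np.mean(np.concatenate([ref, cand])))
    if grand <= 0:
        raise DomainError(f"grand mean must be positive, got {grand}")
    sd_within = float(np.std(cand - ref, ddof=1)) / math.sqrt(2.0)
    return 100.0 * sd_within / grand


@dataclass(frozen=True)
class ComponentAgreement:
    """All agreement statistics for one measured quantity."""

    n: int
    mean_diff: float
    sd_diff: float
    mean_abs_diff: float
    sd_abs_diff: float
    loa_low: float
    loa_high: float
    see: Optional[float]
    icc_a: Optional[float]
    sme_a: Optional[float]
    cv_a: Optional[float]
    rmse: float
    icc_r: Optional[float]
    sme_r: Optional[float]
    cv_r: Optional[float]
    #: statistics that could not be computed, with reasons
    errors: tuple[tuple[str, str], ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class AgreementReport:
    """Per-quantity method-comparison table (reference vs candidate)."""

    components: dict[str, ComponentAgreement]
    #: quantities whose whole row failed, with reasons
    failed: dict[str, str] = field(default_factory=dict)

    #: column order used when rendering the report as a table
    COLUMNS = (
        "n",
        "mean_diff",
        "sd_diff",
        "mean_abs_diff",
        "sd_abs_diff",
        "loa_low",
        "loa_high",
        "see",
        "icc_a",
        "sme_a",
        "cv_a",
        "rmse",
        "icc_r",
        "sme_r",
        "cv_r",
    )

    def to_frame(self) -> pd.DataFrame:
        rows = {
            name: {col: getattr(comp, col) for col in self.COLUMNS}
            for name, comp in self.components.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index")[list(self.COLUMNS)]

    def write(self, path: str | Path) -> None:
        """Write the report as CSV or XLSX depending on the suffix."""
        path = Path(path)
        frame = self.to_frame()
        if path.suffix.lower() == ".xlsx":
            frame.to_excel(path, index_label="component")
        else:
            frame.to_csv(path, index_label="component", float_format="%.12g")


def _component_row(pairs: Pairs) -> ComponentAgreement:
    ba = bland_altman(pairs)
    ref, cand = _as_arrays(pairs)
    adiff = np.abs(cand - ref)
    errors: list[tuple[str, str]] = []

    def attempt(name, fn):
        try:
            return fn()
        except (ArgumentError, DomainError, SingularFitError, UndefinedStatisticError) as e:
            errors.append((name, str(e)))
            return None

    return ComponentAgreement(
        n=len(ref),
        mean_diff=ba.mean_diff,
        sd_diff=ba.sd_diff,
        mean_abs_diff=float(np.mean(adiff)),
        sd_abs_diff=float(np.std(adiff, ddof=1)) if len(ref) > 1 else 0.0,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        see=attempt("see", lambda: see(pairs)),
        icc_a=attempt("icc_a", lambda: icc(pairs, "agreement")),
        sme_a=attempt("sme_a", lambda: sme(pairs, "agreement")),
        cv_a=attempt("cv_a", lambda: cv(pairs)),
        rmse=rmse(pairs),
        icc_r=attempt("icc_r", lambda: icc(pairs, "consistency")),
        sme_r=attempt("sme_r", lambda: sme(pairs, "consistency")),
        cv_r=attempt("cv_r", lambda: cv(pairs)),
        errors=tuple(errors),
    )


def agreement_report(component_pairs: Mapping[str, Pairs]) -> AgreementReport:
    """Assemble the full battery per quantity.

    A failing statistic marks its cell (``None`` plus an entry in
    ``errors``) rather than aborting the report; a quantity whose pairs are
    unusable altogether lands in ``failed``.
    """
    components: dict[str, ComponentAgreement] = {}
    failed: dict[str, str] = {}
    for name, pairs in component_pairs.items():
        try:
            if len(pairs) < 3:
                raise ArgumentError(f"component {name!r} needs >= 3 pairs, got {len(pairs)}")
            components[name] = _component_row(pairs)
        except (ArgumentError, DomainError) as e:
            failed[name] = str(e)
    return AgreementReport(components=components, failed=failed)


def bland_altman_plot(pairs: Pairs, *, title: str = "", path: str | Path | None = None):
    """Mean-difference scatter with bias and limits-of-agreement lines.

    Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(pairs)
    means = [p[0] for p in ba.points]
    diffs = [p[1] for p in ba.points]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, marker="x", color="goldenrod")
    ax.axhline(ba.mean_diff, color="gray", linestyle="--", label=f"bias {ba.mean_diff:.2f}")
    ax.axhline(ba.loa_high, color="red", linestyle="--", label=f"+1.96 SD {ba.loa_high:.2f}")
    ax.axhline(ba.loa_low, color="green", linestyle="--", label=f"-1.96 SD {ba.loa_low:.2f}")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("candidate - reference")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
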