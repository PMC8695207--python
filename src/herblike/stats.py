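"""Group-comparison statistics for compound libraries.

Implements the comparison machinery used to contrast soil-active and
plate-only-active compounds with commercial herbicides: per-descriptor
two-sample t-tests, Fisher's exact test on positive vs non-positive
formal charge, empirical charge CDFs, central percentile intervals and
score histograms. The heavy lifting is delegated to scipy/numpy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .descriptors import CompoundRecord
from .errors import IncompleteDescriptorsError

#: Descriptor rows of the group-comparison report, in the conventional
#: presentation order (formal charge is handled by Fisher's test instead).
COMPARISON_DESCRIPTORS: tuple[str, ...] = (
    "molar_mass",
    "aromatic_pct",
    "rotatable_bonds",
    "hba74",
    "hbd74",
    "psa",
    "logd74",
    "logs",
    "logp",
)


@dataclass(frozen=True)
class ComparisonRow:
    """Two-sample t-test summary for one descriptor."""

    descriptor: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_stat: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class FisherResult:
    """Fisher's exact test on the 2×2 positive-charge × group table.

    ``table`` rows are charge class (positive ≥ +1, then non-positive ≤ 0),
    columns are group A then group B.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    odds_ratio: float


def _descriptor_values(records: Sequence[CompoundRecord], name: str) -> np.ndarray:
    vals = []
    for rec in records:
        if rec.descriptors is None:
            raise IncompleteDescriptorsError(rec.compound_id, (name,))
        vals.append(getattr(rec.descriptors, name))
    return np.asarray(vals, dtype=float)


def compare_descriptors(
    group_a: Sequence[CompoundRecord],
    group_b: Sequence[CompoundRecord],
    alpha: float = 0.05,
    variant: str = "pooled",
) -> list[ComparisonRow]:
    """Per-descriptor two-sample t-tests between two compound groups.

    ``variant`` selects the classic pooled-variance Student's t
    ("pooled", default) or Welch's unequal-variance t ("welch"). Count
    descriptors are tested as printed reports conventionally do, i.e.
    with the same t-test despite their discreteness.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant: {variant!r}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError(
            f"each group needs >= 2 records, got {len(group_a)} and {len(group_b)}"
        )
    rows = []
    for name in COMPARISON_DESCRIPTORS:
        a = _descriptor_values(group_a, name)
        b = _descriptor_values(group_b, name)
        res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
        t = float(res.statistic)
        p = float(res.pvalue)
        if np.isnan(t):  # zero pooled variance, identical constant groups
            t, p = 0.0, 1.0
        rows.append(
            ComparisonRow(
                descriptor=name,
                mean_a=float(a.mean()),
                sd_a=float(a.std(ddof=1)),
                n_a=len(a),
                mean_b=float(b.mean()),
                sd_b=float(b.std(ddof=1)),
                n_b=len(b),
                t_stat=t,
                p_value=p,
                significant=bool(p < alpha),
            )
        )
    return rows


def comparison_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Comparison rows as a tidy DataFrame (CSV-ready)."""
    return pd.DataFrame([row.__dict__ for row in rows])


def fisher_charge_test(
    group_a: Sequence[CompoundRecord], group_b: Sequence[CompoundRecord]
) -> FisherResult:
    """Two-sided Fisher's exact test on positive vs non-positive charge.

    Charge is dichotomised at pH 7.4 as positive (≥ +1) versus
    non-positive (≤ 0); the two-sided p-value sums the probabilities of
    all tables as or less probable than the observed one.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ca = _descriptor_values(group_a, "formal_charge74")
    cb = _descriptor_values(group_b, "formal_charge74")
    table = (
        (int((ca >= 1).sum()), int((cb >= 1).sum())),
        (int((ca <= 0).sum()), int((cb <= 0).sum())),
    )
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return FisherResult(table=table, p_value=float(p), odds_ratio=float(odds))


def charge_cdf(records: Sequence[CompoundRecord]) -> pd.Series:
    """Empirical CDF of formal charge over the integer charge range.

    Returns a Series indexed by integer charge c (from the minimum to the
    maximum observed) holding the fraction of compounds with charge ≤ c;
    non-decreasing and ending at 1.
    """
    if not records:
        raise ValueError("empty group")
    charges = _descriptor_values(records, "formal_charge74").astype(int)
    support = np.arange(charges.min(), charges.max() + 1)
    frac = [(charges <= c).mean() for c in support]
    return pd.Series(frac, index=support, name="cdf")


def percentile_interval(
    records: Sequence[CompoundRecord] | Sequence[float],
    descriptor: str | None = None,
    central_mass: float = 0.8,
) -> tuple[float, float]:
    """Empirical interval containing the central ``central_mass`` of values.

    Returns the ((1−m)/2, 1−(1−m)/2) quantiles, computed with linear
    interpolation between order statistics. Accepts either records plus a
    descriptor name, or a bare value sequence.
    """
    if not 0 < central_mass < 1:
        raise ValueError(f"central_mass must be in (0, 1), got {central_mass}")
    if len(records) == 0:
        raise ValueError("empty group")
    if descriptor is not None:
        values = _descriptor_values(records, descriptor)  # type: ignore[arg-type]
    else:
        values = np.asarray(records, dtype=float)
    tail = (1.0 - central_mass) / 2.0
    lo, hi = np.quantile(values, [tail, 1.0 - tail], method="linear")
    return float(lo), float(hi)


def score_histogram(
    scores: Sequence[float],
    bin_width: float = 1.0,
    score_range: tuple[float, float] = (-12.0, 18.0),
) -> pd.DataFrame:
    """Histogram of herbicide-likeness scores on half-point-aligned bins.

    Bins of width ``bin_width`` are anchored at the lower end of
    ``score_range`` (the attainable range of the default rules); the
    range is widened to cover any out-of-range score so that counts
    always sum to n. Returns a DataFrame with bin_left, bin_right, count.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    lo, hi = score_range
    lo = min(lo, np.floor(scores.min() / bin_width) * bin_width)
    hi = max(hi, np.ceil(scores.max() / bin_width) * bin_width)
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(scores, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
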