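"""Weighted herbicide-likeness scoring.

Each continuous descriptor is scored by how many reference standard
deviations the compound's value lies from the reference mean (bands
z ≤ 1, 1 < z ≤ 2, 2 < z ≤ 3, z > 3); each discrete descriptor by its
integer offset from the reference mode (−2…+2, plus a catch-all for
larger offsets). The total herbicide-likeness score is the plain sum of
the ten per-descriptor scores. Under the default published rules —
where log P is weighted double and a +2 formal charge is penalised
heavily — the maximum is 18 points and the minimum is −12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from .descriptors import (
    ALL_DESCRIPTORS,
    CONTINUOUS_DESCRIPTORS,
    DISCRETE_DESCRIPTORS,
    CompoundRecord,
    DescriptorSet,
    RejectedRow,
)
from .errors import IncompleteDescriptorsError
from .reference import ReferenceModel

#: Band labels for continuous descriptors, innermost first.
BAND_LABELS: tuple[str, ...] = ("within_1sd", "within_2sd", "within_3sd", "beyond_3sd")

#: Standard band scores for continuous descriptors.
STANDARD_BANDS: tuple[float, ...] = (1.5, 1.0, 0.5, -1.0)
#: log P is weighted double inside three standard deviations.
LOGP_BANDS: tuple[float, ...] = (3.0, 2.0, 1.0, -1.0)


@dataclass(frozen=True)
class DiscreteRule:
    """Offset-from-mode scores for one discrete descriptor.

    ``offsets`` covers offsets −2…+2; ``otherwise`` applies beyond ±2.
    """

    offsets: Mapping[int, float]
    otherwise: float

    def __post_init__(self) -> None:
        if set(self.offsets) != {-2, -1, 0, 1, 2}:
            raise ValueError(f"offsets must cover -2..+2, got {sorted(self.offsets)}")

    def score(self, offset: int) -> float:
        return self.offsets[offset] if abs(offset) <= 2 else self.otherwise

    @property
    def max(self) -> float:
        return max(*self.offsets.values(), self.otherwise)

    @property
    def min(self) -> float:
        return min(*self.offsets.values(), self.otherwise)


@dataclass(frozen=True)
class ScoringRules:
    """Band scores per continuous descriptor and offset scores per discrete one."""

    continuous_bands: Mapping[str, tuple[float, float, float, float]]
    discrete_offsets: Mapping[str, DiscreteRule]

    def __post_init__(self) -> None:
        if set(self.continuous_bands) != set(CONTINUOUS_DESCRIPTORS):
            raise ValueError("continuous_bands must cover exactly the six continuous descriptors")
        if set(self.discrete_offsets) != set(DISCRETE_DESCRIPTORS):
            raise ValueError("discrete_offsets must cover exactly the four discrete descriptors")
        for name, bands in self.continuous_bands.items():
            if len(bands) != 4:
                raise ValueError(f"{name}: need 4 band scores, got {len(bands)}")

    @property
    def max_total(self) -> float:
        return max_score(self)

    @property
    def min_total(self) -> float:
        return min_score(self)


def default_rules(hba_na_policy: str = "mirrored") -> ScoringRules:
    """The published scoring rules.

    The H-bond acceptor row leaves its −1/−2 offsets unspecified;
    ``hba_na_policy`` decides how to fill them: "mirrored" (default)
    copies the +1/+2 scores, "strict" scores them with the catch-all −1.
    """
    if hba_na_policy not in ("mirrored", "strict"):
        raise ValueError(f"unknown hba_na_policy: {hba_na_policy!r}")
    symmetric = {-2: 0.5, -1: 1.0, 0: 1.5, 1: 1.0, 2: 0.5}
    if hba_na_policy == "mirrored":
        hba = dict(symmetric)
    else:
        hba = {-2: -1.0, -1: -1.0, 0: 1.5, 1: 1.0, 2: 0.5}
    return ScoringRules(
        continuous_bands={
            name: (LOGP_BANDS if name == "logp" else STANDARD_BANDS)
            for name in CONTINUOUS_DESCRIPTORS
        },
        discrete_offsets={
            "rotatable_bonds": DiscreteRule(dict(symmetric), -1.0),
            "hba74": DiscreteRule(hba, -1.0),
            "hbd74": DiscreteRule(dict(symmetric), -1.0),
            "formal_charge74": DiscreteRule(
                {-2: 1.0, -1: 2.0, 0: 3.0, 1: 2.0, 2: -3.0}, -1.0
            ),
        },
    )


def score_continuous(
    value: float, mean: float, sd: float, band_scores: Sequence[float]
) -> tuple[float, str]:
    """Score one continuous descriptor; returns (score, band label).

    The band is by |value − mean| / sd with closed upper bounds, so a
    value at exactly k·SD falls in the k-th band. Boundary comparisons
    tolerate 1e-9 relative rounding, so a value that sits on a band edge
    up to float representation error still gets the better score. With
    sd = 0 the value either matches the mean (innermost band) or is
    beyond 3 SD.
    """
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    if sd == 0:
        band = 0 if value == mean else 3
    else:
        d = abs(value - mean)
        for band, k in enumerate((1.0, 2.0, 3.0)):
            if d <= k * sd or math.isclose(d, k * sd, rel_tol=1e-9):
                break
        else:
            band = 3
    return float(band_scores[band]), BAND_LABELS[band]


def score_discrete(value: int, mode: int, rule: DiscreteRule) -> tuple[float, str]:
    """Score one discrete descriptor; returns (score, offset label)."""
    offset = int(value) - int(mode)
    label = f"mode{offset:+d}" if abs(offset) <= 2 else "beyond_pm2"
    return float(rule.score(offset)), label


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-descriptor scores and band/offset labels plus their exact total."""

    per_descriptor: Mapping[str, tuple[str, float]]
    total: float

    def scores(self) -> dict[str, float]:
        return {k: s for k, (_lab, s) in self.per_descriptor.items()}


def _exact_sum(scores: Sequence[float]) -> float:
    """Sum scores exactly; half-point rule sets use integer arithmetic."""
    doubled = [s * 2 for s in scores]
    if all(float(d).is_integer() for d in doubled):
        return sum(int(d) for d in doubled) / 2.0
    return float(sum(Fraction(s).limit_denominator(10**6) for s in scores))


def score_compound(
    descriptors: DescriptorSet, model: ReferenceModel, rules: ScoringRules
) -> ScoreBreakdown:
    """Score a complete descriptor set against a reference model.

    The total is the exact sum of the six continuous and four discrete
    per-descriptor scores (half-point arithmetic, no float drift).
    """
    if descriptors is None:
        raise IncompleteDescriptorsError("<unknown>", ALL_DESCRIPTORS)
    per: dict[str, tuple[str, float]] = {}
    for name in CONTINUOUS_DESCRIPTORS:
        mean, sd = model.continuous_stats[name]
        score, label = score_continuous(
            getattr(descriptors, name), mean, sd, rules.continuous_bands[name]
        )
        per[name] = (label, score)
    for name in DISCRETE_DESCRIPTORS:
        score, label = score_discrete(
            getattr(descriptors, name), model.discrete_modes[name], rules.discrete_offsets[name]
        )
        per[name] = (label, score)
    return ScoreBreakdown(per_descriptor=per, total=_exact_sum([s for _l, s in per.values()]))


def max_score(rules: ScoringRules) -> float:
    """Analytic maximum total: sum of per-descriptor maxima."""
    return _exact_sum(
        [max(b) for b in rules.continuous_bands.values()]
        + [r.max for r in rules.discrete_offsets.values()]
    )


def min_score(rules: ScoringRules) -> float:
    """Analytic minimum total: sum of per-descriptor minima."""
    return _exact_sum(
        [min(b) for b in rules.continuous_bands.values()]
        + [r.min for r in rules.discrete_offsets.values()]
    )


@dataclass(frozen=True)
class RankResult:
    """Output of :func:`rank_library`."""

    table: pd.DataFrame
    rejects: list[RejectedRow] = field(default_factory=list)
    threshold: float | None = None
    shortlist: list[str] = field(default_factory=list)

    @property
    def n_above_threshold(self) -> int:
        return len(self.shortlist)


def rank_library(
    records: Sequence[CompoundRecord],
    model: ReferenceModel,
    rules: ScoringRules,
    threshold: float | None = None,
) -> RankResult:
    """Score a library and rank it by total, descending.

    Ties are broken by compound_id lexicographically. Records that cannot
    be scored (missing descriptors) land in ``rejects``; ranking proceeds
    on the rest. With a ``threshold``, the ids of compounds whose total is
    ≥ threshold are reported as the shortlist, in rank order.
    """
    rows = []
    rejects: list[RejectedRow] = []
    for rec in records:
        if rec.descriptors is None:
            rejects.append(RejectedRow(rec.compound_id, "missing descriptors"))
            continue
        try:
            bd = score_compound(rec.descriptors, model, rules)
        except (ValueError, IncompleteDescriptorsError) as exc:
            rejects.append(RejectedRow(rec.compound_id, str(exc)))
            continue
        row: dict[str, object] = {"compound_id": rec.compound_id}
        for name in ALL_DESCRIPTORS:
            label, score = bd.per_descriptor[name]
            row[f"score_{name}"] = score
            row[f"class_{name}"] = label
        row["total"] = bd.total
        rows.append(row)

    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(
            ["total", "compound_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        table.insert(1, "rank", range(1, len(table) + 1))
    shortlist: list[str] = []
    if threshold is not None and not table.empty:
        shortlist = table.loc[table["total"] >= threshold, "compound_id"].tolist()
    return RankResult(table=table, rejects=rejects, threshold=threshold, shortlist=shortlist)
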