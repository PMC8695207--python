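"""Reference statistics of a herbicide (or other) compound library.

A :class:`ReferenceModel` holds, per continuous descriptor, the mean and
sample standard deviation of the reference library, and per discrete
descriptor its mode. The packaged default (:func:`published_reference`)
carries the printed statistics of the 360-commercial-herbicide set, so
scoring against it is reproducible without any dataset download.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .descriptors import (
    ALL_DESCRIPTORS,
    CONTINUOUS_DESCRIPTORS,
    DISCRETE_DESCRIPTORS,
    CompoundRecord,
)
from .errors import IncompleteDescriptorsError


@dataclass(frozen=True)
class ReferenceModel:
    """Per-descriptor reference statistics.

    continuous_stats maps each of the six continuous descriptors to
    (mean, sd); discrete_modes maps each of the four count descriptors to
    its modal value. ``provenance`` records where the numbers came from.
    """

    continuous_stats: Mapping[str, tuple[float, float]]
    discrete_modes: Mapping[str, int]
    n_reference: int
    provenance: str

    def __post_init__(self) -> None:
        have_c = set(self.continuous_stats)
        if have_c != set(CONTINUOUS_DESCRIPTORS):
            raise ValueError(
                f"continuous_stats must cover exactly {CONTINUOUS_DESCRIPTORS}, got {sorted(have_c)}"
            )
        have_d = set(self.discrete_modes)
        if have_d != set(DISCRETE_DESCRIPTORS):
            raise ValueError(
                f"discrete_modes must cover exactly {DISCRETE_DESCRIPTORS}, got {sorted(have_d)}"
            )
        for name, (_mean, sd) in self.continuous_stats.items():
            if sd < 0:
                raise ValueError(f"negative sd for {name}: {sd}")
        for name, mode in self.discrete_modes.items():
            if int(mode) != mode:
                raise ValueError(f"non-integer mode for {name}: {mode}")


def published_reference() -> ReferenceModel:
    """The published commercial-herbicide reference statistics (n = 360).

    Means ± SD for the continuous descriptors and modes for the discrete
    ones, exactly as printed (not refitted), so results are reproducible
    without the underlying database.
    """
    return ReferenceModel(
        continuous_stats={
            "molar_mass": (317.0, 88.0),
            "aromatic_pct": (25.0, 12.0),
            "psa": (72.0, 39.0),
            "logd74": (2.2, 2.4),
            "logs": (-3.5, 1.0),
            "logp": (2.9, 1.5),
        },
        discrete_modes={
            "rotatable_bonds": 5,
            "hba74": 2,
            "hbd74": 0,
            "formal_charge74": 0,
        },
        n_reference=360,
        provenance="published-2021",
    )


def _mode_smallest(values: Sequence[int]) -> int:
    """Most frequent value; ties broken toward the smallest value."""
    counts = Counter(values)
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def fit_reference(
    records: Sequence[CompoundRecord], provenance: str | None = None
) -> ReferenceModel:
    """Fit a ReferenceModel from a library of complete records.

    Continuous statistics are the arithmetic mean and the sample standard
    deviation (n−1 denominator); discrete modes are the most frequent
    value, smallest winning a tie. Order of records does not matter.

    Raises
    ------
    ValueError
        fewer than two records (sample SD undefined).
    IncompleteDescriptorsError
        a record without a full DescriptorSet, named in the message.
    """
    if len(records) < 2:
        raise ValueError(f"need at least 2 records to fit, got {len(records)}")
    for rec in records:
        if rec.descriptors is None:
            raise IncompleteDescriptorsError(rec.compound_id, ALL_DESCRIPTORS)

    continuous = {}
    for name in CONTINUOUS_DESCRIPTORS:
        vals = np.array([getattr(r.descriptors, name) for r in records], dtype=float)
        vals.sort()  # fixed reduction order: permutation-invariant to the bit
        continuous[name] = (float(vals.mean()), float(vals.std(ddof=1)))
    discrete = {}
    for name in DISCRETE_DESCRIPTORS:
        vals = [int(getattr(r.descriptors, name)) for r in records]
        discrete[name] = _mode_smallest(vals)
    return ReferenceModel(
        continuous_stats=continuous,
        discrete_modes=discrete,
        n_reference=len(records),
        provenance=provenance or "fitted",
    )


def save_reference(model: ReferenceModel, path: str | Path) -> None:
    """Serialise a model to a flat YAML file; round-trips losslessly."""
    doc = {
        "continuous": {k: [float(m), float(s)] for k, (m, s) in model.continuous_stats.items()},
        "discrete": {k: int(v) for k, v in model.discrete_modes.items()},
        "n_reference": int(model.n_reference),
        "provenance": model.provenance,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_reference(path: str | Path) -> ReferenceModel:
    """Load a model serialised by :func:`save_reference`."""
    doc = yaml.safe_load(Path(path).read_text())
    try:
        return ReferenceModel(
            continuous_stats={k: (float(v[0]), float(v[1])) for k, v in doc["continuous"].items()},
            discrete_modes={k: int(v) for k, v in doc["discrete"].items()},
            n_reference=int(doc["n_reference"]),
            provenance=str(doc["provenance"]),
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise ValueError(f"{path}: not a valid reference-model file ({exc})") from exc
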