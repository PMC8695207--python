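"""scikit-learn style estimator wrapping the scoring pipeline.

``HerbicideLikenessScorer`` is a transformer: ``fit`` establishes the
per-descriptor reference statistics (either fitted from the supplied
descriptor matrix or taken from the packaged published herbicide model),
``transform`` maps an n×10 descriptor matrix to the n×10 matrix of
per-descriptor scores, and ``score_samples`` returns the total
herbicide-likeness score per compound. It composes with sklearn
pipelines and ``clone``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .descriptors import ALL_DESCRIPTORS, DISCRETE_DESCRIPTORS, DescriptorSet
from .reference import ReferenceModel, published_reference
from .scoring import ScoringRules, default_rules, max_score, min_score, score_compound


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in ALL_DESCRIPTORS if c not in X.columns]
        if missing:
            raise ValueError(f"descriptor matrix lacks columns: {missing}")
        return X[list(ALL_DESCRIPTORS)]
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(ALL_DESCRIPTORS):
        raise ValueError(
            f"expected an (n, {len(ALL_DESCRIPTORS)}) descriptor matrix in canonical "
            f"column order {ALL_DESCRIPTORS}, got shape {X.shape}"
        )
    return pd.DataFrame(X, columns=list(ALL_DESCRIPTORS))


class HerbicideLikenessScorer(TransformerMixin, BaseEstimator):
    """Score compounds for herbicide-likeness against a reference library.

    Parameters
    ----------
    reference : "published" | "fit" | ReferenceModel
        Where the per-descriptor reference statistics come from:
        the packaged published herbicide statistics ("published", the
        default), a fit on the matrix passed to :meth:`fit` ("fit"),
        or an explicit :class:`ReferenceModel`.
    rules : ScoringRules or None
        Band/offset scoring rules; None selects the published defaults.
    hba_na_policy : "mirrored" | "strict"
        Fill-in for the unspecified H-bond-acceptor offsets when using
        the default rules; ignored if ``rules`` is given.

    Attributes
    ----------
    reference_model_ : ReferenceModel
    rules_ : ScoringRules
    continuous_stats_ : dict of descriptor -> (mean, sd)
    discrete_modes_ : dict of descriptor -> int
    n_reference_ : int
    max_score_, min_score_ : float
    """

    def __init__(self, reference="published", rules=None, hba_na_policy="mirrored"):
        self.reference = reference
        self.rules = rules
        self.hba_na_policy = hba_na_policy

    def fit(self, X=None, y=None):
        if isinstance(self.reference, ReferenceModel):
            model = self.reference
        elif self.reference == "published":
            model = published_reference()
        elif self.reference == "fit":
            if X is None:
                raise ValueError('reference="fit" requires a descriptor matrix X')
            frame = _as_frame(X)
            if len(frame) < 2:
                raise ValueError(f"need at least 2 rows to fit, got {len(frame)}")
            from .reference import fit_reference
            from .descriptors import CompoundRecord

            records = [
                CompoundRecord(
                    str(idx),
                    descriptors=DescriptorSet(
                        **{
                            name: (
                                int(row[name])
                                if name in DISCRETE_DESCRIPTORS
                                else float(row[name])
                            )
                            for name in ALL_DESCRIPTORS
                        }
                    ),
                )
                for idx, row in frame.reset_index(drop=True).iterrows()
            ]
            model = fit_reference(records, provenance="fitted-from-matrix")
        else:
            raise ValueError(f"unknown reference source: {self.reference!r}")

        rules = self.rules if isinstance(self.rules, ScoringRules) else default_rules(
            self.hba_na_policy
        )
        self.reference_model_ = model
        self.rules_ = rules
        self.continuous_stats_ = dict(model.continuous_stats)
        self.discrete_modes_ = dict(model.discrete_modes)
        self.n_reference_ = model.n_reference
        self.max_score_ = max_score(rules)
        self.min_score_ = min_score(rules)
        return self

    def _breakdowns(self, X):
        check_is_fitted(self, "reference_model_")
        frame = _as_frame(X)
        out = []
        for _, row in frame.iterrows():
            ds = DescriptorSet(
                **{
                    name: (
                        int(row[name]) if name in DISCRETE_DESCRIPTORS else float(row[name])
                    )
                    for name in ALL_DESCRIPTORS
                }
            )
            out.append(score_compound(ds, self.reference_model_, self.rules_))
        return out

    def transform(self, X) -> np.ndarray:
        """Per-descriptor score matrix, shape (n, 10), canonical column order."""
        bds = self._breakdowns(X)
        return np.array(
            [[bd.per_descriptor[name][1] for name in ALL_DESCRIPTORS] for bd in bds]
        )

    def score_samples(self, X) -> np.ndarray:
        """Total herbicide-likeness score per compound."""
        return np.array([bd.total for bd in self._breakdowns(X)])

    def get_feature_names_out(self, input_features=None):
        return np.array([f"score_{name}" for name in ALL_DESCRIPTORS], dtype=object)
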