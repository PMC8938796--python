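"""Coercion of FeatureTable / DataFrame / array inputs to a common form."""

from __future__ import annotations

import numpy as np
import pandas as pd


def as_matrix(table, labels=None, feature_names=None):
    """Return ``(X, names, labels)`` from a FeatureTable, DataFrame or array.

    FeatureTable carries its own labels; otherwise ``labels`` is required.
    """
    from .features import FeatureTable

    if isinstance(table, FeatureTable):
        X = table.data.to_numpy(float)
        names = list(table.data.columns)
        labels = table.labels if labels is None else np.asarray(labels)
    elif isinstance(table, pd.DataFrame):
        X = table.to_numpy(float)
        names = list(table.columns)
    else:
        X = np.asarray(table, float)
        names = feature_names
    if names is None:
        names = [f"f{j}" for j in range(X.shape[1])]
    if labels is not None:
        labels = np.asarray(labels)
    return X, names, labels
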