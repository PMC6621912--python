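"""Memoryless reference classifiers for the synthetic sequence tasks.

The baseline collapses each sequence to its time-averaged feature vector
and fits a multinomial logistic regression — a model that by
construction cannot exploit temporal order.  On the "motif" task variant
this baseline is competitive (class motifs differ in time-averaged
statistics); on the "order" variant it degrades toward chance, which is
exactly the gap a temporally integrating reservoir should exceed.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression

__all__ = ["time_average_features", "time_average_accuracy"]


def time_average_features(sequences) -> np.ndarray:
    """Collapse each (frames x features) sequence to its per-dimension mean."""
    return np.stack([np.atleast_2d(np.asarray(s, float)).mean(axis=0)
                     for s in sequences])


def time_average_accuracy(
    train_seqs,
    train_labels,
    test_seqs,
    test_labels,
    max_iter: int = 2000,
) -> float:
    """Test accuracy of logistic regression on time-averaged features.

    Deterministic: the solver is convex and the features contain no
    sampling step.
    """
    model = LogisticRegression(max_iter=max_iter)
    model.fit(time_average_features(train_seqs), np.asarray(train_labels))
    pred = model.predict(time_average_features(test_seqs))
    return float(np.mean(pred == np.asarray(test_labels)))
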