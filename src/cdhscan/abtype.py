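"""Random-forest typing of Ab10 haplotypes (Ab10-I / Ab10-II / Ab10-III).

Cytological Ab10 types differ in which knob and gene regions they carry, so
their scaled tag-index profiles over the haplotype differ bin by bin. A
random forest trained on typed controls (stratified 70/30 split) predicts
the type of experimental Ab10-positive samples; a sample is typed only when
at least 65% of trees vote for the same class, otherwise it is ambiguous.
Gini importances expose the bins that carry the type signal, and a PCA of
those bins visualizes the (considerable) natural variation among types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

VOTE_THRESHOLD = 0.65
AMBIGUOUS = "ambiguous"


@dataclass
class TypeModel:
    forest: RandomForestClassifier
    bins: list[str]
    classes: list[str]
    importances: pd.Series  # mean decrease in Gini impurity per bin
    train_samples: list[str]
    test_samples: list[str]
    holdout_accuracy: float
    vote_threshold: float = VOTE_THRESHOLD


def train_type_model(
    scaled_index: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    test_fraction: float = 0.3,
    n_estimators: int = 500,
    vote_threshold: float = VOTE_THRESHOLD,
) -> TypeModel:
    """Fit the forest on 70% of typed controls; report held-out accuracy.

    ``scaled_index`` is bins x samples (scaled tag index over the Ab10
    haplotype); ``labels`` maps control sample -> type. Every type needs at
    least 2 controls so the stratified split covers all classes.
    """
    labels = labels.dropna()
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two Ab10 types to train a type model")
    if (counts < 2).any():
        raise ValueError(f"types with fewer than 2 controls: {list(counts.index[counts < 2])}")

    samples = list(labels.index)
    X = scaled_index[samples].to_numpy(dtype=float).T
    y = labels.to_numpy()
    idx = np.arange(len(samples))
    tr, te = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    forest = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt", random_state=seed
    )
    forest.fit(X[tr], y[tr])
    acc = float((forest.predict(X[te]) == y[te]).mean())
    return TypeModel(
        forest=forest,
        bins=list(scaled_index.index),
        classes=list(forest.classes_),
        importances=pd.Series(forest.feature_importances_, index=scaled_index.index),
        train_samples=[samples[i] for i in tr],
        test_samples=[samples[i] for i in te],
        holdout_accuracy=acc,
        vote_threshold=vote_threshold,
    )


def vote_fractions(model: TypeModel, scaled_index: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Per-sample fraction of trees voting for each type (rows sum to 1)."""
    X = scaled_index.loc[model.bins, list(samples)].to_numpy(dtype=float).T
    tally = np.zeros((len(samples), len(model.classes)))
    rows = np.arange(len(samples))
    for tree in model.forest.estimators_:
        # component trees predict indices into forest.classes_
        pred = tree.predict(X).astype(int)
        tally[rows, pred] += 1
    tally /= len(model.forest.estimators_)
    return pd.DataFrame(tally, index=list(samples), columns=model.classes)


def predict_types(
    model: TypeModel,
    scaled_index: pd.DataFrame,
    samples: list[str],
    vote_threshold: float | None = None,
) -> pd.DataFrame:
    """Type calls with the vote-confidence rule.

    call = argmax type iff its vote fraction >= threshold, else ambiguous.
    Columns: sample_id, call, top_vote_fraction.
    """
    thr = model.vote_threshold if vote_threshold is None else vote_threshold
    votes = vote_fractions(model, scaled_index, samples)
    top = votes.max(axis=1)
    winner = votes.idxmax(axis=1)
    call = winner.where(top >= thr - 1e-12, AMBIGUOUS)
    return pd.DataFrame(
        {"sample_id": list(samples), "call": call.values, "top_vote_fraction": top.values}
    )


def top_gini_bins(model: TypeModel, n: int) -> pd.Series:
    """The n bins with the highest mean-decrease-Gini importance
    (descending; clamped to the feature count)."""
    return model.importances.sort_values(ascending=False).head(max(0, n))


def type_pca(
    scaled_index: pd.DataFrame,
    bins: list[str],
    samples: list[str],
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA embedding of samples over the selected bins.

    Returns (coordinates samples x PCs, explained variance fractions).
    """
    X = scaled_index.loc[list(bins), list(samples)].to_numpy(dtype=float).T
    k = min(n_components, X.shape[0], X.shape[1])
    pca = PCA(n_components=k)
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=list(samples), columns=cols), pca.explained_variance_ratio_
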