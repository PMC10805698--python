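"""Post-hoc explainability for fitted attention-MIL models.

The attention weights the model assigns to instances are the primary
interpretability signal. This module provides the standard readouts:

* per-feature attention z-scores — attention tables (feature x head) are
  z-scored within each head, averaged over heads, then over
  cross-validation folds, making heads and folds comparable despite
  arbitrary per-head scales;
* extraction of the top-attention instances of a head;
* K-means clustering of instance feature vectors with clusters relabelled
  in descending median-attention order;
* position probability matrices (PPMs) and per-position information
  content (in bits) for sequence logos of high-attention instances,
  computed separately per variant class (SBS / DBS / InDel).

Because one attention head may attend to several distinct motifs, the
information content of a pooled logo is a lower bound on the information
the head uses; outputs carry that caveat in their metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .concepts import NUC_ORDER, PAD, SequenceConcept

logger = logging.getLogger(__name__)

__all__ = [
    "attention_zscores",
    "top_attention",
    "cluster_instances",
    "PositionProbabilityMatrix",
    "logo_matrix",
    "information_bits",
]


def attention_zscores(folds: Sequence[pd.DataFrame]) -> pd.Series:
    """Average per-feature attention z-scores across heads and folds.

    Each element of `folds` is a (feature x head) table of attention
    values for one cross-validation fold. Within every head the values
    are z-scored across features ((a - mean) / sd); heads are then
    averaged, and finally folds. A head with zero variance carries no
    ranking information and contributes 0, with a warning.
    """
    if not folds:
        raise ValueError("no attention tables given")
    per_fold = []
    for i, table in enumerate(folds):
        if len(table) < 2:
            raise ValueError("z-scores need >= 2 features per head")
        z = pd.DataFrame(index=table.index, columns=table.columns, dtype=float)
        for col in table.columns:
            a = table[col].to_numpy(dtype=float)
            sd = a.std()
            if sd == 0:
                logger.warning(
                    "attention head %r in fold %d has zero variance; "
                    "contributing 0",
                    col,
                    i,
                )
                z[col] = 0.0
            else:
                z[col] = (a - a.mean()) / sd
        per_fold.append(z.mean(axis=1))
    return pd.concat(per_fold, axis=1).mean(axis=1)


def top_attention(
    instances: Sequence, attn: np.ndarray, head: int = 0, frac: float = 0.05
):
    """The ceil(frac * n) instances with highest attention in one head.

    Ties are broken by stable input order. Returns (subset, indices).
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0, 1]")
    attn = np.asarray(attn)
    a = attn if attn.ndim == 1 else attn[:, head]
    n = len(a)
    k = int(np.ceil(frac * n))
    # stable sort descending: sort by -a keeps input order among ties
    order = np.argsort(-a, kind="stable")[:k]
    order = np.sort(order)  # report in input order
    subset = [instances[i] for i in order]
    return subset, order


def cluster_instances(
    feature_vectors: np.ndarray,
    attn: np.ndarray,
    k: int,
    seed: int = 0,
    scale: bool = True,
) -> np.ndarray:
    """K-means assignments relabelled by descending median attention.

    Cluster 0 always has the highest median attention. Features are
    scaled to unit variance by default (``scale=False`` clusters raw).
    """
    X = np.asarray(feature_vectors, dtype=float)
    attn = np.asarray(attn, dtype=float).ravel()
    if k > len(X):
        raise ValueError(f"k={k} exceeds number of instances {len(X)}")
    if scale:
        sd = X.std(axis=0)
        X = X / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(X)
    medians = np.array(
        [np.median(attn[raw == c]) if (raw == c).any() else -np.inf for c in range(k)]
    )
    # rank clusters: 0 = highest median attention
    order = np.argsort(-medians, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[raw]


@dataclass
class PositionProbabilityMatrix:
    """Column-stochastic nucleotide probabilities for a sequence logo.

    Layout: 5' flank | allele block | 3' flank, with PAD positions
    excluded from each column's denominator. ``information_caveat``
    records that pooled-logo bits are a lower bound when a head attends
    to several motifs.
    """

    probs: np.ndarray  # (positions, 4)
    variant_class: str
    n_sequences: int
    information_caveat: str = (
        "bits are a lower bound: one attention head may mix several motifs"
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, columns=list(NUC_ORDER))


def logo_matrix(
    concepts: Sequence[SequenceConcept],
    variant_class: str = "SBS",
    allele: str = "alt",
) -> PositionProbabilityMatrix:
    """Position probability matrix over aligned 5' | allele | 3' layouts.

    All concepts must share the same width. Probabilities are computed
    separately per variant class by the caller (SBSs, doublets and InDels
    have different allele-block structure); `allele` picks whether the
    reference or alternate allele fills the central block.
    """
    if not concepts:
        raise ValueError("no sequence concepts given")
    W = concepts[0].W
    if any(c.W != W for c in concepts):
        raise ValueError("all concepts must share the same width W")
    rows = []
    for c in concepts:
        mid = c.alt_seq if allele == "alt" else c.ref_seq
        rows.append(np.concatenate([c.five_prime, mid, c.three_prime]))
    arr = np.stack(rows)  # (n, 3W) int codes with PAD
    n_pos = arr.shape[1]
    probs = np.zeros((n_pos, 4))
    for j in range(n_pos):
        col = arr[:, j]
        col = col[col != PAD]
        if len(col):
            probs[j] = np.bincount(col, minlength=4) / len(col)
        else:
            probs[j] = 0.25  # all-PAD column: uninformative
    return PositionProbabilityMatrix(
        probs=probs, variant_class=variant_class, n_sequences=len(concepts)
    )


def information_bits(ppm: PositionProbabilityMatrix) -> np.ndarray:
    """Per-position information content, ``2 - H(p)`` bits over A/C/G/T.

    0 for a uniform column, 2 for a one-hot column. No small-sample
    correction is applied.
    """
    p = np.asarray(ppm.probs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = -plogp.sum(axis=1)
    return 2.0 - entropy
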