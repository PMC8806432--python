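"""Binary relative-ordering pair matrix.

For every unordered pair of genes (a, b), taken once with a before b in
the canonical (input) gene order, and every sample s, the pair indicator
is

    P[(a,b), s] = 1  if expr(a, s) > expr(b, s)  else 0

(ties give 0). The indicator depends only on the within-sample ordering
of the two genes, so it is invariant under any strictly increasing
per-sample transform of expression — no normalisation across samples or
platforms is required. Pairs whose 1-frequency across samples falls
outside the open interval (low, high) are near-constant and carry no
ordering information; they are dropped by the validity filter.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

log = logging.getLogger(__name__)

PAIR_SEP = "|"


@dataclasses.dataclass
class PairMatrix:
    """Binary pairs x samples matrix with per-pair 1-frequency."""

    values: pd.DataFrame  # index: "a|b" pair ids, columns: sample ids; 0/1

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("pair matrix entries must be 0 or 1")

    @property
    def pair_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [tuple(p.split(PAIR_SEP, 1)) for p in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def freq1(self) -> pd.Series:
        return self.values.mean(axis=1)

    def write(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "freq1", self.freq1)
        out.to_csv(path, sep="\t", index_label="pair_id")

    @classmethod
    def read(cls, path) -> "PairMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.drop(columns=["freq1"]).astype(np.int8))


def pair_id(gene_a: str, gene_b: str) -> str:
    return f"{gene_a}{PAIR_SEP}{gene_b}"


def build_pair_matrix(values: pd.DataFrame, samples=None) -> PairMatrix:
    """Construct the 0-or-1 matrix over all gene pairs.

    Parameters
    ----------
    values : genes x samples expression DataFrame (raw scale; the result
        is identical on any strictly increasing per-sample rescaling).
        Row order defines the canonical gene order; pairs are the i < j
        upper triangle, so n genes give n(n-1)/2 rows.
    samples : optional subset/order of sample columns (e.g. tumor only).
    """
    if samples is not None:
        values = values[list(samples)]
    n = len(values.index)
    if n < 2:
        raise ValueError(f"need at least 2 genes to form pairs, got {n}")
    if values.shape[1] < 1:
        raise ValueError("need at least 1 sample")
    genes = list(values.index)
    A = values.to_numpy(float)
    iu, ju = np.triu_indices(n, k=1)
    P = (A[iu] > A[ju]).astype(np.int8)
    ids = [pair_id(genes[i], genes[j]) for i, j in zip(iu, ju)]
    return PairMatrix(values=pd.DataFrame(P, index=ids, columns=values.columns))


def filter_valid_pairs(pm: PairMatrix, low: float = 0.20, high: float = 0.80) -> PairMatrix:
    """Retain pairs with 1-frequency strictly inside (low, high).

    Strict conjunctive bounds: a pair at exactly ``low`` or ``high`` is
    removed. Idempotent; an empty result is allowed (logged).
    """
    if not low < high:
        raise ValueError(f"need low < high, got ({low}, {high})")
    f = pm.freq1
    keep = (f > low) & (f < high)
    out = PairMatrix(values=pm.values.loc[keep.to_numpy()])
    log.info("filter_valid_pairs: %d -> %d pairs in (%g, %g)", len(f), len(out.values), low, high)
    if out.values.empty:
        log.warning("filter_valid_pairs: no valid pairs remain")
    return out


class PairMatrixTransformer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer from expression to valid pair indicators.

    ``fit`` fixes the canonical pair set and, using the training samples,
    the valid pairs (1-frequency strictly inside ``(low, high)``);
    ``transform`` maps a samples x genes expression frame to the binary
    samples x valid-pairs indicator frame. Because the indicator is
    rank-based per sample, train/test expression need not share a scale.

    Parameters
    ----------
    low, high : validity bounds on the training 1-frequency.
    filter_pairs : disable to keep all n(n-1)/2 pairs.
    """

    def __init__(self, low: float = 0.20, high: float = 0.80, filter_pairs: bool = True):
        self.low = low
        self.high = high
        self.filter_pairs = filter_pairs

    def fit(self, X: pd.DataFrame, y=None) -> "PairMatrixTransformer":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x genes DataFrame with gene-id columns")
        pm = build_pair_matrix(X.T)
        if self.filter_pairs:
            pm = filter_valid_pairs(pm, self.low, self.high)
        self.gene_ids_ = list(X.columns)
        self.pair_ids_ = pm.pair_ids
        self.freq1_ = pm.freq1
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "pair_ids_")
        pm = build_pair_matrix(X[self.gene_ids_].T)
        return pm.values.loc[self.pair_ids_].T.astype(np.int8)

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X).transform(X)
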