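"""Principal component analysis of population × locus allele-frequency matrices.

The frequency matrix is column-centered (each locus centred on its across-
population mean; no variance scaling by default, since the input frequencies
share a common [0, 1] scale) and decomposed by singular values.  With K
populations and L loci there are at most min(K − 1, L) non-trivial
components; each component's variance fraction is σ_k² / Σ σ².

Sign convention: every loading vector is flipped so that its largest-
magnitude entry is positive, making score plots reproducible across runs
and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import FrequencyMatrix

__all__ = ["PcaResult", "pca_frequencies", "FrequencyPCA"]


@dataclass(frozen=True)
class PcaResult:
    """PCA decomposition of a population × locus frequency matrix."""

    scores: pd.DataFrame  #: population coordinates, one column per component
    loadings: pd.DataFrame  #: locus contributions, one column per component
    variance_fraction: np.ndarray  #: per-component share of total variance


class FrequencyPCA(TransformerMixin, BaseEstimator):
    """PCA of allele-frequency profiles across populations.

    Parameters
    ----------
    n_components : int or None
        Components to retain; None keeps every non-trivial component
        (min(populations − 1, loci)).
    scale : bool
        If True, divide each centred locus column by its standard
        deviation before the decomposition (sensitivity analysis only;
        default False — raw frequencies).

    Attributes
    ----------
    components_ : ndarray, (n_components, loci)
        Loading vectors (rows), orthonormal, sign-fixed.
    explained_variance_ratio_ : ndarray
        Variance fractions, non-increasing; over all non-trivial
        components they sum to 1.
    mean_ : ndarray
        Per-locus column means used for centering.
    """

    def __init__(self, n_components: int | None = None, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def _validate(self, X) -> tuple[np.ndarray, list, list]:
        if isinstance(X, FrequencyMatrix):
            return X.to_numpy(), X.populations, X.loci
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.index), list(X.columns)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D population × locus matrix")
        return X, [f"pop{i}" for i in range(X.shape[0])], [f"locus{j}" for j in range(X.shape[1])]

    def fit(self, X, y=None):
        values, pops, loci = self._validate(X)
        k, l = values.shape
        if k < 2 or l < 1:
            raise ValueError("PCA needs at least 2 populations and 1 locus")
        self.mean_ = values.mean(axis=0)
        centered = values - self.mean_
        if self.scale:
            sd = centered.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            self.scale_ = sd
            centered = centered / sd
        total_var = float((centered**2).sum())
        if total_var == 0.0:
            raise ValueError("constant frequency matrix: PCA variance undefined")
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        max_rank = min(k - 1, l)
        u, s, vt = u[:, :max_rank], s[:max_rank], vt[:max_rank]
        # sign convention: largest-|loading| entry of each component positive
        flip = np.where(vt[np.arange(len(s)), np.abs(vt).argmax(axis=1)] < 0, -1.0, 1.0)
        vt = vt * flip[:, None]
        u = u * flip[None, :]
        ncomp = len(s) if self.n_components is None else min(self.n_components, len(s))
        self.populations_ = pops
        self.loci_ = loci
        self.singular_values_ = s
        self.components_ = vt[:ncomp]
        self.explained_variance_ratio_ = (s**2 / total_var)[:ncomp]
        self.n_components_ = ncomp
        self._scores_full = u * s
        return self

    def transform(self, X) -> np.ndarray:
        values, _, _ = self._validate(X)
        centered = values - self.mean_
        if self.scale:
            centered = centered / self.scale_
        return centered @ self.components_.T

    def result(self) -> PcaResult:
        cols = [f"PC{i + 1}" for i in range(self.n_components_)]
        return PcaResult(
            scores=pd.DataFrame(
                self._scores_full[:, : self.n_components_],
                index=pd.Index(self.populations_, name="population"), columns=cols,
            ),
            loadings=pd.DataFrame(
                self.components_.T,
                index=pd.Index(self.loci_, name="locus"), columns=cols,
            ),
            variance_fraction=self.explained_variance_ratio_.copy(),
        )


def pca_frequencies(
    m: FrequencyMatrix, n_components: int | None = None, *, scale: bool = False
) -> PcaResult:
    """Decompose a frequency matrix; thin wrapper over :class:`FrequencyPCA`."""
    return FrequencyPCA(n_components=n_components, scale=scale).fit(m).result()
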