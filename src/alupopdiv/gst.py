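"""Nei's gene-diversity decomposition for biallelic loci across populations.

For K populations with insertion frequencies p_1..p_K at a locus:

    Hs  = (1/K) Σ_j 2 p_j (1 − p_j)      mean within-population diversity
    p̄   = (1/K) Σ_j p_j
    Ht  = 2 p̄ (1 − p̄)                    total diversity at the mean frequency
    Gst = (Ht − Hs) / Ht                  between-population fraction

Ht ≥ Hs always (Jensen: 2p(1−p) is concave), so Gst ∈ [0, 1]; Gst is the
share of total gene diversity attributable to frequency differences between
populations.  Populations enter unweighted — the decomposition needs no
sample sizes (an n-weighted variant is available behind a flag).

Multi-locus aggregation follows the "mean-of-ratios" convention by default:
Ht, Hs and Gst are each averaged over loci, so the aggregate Gst is the mean
of the per-locus Gst values.  The classical "ratio-of-means" alternative
(Gst_all = (mean Ht − mean Hs)/mean Ht) is provided and labelled; the two
differ whenever diversity varies across loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import FrequencyMatrix

__all__ = [
    "LocusDiversity",
    "DiversitySummary",
    "locus_diversity",
    "gst_from_ht_hs",
    "multilocus_diversity",
    "GstDecomposition",
]

CONVENTIONS = ("mean-of-ratios", "ratio-of-means")


@dataclass(frozen=True)
class LocusDiversity:
    """Per-locus decomposition: total, within, and between-population parts."""

    locus: str
    Ht: float
    Hs: float
    Gst: float


@dataclass(frozen=True)
class DiversitySummary:
    per_locus: list[LocusDiversity]
    Ht_all: float
    Hs_all: float
    Gst_all: float
    convention: str


def gst_from_ht_hs(Ht: float, Hs: float) -> float:
    """Gst = (Ht − Hs)/Ht; undefined at Ht ≤ 0."""
    if Ht <= 0:
        raise ValueError(f"Gst undefined for Ht = {Ht} (no total diversity)")
    return (Ht - Hs) / Ht


def locus_diversity(
    freqs, locus: str = "", *, weights=None
) -> LocusDiversity:
    """Decompose one locus's diversity across K ≥ 2 populations.

    Parameters
    ----------
    freqs : array-like of float
        Insertion-allele frequencies, one per population.
    locus : str
        Label carried into the result.
    weights : array-like, optional
        Population weights (e.g. sample sizes); default unweighted.

    Raises
    ------
    ValueError
        If all populations are fixed for the same allele (Ht = 0), where
        Gst is undefined; callers aggregating over loci should exclude
        such loci.
    """
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need frequencies for at least two populations")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape or (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be non-negative, same length as freqs")
        w = w / w.sum()
    hs = float(np.sum(w * 2 * p * (1 - p)))
    p_bar = float(np.sum(w * p))
    ht = 2 * p_bar * (1 - p_bar)
    if ht <= 0:
        raise ValueError(
            f"locus {locus or '<unnamed>'!r}: all populations fixed for the same "
            "allele (Ht = 0), Gst undefined"
        )
    return LocusDiversity(locus=locus, Ht=ht, Hs=hs, Gst=gst_from_ht_hs(ht, hs))


def multilocus_diversity(
    per_locus: list[LocusDiversity], convention: str = "mean-of-ratios"
) -> DiversitySummary:
    """Aggregate per-locus decompositions into an "All loci" summary."""
    if not per_locus:
        raise ValueError("multilocus aggregation needs at least one locus")
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")
    ht = np.array([d.Ht for d in per_locus])
    hs = np.array([d.Hs for d in per_locus])
    ht_all, hs_all = float(ht.mean()), float(hs.mean())
    if convention == "mean-of-ratios":
        gst_all = float(np.mean([d.Gst for d in per_locus]))
    else:
        gst_all = gst_from_ht_hs(ht_all, hs_all)
    return DiversitySummary(
        per_locus=list(per_locus), Ht_all=ht_all, Hs_all=hs_all,
        Gst_all=gst_all, convention=convention,
    )


class GstDecomposition(BaseEstimator):
    """Nei's Ht/Hs/Gst decomposition of a population × locus frequency matrix.

    Parameters
    ----------
    convention : {"mean-of-ratios", "ratio-of-means"}
        Multi-locus aggregation rule (see module docstring).
    weighted : bool
        If True, weight populations by their per-locus sample sizes (the
        matrix must then carry ``n``); default False (unweighted means).

    Attributes
    ----------
    per_locus_ : pandas.DataFrame
        One row per retained locus with columns Ht, Hs, Gst.
    Ht_all_, Hs_all_, Gst_all_ : float
        Multi-locus aggregates under the chosen convention.
    excluded_loci_ : list of str
        Loci fixed for one allele in every population (Ht = 0), excluded
        from the aggregates.
    summary_ : DiversitySummary
    """

    def __init__(self, convention: str = "mean-of-ratios", weighted: bool = False):
        self.convention = convention
        self.weighted = weighted

    def fit(self, X, y=None):
        m = X if isinstance(X, FrequencyMatrix) else FrequencyMatrix(p=pd.DataFrame(X))
        if self.weighted and m.n is None:
            raise ValueError("weighted=True requires sample sizes in the frequency matrix")
        per_locus, excluded = [], []
        for locus in m.loci:
            w = m.n[locus].to_numpy() if self.weighted else None
            try:
                per_locus.append(locus_diversity(m.p[locus].to_numpy(), str(locus), weights=w))
            except ValueError:
                excluded.append(str(locus))
        if excluded:
            warnings.warn(
                f"loci fixed across all populations excluded from aggregation: {excluded}",
                UserWarning, stacklevel=2,
            )
        summary = multilocus_diversity(per_locus, self.convention)
        self.per_locus_ = pd.DataFrame(
            [(d.Ht, d.Hs, d.Gst) for d in summary.per_locus],
            index=pd.Index([d.locus for d in summary.per_locus], name="locus"),
            columns=["Ht", "Hs", "Gst"],
        )
        self.Ht_all_ = summary.Ht_all
        self.Hs_all_ = summary.Hs_all
        self.Gst_all_ = summary.Gst_all
        self.excluded_loci_ = excluded
        self.summary_ = summary
        return self

    def summary_frame(self) -> pd.DataFrame:
        """Per-locus table plus an "All loci" row, mirroring the usual
        published layout (locus, Ht, Hs, Gst)."""
        out = self.per_locus_.copy()
        out.loc["All loci"] = [self.Ht_all_, self.Hs_all_, self.Gst_all_]
        return out
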