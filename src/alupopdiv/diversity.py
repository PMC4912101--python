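"""Single-locus diversity statistics for biallelic insertion/deletion loci.

Allele frequencies are obtained by direct counting (each II genotype
contributes two insertion alleles, each ID one).  Expected heterozygosity is
the Hardy–Weinberg value 2pq; observed heterozygosity is the fraction of ID
individuals.  Departure from Hardy–Weinberg proportions is tested with a
χ² goodness-of-fit test on the three genotype classes (1 df for a biallelic
locus, the allele frequency being estimated from the data), with Bonferroni
adjustment across the family of tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import GenotypeCounts, GenotypeTable

__all__ = [
    "LocusFrequency",
    "HweResult",
    "MonomorphicLocusError",
    "allele_frequency",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "average_heterozygosity",
    "hwe_test",
    "bonferroni_adjust",
    "PopulationDiversity",
]


class MonomorphicLocusError(ValueError):
    """Raised when a statistic is undefined on a monomorphic (fixed) cell."""


@dataclass(frozen=True)
class LocusFrequency:
    """Insertion/deletion allele frequencies at one locus in one population."""

    p: float  #: insertion (+) allele frequency
    q: float  #: deletion (−) allele frequency, 1 − p
    n: int  #: diploid sample size

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("sample size must be >= 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"allele frequency {self.p} outside [0, 1]")


@dataclass(frozen=True)
class HweResult:
    """Result of a χ² goodness-of-fit test for Hardy–Weinberg proportions."""

    chi2: float
    df: int
    p_value: float
    p_adjusted: float
    m: int  #: number of tests in the Bonferroni family


def allele_frequency(counts: GenotypeCounts) -> LocusFrequency:
    """Insertion-allele frequency by direct counting: p = (2·n_II + n_ID)/2n."""
    counts = GenotypeCounts(*counts)
    n = counts.n
    if n == 0:
        raise ValueError("allele frequency undefined for an empty cell (n = 0)")
    p = (2 * counts.n_II + counts.n_ID) / (2 * n)
    return LocusFrequency(p=p, q=1.0 - p, n=n)


def expected_heterozygosity(f: LocusFrequency | float) -> float:
    """Hardy–Weinberg expected heterozygosity, 2pq.

    Accepts a :class:`LocusFrequency` or a bare insertion frequency.
    Maximal (0.5) at p = 0.5 and zero at a fixed locus.
    """
    p = f.p if isinstance(f, LocusFrequency) else float(f)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency {p} outside [0, 1]")
    q = f.q if isinstance(f, LocusFrequency) else 1.0 - p
    return 2.0 * p * q


def observed_heterozygosity(counts: GenotypeCounts) -> float:
    """Observed heterozygote proportion, n_ID / n."""
    counts = GenotypeCounts(*counts)
    if counts.n == 0:
        raise ValueError("observed heterozygosity undefined for an empty cell")
    return counts.n_ID / counts.n


def average_heterozygosity(values: Iterable[float]) -> float:
    """Unweighted arithmetic mean of per-locus heterozygosities."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("average heterozygosity needs at least one locus")
    return float(values.mean())


def hwe_test(counts: GenotypeCounts, *, m: int = 1) -> HweResult:
    """χ² goodness-of-fit test of Hardy–Weinberg proportions (1 df).

    Expected genotype counts are (np̂², 2np̂q̂, nq̂²) with p̂ estimated by
    direct counting; the statistic is Σ(obs − exp)²/exp over the three
    genotype classes, with no continuity correction.

    Parameters
    ----------
    counts : GenotypeCounts
    m : int
        Bonferroni family size used for ``p_adjusted`` (min(1, m·p)).

    Raises
    ------
    MonomorphicLocusError
        If the cell is fixed (p̂ ∈ {0, 1}); the test is undefined there.
    """
    counts = GenotypeCounts(*counts)
    f = allele_frequency(counts)
    if f.p in (0.0, 1.0):
        raise MonomorphicLocusError(
            f"Hardy-Weinberg test undefined on a monomorphic cell (p = {f.p})"
        )
    n = f.n
    expected = np.array([n * f.p**2, 2 * n * f.p * f.q, n * f.q**2])
    observed = np.array(counts, dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(
        chi2=chi2, df=1, p_value=p_value,
        p_adjusted=min(1.0, m * p_value), m=m,
    )


def bonferroni_adjust(p_values: Sequence[float]) -> list[float]:
    """Bonferroni adjustment: each p becomes min(1, m·p), m = family size."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(np.minimum(1.0, len(p) * p))


class PopulationDiversity(BaseEstimator):
    """Per-population, per-locus diversity summary of a genotype table.

    Computes, for every population × locus cell: the insertion-allele
    frequency by direct counting, observed and expected (2pq)
    heterozygosity, and the Hardy–Weinberg χ² test with Bonferroni
    correction; plus per-population multi-locus average heterozygosities.

    Parameters
    ----------
    het : {"observed", "expected"}
        Which per-locus series feeds the multi-locus average.
    hwe_family : {"run", "per-locus", "none"}
        Bonferroni family: every testable cell in the run (default), the
        cells of one locus, or no adjustment.

    Attributes
    ----------
    frequencies_ : FrequencyMatrix
        Insertion-allele frequencies with per-cell sample sizes.
    het_observed_, het_expected_ : pandas.DataFrame
        Population × locus heterozygosities.
    het_average_ : pandas.Series
        Per-population unweighted mean across loci of the selected series.
    hwe_ : pandas.DataFrame
        Tidy HWE report: population, locus, chi2, df, p_value, p_adjusted, m;
        monomorphic cells are flagged in ``monomorphic_`` and skipped.
    """

    def __init__(self, het: str = "observed", hwe_family: str = "run"):
        self.het = het
        self.hwe_family = hwe_family

    def fit(self, X: GenotypeTable, y=None):
        if self.het not in ("observed", "expected"):
            raise ValueError(f"het must be 'observed' or 'expected', got {self.het!r}")
        if self.hwe_family not in ("run", "per-locus", "none"):
            raise ValueError(f"unknown hwe_family {self.hwe_family!r}")
        from .io import FrequencyMatrix  # local to avoid cycle at import time

        counts = X.counts_array()
        n = counts.sum(axis=2)
        self.frequencies_ = FrequencyMatrix.from_genotype_table(X)
        p = self.frequencies_.to_numpy()
        idx = pd.Index(X.populations, name="population")
        cols = pd.Index(X.loci, name="locus")
        self.het_observed_ = pd.DataFrame(counts[:, :, 1] / n, index=idx, columns=cols)
        self.het_expected_ = pd.DataFrame(2 * p * (1 - p), index=idx, columns=cols)
        series = self.het_observed_ if self.het == "observed" else self.het_expected_
        self.het_average_ = series.mean(axis=1)

        rows, mono = [], []
        for i, pop in enumerate(X.populations):
            for j, locus in enumerate(X.loci):
                cell = GenotypeCounts(*counts[i, j])
                try:
                    res = hwe_test(cell)
                except MonomorphicLocusError:
                    mono.append((pop, locus))
                    continue
                rows.append((pop, locus, res.chi2, res.df, res.p_value))
        hwe = pd.DataFrame(rows, columns=["population", "locus", "chi2", "df", "p_value"])
        if self.hwe_family == "run":
            hwe["m"] = len(hwe)
            hwe["p_adjusted"] = bonferroni_adjust(hwe["p_value"]) if len(hwe) else []
        elif self.hwe_family == "per-locus":
            hwe["m"] = hwe.groupby("locus")["p_value"].transform("size")
            hwe["p_adjusted"] = np.minimum(1.0, hwe["m"] * hwe["p_value"])
        else:
            hwe["m"] = 1
            hwe["p_adjusted"] = hwe["p_value"]
        self.hwe_ = hwe
        self.monomorphic_ = mono
        return self

    def summary(self) -> pd.DataFrame:
        """Population × locus table of the selected heterozygosity series
        plus an ``All loci`` average column."""
        series = self.het_observed_ if self.het == "observed" else self.het_expected_
        out = series.copy()
        out["All loci"] = self.het_average_
        return out
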