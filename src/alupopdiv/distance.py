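"""Pairwise genetic distances between populations from allele frequencies.

Two classical frequency-based distances are provided for biallelic loci:

* ``nei1972`` — Nei's standard genetic distance
  D = −ln( J_ab / sqrt(J_a · J_b) ), where per locus
  J_ab = p_a p_b + q_a q_b, J_a = p_a² + q_a², J_b = p_b² + q_b², and each
  J is averaged over loci before the ratio is taken.
* ``da1983`` — Nei's Da distance,
  Da = 1 − (1/L) Σ_loci ( sqrt(p_a p_b) + sqrt(q_a q_b) ).

Both are zero for identical frequency profiles; Da is bounded by 1 and is
exactly 1 for a single fixed difference.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix

from .io import FrequencyMatrix

__all__ = ["DISTANCE_METHODS", "nei_distance", "distance_matrix"]

DISTANCE_METHODS = ("nei1972", "da1983")


def _pair_distance(pa: np.ndarray, pb: np.ndarray, method: str) -> float:
    qa, qb = 1.0 - pa, 1.0 - pb
    if method == "nei1972":
        jab = float(np.mean(pa * pb + qa * qb))
        ja = float(np.mean(pa**2 + qa**2))
        jb = float(np.mean(pb**2 + qb**2))
        if jab <= 0.0:
            raise ValueError(
                "Nei (1972) distance infinite: zero gene identity between the pair"
            )
        # guard against D = -0.0 / tiny negative from rounding when a == b
        return max(0.0, -np.log(jab / np.sqrt(ja * jb)))
    if method == "da1983":
        return float(1.0 - np.mean(np.sqrt(pa * pb) + np.sqrt(qa * qb)))
    raise ValueError(f"unknown distance method {method!r}; expected one of {DISTANCE_METHODS}")


def nei_distance(m: FrequencyMatrix, pop_a: str, pop_b: str, method: str = "nei1972") -> float:
    """Genetic distance between two populations of a frequency matrix."""
    for pop in (pop_a, pop_b):
        if pop not in m.populations:
            raise KeyError(f"unknown population {pop!r}")
    pa = m.p.loc[pop_a].to_numpy(dtype=float)
    pb = m.p.loc[pop_b].to_numpy(dtype=float)
    return _pair_distance(pa, pb, method)


def distance_matrix(m: FrequencyMatrix, method: str = "nei1972") -> DistanceMatrix:
    """All pairwise distances as a labelled symmetric matrix."""
    pops = m.populations
    p = m.to_numpy()
    d = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            d[i, j] = d[j, i] = _pair_distance(p[i], p[j], method)
    return DistanceMatrix(d, ids=pops)
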