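"""Synthetic genotype data with known ground-truth population structure.

The generator implements the Balding–Nichols island model: for each locus an
ancestral insertion frequency p0 is drawn (uniform on [0.1, 0.9] by
default), and each of K populations receives an independent frequency from

    Beta( p0 (1 − F)/F,  (1 − p0)(1 − F)/F )

whose mean is p0 and whose variance is F·p0(1 − p0) — so the differentiation
parameter F is exactly the expected Gst estimand at that locus.  Within each
population, diploid genotypes are drawn under Hardy–Weinberg proportions
(p², 2pq, q²); loci are independent and the insertion/deletion states are
mutationally stable, matching the biology of fixed Alu insertions.

Defaults mirror a small multi-population survey design (12 endogamous
populations, 7 loci, ~50 diploids each, F = 0.036 — the order of
differentiation typical of regional human caste/tribe groups).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GENOTYPES, GenotypeTable

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_frequencies",
    "simulate_genotype_counts",
    "simulate_genotypes",
    "BaldingNicholsSimulator",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Balding–Nichols simulation parameters.

    K populations × L loci, n diploids per population (scalar or length-K),
    differentiation F ∈ (0, 1), ancestral frequency law uniform on
    [p0_min, p0_max], and an integer RNG seed.  Identical config + seed
    gives bit-identical output.
    """

    K: int = 12
    L: int = 7
    n: int | tuple = 50
    F: float = 0.036
    p0_min: float = 0.1
    p0_max: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("need at least K = 2 populations")
        if self.L < 1:
            raise ValueError("need at least L = 1 locus")
        if not 0.0 < self.F < 1.0:
            raise ValueError(f"F must lie strictly in (0, 1), got {self.F}")
        if not 0.0 <= self.p0_min <= self.p0_max <= 1.0:
            raise ValueError("ancestral frequency bounds must satisfy 0 <= min <= max <= 1")
        ns = self.n_per_population
        if any(v < 1 for v in ns):
            raise ValueError("per-population sample sizes must be >= 1")

    @property
    def n_per_population(self) -> tuple:
        if np.isscalar(self.n):
            return tuple([int(self.n)] * self.K)
        if len(self.n) != self.K:
            raise ValueError("per-population n must have length K")
        return tuple(int(v) for v in self.n)

    @property
    def populations(self) -> list[str]:
        return [f"pop{i + 1:02d}" for i in range(self.K)]

    @property
    def loci(self) -> list[str]:
        return [f"L{j + 1:02d}" for j in range(self.L)]


@dataclass
class SimulatedDataset:
    """Genotypes plus the ground truth that generated them."""

    config: SimulationConfig
    ancestral: np.ndarray  #: (L,) ancestral insertion frequencies p0
    frequencies: np.ndarray  #: (K, L) true per-population frequencies
    counts: np.ndarray  #: (K, L, 3) genotype counts II/ID/DD
    genotypes: GenotypeTable = field(repr=False)

    def truth_dict(self) -> dict:
        return {
            "config": {**asdict(self.config), "n": list(self.config.n_per_population)},
            "ancestral": self.ancestral.tolist(),
            "frequencies": self.frequencies.tolist(),
        }

    def write(self, outdir) -> None:
        """Write genotypes.tsv + truth.json into a directory."""
        from .io import write_genotype_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genotype_table(self.genotypes, outdir / "genotypes.tsv")
        (outdir / "truth.json").write_text(
            json.dumps(self.truth_dict(), indent=1, sort_keys=True) + "\n"
        )


def simulate_frequencies(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    """Draw ancestral and per-population insertion frequencies.

    Returns
    -------
    (ancestral, frequencies) : (L,) and (K, L) arrays
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    p0 = rng.uniform(cfg.p0_min, cfg.p0_max, size=cfg.L)
    shape = (1.0 - cfg.F) / cfg.F
    p = rng.beta(p0 * shape, (1.0 - p0) * shape, size=(cfg.K, cfg.L))
    return p0, p


def simulate_genotype_counts(
    freqs: np.ndarray, n_per_population, rng: np.random.Generator
) -> np.ndarray:
    """HWE genotype counts per cell: multinomial(n, (p², 2pq, q²)).

    Vectorised over cells; returns (K, L, 3).
    """
    p = np.asarray(freqs, dtype=float)
    K, L = p.shape
    q = 1.0 - p
    probs = np.stack([p**2, 2 * p * q, q**2], axis=-1)
    counts = np.empty((K, L, 3), dtype=np.int64)
    for i in range(K):
        counts[i] = rng.multinomial(n_per_population[i], probs[i])
    return counts


def _counts_to_table(cfg: SimulationConfig, counts: np.ndarray) -> GenotypeTable:
    pops, loci = cfg.populations, cfg.loci
    ns = cfg.n_per_population
    rows = []
    for i, pop in enumerate(pops):
        for j, locus in enumerate(loci):
            calls = np.repeat(GENOTYPES, counts[i, j])
            for ind, g in enumerate(calls):
                rows.append((pop, f"{pop}_ind{ind + 1:04d}", locus, g))
    df = pd.DataFrame(rows, columns=["population", "individual", "locus", "genotype"])
    return GenotypeTable(records=df, populations=pops, loci=loci)


def simulate_genotypes(cfg: SimulationConfig) -> SimulatedDataset:
    """Full simulation: frequencies, genotype counts and an individual-level table."""
    rng = np.random.default_rng(cfg.seed)
    p0, p = simulate_frequencies(cfg, rng)
    counts = simulate_genotype_counts(p, cfg.n_per_population, rng)
    return SimulatedDataset(
        config=cfg, ancestral=p0, frequencies=p, counts=counts,
        genotypes=_counts_to_table(cfg, counts),
    )


class BaldingNicholsSimulator:
    """Convenience front-end mirroring the estimator idiom: configure once,
    draw datasets with varying seeds."""

    def __init__(self, K: int = 12, L: int = 7, n=50, F: float = 0.036,
                 p0_min: float = 0.1, p0_max: float = 0.9):
        self.K, self.L, self.n, self.F = K, L, n, F
        self.p0_min, self.p0_max = p0_min, p0_max

    def config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(K=self.K, L=self.L, n=self.n, F=self.F,
                                p0_min=self.p0_min, p0_max=self.p0_max, seed=seed)

    def sample(self, seed: int) -> SimulatedDataset:
        return simulate_genotypes(self.config(seed))

    def sample_counts(self, seed: int):
        """Frequencies + genotype counts only (no individual-level table);
        cheap enough for replicated parameter-recovery studies."""
        cfg = self.config(seed)
        rng = np.random.default_rng(cfg.seed)
        p0, p = simulate_frequencies(cfg, rng)
        counts = simulate_genotype_counts(p, cfg.n_per_population, rng)
        return cfg, p0, p, counts
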