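"""Data model and TSV I/O for biallelic insertion/deletion genotype data.

An Alu presence/absence locus has two alleles — insertion present (+) and
absent (−) — giving three diploid genotypes: II (+/+), ID (+/−), DD (−/−).
Two carriers are defined here:

* :class:`GenotypeTable` — individual-level calls, one row per
  individual × locus, keyed by population.
* :class:`FrequencyMatrix` — a population × locus table of insertion-allele
  frequencies (the deletion frequency is always ``1 − p``, derived, never
  stored), optionally with per-cell diploid sample sizes.

Both round-trip losslessly through plain TSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPES",
    "GenotypeCounts",
    "GenotypeTable",
    "FrequencyMatrix",
    "GenotypeParseError",
    "GenotypeValidationError",
    "read_genotype_table",
    "write_genotype_table",
    "tabulate_counts",
    "read_frequency_matrix",
    "write_frequency_matrix",
]

#: Canonical genotype codes: insertion homozygote, heterozygote, deletion homozygote.
GENOTYPES = ("II", "ID", "DD")

# Accepted aliases for each genotype token (case-sensitive on the +/- forms).
_TOKEN_ALIASES = {
    "II": "II", "+/+": "II", "++": "II",
    "ID": "ID", "+/-": "ID", "-/+": "ID", "+-": "ID", "DI": "ID",
    "DD": "DD", "-/-": "DD", "--": "DD",
}


class GenotypeParseError(ValueError):
    """A genotype file row could not be parsed."""


class GenotypeValidationError(ValueError):
    """A structurally valid file violates the data-model invariants."""


class GenotypeCounts(NamedTuple):
    """Genotype counts for one population × locus cell."""

    n_II: int
    n_ID: int
    n_DD: int

    @property
    def n(self) -> int:
        """Typed diploid sample size (missing calls excluded)."""
        return self.n_II + self.n_ID + self.n_DD


def _normalise_token(token: str, missing: str) -> str | None:
    token = token.strip()
    if token == missing or token == "":
        return None
    try:
        return _TOKEN_ALIASES[token]
    except KeyError:
        raise GenotypeParseError(
            f"unknown genotype token {token!r}; expected one of "
            f"{sorted(set(_TOKEN_ALIASES))} or missing code {missing!r}"
        ) from None


@dataclass
class GenotypeTable:
    """Individual-level II/ID/DD calls keyed by population and locus.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``population``, ``individual``, ``locus``, ``genotype``;
        ``genotype`` is one of ``II``/``ID``/``DD`` or NaN for missing.
    populations, loci : sequence of str, optional
        Declared orderings; default to order of first appearance.
    """

    records: pd.DataFrame
    populations: list[str] = field(default_factory=list)
    loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = ["population", "individual", "locus", "genotype"]
        missing_cols = [c for c in required if c not in self.records.columns]
        if missing_cols:
            raise GenotypeValidationError(f"records missing columns {missing_cols}")
        self.records = self.records[required].copy()
        for col in ("population", "individual", "locus"):
            self.records[col] = self.records[col].astype(str)
        if not self.populations:
            self.populations = list(dict.fromkeys(self.records["population"]))
        if not self.loci:
            self.loci = list(dict.fromkeys(self.records["locus"]))
        if len(set(self.loci)) != len(self.loci):
            raise GenotypeValidationError("locus names must be unique")
        if len(set(self.populations)) != len(self.populations):
            raise GenotypeValidationError("population labels must be unique")
        undeclared_pop = set(self.records["population"]) - set(self.populations)
        if undeclared_pop:
            raise GenotypeValidationError(f"records reference undeclared populations {sorted(undeclared_pop)}")
        undeclared_loc = set(self.records["locus"]) - set(self.loci)
        if undeclared_loc:
            raise GenotypeValidationError(f"records reference undeclared loci {sorted(undeclared_loc)}")
        bad = ~(self.records["genotype"].isin(GENOTYPES) | self.records["genotype"].isna())
        if bad.any():
            raise GenotypeValidationError(
                f"invalid genotype codes {sorted(self.records.loc[bad, 'genotype'].unique())}"
            )
        dup = self.records.duplicated(subset=["population", "individual", "locus"])
        if dup.any():
            first = self.records[dup].iloc[0]
            raise GenotypeValidationError(
                "duplicate call for individual "
                f"{first['individual']!r} at locus {first['locus']!r} in population {first['population']!r}"
            )

    def counts(self, population: str, locus: str) -> GenotypeCounts:
        """Tabulate II/ID/DD counts for one cell; missing calls are excluded."""
        if population not in self.populations:
            raise KeyError(f"unknown population {population!r}")
        if locus not in self.loci:
            raise KeyError(f"unknown locus {locus!r}")
        sub = self.records[
            (self.records["population"] == population) & (self.records["locus"] == locus)
        ]["genotype"]
        vc = sub.value_counts()
        return GenotypeCounts(*(int(vc.get(g, 0)) for g in GENOTYPES))

    def counts_array(self) -> np.ndarray:
        """All cells at once: array of shape (populations, loci, 3)."""
        out = np.zeros((len(self.populations), len(self.loci), 3), dtype=np.int64)
        pop_idx = {p: i for i, p in enumerate(self.populations)}
        loc_idx = {l: j for j, l in enumerate(self.loci)}
        geno_idx = {g: k for k, g in enumerate(GENOTYPES)}
        sub = self.records.dropna(subset=["genotype"])
        grouped = sub.groupby(["population", "locus", "genotype"], observed=True).size()
        for (pop, loc, g), c in grouped.items():
            out[pop_idx[pop], loc_idx[loc], geno_idx[g]] = c
        return out

    @property
    def n_records(self) -> int:
        return len(self.records)


def read_genotype_table(path, *, missing: str = "NA") -> GenotypeTable:
    """Read a genotype TSV (columns population, individual, locus, genotype).

    ``+/+``-style and ``II``-style genotype tokens are equivalent; the
    ``missing`` code (default ``NA``) marks an untyped call.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["population", "individual", "locus", "genotype"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise GenotypeParseError(f"{path}: header missing columns {missing_cols}")
    genos = []
    for i, token in enumerate(df["genotype"]):
        try:
            genos.append(_normalise_token(token, missing))
        except GenotypeParseError as exc:
            # +2: one for the header line, one for 1-based numbering
            raise GenotypeParseError(f"{path}: line {i + 2}: {exc}") from None
    df = df.assign(genotype=pd.array(genos, dtype="object"))
    # canonical (sorted) label order so results do not depend on row order
    return GenotypeTable(
        records=df,
        populations=sorted(set(df["population"])),
        loci=sorted(set(df["locus"])),
    )


def write_genotype_table(table: GenotypeTable, path, *, missing: str = "NA") -> None:
    """Write a :class:`GenotypeTable` as canonical-token TSV."""
    out = table.records.copy()
    out["genotype"] = out["genotype"].fillna(missing)
    out.to_csv(path, sep="\t", index=False)


def tabulate_counts(table: GenotypeTable, population: str, locus: str) -> GenotypeCounts:
    """Functional alias for :meth:`GenotypeTable.counts`."""
    return table.counts(population, locus)


@dataclass
class FrequencyMatrix:
    """Population × locus insertion-allele frequencies with optional sample sizes.

    ``p`` holds the insertion (+) allele frequency; the deletion frequency is
    ``1 − p`` by construction.  ``n`` (diploid sample sizes, same shape) may be
    absent when only frequencies were published.  Sample sizes are stored per
    locus because published per-locus typing counts can differ from a
    population's declared recruitment size.
    """

    p: pd.DataFrame
    n: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.p = self.p.astype(float)
        self.p.index = self.p.index.astype(str).rename("population")
        self.p.columns = self.p.columns.astype(str).rename("locus")
        if self.p.index.has_duplicates or self.p.columns.has_duplicates:
            raise GenotypeValidationError("population and locus labels must be unique")
        values = self.p.to_numpy()
        if np.isnan(values).any():
            raise GenotypeValidationError("frequency matrix contains missing cells")
        if ((values < 0) | (values > 1)).any():
            bad = np.argwhere((values < 0) | (values > 1))[0]
            raise GenotypeValidationError(
                f"frequency outside [0, 1] at population {self.p.index[bad[0]]!r}, "
                f"locus {self.p.columns[bad[1]]!r}: {values[tuple(bad)]}"
            )
        if self.n is not None:
            self.n = self.n.reindex(index=self.p.index, columns=self.p.columns).astype(float)

    @property
    def populations(self) -> list[str]:
        return list(self.p.index)

    @property
    def loci(self) -> list[str]:
        return list(self.p.columns)

    def to_numpy(self) -> np.ndarray:
        return self.p.to_numpy(dtype=float)

    @classmethod
    def from_genotype_table(cls, table: GenotypeTable) -> "FrequencyMatrix":
        """Allele frequencies by direct counting, per population × locus cell.

        p = (2·n_II + n_ID) / 2n over the non-missing calls in each cell.
        Cells with no typed individuals are an error (frequency undefined).
        """
        counts = table.counts_array()
        n = counts.sum(axis=2)
        if (n == 0).any():
            i, j = np.argwhere(n == 0)[0]
            raise GenotypeValidationError(
                f"no typed individuals for population {table.populations[i]!r} "
                f"at locus {table.loci[j]!r}: allele frequency undefined"
            )
        p = (2 * counts[:, :, 0] + counts[:, :, 1]) / (2 * n)
        idx = pd.Index(table.populations, name="population")
        cols = pd.Index(table.loci, name="locus")
        return cls(
            p=pd.DataFrame(p, index=idx, columns=cols),
            n=pd.DataFrame(n, index=idx, columns=cols),
        )


def read_frequency_matrix(path) -> FrequencyMatrix:
    """Read a frequencies TSV: first column population, one column per locus,
    optional paired ``n_<locus>`` columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    n_cols = [c for c in df.columns if re.match(r"^n_", str(c))]
    p_cols = [c for c in df.columns if c not in n_cols]
    p = df[p_cols]
    p.index.name = "population"
    p.columns.name = "locus"
    n = None
    if n_cols:
        n = df[n_cols].rename(columns=lambda c: re.sub(r"^n_", "", str(c)))
        n = n.reindex(columns=p_cols)
        n.index.name = "population"
        n.columns.name = "locus"
    return FrequencyMatrix(p=p, n=n)


def write_frequency_matrix(m: FrequencyMatrix, path, *, precision: int = 4) -> None:
    """Write a :class:`FrequencyMatrix` as TSV (default 4-decimal frequencies)."""
    out = m.p.round(precision).copy()
    if m.n is not None:
        for locus in m.loci:
            col = m.n[locus]
            # keep sample sizes as integers in the text file
            out[f"n_{locus}"] = col.astype("Int64") if (col.dropna() % 1 == 0).all() else col
    out.to_csv(path, sep="\t", float_format=f"%.{precision}f")
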