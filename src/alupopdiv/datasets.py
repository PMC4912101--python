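"""Published summary tables from a survey of 7 Alu insertion loci in 12
South Indian caste and tribal populations.

The survey typed ACE, TPA25, FXIIIB, CD4, APO, D1 and PV92 in 574
individuals across 10 endogamous caste groups and 2 Western Ghats hill
tribes (Kani, Paliyar) and published per-population summary statistics
rather than individual genotypes.  Those printed tables are bundled here
verbatim as re-analysis inputs: allele frequencies and heterozygosities for
the two tribes, per-locus heterozygosities for all 12 populations, and
Ht/Hs/Gst gene-diversity decompositions (both for the 12 study populations
and for tribal comparisons pooling previously published South Indian [SIT]
and North Indian [NIT] tribes).

Known internal inconsistencies of the printed source are preserved as
printed (they are the published record): the pooled-diversity FXIIIB row
has Hs > Ht and its CD4 row does not satisfy Gst = (Ht − Hs)/Ht, and the
Kani ACE bold heterozygosity (0.5918) exceeds the biallelic maximum 0.5.
Downstream identity checks therefore use the rows that are arithmetically
consistent.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "LOCI",
    "load_tribal_allele_frequencies",
    "load_tribal_gene_diversity",
    "load_population_heterozygosities",
    "load_pooled_gene_diversity",
]

#: The seven human-specific Alu insertion/deletion markers of the survey.
LOCI = ("ACE", "TPA25", "FXIIIB", "CD4", "APO", "D1", "PV92")

# --- tribal allele frequencies / heterozygosities (Kani n=49, Paliyar n=57) ---
_TRIBAL = {
    # locus: (p_ins, p_del, 2pq printed, observed het) per tribe
    "Kani": {
        "p": [0.5000, 0.7959, 0.4795, 0.8979, 0.7857, 0.4387, 0.5306],
        "q": [0.5000, 0.2040, 0.5204, 0.1020, 0.2142, 0.5612, 0.4693],
        "het_exp": [0.5000, 0.3247, 0.4991, 0.1831, 0.3367, 0.4924, 0.4980],
        "het_obs": [0.5918, 0.3265, 0.2244, 0.1224, 0.1428, 0.1020, 0.5306],
        "het_obs_all": 0.2915,
        "n": 49,
    },
    "Paliyar": {
        "p": [0.4912, 0.5701, 0.6315, 0.8421, 0.5964, 0.5438, 0.6052],
        "q": [0.5087, 0.4298, 0.3684, 0.1570, 0.4035, 0.4561, 0.3947],
        "het_exp": [0.4998, 0.4900, 0.4653, 0.2644, 0.4812, 0.4961, 0.4778],
        "het_obs": [0.5614, 0.5087, 0.2105, 0.1754, 0.3508, 0.3859, 0.4385],
        "het_obs_all": 0.3759,
        "n": 57,
    },
}


def load_tribal_allele_frequencies() -> pd.DataFrame:
    """Per-locus published values for the two surveyed tribes.

    Tidy frame with columns ``tribe, locus, p, q, het_exp, het_obs`` —
    insertion frequency, printed deletion frequency, the printed 2pq row
    and the printed observed heterozygosity.
    """
    rows = []
    for tribe, d in _TRIBAL.items():
        for j, locus in enumerate(LOCI):
            rows.append((tribe, locus, d["p"][j], d["q"][j], d["het_exp"][j], d["het_obs"][j]))
    return pd.DataFrame(rows, columns=["tribe", "locus", "p", "q", "het_exp", "het_obs"])


# --- gene diversity of tribal comparisons (SIT / NIT / combined) ---
# per group: {locus: (Ht, Hs, Gst)}; "All loci" is the published aggregate row
_TRIBAL_DIVERSITY = {
    "SIT": {
        "ACE": (0.48539, 0.45038, 0.07212),
        "FXIIIB": (0.45151, 0.41058, 0.09065),
        "CD4": (0.09986, 0.09412, 0.05750),
        "APO": (0.39732, 0.35581, 0.10445),
        "PV92": (0.49817, 0.45311, 0.09046),
        "All loci": (0.38645, 0.35284, 0.08304),
    },
    "NIT": {
        "ACE": (0.47991, 0.44763, 0.06726),
        "FXIIIB": (0.42369, 0.39324, 0.07186),
        "CD4": (0.09859, 0.09197, 0.06712),
        "APO": (0.46798, 0.38898, 0.16879),
        "PV92": (0.48481, 0.46197, 0.04711),
        "TPA25": (0.47886, 0.45235, 0.05536),
        "D1": (0.44524, 0.46342, 0.03921),
        "All loci": (0.41129, 0.38565, 0.07381),
    },
    "CSNIT": {
        "ACE": (0.47590, 0.4400, 0.0753),
        "FXIIIB": (0.42350, 0.3880, 0.0836),
        "CD4": (0.07370, 0.0693, 0.0600),
        "APO": (0.43630, 0.3642, 0.1651),
        "PV92": (0.49940, 0.4516, 0.0958),
        "All loci": (0.38180, 0.3426, 0.0959),
    },
}


def load_tribal_gene_diversity(group: str = "SIT") -> pd.DataFrame:
    """Published Ht/Hs/Gst for tribal comparisons.

    ``group`` is ``"SIT"`` (five South Indian tribes), ``"NIT"`` (four North
    Indian tribes) or ``"CSNIT"`` (combined); index = locus plus an
    ``All loci`` aggregate row, columns ``Ht, Hs, Gst``.
    """
    try:
        d = _TRIBAL_DIVERSITY[group]
    except KeyError:
        raise KeyError(f"unknown group {group!r}; expected SIT, NIT or CSNIT") from None
    return pd.DataFrame.from_dict(d, orient="index", columns=["Ht", "Hs", "Gst"]).rename_axis("locus")


# --- per-population heterozygosities at each locus, all 12 populations ---
_POP_HET = {
    # population: (n, [ACE, TPA25, FXIIIB, CD4, APO, D1, PV92], all-loci)
    "Pallan": (50, [0.4130, 0.4782, 0.4782, 0.1521, 0.3043, 0.3478, 0.5217], 0.3850),
    "Nair": (56, [0.6041, 0.5535, 0.4464, 0.1785, 0.4107, 0.2678, 0.5892], 0.4357),
    "Namboothiri": (35, [0.2894, 0.4210, 0.5000, 0.1052, 0.7631, 0.4210, 0.4736], 0.42477),
    "Kani": (49, [0.5918, 0.3265, 0.2244, 0.1224, 0.1428, 0.1020, 0.5306], 0.29152),
    "Vanniyar": (51, [0.5600, 0.4600, 0.4000, 0.1800, 0.2200, 0.1200, 0.4000], 0.33428),
    "Paliyar": (58, [0.5614, 0.5087, 0.2105, 0.1754, 0.3508, 0.3859, 0.4385], 0.37590),
    "Narikuravar": (41, [0.6097, 0.1707, 0.3658, 0.2439, 0.3658, 0.2439, 0.3414], 0.33447),
    "Sourastra": (39, [0.4102, 0.4615, 0.3846, 0.1025, 0.2307, 0.3333, 0.5128], 0.34797),
    "Iyer": (44, [0.4883, 0.4186, 0.2790, 0.1395, 0.1627, 0.2352, 0.5581], 0.32594),
    "V.Goundar": (44, [0.5227, 0.5681, 0.4772, 0.0909, 0.2045, 0.5227, 0.5227], 0.41556),
    "Kallar": (53, [0.6425, 0.5476, 0.4761, 0.1190, 0.5238, 0.1904, 0.2380], 0.39110),
    "Yadava": (54, [0.5000, 0.8148, 0.3703, 0.0363, 0.6666, 0.4363, 0.4545], 0.46845),
}


def load_population_heterozygosities() -> pd.DataFrame:
    """Per-locus heterozygosities for all 12 study populations.

    Index = population; columns = the seven loci plus ``All loci`` (the
    published multi-locus average) and ``n`` (declared sample size).
    """
    rows = {
        pop: dict(zip(LOCI, vals), **{"All loci": avg, "n": n})
        for pop, (n, vals, avg) in _POP_HET.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("population")


# --- pooled gene diversity over the 12 study populations ---
_POOLED_DIVERSITY = {
    "ACE": (0.4959, 0.4664, 0.0595),
    "TPA25": (0.4784, 0.4572, 0.0444),
    "FXIIIB": (0.4951, 0.5219, 0.0494),
    "CD4": (0.2550, 0.1485, 0.0109),
    "APO": (0.4336, 0.4153, 0.0420),
    "D1": (0.4994, 0.4871, 0.0246),
    "PV92": (0.4900, 0.4773, 0.02602),
    "All loci": (0.4496, 0.4248, 0.03671),
}

#: Pooled-diversity loci whose printed (Ht, Hs, Gst) satisfy Gst = (Ht−Hs)/Ht.
CONSISTENT_POOLED_LOCI = ("ACE", "TPA25", "APO", "D1", "PV92")


def load_pooled_gene_diversity() -> pd.DataFrame:
    """Published per-locus Ht/Hs/Gst over the 12 study populations, with the
    ``All loci`` aggregate row (mean of the per-locus values)."""
    return pd.DataFrame.from_dict(
        _POOLED_DIVERSITY, orient="index", columns=["Ht", "Hs", "Gst"]
    ).rename_axis("locus")
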