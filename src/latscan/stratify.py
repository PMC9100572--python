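"""E1/E2 maturity-genotype calling and panel stratification.

The two major maturity loci E1 and E2 dominate flowering-time variation in US
soybean; to avoid their confounding effect, the disparity scan is run within a
single E-genotype stratum. Genotypes are called from two diagnostic variant
positions (defaults are the Wm82.a2.v1 coordinates of the E1 T75R missense and
the E2 K528* nonsense mutations); the alternate state at a diagnostic site
gives the recessive early-flowering allele (e1-as, e2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)

E1_SITE_DEFAULT = "06:20207322"  # T75R missense
E2_SITE_DEFAULT = "10:45310798"  # K528* nonsense

GENOTYPE_CLASSES = (("e1-as", "E2"), ("e1-as", "e2"), ("E1", "E2"), ("E1", "e2"))
EXCLUDED_CLASS = ("E1", "e2")
ANALYSIS_GROUP_DEFAULT = ("e1-as", "E2")


@dataclass(frozen=True)
class EGenotype:
    e1: str  # "E1" | "e1-as"
    e2: str  # "E2" | "e2"

    def as_tuple(self) -> tuple[str, str]:
        return (self.e1, self.e2)


def call_e_genotypes(
    genotypes: pd.DataFrame,
    e1_site: str = E1_SITE_DEFAULT,
    e2_site: str = E2_SITE_DEFAULT,
) -> pd.DataFrame:
    """Call per-accession E1/E2 genotypes from the diagnostic sites.

    ``genotypes`` is the accession x site dosage matrix. Any nonzero dosage at
    a diagnostic site is an alternate call (heterozygous calls, if present,
    are counted as alternate and logged).
    """
    for site in (e1_site, e2_site):
        if site not in genotypes.columns:
            raise KeyError(f"diagnostic site {site} missing from the variant table")
    het = genotypes[[e1_site, e2_site]].eq(1).any(axis=1)
    if het.any():
        log.warning(
            "%d accessions heterozygous at a diagnostic site; treated as alternate",
            int(het.sum()),
        )
    e1 = genotypes[e1_site].gt(0).map({True: "e1-as", False: "E1"})
    e2 = genotypes[e2_site].gt(0).map({True: "e2", False: "E2"})
    return pd.DataFrame({"e1": e1, "e2": e2}, index=genotypes.index)


def stratify(
    metadata: pd.DataFrame,
    e_genotypes: pd.DataFrame,
    analysis_group: tuple[str, str] = ANALYSIS_GROUP_DEFAULT,
    excluded_class: tuple[str, str] = EXCLUDED_CLASS,
) -> tuple[pd.DataFrame, dict[tuple[str, str], int], list[str]]:
    """Partition the panel into E-genotype classes and select the analysis subset.

    Returns (analysis-subset metadata rows, census of the four classes,
    excluded accession ids). The census always sums to the panel size.
    """
    meta = metadata.join(e_genotypes, how="inner")
    if len(meta) != len(metadata):
        raise ValueError("E genotypes missing for some accessions")
    census = {
        cls: int(((meta["e1"] == cls[0]) & (meta["e2"] == cls[1])).sum())
        for cls in GENOTYPE_CLASSES
    }
    excluded = meta.index[
        (meta["e1"] == excluded_class[0]) & (meta["e2"] == excluded_class[1])
    ].tolist()
    subset = meta[(meta["e1"] == analysis_group[0]) & (meta["e2"] == analysis_group[1])]
    if len(subset) == 0:
        raise ValueError(f"analysis group {analysis_group} is empty")
    return subset, census, excluded
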