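"""Amino-acid-level allele encoding of effect-annotated variants.

Variants predicted to alter the protein product non-conservatively are the
"allele-defining" set: exonic indels (inframe and frameshift), nonsense
(stop-gained) mutations, splice-site mutations, start/stop loss or gain, and
missense substitutions whose reference and alternate residues fall in
different physicochemical groups. Per gene, each accession's ref/alt states at
the qualifying positions are concatenated into a tuple; distinct tuples are
distinct putative alleles.

Only primary-transcript annotations are consumed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Physicochemical classes used to call a missense substitution
#: non-conservative when the two residues change class. Overridable from a
#: two-column TSV (residue, group) via :func:`load_grouping`.
DEFAULT_GROUPING: dict[str, str] = {
    **{aa: "aliphatic" for aa in "AVLIM"},
    **{aa: "aromatic" for aa in "FWY"},
    **{aa: "polar" for aa in "STNQC"},
    **{aa: "positive" for aa in "KRH"},
    **{aa: "negative" for aa in "DE"},
    **{aa: "special" for aa in "GP"},
}


class EffectClass(str, Enum):
    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"
    SPLICE_SITE = "splice_site"
    INFRAME_INDEL = "inframe_indel"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Effect classes that qualify a variant as allele-defining regardless of the
#: residues involved; missense additionally requires a non-conservative change.
ALWAYS_QUALIFYING = frozenset(
    {
        EffectClass.STOP_GAINED,
        EffectClass.STOP_LOST,
        EffectClass.START_LOST,
        EffectClass.SPLICE_SITE,
        EffectClass.INFRAME_INDEL,
        EffectClass.FRAMESHIFT,
    }
)

#: Effect classes whose annotation carries a residue substitution.
_AA_CLASSES = frozenset({EffectClass.MISSENSE, EffectClass.STOP_LOST, EffectClass.START_LOST})


@dataclass(frozen=True)
class AnnotatedVariant:
    """One effect-annotated variant call on the primary transcript."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene_id: str
    effect_class: EffectClass
    aa_ref: str | None = None
    aa_alt: str | None = None
    aa_pos: int | None = None
    transcript_rank: str = "primary"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")

    @property
    def site(self) -> str:
        return f"{self.chrom}:{self.pos}"


def load_grouping(path) -> dict[str, str]:
    """Read a residue->group mapping from a two-column TSV (residue, group)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["residue", "group"], comment="#")
    grouping = dict(zip(df["residue"].str.strip(), df["group"].str.strip()))
    missing = STANDARD_RESIDUES - grouping.keys()
    if missing:
        raise ValueError(f"grouping file {path} misses residues: {sorted(missing)}")
    return grouping


def _check_residue(aa: str) -> str:
    if aa not in STANDARD_RESIDUES:
        raise ValueError(f"non-standard amino-acid symbol {aa!r}")
    return aa


def is_nonconservative(aa_ref: str, aa_alt: str, grouping: dict[str, str] | None = None) -> bool:
    """True iff the two residues belong to different physicochemical groups."""
    grouping = DEFAULT_GROUPING if grouping is None else grouping
    return grouping[_check_residue(aa_ref)] != grouping[_check_residue(aa_alt)]


def qualifies(
    v: AnnotatedVariant,
    grouping: dict[str, str] | None = None,
    exclude_sites: set[str] | frozenset[str] = frozenset(),
) -> bool:
    """Is this variant allele-defining?

    ``exclude_sites`` is a manual per-variant blacklist ("chrom:pos") for
    calls judged to be alignment artifacts, e.g. frameshifts arising inside
    homopolymer runs.
    """
    if v.effect_class is None:
        raise ValueError(f"variant {v.site} lacks an effect class")
    if v.transcript_rank != "primary":
        return False
    if v.site in exclude_sites:
        return False
    eff = EffectClass(v.effect_class)
    if eff in ALWAYS_QUALIFYING:
        return True
    if eff is EffectClass.MISSENSE:
        return is_nonconservative(v.aa_ref, v.aa_alt, grouping)
    return False


@dataclass
class GeneAlleleCatalog:
    """Distinct concatenated alleles of one gene over a panel.

    ``allele_states`` maps each allele label to its tuple of per-site states
    (0 = reference, k = k-th ALT allele of that site); ``assignments`` maps
    each accession id to its allele label.
    """

    gene_id: str
    variants: list[AnnotatedVariant]
    allele_states: dict[str, tuple[int, ...]]
    assignments: dict[str, str]
    carrier_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.carrier_counts:
            counts: dict[str, int] = {}
            for lab in self.assignments.values():
                counts[lab] = counts.get(lab, 0) + 1
            self.carrier_counts = counts

    @property
    def n_accessions(self) -> int:
        return len(self.assignments)

    def labels_for(self, accessions) -> list[str]:
        return [self.assignments[a] for a in accessions]


def build_gene_alleles(
    gene_id: str,
    variants: list[AnnotatedVariant],
    genotypes: pd.DataFrame,
    het_as_alt: bool = True,
) -> GeneAlleleCatalog:
    """Concatenate per-site states into putative alleles for one gene.

    Parameters
    ----------
    variants : list of qualifying variants for this gene.
    genotypes : DataFrame, accessions x sites; integer alternate-allele dosage
        (0/2 for homozygous panels, multiallelic sites use the ALT index of the
        carried allele). Column order need not match ``variants``; sites are
        sorted internally by (chrom, pos). No missing values allowed.
    het_as_alt : treat dosage 1 (heterozygous) as carrying the alternate state.

    Allele labels: the all-reference tuple is "Ref"; the others "Alt1",
    "Alt2", ... by descending carrier count, ties broken by tuple
    lexicographic order.
    """
    order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
    variants = [variants[i] for i in order]
    sites = [v.site for v in variants]
    missing_cols = [s for s in sites if s not in genotypes.columns]
    if missing_cols:
        raise ValueError(f"gene {gene_id}: genotype matrix lacks sites {missing_cols}")
    g = genotypes[sites]
    if g.isna().any().any():
        raise ValueError(f"gene {gene_id}: genotype matrix contains missing values")

    arr = g.to_numpy(int)
    if het_as_alt:
        # collapse dosage to carried state: 0 stays ref; 1 and 2 carry ALT1;
        # values >2 index further ALT alleles at multiallelic sites
        state = np.where(arr == 0, 0, np.maximum(arr - 1, 1))
    else:
        state = np.where(arr >= 2, np.maximum(arr - 1, 1), 0)

    tuples = [tuple(row) for row in state]
    counts: dict[tuple[int, ...], int] = {}
    for t in tuples:
        counts[t] = counts.get(t, 0) + 1

    ref_tuple = (0,) * len(sites)
    alt_tuples = sorted(
        (t for t in counts if t != ref_tuple), key=lambda t: (-counts[t], t)
    )
    label_of = {ref_tuple: "Ref"}
    for i, t in enumerate(alt_tuples, 1):
        label_of[t] = f"Alt{i}"

    assignments = {acc: label_of[t] for acc, t in zip(g.index, tuples)}
    allele_states = {lab: t for t, lab in label_of.items() if counts.get(t)}
    if ref_tuple not in counts:
        allele_states.pop("Ref", None)
    return GeneAlleleCatalog(gene_id, variants, allele_states, assignments)


def build_catalogs(
    variants: list[AnnotatedVariant],
    genotypes: pd.DataFrame,
    grouping: dict[str, str] | None = None,
    exclude_sites: set[str] | frozenset[str] = frozenset(),
    het_as_alt: bool = True,
) -> dict[str, GeneAlleleCatalog]:
    """Filter variants to the allele-defining set and build per-gene catalogs."""
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in variants:
        if qualifies(v, grouping, exclude_sites):
            by_gene.setdefault(v.gene_id, []).append(v)
    return {
        gene: build_gene_alleles(gene, vs, genotypes, het_as_alt=het_as_alt)
        for gene, vs in by_gene.items()
    }


def filter_testable_genes(
    catalogs: dict[str, GeneAlleleCatalog],
    candidate_genes: list[str],
    min_carriers: int = 10,
) -> list[str]:
    """Candidate genes with >=1 qualifying variant and >=1 non-Ref allele
    carried by at least ``min_carriers`` accessions; input order preserved."""
    keep = []
    for gene in candidate_genes:
        cat = catalogs.get(gene)
        if cat is None or not cat.variants:
            if cat is None:
                warnings.warn(f"candidate gene {gene} absent from catalogs; excluded")
            continue
        if any(
            n >= min_carriers for lab, n in cat.carrier_counts.items() if lab != "Ref"
        ):
            keep.append(gene)
    return keep


def catalogs_to_frame(catalogs: dict[str, GeneAlleleCatalog]) -> pd.DataFrame:
    """Flatten catalogs for TSV export: gene, allele, variant state tuple, carriers."""
    rows = []
    for gene, cat in catalogs.items():
        for lab, states in cat.allele_states.items():
            rows.append(
                {
                    "gene": gene,
                    "allele": lab,
                    "sites": ";".join(v.site for v in cat.variants),
                    "states": ";".join(map(str, states)),
                    "carriers": cat.carrier_counts.get(lab, 0),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "allele", "sites", "states", "carriers"])
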