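"""End-to-end candidate-gene scan orchestration.

Stages: read inputs -> build amino-acid-level allele catalogs -> assign
latitudes -> call and stratify E genotypes -> permutation-calibrated
disparity scan within the analysis stratum -> conservation assessment of the
variants of significant genes -> report. A JSON manifest records the
configuration, seed and record counts at every filter stage; identical config
and seed reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import conservation as cons
from . import io as lio
from .alleles import build_catalogs, catalogs_to_frame, filter_testable_genes, load_grouping
from .disparity import DisparityScan, ScanResults
from .latitude import StateLatitudes, assign_latitudes
from .stratify import (
    ANALYSIS_GROUP_DEFAULT,
    E1_SITE_DEFAULT,
    E2_SITE_DEFAULT,
    call_e_genotypes,
    stratify,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and parameters of one scan run."""

    variants: str                       # VCF (.vcf) or annotated-variant TSV
    metadata: str                       # accession CSV
    state_table: str                    # state latitude CSV
    out_dir: str
    genotypes: str | None = None        # genotype TSV (required with TSV variants)
    ortholog_list: str | None = None    # candidate gene ids, one per line
    alignments_dir: str | None = None   # {gene}.fasta aligned peptide sets
    grouping_file: str | None = None    # residue physicochemical groups TSV
    exclude_sites: list[str] = field(default_factory=list)
    analysis_group: tuple[str, str] = ANALYSIS_GROUP_DEFAULT
    e1_site: str = E1_SITE_DEFAULT
    e2_site: str = E2_SITE_DEFAULT
    min_carriers: int = 10
    n_perm: int = 1000
    alpha: float = 0.05
    ic_threshold: float = cons.IC_THRESHOLD_DEFAULT
    modal_freq_threshold: float = cons.MODAL_FREQ_DEFAULT
    flank: int = cons.FLANK_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")


@dataclass
class RunResult:
    manifest: dict
    scan: ScanResults
    census: dict
    results_table: pd.DataFrame
    conservation_table: pd.DataFrame
    northern_profile: pd.DataFrame


def _load_inputs(config: RunConfig):
    path = Path(config.variants)
    if path.suffix == ".vcf":
        variants, genotypes = lio.read_vcf(path)
    else:
        variants = lio.read_variants_tsv(path)
        if config.genotypes is None:
            raise ValueError("TSV variants require a genotypes table")
        genotypes = lio.read_genotypes_tsv(config.genotypes)
    metadata = pd.read_csv(config.metadata, index_col="accession")
    states = StateLatitudes.from_csv(config.state_table)
    return variants, genotypes, metadata, states


def run_scan(config: RunConfig) -> RunResult:
    """Run the full scan and write result files + manifest under out_dir."""
    out = lio.ensure_dir(config.out_dir)
    stage = "load inputs"
    try:
        variants, genotypes, metadata, states = _load_inputs(config)
        grouping = load_grouping(config.grouping_file) if config.grouping_file else None

        stage = "latitude assignment"
        if "LATITUDE" not in metadata.columns:
            metadata = assign_latitudes(metadata, states)
        metadata.to_csv(out / "metadata_with_latitude.csv", index_label="accession")

        stage = "allele catalog"
        catalogs = build_catalogs(
            variants, genotypes, grouping, frozenset(config.exclude_sites)
        )
        catalogs_to_frame(catalogs).to_csv(out / "allele_catalogs.tsv", sep="\t", index=False)

        stage = "E stratification"
        e_geno = call_e_genotypes(genotypes, config.e1_site, config.e2_site)
        subset, census, excluded = stratify(metadata, e_geno, config.analysis_group)
        census_df = pd.DataFrame(
            [(f"{a}/{b}", n) for (a, b), n in census.items()], columns=["class", "n"]
        )
        census_df.to_csv(out / "e_census.tsv", sep="\t", index=False)

        stage = "gene filtering"
        candidates = (
            [l.strip() for l in Path(config.ortholog_list).read_text().splitlines() if l.strip()]
            if config.ortholog_list
            else [g for g in catalogs if g not in ("E1", "E2")]
        )
        with_variants = [g for g in candidates if g in catalogs and catalogs[g].variants]
        testable = filter_testable_genes(catalogs, candidates, config.min_carriers)
        (out / "testable_genes.txt").write_text("\n".join(testable) + "\n")

        stage = "disparity scan"
        scan = DisparityScan(
            catalogs, subset["LATITUDE"], testable, config.min_carriers
        ).fit(n_perm=config.n_perm, alpha=config.alpha, seed=config.seed)
        results_table = scan.frame()
        results_table.to_csv(out / "disparity_results.tsv", sep="\t", index=False)
        boxdata = {
            gene: {
                lab: subset.loc[
                    [a for a in subset.index if catalogs[gene].assignments.get(a, "Ref") == lab],
                    "LATITUDE",
                ].tolist()
                for lab in r.group_table["allele"]
            }
            for gene, r in scan.results.items()
            if r.significant
        }
        (out / "boxplot_data.json").write_text(json.dumps(boxdata, indent=1))

        stage = "conservation"
        cons_table = _assess_conservation(config, catalogs, scan)
        cons_table.to_csv(out / "conservation.tsv", sep="\t", index=False)

        stage = "report"
        profile = northern_allele_profile(scan, catalogs, subset)
        profile.to_csv(out / "northern_allele_profile.tsv", sep="\t")
        summary = _candidate_summary(scan, cons_table)
        summary.to_csv(out / "candidate_summary.tsv", sep="\t", index=False)

        manifest = {
            "config": {k: v for k, v in asdict(config).items()},
            "seed": config.seed,
            "counts": {
                "panel": int(len(metadata)),
                "analysis_stratum": int(len(subset)),
                "excluded_class": int(len(excluded)),
                "candidates": len(candidates),
                "with_qualifying_variants": len(with_variants),
                "testable": len(testable),
                "tested": len(scan.results),
                "skipped": len(scan.skipped),
                "significant": len(scan.significant_genes),
            },
            "skipped": scan.skipped,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    except Exception as err:
        raise RuntimeError(f"scan failed at stage {stage!r}: {err}") from err

    return RunResult(
        manifest=manifest,
        scan=scan,
        census=census,
        results_table=results_table,
        conservation_table=cons_table,
        northern_profile=profile,
    )


def _assess_conservation(config: RunConfig, catalogs, scan: ScanResults) -> pd.DataFrame:
    rows = []
    aln_dir = Path(config.alignments_dir) if config.alignments_dir else None
    for gene in scan.significant_genes:
        if aln_dir is None:
            break
        path = aln_dir / f"{gene}.fasta"
        if not path.exists():
            log.warning("no alignment for significant gene %s", gene)
            continue
        for v in catalogs[gene].variants:
            if v.aa_pos is None or v.aa_ref is None or v.aa_alt in (None, "*"):
                continue
            _, call = cons.assess_variant(
                path, v.aa_pos, v.aa_ref, v.aa_alt, gene_id=gene,
                flank=config.flank, ic_threshold=config.ic_threshold,
                modal_freq_threshold=config.modal_freq_threshold,
            )
            rows.append(
                {
                    "gene": gene,
                    "site": v.site,
                    "aa_pos": v.aa_pos,
                    "aa_ref": v.aa_ref,
                    "aa_alt": v.aa_alt,
                    "column": call.variant_column,
                    "ic_bits": call.information,
                    "modal_residue": call.modal_residue,
                    "modal_freq": call.modal_frequency,
                    "conserved_site": call.conserved_site,
                    "ref_is_conserved": call.ref_is_conserved,
                    "alt_is_conserved": call.alt_is_conserved,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "site", "aa_pos", "aa_ref", "aa_alt", "column", "ic_bits",
            "modal_residue", "modal_freq", "conserved_site", "ref_is_conserved",
            "alt_is_conserved",
        ],
    )


def _candidate_summary(scan: ScanResults, cons_table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for gene in scan.significant_genes:
        r = scan.results[gene]
        sub = cons_table[cons_table["gene"] == gene] if len(cons_table) else cons_table
        rows.append(
            {
                "gene": gene,
                "kind": r.kind,
                "p_empirical": r.pvalue,
                "delta_top": float(
                    r.group_table["mean_latitude"].max()
                    - r.group_table["mean_latitude"].min()
                ),
                "northern_allele": r.northern_allele,
                "n_conserved_variants": int(sub["conserved_site"].sum()) if len(sub) else 0,
                "n_assessed_variants": int(len(sub)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "kind", "p_empirical", "delta_top", "northern_allele",
            "n_conserved_variants", "n_assessed_variants",
        ],
    )


def northern_allele_profile(scan: ScanResults, catalogs, subset: pd.DataFrame) -> pd.DataFrame:
    """Per-accession count of "northern" alleles among significant genes.

    For each significant gene the allele with the higher mean latitude is the
    "northern" allele; each accession's count of northern alleles carried is
    returned sorted by descending count.
    """
    counts = pd.Series(0, index=subset.index, dtype=int)
    for gene in scan.significant_genes:
        northern = scan.results[gene].northern_allele
        carried = pd.Series(
            [catalogs[gene].assignments.get(a, "Ref") == northern for a in subset.index],
            index=subset.index,
        )
        counts += carried.astype(int)
    out = pd.DataFrame(
        {"northern_alleles": counts, "latitude": subset["LATITUDE"]}
    ).sort_values(["northern_alleles", "latitude"], ascending=False)
    out.index.name = "accession"
    return out


def published_scan(
    ts1: pd.DataFrame,
    gene_columns: list[str],
    latitude_col: str = "LATITUDE",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Disparity tests on a published per-accession table.

    ``ts1`` must hold one row per accession with an assigned-latitude column
    and one allele-label column per gene (the layout of the study's
    supplementary per-line table). Returns {gene: GeneDisparityResults}. This
    entry point exists so the published per-line data, once obtained, can be
    pushed through the identical statistical machinery as the synthetic runs.
    """
    from .disparity import GeneDisparity, gene_seed

    out = {}
    for gene in gene_columns:
        sub = ts1[[latitude_col, gene]].dropna()
        out[gene] = GeneDisparity(
            sub[latitude_col].to_numpy(float), sub[gene].to_numpy(), gene_id=gene
        ).fit(n_perm=n_perm, alpha=alpha, seed=gene_seed(seed, gene))
    return out
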