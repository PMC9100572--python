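"""Reading and writing the flat formats the pipeline consumes and emits.

Variants travel either as a minimal VCF v4.2 with a SnpEff-style ANN INFO
subfield (``allele|effect|gene|transcript|HGVS.p``) or as an equivalent
annotated-variant TSV; genotypes are an accession x site integer dosage
matrix. VCF parsing goes through pysam.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
import pysam
from Bio.SeqUtils import seq1, seq3

from .alleles import AnnotatedVariant, EffectClass

#: SnpEff annotation terms -> internal effect classes.
EFFECT_TERMS = {
    "missense_variant": EffectClass.MISSENSE,
    "synonymous_variant": EffectClass.SYNONYMOUS,
    "stop_gained": EffectClass.STOP_GAINED,
    "stop_lost": EffectClass.STOP_LOST,
    "start_lost": EffectClass.START_LOST,
    "splice_donor_variant": EffectClass.SPLICE_SITE,
    "splice_acceptor_variant": EffectClass.SPLICE_SITE,
    "splice_region_variant": EffectClass.SPLICE_SITE,
    "conservative_inframe_insertion": EffectClass.INFRAME_INDEL,
    "conservative_inframe_deletion": EffectClass.INFRAME_INDEL,
    "disruptive_inframe_insertion": EffectClass.INFRAME_INDEL,
    "disruptive_inframe_deletion": EffectClass.INFRAME_INDEL,
    "frameshift_variant": EffectClass.FRAMESHIFT,
}
_CLASS_TO_TERM = {
    EffectClass.MISSENSE: "missense_variant",
    EffectClass.SYNONYMOUS: "synonymous_variant",
    EffectClass.STOP_GAINED: "stop_gained",
    EffectClass.STOP_LOST: "stop_lost",
    EffectClass.START_LOST: "start_lost",
    EffectClass.SPLICE_SITE: "splice_donor_variant",
    EffectClass.INFRAME_INDEL: "conservative_inframe_insertion",
    EffectClass.FRAMESHIFT: "frameshift_variant",
    EffectClass.OTHER: "intergenic_region",
}

_HGVS_P = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|\*)$")


def hgvs_p(aa_ref: str, aa_pos: int, aa_alt: str) -> str:
    """One-letter substitution -> HGVS.p string, e.g. (M, 37, T) -> p.Met37Thr."""
    alt = "*" if aa_alt == "*" else seq3(aa_alt)
    return f"p.{seq3(aa_ref)}{aa_pos}{alt}"


def parse_hgvs_p(text: str) -> tuple[str, int, str] | None:
    """HGVS.p substitution -> (aa_ref, aa_pos, aa_alt), else None."""
    m = _HGVS_P.match(text or "")
    if not m:
        return None
    ref3, pos, alt3 = m.groups()
    alt = "*" if alt3 == "*" else seq1(alt3)
    return seq1(ref3), int(pos), alt


def write_vcf(path, variants: list[AnnotatedVariant], genotypes: pd.DataFrame) -> None:
    """Write a minimal VCF v4.2 with per-variant ANN annotation.

    ``genotypes`` holds alternate dosage (0/1/2) per accession (rows) and site
    "chrom:pos" (columns); emitted genotypes are 0/0, 0/1 or 1/1.
    """
    accs = list(genotypes.index)
    chroms = sorted({v.chrom for v in variants})
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional '
            "annotations: 'Allele | Annotation | Gene_ID | Feature_ID | "
            "HGVS.p'\">\n"
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(accs) + "\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            p_field = (
                hgvs_p(v.aa_ref, v.aa_pos, v.aa_alt)
                if v.aa_ref is not None and v.aa_pos is not None
                else ""
            )
            ann = f"{v.alt}|{_CLASS_TO_TERM[EffectClass(v.effect_class)]}|{v.gene_id}|{v.gene_id}.1|{p_field}"
            col = genotypes[v.site]
            gts = "\t".join(gt_of[int(col[a])] for a in accs)
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\tANN={ann}\tGT\t{gts}\n"
            )


def read_vcf(path) -> tuple[list[AnnotatedVariant], pd.DataFrame]:
    """Read an ANN-annotated VCF into variants + an accession x site dosage matrix.

    Only primary-transcript annotations are consumed; records without an ANN
    entry become effect class "other". Multiallelic records contribute one
    tuple state per ALT allele (dosage = ALT index for homozygous carriers).
    """
    vf = pysam.VariantFile(str(path))
    accs = list(vf.header.samples)
    variants: list[AnnotatedVariant] = []
    dosages: dict[str, list[int]] = {}
    for rec in vf:
        ann_entries = rec.info.get("ANN", ())
        if isinstance(ann_entries, str):
            ann_entries = (ann_entries,)
        ann = ann_entries[0] if ann_entries else None
        effect = EffectClass.OTHER
        gene = ""
        aa = None
        if ann:
            fields = ann.split("|")
            term = fields[1] if len(fields) > 1 else ""
            effect = EFFECT_TERMS.get(term.split("&")[0], EffectClass.OTHER)
            gene = fields[2] if len(fields) > 2 else ""
            aa = parse_hgvs_p(fields[4]) if len(fields) > 4 else None
        aa_ref, aa_pos, aa_alt = (aa if aa else (None, None, None))
        if aa:
            aa_ref, aa_pos, aa_alt = aa
        v = AnnotatedVariant(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alt=",".join(rec.alts or ("N",)),
            gene_id=gene,
            effect_class=effect,
            aa_ref=aa_ref,
            aa_alt=aa_alt,
            aa_pos=aa_pos,
        )
        variants.append(v)
        row = []
        for a in accs:
            idx = [i for i in (rec.samples[a].allele_indices or ()) if i is not None]
            if not idx or max(idx) == 0:
                d = 0  # homozygous reference (or no call -> reference)
            else:
                k = max(idx)
                # dosage convention: 1 = het ref/alt1, k+1 = carries ALT(k)
                d = 1 if (0 in idx and k == 1) else k + 1
            row.append(d)
        dosages[v.site] = row
    geno = pd.DataFrame(dosages, index=pd.Index(accs, name="accession"))
    return variants, geno


# --- annotated-variant TSV dialect (equivalent to the VCF + ANN) ---

_VARIANT_COLS = [
    "chrom", "pos", "ref", "alt", "gene_id", "effect_class",
    "aa_ref", "aa_pos", "aa_alt", "transcript_rank",
]


def write_variants_tsv(path, variants: list[AnnotatedVariant]) -> None:
    rows = [
        {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene_id": v.gene_id, "effect_class": EffectClass(v.effect_class).value,
            "aa_ref": v.aa_ref or "", "aa_pos": v.aa_pos or "", "aa_alt": v.aa_alt or "",
            "transcript_rank": v.transcript_rank,
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=_VARIANT_COLS).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for _, r in df.iterrows():
        aa_pos = r.get("aa_pos")
        out.append(
            AnnotatedVariant(
                chrom=str(r["chrom"]),
                pos=int(r["pos"]),
                ref=str(r["ref"]),
                alt=str(r["alt"]),
                gene_id=str(r["gene_id"]),
                effect_class=EffectClass(r["effect_class"]),
                aa_ref=r["aa_ref"] if isinstance(r.get("aa_ref"), str) and r["aa_ref"] else None,
                aa_alt=r["aa_alt"] if isinstance(r.get("aa_alt"), str) and r["aa_alt"] else None,
                aa_pos=int(aa_pos) if pd.notna(aa_pos) and aa_pos != "" else None,
                transcript_rank=str(r.get("transcript_rank", "primary")),
            )
        )
    return out


def write_genotypes_tsv(path, genotypes: pd.DataFrame) -> None:
    genotypes.to_csv(path, sep="\t", index_label="accession")


def read_genotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="accession")


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
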