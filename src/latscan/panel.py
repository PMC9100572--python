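"""Synthetic elite-line panel generator with known planted effects.

Emulates the study system: a panel of elite US soybean lines (default 264)
spanning roughly 27.6-48.9°N, with two major maturity loci (E1-like and
E2-like, effects of several degrees of latitude), a set of minor candidate
genes with planted allele-latitude disparities of 0-1°N, realistic
alternate-allele carrier counts, and per-gene ortholog alignments with
controllable per-column conservation. Every planted quantity is recorded in a
truth table so downstream stages can be tested against known ground truth.

The allele-frequency model is a logistic cline: for each gene the carrier
probability of the alternate allele is ``expit(a + b*(lat - mean))``, with the
intercept solved for the target carrier fraction and the slope solved
numerically so that the expected carrier-minus-noncarrier mean-latitude gap
equals the planted disparity.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import io as lio
from .alleles import DEFAULT_GROUPING, AnnotatedVariant, EffectClass
from .latitude import StateLatitudes, StateSpan, assign_latitudes
from .stratify import E1_SITE_DEFAULT, E2_SITE_DEFAULT

# Approximate border/centroid latitudes (decimal °N) of states contributing
# elite lines; Illinois borders are the exact values used by the latitude
# rescaling worked example.
DEFAULT_STATES = [
    StateSpan("Minnesota", 49.384358, 43.499356, 46.441850),
    StateSpan("Michigan", 48.306063, 41.696118, 44.346550),
    StateSpan("Nebraska", 43.001708, 39.999998, 41.500850),
    StateSpan("Illinois", 42.496369, 37.231888, 40.033100),
    StateSpan("Missouri", 40.613640, 35.995683, 38.304661),
    StateSpan("Arkansas", 36.499600, 33.004106, 34.751850),
    StateSpan("Georgia", 35.000659, 30.357851, 32.678125),
    StateSpan("Texas", 36.500704, 25.837377, 31.168700),
]

#: Planted minor-gene disparities (°N) mirroring the magnitudes of the
#: candidate genes reported for the real panel, plus null genes.
DEFAULT_PLANTED = {
    "GeneA": 0.76, "GeneB": 0.58, "GeneC": 0.88, "GeneD": 0.59,
    "GeneE": 0.58, "GeneF": 0.64, "GeneG": 0.67, "GeneH": 0.41,
}

QUALIFYING_CLASS_POOL = (
    EffectClass.MISSENSE,        # drawn non-conservative
    EffectClass.STOP_GAINED,
    EffectClass.SPLICE_SITE,
    EffectClass.INFRAME_INDEL,
    EffectClass.FRAMESHIFT,
)
DECOY_CLASS_POOL = (EffectClass.SYNONYMOUS, EffectClass.MISSENSE)  # missense drawn conservative


@dataclass(frozen=True)
class MajorLocus:
    """A planted major maturity locus (diagnostic site + large effect)."""

    site: str            # "chrom:pos"
    delta: float         # °N between alternate carriers and non-carriers
    effect_class: EffectClass
    aa_ref: str | None = None
    aa_alt: str | None = None
    aa_pos: int | None = None


@dataclass(frozen=True)
class PanelConfig:
    """Study conditions for the synthetic panel."""

    n_accessions: int = 264
    states: tuple[StateSpan, ...] = tuple(DEFAULT_STATES)
    planted_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED)
    )
    n_null_genes: int = 12
    major_loci: tuple[MajorLocus, MajorLocus] = (
        MajorLocus(E1_SITE_DEFAULT, 4.6, EffectClass.MISSENSE, "T", "R", 75),
        MajorLocus(E2_SITE_DEFAULT, 2.5, EffectClass.STOP_GAINED, "K", "*", 528),
    )
    #: E-genotype class counts (e1-as/E2, e1-as/e2, E1/E2, E1/e2); rescaled
    #: proportionally when n_accessions differs from their sum.
    e_class_counts: tuple[int, int, int, int] = (187, 41, 31, 5)
    #: mean adaptation latitude of the e1-as/E2 stratum (°N); the other class
    #: bands are placed from it via the planted major-locus effects
    class_band_center: float = 40.5
    #: within-class latitude SD (°N) for (e1-as/E2, e1-as/e2, E1 classes);
    #: the analysis stratum is tight, the tails wider, mirroring the
    #: maturity-group band structure of an elite panel
    class_latitude_sd: tuple[float, float, float] = (1.5, 2.0, 2.5)
    carrier_freq_range: tuple[float, float] = (0.06, 0.6)
    maturity_noise_sd: float = 0.15      # RM units
    maturity_available_frac: float = 141 / 264
    heterozygotes: bool = False          # panels are inbred; off by default
    alignment_n_genera: int = 100
    alignment_length: int = 80
    alignment_concentration: float = 99.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.carrier_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"carrier_freq_range {self.carrier_freq_range} not within (0, 1)")
        for s in self.states:
            if not s.north > s.south:
                raise ValueError(f"state {s.name}: north <= south")
        if self.n_accessions < 2 * len(self.states):
            raise ValueError("need at least two accessions per state program")

    @property
    def gene_ids(self) -> list[str]:
        nulls = [f"Null{i+1:02d}" for i in range(self.n_null_genes)]
        return list(self.planted_effects) + nulls

    @property
    def all_deltas(self) -> dict[str, float]:
        d = dict(self.planted_effects)
        d.update({f"Null{i+1:02d}": 0.0 for i in range(self.n_null_genes)})
        return d


@dataclass
class Panel:
    """One realized synthetic panel."""

    config: PanelConfig
    metadata: pd.DataFrame          # accession-indexed, incl. LATITUDE columns
    variants: list[AnnotatedVariant]
    genotypes: pd.DataFrame         # accession x site dosage
    truth: pd.DataFrame             # gene, delta, sites, conserved columns

    def write(self, outdir) -> None:
        out = lio.ensure_dir(outdir)
        self.metadata.to_csv(out / "metadata.csv", index_label="accession")
        lio.write_vcf(out / "variants.vcf", self.variants, self.genotypes)
        lio.write_variants_tsv(out / "variants.tsv", self.variants)
        lio.write_genotypes_tsv(out / "genotypes.tsv", self.genotypes)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        StateLatitudes(list(self.config.states)).to_csv(out / "states.csv")

    def state_table(self) -> StateLatitudes:
        return StateLatitudes(list(self.config.states))


# ---------------------------------------------------------------------------
# cline model


def _solve_intercept(lat_c: np.ndarray, b: float, frac: float) -> float:
    """Intercept a with mean(expit(a + b*lat_c)) = frac; monotone in a."""
    f = lambda a: expit(a + b * lat_c).mean() - frac
    # bracket must outrun |b| * max|lat_c| so both signs are reachable
    lim = 60.0 + abs(b) * float(np.abs(lat_c).max())
    return brentq(f, -lim, lim, xtol=1e-10)


def _expected_gap(lat: np.ndarray, p: np.ndarray) -> float:
    """Expected carrier-minus-noncarrier mean latitude under Bernoulli(p)."""
    return float((p * lat).sum() / p.sum() - ((1 - p) * lat).sum() / (1 - p).sum())


def cline_model(latitudes, delta: float, frac: float) -> tuple[float, float, float]:
    """Fit (intercept, slope, centering mean) of the logistic cline.

    The slope is solved so the expected carrier/noncarrier latitude gap on
    ``latitudes`` equals ``delta`` (°N, may be negative) at carrier fraction
    ``frac``. ``delta=0`` gives a flat cline exactly.
    """
    lat = np.asarray(latitudes, dtype=float)
    center = float(lat.mean())
    lat_c = lat - center
    if delta == 0.0:
        return float(np.log(frac / (1.0 - frac))), 0.0, center

    def gap(b: float) -> float:
        a = _solve_intercept(lat_c, b, frac)
        return _expected_gap(lat, expit(a + b * lat_c)) - delta

    lo, hi = (0.0, 8.0) if delta > 0 else (-8.0, 0.0)
    try:
        b = brentq(gap, lo, hi, xtol=1e-8)
    except ValueError:
        # requested disparity beyond what this geography can realize: saturate
        b = hi if delta > 0 else lo
    a = _solve_intercept(lat_c, b, frac)
    return float(a), float(b), center


def cline_probabilities(latitudes, delta: float, frac: float) -> np.ndarray:
    """Per-accession carrier probabilities realizing the planted disparity."""
    a, b, center = cline_model(latitudes, delta, frac)
    return expit(a + b * (np.asarray(latitudes, dtype=float) - center))


def _draw_exact(rng: np.random.Generator, p: np.ndarray, m: int) -> np.ndarray:
    """Boolean carrier vector with exactly m carriers, approximately Bernoulli(p).

    Bernoulli draws are repaired to the exact count by uniformly promoting or
    demoting random individuals; the repair is O(sqrt(n)) so the expected
    latitude gap of the draw is essentially preserved.
    """
    z = rng.random(p.size) < p
    diff = int(z.sum()) - m
    while diff > 0:
        z[rng.choice(np.flatnonzero(z))] = False
        diff -= 1
    while diff < 0:
        z[rng.choice(np.flatnonzero(~z))] = True
        diff += 1
    return z


# ---------------------------------------------------------------------------
# panel generation


def _scale_counts(counts: tuple[int, ...], n: int) -> list[int]:
    total = sum(counts)
    if total == n:
        return list(counts)
    scaled = [max(1, round(c * n / total)) for c in counts]
    scaled[0] += n - sum(scaled)
    return scaled


def _nonconservative_pair(rng: np.random.Generator) -> tuple[str, str]:
    aas = list(DEFAULT_GROUPING)
    while True:
        a, b = rng.choice(aas, size=2, replace=False)
        if DEFAULT_GROUPING[a] != DEFAULT_GROUPING[b]:
            return str(a), str(b)


def _conservative_pair(rng: np.random.Generator) -> tuple[str, str]:
    groups: dict[str, list[str]] = {}
    for aa, g in DEFAULT_GROUPING.items():
        groups.setdefault(g, []).append(aa)
    g = rng.choice([g for g, aas in groups.items() if len(aas) >= 2])
    a, b = rng.choice(groups[str(g)], size=2, replace=False)
    return str(a), str(b)


def generate_panel(config: PanelConfig) -> Panel:
    """Generate accession metadata, annotated variants, genotypes and truth.

    Deterministic under ``config.seed``: two calls with the same config return
    byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_accessions
    states = list(config.states)
    north_most = max(s.north for s in states)
    south_most = min(s.south for s in states)

    # --- E-genotype classes and their adaptation bands ---------------------
    # Maturity-group structure: the E genotype places a line in a latitude
    # band, so class is drawn first and latitude conditional on class.
    e1, e2 = config.major_loci
    c1, c2, c3, c4 = _scale_counts(config.e_class_counts, n)
    # band means: stratum center is configured; the e1-as/e2 band sits the
    # planted E2 effect above it; the old-E1 band sits the planted E1 effect
    # below the e1-as carrier mean
    mu_stratum = config.class_band_center
    mu_e1as_e2 = mu_stratum + e2.delta
    mu_e1as = (c1 * mu_stratum + c2 * mu_e1as_e2) / (c1 + c2)
    mu_e1 = mu_e1as - e1.delta
    sd_stratum, sd_north, sd_south = config.class_latitude_sd
    class_of = np.repeat(np.arange(4), [c1, c2, c3, c4])
    rng.shuffle(class_of)
    mu = np.array([mu_stratum, mu_e1as_e2, mu_e1, mu_e1])[class_of]
    sd = np.array([sd_stratum, sd_north, sd_south, sd_south])[class_of]
    true_lat = np.clip(
        rng.normal(mu, sd), south_most + 0.05, north_most - 0.05
    )
    is_e1as = class_of < 2
    is_e2 = (class_of == 1) | (class_of == 3)

    # --- state of origin: any state whose span covers the line's latitude ---
    covering = [
        [si for si, s in enumerate(states) if s.south <= l <= s.north]
        for l in true_lat
    ]
    state_idx = np.array([c[rng.integers(len(c))] for c in covering])
    # programs need >= 2 lines; move singletons to another covering state
    for si in range(len(states)):
        members = np.flatnonzero(state_idx == si)
        if len(members) == 1:
            i = members[0]
            alts = [sj for sj in covering[i] if sj != si and (state_idx == sj).sum() > 0]
            if alts:
                state_idx[i] = alts[int(rng.integers(len(alts)))]

    # RM is affine in latitude (earlier maturity farther north) plus noise
    rm = 8.0 * (north_most - true_lat) / (north_most - south_most)
    rm = rm + rng.normal(0.0, config.maturity_noise_sd, size=n)
    has_rm = rng.random(n) < config.maturity_available_frac

    meta = pd.DataFrame(
        {
            "state": [states[si].name for si in state_idx],
            "program": [f"prog_{states[si].name}" for si in state_idx],
            "maturity_score": np.where(has_rm, np.round(rm, 2), np.nan),
            "score_kind": np.where(has_rm, "RM", ""),
            "true_latitude": np.round(true_lat, 6),
        },
        index=pd.Index([f"EL{i+1:04d}" for i in range(n)], name="accession"),
    )
    meta = assign_latitudes(meta, StateLatitudes(states))
    lat = meta["LATITUDE"].to_numpy(float)

    variants: list[AnnotatedVariant] = []
    geno: dict[str, np.ndarray] = {}
    hom = 1 if config.heterozygotes else 2

    for locus, gene, carriers in (
        (e1, "E1", is_e1as),
        (e2, "E2", is_e2),
    ):
        chrom, pos = locus.site.split(":")
        variants.append(
            AnnotatedVariant(
                chrom=chrom, pos=int(pos), ref="C", alt="G", gene_id=gene,
                effect_class=locus.effect_class,
                aa_ref=locus.aa_ref, aa_alt=locus.aa_alt, aa_pos=locus.aa_pos,
            )
        )
        geno[locus.site] = np.where(carriers, hom, 0)

    # --- minor genes -------------------------------------------------------
    deltas = config.all_deltas
    truth_rows = []
    lo, hi = config.carrier_freq_range
    # minor-gene disparities are planted within the analysis stratum, where
    # the scan measures them; the fitted cline extends over the whole panel
    stratum_lat = lat[class_of == 0]
    for gi, gene in enumerate(config.gene_ids):
        delta = deltas[gene]
        frac = float(rng.uniform(lo, hi))
        a, b, center = cline_model(stratum_lat, delta, frac)
        p = expit(a + b * (lat - center))
        carriers = rng.random(n) < p

        chrom = f"{(gi % 20) + 1:02d}"
        base = 1_000_000 + gi * 10_000
        n_qual = int(rng.integers(1, 3))
        sites = []
        aa_positions_used: set[int] = set()
        for j in range(n_qual):
            eff = QUALIFYING_CLASS_POOL[int(rng.integers(len(QUALIFYING_CLASS_POOL)))]
            aa_ref = aa_alt = aa_pos = None
            if eff is EffectClass.MISSENSE:
                aa_ref, aa_alt = _nonconservative_pair(rng)
            if eff in (EffectClass.MISSENSE,):
                while True:
                    aa_pos = int(rng.integers(15, config.alignment_length - 14))
                    if aa_pos not in aa_positions_used:
                        aa_positions_used.add(aa_pos)
                        break
            site_pos = base + j * 100
            v = AnnotatedVariant(
                chrom=chrom, pos=site_pos, ref="A", alt="T", gene_id=gene,
                effect_class=eff, aa_ref=aa_ref, aa_alt=aa_alt, aa_pos=aa_pos,
            )
            variants.append(v)
            geno[v.site] = np.where(carriers, hom, 0)
            sites.append(v.site)
        # decoy variant that must not qualify (synonymous or conservative missense)
        if rng.random() < 0.5:
            eff = DECOY_CLASS_POOL[int(rng.integers(len(DECOY_CLASS_POOL)))]
            aa_ref = aa_alt = aa_pos = None
            if eff is EffectClass.MISSENSE:
                aa_ref, aa_alt = _conservative_pair(rng)
                aa_pos = int(rng.integers(15, config.alignment_length - 14))
            v = AnnotatedVariant(
                chrom=chrom, pos=base + 900, ref="G", alt="C", gene_id=gene,
                effect_class=eff, aa_ref=aa_ref, aa_alt=aa_alt, aa_pos=aa_pos,
            )
            variants.append(v)
            geno[v.site] = np.where(rng.random(n) < 0.3, hom, 0)

        # conservation ground truth for this gene's alignment
        n_cons = int(rng.integers(8, 20))
        cons_set = set(
            int(c)
            for c in rng.choice(
                np.arange(1, config.alignment_length + 1), size=n_cons, replace=False
            )
        )
        # half the time a missense variant falls inside a conserved domain,
        # mirroring the mixture seen among real candidate-gene variants
        for ap in aa_positions_used:
            if rng.random() < 0.5:
                cons_set.add(ap)
            else:
                cons_set.discard(ap)
        cons_cols = sorted(cons_set)
        truth_rows.append(
            {
                "gene": gene,
                "delta": delta,
                "carrier_frac": frac,
                "n_carriers": int(carriers.sum()),
                "sites": ";".join(sites),
                "conserved_columns": ";".join(map(str, cons_cols)),
            }
        )

    genotypes = pd.DataFrame(geno, index=meta.index)
    truth = pd.DataFrame(truth_rows)
    return Panel(config=config, metadata=meta, variants=variants,
                 genotypes=genotypes, truth=truth)


# ---------------------------------------------------------------------------
# synthetic ortholog alignments


def generate_ortholog_alignment(
    gene: str,
    n_genera: int,
    conserved_columns,
    concentration: float = 99.0,
    seed: int = 0,
    length: int = 80,
    modal_residues: dict[int, str] | None = None,
    reference_overrides: dict[int, str] | None = None,
) -> list[tuple[str, str]]:
    """Aligned peptide set, one sequence per synthetic genus.

    At conserved columns (1-based) a single residue reaches frequency >= 0.95
    (the deviant fraction is ``min(1/(1+concentration), 0.05)``); elsewhere
    residues are drawn near-uniformly over the 20 standard amino acids. The
    first record is the reference (query) sequence; ``reference_overrides``
    forces particular residues onto it, e.g. to place the non-conserved
    reference state of a variant at its column.
    """
    if n_genera < 2:
        raise ValueError("need at least two genera")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    conserved = set(int(c) for c in conserved_columns)
    bad = [c for c in conserved if not 1 <= c <= length]
    if bad:
        raise ValueError(f"conserved column(s) {bad} outside 1..{length}")
    rng = np.random.default_rng(seed)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    cols = np.empty((length, n_genera), dtype="<U1")
    deviant_frac = min(1.0 / (1.0 + concentration), 0.05)
    n_dev = int(np.floor(n_genera * deviant_frac))
    for col in range(1, length + 1):
        if col in conserved:
            modal = (
                modal_residues[col]
                if modal_residues and col in modal_residues
                else str(rng.choice(aas))
            )
            column = np.full(n_genera, modal, dtype="<U1")
            if n_dev:
                rows = rng.choice(n_genera, size=n_dev, replace=False)
                others = aas[aas != modal]
                column[rows] = rng.choice(others, size=n_dev)
            cols[col - 1] = column
        else:
            cols[col - 1] = rng.choice(aas, size=n_genera)
    seqs = ["".join(cols[:, i]) for i in range(n_genera)]
    if reference_overrides:
        ref = list(seqs[0])
        for col, res in reference_overrides.items():
            ref[col - 1] = res
        seqs[0] = "".join(ref)
    names = [f"Glycine|{gene}"] + [f"Genus{i:03d}|{gene}" for i in range(1, n_genera)]
    return list(zip(names, seqs))


def write_panel_alignments(panel: Panel, outdir) -> dict[str, list[int]]:
    """Write one aligned FASTA per minor gene, consistent with its variants.

    Missense variant columns are forced conserved; the modal residue is the
    alternate or the reference residue with equal probability (recorded in the
    returned mapping via the truth table's conserved columns), and the
    reference row always shows the annotated reference residue.
    """
    cfg = panel.config
    out = lio.ensure_dir(outdir)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11A]))
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in panel.variants:
        by_gene.setdefault(v.gene_id, []).append(v)
    written: dict[str, list[int]] = {}
    for _, row in panel.truth.iterrows():
        gene = row["gene"]
        cons = [int(c) for c in str(row["conserved_columns"]).split(";") if c]
        modal: dict[int, str] = {}
        ref_over: dict[int, str] = {}
        for v in by_gene.get(gene, []):
            if v.aa_pos is None or v.aa_ref is None or v.aa_alt in (None, "*"):
                continue
            ref_over[v.aa_pos] = v.aa_ref
            if v.aa_pos in cons:
                modal[v.aa_pos] = v.aa_alt if rng.random() < 0.5 else v.aa_ref
        records = generate_ortholog_alignment(
            gene,
            cfg.alignment_n_genera,
            cons,
            concentration=cfg.alignment_concentration,
            seed=int(
                np.random.SeedSequence(
                    [cfg.seed, zlib.crc32(gene.encode())]
                ).generate_state(1)[0]
                % 2**31
            ),
            length=cfg.alignment_length,
            modal_residues=modal,
            reference_overrides=ref_over,
        )
        lio.write_fasta(out / f"{gene}.fasta", records)
        written[gene] = cons
    return written
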