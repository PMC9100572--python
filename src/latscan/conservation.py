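"""Amino-acid conservation windows around allele-defining variants.

Given a multiple sequence alignment of ortholog peptides (one representative
per genus, the highest-percent-identity hit), the alignment is clipped to ten
columns either side of each variant position and per-column residue
frequencies and information content computed, following the sequence-logo
convention:

    IC = log2(20) - H,   H = -sum_a p_a log2 p_a    (gaps excluded)

A variant column is called a conserved site when its IC and modal-residue
frequency both clear configurable thresholds (defaults 2.0 bits and 0.8);
the reference and alternate residues are then classified by whether they
match the conserved (modal) residue, so one can tell whether the reference
line or the alternate allele carries the conserved state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")
_RES_INDEX = {a: i for i, a in enumerate(RESIDUES)}
GAP = "-"
MAX_IC = math.log2(20)

IC_THRESHOLD_DEFAULT = 2.0     # bits
MODAL_FREQ_DEFAULT = 0.8
MAX_GAP_FRACTION = 0.5         # columns gappier than this are never conserved
FLANK_DEFAULT = 10             # columns either side of the variant


@dataclass(frozen=True)
class OrthologHit:
    """One BLASTP-style ortholog hit: genus, id, percent identity, peptide."""

    genus: str
    seq_id: str
    percent_identity: float
    sequence: str

    def __post_init__(self) -> None:
        if not self.genus:
            raise ValueError("genus must be non-empty")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent identity {self.percent_identity} outside [0, 100]")


def select_genus_representatives(hits: list[OrthologHit]) -> list[OrthologHit]:
    """One hit per genus: the highest percent identity, ties broken by
    lexicographically smallest sequence id; output sorted by genus."""
    best: dict[str, OrthologHit] = {}
    for h in hits:
        cur = best.get(h.genus)
        if (
            cur is None
            or h.percent_identity > cur.percent_identity
            or (h.percent_identity == cur.percent_identity and h.seq_id < cur.seq_id)
        ):
            best[h.genus] = h
    return [best[g] for g in sorted(best)]


def read_alignment(path) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA: (ids, equal-length gapped sequences)."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError(f"{path}: sequences are not aligned (unequal lengths)")
    return ids, seqs


def map_position_to_column(reference_row: str, aa_pos: int) -> int:
    """1-based alignment column holding the ``aa_pos``-th non-gap residue of
    the reference row."""
    if aa_pos < 1:
        raise ValueError("aa_pos is 1-based")
    count = 0
    for col, ch in enumerate(reference_row, start=1):
        if ch != GAP:
            count += 1
            if count == aa_pos:
                return col
    raise ValueError(
        f"aa_pos {aa_pos} beyond reference length ({count} non-gap residues)"
    )


def column_information(column: str) -> tuple[np.ndarray, float, float]:
    """Residue frequency vector (gap-excluded), information content in bits,
    and gap fraction for one alignment column."""
    n_gap = column.count(GAP)
    gap_frac = n_gap / len(column)
    residues = [c for c in column if c != GAP]
    if len(residues) < 2:
        raise ValueError("column has fewer than two non-gap residues")
    freqs = np.zeros(len(RESIDUES))
    for c in residues:
        try:
            freqs[_RES_INDEX[c]] += 1
        except KeyError:
            raise ValueError(f"non-standard residue {c!r} in column") from None
    freqs /= freqs.sum()
    nz = freqs[freqs > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return freqs, MAX_IC - entropy, gap_frac


@dataclass
class ConservationWindow:
    """Clipped alignment window around one variant position."""

    gene_id: str
    aa_pos: int                  # 1-based residue index in the reference peptide
    variant_column: int          # 1-based alignment column
    window_start: int            # 1-based, inclusive
    window_end: int
    frequencies: np.ndarray      # (n_columns, 20)
    information: np.ndarray      # bits per column
    gap_fractions: np.ndarray
    n_sequences: int
    truncated_left: bool = False
    truncated_right: bool = False

    @property
    def n_columns(self) -> int:
        return self.window_end - self.window_start + 1

    def column_offset(self, column: int) -> int:
        return column - self.window_start

    def logo_matrix(self) -> pd.DataFrame:
        """Letter heights (p * IC) per column, for external logo rendering."""
        heights = self.frequencies * self.information[:, None]
        return pd.DataFrame(
            heights,
            index=pd.RangeIndex(self.window_start, self.window_end + 1, name="column"),
            columns=list(RESIDUES),
        )


def clip_window(
    seqs: list[str],
    column: int,
    flank: int = FLANK_DEFAULT,
    gene_id: str = "gene",
    aa_pos: int | None = None,
) -> ConservationWindow:
    """Clip the alignment to ``flank`` columns either side of ``column``
    (1-based), truncating at alignment ends, and compute per-column
    frequencies and information content."""
    L = len(seqs[0])
    if not 1 <= column <= L:
        raise ValueError(f"column {column} outside alignment of length {L}")
    start = max(1, column - flank)
    end = min(L, column + flank)
    freqs, ics, gaps = [], [], []
    for col in range(start, end + 1):
        col_str = "".join(s[col - 1] for s in seqs)
        try:
            f, ic, gf = column_information(col_str)
        except ValueError:
            # all-gap (or near) column: flagged undefined, excluded from calls
            f, ic, gf = np.zeros(len(RESIDUES)), np.nan, col_str.count(GAP) / len(col_str)
        freqs.append(f)
        ics.append(ic)
        gaps.append(gf)
    return ConservationWindow(
        gene_id=gene_id,
        aa_pos=aa_pos if aa_pos is not None else column,
        variant_column=column,
        window_start=start,
        window_end=end,
        frequencies=np.asarray(freqs),
        information=np.asarray(ics),
        gap_fractions=np.asarray(gaps),
        n_sequences=len(seqs),
        truncated_left=(column - flank < 1),
        truncated_right=(column + flank > L),
    )


@dataclass(frozen=True)
class VariantConservation:
    """Conservation call for one variant column."""

    gene_id: str
    aa_pos: int
    variant_column: int
    information: float
    modal_residue: str | None
    modal_frequency: float
    conserved_site: bool
    conserved_residue: str | None
    ref_is_conserved: bool
    alt_is_conserved: bool


def classify_variant_conservation(
    window: ConservationWindow,
    aa_ref: str,
    aa_alt: str,
    ic_threshold: float = IC_THRESHOLD_DEFAULT,
    modal_freq_threshold: float = MODAL_FREQ_DEFAULT,
    reference_row: str | None = None,
) -> VariantConservation:
    """Is the variant column conserved, and which residue is the conserved one?

    A column is a conserved site iff its IC >= ``ic_threshold`` and its modal
    residue frequency >= ``modal_freq_threshold`` (and its gap fraction is at
    most 0.5). When ``reference_row`` is supplied, a mismatch between
    ``aa_ref`` and the reference row's residue at the variant column is warned
    about (annotation/alignment inconsistency) but classification proceeds.
    """
    i = window.column_offset(window.variant_column)
    ic = float(window.information[i])
    f = window.frequencies[i]
    gap_frac = float(window.gap_fractions[i])
    if reference_row is not None:
        obs = reference_row[window.variant_column - 1]
        if obs != aa_ref:
            log.warning(
                "%s: reference row has %r at column %d but annotation says aa_ref=%r",
                window.gene_id, obs, window.variant_column, aa_ref,
            )
    if np.isnan(ic) or f.sum() == 0:
        return VariantConservation(
            window.gene_id, window.aa_pos, window.variant_column,
            float("nan"), None, 0.0, False, None, False, False,
        )
    modal_i = int(f.argmax())
    modal_res = RESIDUES[modal_i]
    modal_freq = float(f[modal_i])
    conserved = (
        ic >= ic_threshold
        and modal_freq >= modal_freq_threshold
        and gap_frac <= MAX_GAP_FRACTION
    )
    return VariantConservation(
        gene_id=window.gene_id,
        aa_pos=window.aa_pos,
        variant_column=window.variant_column,
        information=ic,
        modal_residue=modal_res,
        modal_frequency=modal_freq,
        conserved_site=conserved,
        conserved_residue=modal_res if conserved else None,
        ref_is_conserved=conserved and aa_ref == modal_res,
        alt_is_conserved=conserved and aa_alt == modal_res,
    )


def assess_variant(
    alignment_path,
    aa_pos: int,
    aa_ref: str,
    aa_alt: str,
    gene_id: str = "gene",
    reference_id: str | None = None,
    flank: int = FLANK_DEFAULT,
    ic_threshold: float = IC_THRESHOLD_DEFAULT,
    modal_freq_threshold: float = MODAL_FREQ_DEFAULT,
) -> tuple[ConservationWindow, VariantConservation]:
    """End-to-end conservation assessment of one variant from an aligned FASTA.

    The reference row is the record whose id equals ``reference_id`` (default:
    first record, the convention of the synthetic alignments).
    """
    ids, seqs = read_alignment(alignment_path)
    ref_i = 0 if reference_id is None else ids.index(reference_id)
    ref_row = seqs[ref_i]
    column = map_position_to_column(ref_row, aa_pos)
    window = clip_window(seqs, column, flank=flank, gene_id=gene_id, aa_pos=aa_pos)
    call = classify_variant_conservation(
        window, aa_ref, aa_alt,
        ic_threshold=ic_threshold,
        modal_freq_threshold=modal_freq_threshold,
        reference_row=ref_row,
    )
    return window, call
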