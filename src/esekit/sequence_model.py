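"""Exons, introns, ortholog alignments, SNPs and site classification.

The evolutionary analyses in this package work on internal protein-coding
exons with their flanking intron sequence, human/mouse orthologous exon
pairs aligned at codon level, and per-exon SNP positions.  This module
defines those containers plus the shared low-level rules:

* ESE masking -- a position is "ESE" iff it is covered by at least one
  occurrence of any motif of a given catalogue (human sequence only);
* four-fold degenerate site selection -- third positions of codons whose
  four-fold family is identical in both species;
* the ortholog filtering pipeline (one2one, ATG/stop/frame sanity, equal
  exon counts, <=5% exon length difference, internal exons only, trimming
  to codon frame);
* back-translation of a peptide alignment onto the source CDSs;
* the merged intron|exon|intron composite layout used for positional
  density profiles.

Coordinates are 0-based half-open internally; distances from a splice site
count the first exonic (or intronic) base as distance 1.  All sequences are
sense-strand by contract: minus-strand genes must be reverse-complemented
upstream, so no strand logic exists here.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .motif_sets import HexamerSet

logger = logging.getLogger(__name__)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)      # {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(sorted(_STANDARD_TABLE.forward_table))  # 61 codons

#: two-base prefixes of the eight four-fold degenerate codon families
FOURFOLD_PREFIXES = frozenset(
    prefix
    for prefix in {c[:2] for c in SENSE_CODONS}
    if all(
        prefix + b in _STANDARD_TABLE.forward_table
        and _STANDARD_TABLE.forward_table[prefix + b]
        == _STANDARD_TABLE.forward_table[prefix + "A"]
        for b in "ACGT"
    )
)

GAP_CODON = "---"


class ProfileSkip(ValueError):
    """Raised when an exon does not qualify for the composite profile."""


@dataclass
class ExonRecord:
    """An internal exon with flanking intron sequence and annotations.

    ``upstream_intron_seq`` / ``downstream_intron_seq`` hold the intronic
    sequence immediately adjacent to the exon (at least 100 nt when
    available); the ``*_len`` fields carry the full intron lengths, which
    may exceed the stored sequence.  ``splice5_score`` / ``splice3_score``
    are externally computed splice-site strengths (e.g. maximum-entropy
    scores); ``inclusion`` and ``conservation`` are optional class labels
    (``alternative``/``constitutive``, ``conserved``/``non_conserved``).
    """

    gene_id: str
    exon_index: int
    exon_seq: str
    upstream_intron_seq: str = ""
    downstream_intron_seq: str = ""
    upstream_intron_len: Optional[int] = None
    downstream_intron_len: Optional[int] = None
    splice5_score: Optional[float] = None
    splice3_score: Optional[float] = None
    inclusion: Optional[str] = None
    conservation: Optional[str] = None

    def __post_init__(self) -> None:
        self.exon_seq = self.exon_seq.upper()
        self.upstream_intron_seq = self.upstream_intron_seq.upper()
        self.downstream_intron_seq = self.downstream_intron_seq.upper()
        if len(self.exon_seq) < 1:
            raise ValueError(f"{self.exon_id}: empty exon sequence")
        for s in (self.exon_seq, self.upstream_intron_seq, self.downstream_intron_seq):
            if set(s) - set("ACGTN"):
                raise ValueError(f"{self.exon_id}: non-ACGTN characters in sequence")
        if self.upstream_intron_len is None:
            self.upstream_intron_len = len(self.upstream_intron_seq)
        if self.downstream_intron_len is None:
            self.downstream_intron_len = len(self.downstream_intron_seq)
        if self.upstream_intron_len < len(self.upstream_intron_seq):
            raise ValueError(f"{self.exon_id}: intron length below stored sequence")
        if self.downstream_intron_len < len(self.downstream_intron_seq):
            raise ValueError(f"{self.exon_id}: intron length below stored sequence")

    @property
    def exon_id(self) -> str:
        return f"{self.gene_id}:{self.exon_index}"

    def __len__(self) -> int:
        return len(self.exon_seq)


@dataclass
class OrthologExonPair:
    """A human/mouse internal exon aligned at codon level.

    Both rows are tuples of 3-character codons; gaps are ``---``.  The
    human row with gaps removed is the human exon sequence in frame.
    """

    gene_id: str
    exon_index: int
    human_codons: tuple
    mouse_codons: tuple

    def __post_init__(self) -> None:
        self.human_codons = tuple(c.upper() for c in self.human_codons)
        self.mouse_codons = tuple(c.upper() for c in self.mouse_codons)
        if len(self.human_codons) != len(self.mouse_codons):
            raise ValueError(f"{self.gene_id}:{self.exon_index}: unequal aligned length")
        for row in (self.human_codons, self.mouse_codons):
            for c in row:
                if len(c) != 3:
                    raise ValueError(f"codon {c!r} is not a triplet")

    @property
    def n_codons(self) -> int:
        return len(self.human_codons)

    def human_sequence(self) -> str:
        """Ungapped human exon sequence."""
        return "".join(c for c in self.human_codons if c != GAP_CODON)


class SNPTable:
    """Per-exon 0-based offsets of SNP-bearing positions.

    Multiple SNP records at one position collapse to a single site: the
    analyses ask about the proportion of sites with one or more SNPs, not
    SNP counts.
    """

    def __init__(self, positions: Optional[dict] = None) -> None:
        self._positions: dict = {}
        if positions:
            for exon_id, offsets in positions.items():
                for off in offsets:
                    self.add(exon_id, off)

    def add(self, exon_id: str, offset: int) -> None:
        if offset < 0:
            raise ValueError(f"negative SNP offset {offset} in {exon_id}")
        self._positions.setdefault(exon_id, set()).add(int(offset))

    def get(self, exon_id: str) -> frozenset:
        return frozenset(self._positions.get(exon_id, ()))

    def __len__(self) -> int:
        return sum(len(v) for v in self._positions.values())

    def exon_ids(self) -> list:
        return sorted(self._positions)


def mask_ese_positions(seq: str, hexamers: HexamerSet) -> np.ndarray:
    """Boolean per-position ESE coverage of ``seq``.

    Position i is True iff it lies within at least one occurrence of any
    catalogue motif (all six positions of a match are flagged).  Ambiguous
    bases (N) never match.  An empty catalogue yields an all-False mask.
    """
    seq = seq.upper()
    mask = np.zeros(len(seq), dtype=bool)
    motifs = hexamers.motifs
    if not motifs:
        return mask
    for i in range(len(seq) - 5):
        if seq[i:i + 6] in motifs:
            mask[i:i + 6] = True
    return mask


def fourfold_sites(pair: OrthologExonPair) -> list:
    """Alignment offsets of analysable four-fold degenerate third sites.

    A third position qualifies when both aligned codons are ungapped, both
    belong to a four-fold degenerate family, and the family (the first two
    codon bases) is the same in both species -- so any third-base
    difference is synonymous in both.
    Offsets are 0-based into the aligned nucleotide sequence.
    """
    sites = []
    for j, (h, m) in enumerate(zip(pair.human_codons, pair.mouse_codons)):
        if h == GAP_CODON or m == GAP_CODON:
            continue
        if h[:2] != m[:2]:
            continue
        if h[:2] in FOURFOLD_PREFIXES and set(h + m) <= set("ACGT"):
            sites.append(3 * j + 2)
    return sites


def backtranslate_alignment(
    peptide_human: str,
    peptide_mouse: str,
    cds_human: str,
    cds_mouse: str,
    gene_id: str = "?",
    exon_index: int = 0,
) -> OrthologExonPair:
    """Reconstruct a codon alignment from a peptide alignment and the CDSs.

    Each aligned residue is replaced by its source codon and each peptide
    gap by ``---``.  The ungapped peptides must translate exactly from the
    CDSs under the standard code; a mismatch raises a ValueError naming the
    offending residue.
    """
    if len(peptide_human) != len(peptide_mouse):
        raise ValueError("aligned peptide rows differ in length")

    def codon_rows(peptide: str, cds: str, species: str) -> list:
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError(f"{species} CDS length is not a multiple of 3")
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        residues = [aa for aa in peptide if aa != "-"]
        if len(residues) != len(codons):
            raise ValueError(
                f"{species}: {len(residues)} aligned residues but {len(codons)} codons"
            )
        out, k = [], 0
        for aa in peptide:
            if aa == "-":
                out.append(GAP_CODON)
                continue
            codon = codons[k]
            translated = str(Seq(codon).translate())
            if translated != aa.upper():
                raise ValueError(
                    f"{species} residue {k + 1}: peptide has {aa!r} but codon "
                    f"{codon} translates to {translated!r}"
                )
            out.append(codon)
            k += 1
        return out

    return OrthologExonPair(
        gene_id,
        exon_index,
        tuple(codon_rows(peptide_human, cds_human, "human")),
        tuple(codon_rows(peptide_mouse, cds_mouse, "mouse")),
    )


@dataclass
class GenePair:
    """A human/mouse ortholog gene pair prior to filtering.

    ``*_exon_lengths`` partition each CDS into consecutive exonic chunks
    (coding parts only), so ``sum(lengths) == len(cds)``.
    """

    gene_id: str
    human_cds: str
    mouse_cds: str
    human_exon_lengths: tuple
    mouse_exon_lengths: tuple
    ortholog_type: str = "one2one"

    def __post_init__(self) -> None:
        self.human_cds = self.human_cds.upper()
        self.mouse_cds = self.mouse_cds.upper()
        if sum(self.human_exon_lengths) != len(self.human_cds):
            raise ValueError(f"{self.gene_id}: human exon lengths do not tile the CDS")
        if sum(self.mouse_exon_lengths) != len(self.mouse_cds):
            raise ValueError(f"{self.gene_id}: mouse exon lengths do not tile the CDS")


def _cds_ok(cds: str) -> Optional[str]:
    """Return a rejection reason for a CDS, or None if it passes."""
    if set(cds) - set("ACGT"):
        return "nonstandard_base"
    if len(cds) % 3:
        return "not_multiple_of_3"
    if not cds.startswith("ATG"):
        return "no_start_atg"
    if cds[-3:] not in STOP_CODONS:
        return "no_stop"
    internal = {cds[i:i + 3] for i in range(0, len(cds) - 3, 3)}
    if internal & STOP_CODONS:
        return "internal_stop"
    return None


def _trim_to_frame(start: int, end: int) -> tuple:
    """Trim a CDS interval inward to codon boundaries (0-based half-open)."""
    t_start = start + (-start) % 3
    t_end = end - end % 3
    return t_start, t_end


def filter_ortholog_exons(gene_pairs: Sequence[GenePair]) -> tuple:
    """Apply the ortholog-exon filtering pipeline.

    Filters, in order: one2one orthologs only; duplicated gene ids resolved
    to the longest human CDS (ties by longest mouse CDS); CDS sanity (ATG
    start, stop end, length % 3 == 0, no internal stops, ACGT only, both
    species); equal exon counts; any internal orthologous exon pair
    differing by more than 5% of the human exon length rejects the gene;
    first and last exons dropped; exon boundaries trimmed inward to codon
    frame.  Exons whose trimmed human and mouse spans differ in codon count
    are dropped individually (they would need a peptide alignment, supplied
    separately through :func:`backtranslate_alignment`).

    Returns ``(pairs, tally)`` where ``tally`` counts rejections by reason.
    """
    tally: Counter = Counter()

    kept = []
    for gp in gene_pairs:
        if gp.ortholog_type != "one2one":
            tally["not_one2one"] += 1
        else:
            kept.append(gp)

    by_gene: dict = {}
    for gp in kept:
        prev = by_gene.get(gp.gene_id)
        if prev is None:
            by_gene[gp.gene_id] = gp
        else:
            tally["duplicate_gene"] += 1
            key = (len(gp.human_cds), len(gp.mouse_cds))
            prev_key = (len(prev.human_cds), len(prev.mouse_cds))
            if key > prev_key:
                by_gene[gp.gene_id] = gp

    pairs = []
    for gene_id in sorted(by_gene):
        gp = by_gene[gene_id]
        reason = _cds_ok(gp.human_cds) or _cds_ok(gp.mouse_cds)
        if reason:
            tally[reason] += 1
            continue
        if len(gp.human_exon_lengths) != len(gp.mouse_exon_lengths):
            tally["exon_count_mismatch"] += 1
            continue
        n_exons = len(gp.human_exon_lengths)
        if n_exons < 3:
            tally["no_internal_exons"] += 1
            continue
        if any(
            abs(h - m) > 0.05 * h
            for h, m in zip(gp.human_exon_lengths[1:-1], gp.mouse_exon_lengths[1:-1])
        ):
            tally["exon_length_gt_5pct"] += 1
            continue

        h_starts = np.concatenate([[0], np.cumsum(gp.human_exon_lengths)])
        m_starts = np.concatenate([[0], np.cumsum(gp.mouse_exon_lengths)])
        for i in range(1, n_exons - 1):
            hs, he = _trim_to_frame(int(h_starts[i]), int(h_starts[i + 1]))
            ms, me = _trim_to_frame(int(m_starts[i]), int(m_starts[i + 1]))
            if he - hs < 3 or me - ms < 3:
                tally["exon_too_short_after_trim"] += 1
                continue
            if he - hs != me - ms:
                tally["unaligned_codon_count"] += 1
                continue
            h_codons = tuple(
                gp.human_cds[j:j + 3] for j in range(hs, he, 3)
            )
            m_codons = tuple(
                gp.mouse_cds[j:j + 3] for j in range(ms, me, 3)
            )
            pairs.append(OrthologExonPair(gene_id, i, h_codons, m_codons))
    return pairs, dict(tally)


@dataclass(frozen=True)
class CompositeProfile:
    """The merged intron|exon|intron layout of one exon.

    ``sequence`` is the composite string; ``region`` labels every composite
    position (``intron_5``, ``exon_5_flank``, ``exon_core``,
    ``exon_3_flank``, ``intron_3``); ``distance`` is the 1-based distance
    from the nearest splice site (into the exon for exonic positions, into
    the intron for intronic ones); ``source_offsets`` indexes each
    composite position into the full concatenation
    ``upstream_flank + exon + downstream_flank`` so that masks computed on
    the continuous sequence (motifs may span region boundaries) can be
    sampled at composite coordinates.
    """

    sequence: str
    region: tuple
    distance: np.ndarray
    source_offsets: np.ndarray
    full_sequence: str


def merged_profile_sequence(
    exon: ExonRecord, flank_nt: int = 100, end_window: int = 50, core_window: int = 100
) -> CompositeProfile:
    """Build the composite intron-exon-intron profile sequence for one exon.

    The composite holds the last ``flank_nt`` of the upstream intron, the
    exon contribution, and the first ``flank_nt`` of the downstream intron.
    The exon contributes its first and last ``end_window`` nt, plus the
    central ``core_window`` nt when the exon exceeds
    ``2*end_window + core_window`` (200 nt with defaults).  For exons of
    51-100 nt the two end windows overlap; overlapping positions are
    emitted once, so the whole exon is used without double counting.

    Raises :class:`ProfileSkip` when the exon is <= ``end_window`` nt or
    either intron flank is shorter than ``flank_nt``.
    """
    L = len(exon.exon_seq)
    if L <= end_window:
        raise ProfileSkip(f"{exon.exon_id}: exon of {L} nt (need > {end_window})")
    if (
        len(exon.upstream_intron_seq) < flank_nt
        or len(exon.downstream_intron_seq) < flank_nt
    ):
        raise ProfileSkip(f"{exon.exon_id}: insufficient flanking intron sequence")

    up = exon.upstream_intron_seq[-flank_nt:]
    down = exon.downstream_intron_seq[:flank_nt]
    full = up + exon.exon_seq + down

    offsets: list = []
    regions: list = []
    dists: list = []

    for j in range(flank_nt):
        offsets.append(j)
        regions.append("intron_5")
        dists.append(flank_nt - j)

    half = (L + 1) // 2  # positions 0..half-1 belong to the 5' half

    def exon_pos(p: int, region: str) -> None:
        offsets.append(flank_nt + p)
        regions.append(region)
        dists.append(p + 1 if p < half else L - p)

    if L > 2 * end_window + core_window:
        for p in range(end_window):
            exon_pos(p, "exon_5_flank")
        core_start = (L - core_window) // 2
        for p in range(core_start, core_start + core_window):
            exon_pos(p, "exon_core")
        for p in range(L - end_window, L):
            exon_pos(p, "exon_3_flank")
    else:
        seen_cut = min(end_window, L - end_window)  # overlap handling
        for p in range(seen_cut):
            exon_pos(p, "exon_5_flank")
        for p in range(max(seen_cut, L - end_window), L):
            exon_pos(p, "exon_3_flank")
        # positions between the windows (101-200 nt exons) are omitted,
        # matching the fixed 100-nt exon contribution of the layout

    for j in range(flank_nt):
        offsets.append(flank_nt + L + j)
        regions.append("intron_3")
        dists.append(j + 1)

    offsets_arr = np.asarray(offsets, dtype=np.intp)
    return CompositeProfile(
        sequence="".join(full[o] for o in offsets),
        region=tuple(regions),
        distance=np.asarray(dists, dtype=np.intp),
        source_offsets=offsets_arr,
        full_sequence=full,
    )
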