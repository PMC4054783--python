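"""Synthetic genomes with controlled ground truth.

Every analysis in the package has a download-free parameter-recovery test
built on this module.  The generator emulates the statistical structure the
analyses assume, with every effect size an explicit dial recorded in the
truth record:

* internal exons (lognormal lengths, median ~130 nt -- the typical human
  internal exon) filled with usage-weighted codons, flanked by 100 nt of
  intronic sequence from a background composition;
* enhancer motifs from a "true pool" stamped into exons at positions drawn
  from a logistic distance-from-boundary curve (plateau near the splice
  sites, floor in the core).  The truth mask is re-derived from the final
  sequence as coverage by pool motifs, so it equals exactly what
  :func:`~esekit.sequence_model.mask_ese_positions` reports for the pool;
* a mouse copy of each exon substituting four-fold degenerate third
  positions at rate ``d`` outside the truth mask and ``d*r`` inside;
* SNPs at per-site rate ``s`` outside the mask and ``s*q`` inside;
* splice-site scores rank-correlated (Gaussian copula) with realised flank
  enhancer density; intron lengths optionally likewise;
* optional distance-dependent synonymous codon choice, for the
  codon-slope analyses;
* exon class labels with a density multiplier for constitutive exons, and
  a genes x tissues expression matrix with negative controls.

Identical spec and seed give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .codon_metrics import CodonUsage
from .motif_sets import DNA_BASES, HexamerSet, all_hexamers
from .sequence_model import (
    FOURFOLD_PREFIXES,
    ExonRecord,
    GenePair,
    OrthologExonPair,
    SENSE_CODONS,
    SNPTable,
    STOP_CODONS,
    mask_ese_positions,
)


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of the Gaussian copula achieving a Spearman target."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic genome; defaults are the study conditions.

    ``pool`` (or ``pool_size``, drawn uniformly from the 4,096 hexamers)
    plays the role of the true enhancer pool; the default size of 850
    matches the capture-recapture estimate of the true pool.  The embedding
    curve gives the per-start stamping probability
    ``floor + (plateau - floor) / (1 + exp((d - midpoint)/scale))`` at
    distance d from the nearer exon end.  ``divergence_rate`` /
    ``ese_rate_multiplier`` and ``snp_rate`` / ``snp_ese_multiplier``
    default to the magnitudes the selection analyses report (a ~15% rate
    deficit; SNP site proportions near 0.036 vs 0.030).
    """

    seed: int
    n_exons: int = 2_000
    exon_len_median: float = 130.0
    exon_len_sigma: float = 0.45
    exon_len_min: int = 60
    exon_len_max: int = 600
    flank_nt: int = 100
    intron_len_median: float = 1_500.0
    intron_len_sigma: float = 1.0
    base_composition: tuple = (0.25, 0.25, 0.25, 0.25)  # A, C, G, T
    pool: Optional[HexamerSet] = None
    pool_size: int = 850
    embed_plateau: float = 0.06
    embed_floor: float = 0.01
    embed_midpoint: float = 50.0
    embed_scale: float = 10.0
    constitutive_embed_multiplier: float = 1.0
    p_alternative: float = 0.3
    p_conserved: float = 0.5
    rho_score_density: float = -0.1
    score_mean: float = 8.0
    score_sd: float = 3.0
    rho_intron_density: float = 0.0
    synonym_gradient: dict = field(default_factory=dict)
    gradient_max_distance: int = 35
    divergence_rate: float = 0.35
    ese_rate_multiplier: float = 0.85
    snp_rate: float = 0.036
    snp_ese_multiplier: float = 0.833

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        comp = np.asarray(self.base_composition, dtype=float)
        if (comp < 0).any() or not math.isclose(comp.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("base composition must be fractions summing to 1")
        for name in ("embed_plateau", "embed_floor"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.embed_plateau * max(1.0, self.constitutive_embed_multiplier) > 1:
            raise ValueError("embedding curve demands probability > 1")
        if self.divergence_rate * max(1.0, self.ese_rate_multiplier) > 1:
            raise ValueError("divergence rates exceed 1")
        if self.snp_rate * max(1.0, self.snp_ese_multiplier) > 1:
            raise ValueError("SNP rates exceed 1")


def gen_hexamer_catalogues(
    pool_size: int,
    set_sizes: Sequence[int],
    seed: Optional[int] = None,
    names: Optional[Sequence[str]] = None,
) -> tuple:
    """Draw catalogues from a true enhancer pool.

    A pool of ``pool_size`` hexamers is drawn uniformly without replacement
    from the 4,096-hexamer universe; each catalogue is then drawn without
    replacement from the pool.  Returns ``(pool, catalogues, truth)`` where
    ``truth`` records pool membership and the realised all-way
    intersection.  ``pool_size = 4096`` reduces to the uniform null.
    """
    if any(n > pool_size for n in set_sizes):
        raise ValueError("catalogue size exceeds the pool")
    rng = np.random.default_rng(seed)
    universe = np.array(all_hexamers())
    pool_idx = rng.choice(len(universe), size=pool_size, replace=False)
    pool_motifs = universe[pool_idx]
    pool = HexamerSet.from_iterable("true_pool", pool_motifs)
    names = names or [f"catalogue_{i}" for i in range(len(set_sizes))]
    catalogues = []
    for name, n in zip(names, set_sizes):
        idx = rng.choice(pool_size, size=n, replace=False)
        catalogues.append(HexamerSet.from_iterable(name, pool_motifs[idx]))
    common = frozenset.intersection(*(c.motifs for c in catalogues)) if catalogues else frozenset()
    truth = {
        "pool_size": pool_size,
        "set_sizes": list(set_sizes),
        "pool": sorted(pool.motifs),
        "observed_intersection": len(common),
    }
    return pool, catalogues, truth


def _random_dna(rng: np.random.Generator, n: int, comp: np.ndarray) -> str:
    return "".join(rng.choice(list(DNA_BASES), size=n, p=comp))


def _copula_assign(
    rng: np.random.Generator,
    anchor: np.ndarray,
    marginal_sorted: np.ndarray,
    rho_spearman: float,
) -> np.ndarray:
    """Assign a marginal to units with a target Spearman against ``anchor``.

    Gaussian copula: normal scores of the (randomly tie-broken) anchor
    ranks are mixed with independent noise at the Pearson equivalent of the
    Spearman target, and the sorted marginal values are assigned by the
    rank of the mixture.  Marginal distribution is preserved exactly.
    """
    n = len(anchor)
    tie_break = rng.random(n)
    order = np.lexsort((tie_break, anchor))
    ranks = np.empty(n, dtype=np.intp)
    ranks[order] = np.arange(n)
    from scipy.stats import norm

    z_anchor = norm.ppf((ranks + 0.5) / n)
    r_p = spearman_to_pearson(rho_spearman)
    z = r_p * z_anchor + math.sqrt(max(0.0, 1 - r_p ** 2)) * rng.standard_normal(n)
    out = np.empty(n)
    out[np.argsort(z, kind="stable")] = np.sort(marginal_sorted)
    return out


def _embed_probability(spec: SyntheticSpec, d: int) -> float:
    return spec.embed_floor + (spec.embed_plateau - spec.embed_floor) / (
        1.0 + math.exp((d - spec.embed_midpoint) / spec.embed_scale)
    )


def gen_genome(spec: SyntheticSpec) -> tuple:
    """Generate exons with embedded enhancers; returns ``(exons, truth)``.

    Exon sequences are usage-weighted codons (multiple of 3 nt, so frame
    starts at 0); pool motifs are stamped over the sequence with the
    logistic embedding curve (overwrite semantics, collisions allowed); the
    truth mask is coverage by pool motifs in the final sequence.  Splice
    scores and intron lengths are assigned by Gaussian copula against the
    realised flank density.  ``truth`` records the spec, the pool, and
    per-exon masks, labels and realised densities.
    """
    rng = np.random.default_rng(spec.seed)
    comp = np.asarray(spec.base_composition, dtype=float)
    usage = CodonUsage.human_genome()
    usage_arr = usage.as_array()

    if spec.pool is not None:
        pool = spec.pool
    else:
        universe = np.array(all_hexamers())
        idx = rng.choice(len(universe), size=spec.pool_size, replace=False)
        pool = HexamerSet.from_iterable("true_pool", universe[idx])
    pool_motifs = np.array(sorted(pool.motifs))

    # precompute within-pair base proportions for the synonym gradient
    gradient = {}
    for (a, b), beta in spec.synonym_gradient.items():
        a, b = a.upper(), b.upper()
        p0 = usage[a] / (usage[a] + usage[b])
        gradient[a] = (a, b, p0, beta)
        gradient[b] = (a, b, p0, beta)

    exons: list = []
    truth_exons: dict = {}
    n_codons_list = []
    lengths = np.exp(
        rng.normal(math.log(spec.exon_len_median), spec.exon_len_sigma, spec.n_exons)
    )
    lengths = np.clip(lengths, spec.exon_len_min, spec.exon_len_max)
    n_codons_list = np.maximum(2, np.round(lengths / 3).astype(int))

    inclusion = np.where(
        rng.random(spec.n_exons) < spec.p_alternative, "alternative", "constitutive"
    )
    conservation = np.where(
        rng.random(spec.n_exons) < spec.p_conserved, "conserved", "non_conserved"
    )
    intron_lens = np.maximum(
        spec.flank_nt,
        np.round(
            np.exp(
                rng.normal(
                    math.log(spec.intron_len_median),
                    spec.intron_len_sigma,
                    (spec.n_exons, 2),
                )
            )
        ).astype(int),
    )

    for i in range(spec.n_exons):
        n_codons = int(n_codons_list[i])
        codon_idx = rng.choice(61, size=n_codons, p=usage_arr)
        codons = [SENSE_CODONS[j] for j in codon_idx]
        if gradient:
            for j in range(n_codons):
                entry = gradient.get(codons[j])
                if entry is None:
                    continue
                a, b, p0, beta = entry
                t = min(j + 1, n_codons - j, spec.gradient_max_distance)
                p_a = min(0.98, max(0.02, p0 + beta * t))
                codons[j] = a if rng.random() < p_a else b
        seq = list("".join(codons))
        L = len(seq)

        mult = (
            spec.constitutive_embed_multiplier
            if inclusion[i] == "constitutive"
            else 1.0
        )
        stamps = []
        for start in range(L - 5):
            d = min(start + 1, L - start - 5)
            if rng.random() < min(1.0, _embed_probability(spec, d) * mult):
                motif = pool_motifs[rng.integers(len(pool_motifs))]
                seq[start:start + 6] = motif
                stamps.append(start)
        exon_seq = "".join(seq)

        up = _random_dna(rng, spec.flank_nt, comp)
        down = _random_dna(rng, spec.flank_nt, comp)
        exons.append(
            ExonRecord(
                gene_id=f"g{i:05d}",
                exon_index=1,
                exon_seq=exon_seq,
                upstream_intron_seq=up,
                downstream_intron_seq=down,
                upstream_intron_len=int(intron_lens[i, 0]),
                downstream_intron_len=int(intron_lens[i, 1]),
                inclusion=str(inclusion[i]),
                conservation=str(conservation[i]),
            )
        )
        truth_exons[exons[-1].exon_id] = {"stamps": stamps}

    # realised flank densities (terminal 50 nt minus terminal 3) per end
    dens5 = np.empty(spec.n_exons)
    dens3 = np.empty(spec.n_exons)
    masks = []
    for i, exon in enumerate(exons):
        mask = mask_ese_positions(exon.exon_seq, pool)
        masks.append(mask)
        L = len(mask)
        w5 = mask[3:min(50, L)]
        w3 = mask[max(0, L - 50):L - 3]
        dens5[i] = w5.mean() if w5.size else 0.0
        dens3[i] = w3.mean() if w3.size else 0.0

    score_marginal = rng.normal(spec.score_mean, spec.score_sd, spec.n_exons)
    score5 = _copula_assign(rng, dens5, score_marginal, spec.rho_score_density)
    score_marginal3 = rng.normal(spec.score_mean, spec.score_sd, spec.n_exons)
    score3 = _copula_assign(rng, dens3, score_marginal3, spec.rho_score_density)
    if spec.rho_intron_density != 0.0:
        intron5 = _copula_assign(
            rng, dens5, intron_lens[:, 0].astype(float), spec.rho_intron_density
        )
        intron3 = _copula_assign(
            rng, dens3, intron_lens[:, 1].astype(float), spec.rho_intron_density
        )
    else:
        intron5 = intron_lens[:, 0].astype(float)
        intron3 = intron_lens[:, 1].astype(float)

    for i, exon in enumerate(exons):
        exon.splice5_score = float(score5[i])
        exon.splice3_score = float(score3[i])
        exon.upstream_intron_len = int(round(intron5[i]))
        exon.downstream_intron_len = int(round(intron3[i]))
        t = truth_exons[exon.exon_id]
        t["mask"] = "".join("1" if m else "0" for m in masks[i])
        t["density5"] = float(dens5[i])
        t["density3"] = float(dens3[i])
        t["inclusion"] = exon.inclusion
        t["conservation"] = exon.conservation

    params = asdict(spec)
    params["pool"] = sorted(pool.motifs)
    truth = {"params": params, "exons": truth_exons}
    return exons, truth


_OTHER_BASES = {b: [c for c in DNA_BASES if c != b] for b in DNA_BASES}


def gen_ortholog_pairs(
    exons: Sequence[ExonRecord],
    pool: HexamerSet,
    d: Optional[float] = None,
    r: Optional[float] = None,
    seed: Optional[int] = None,
    spec: Optional[SyntheticSpec] = None,
) -> list:
    """Mouse copies of the exons with a rate deficit inside enhancers.

    Each four-fold degenerate third position is substituted (to a uniform
    different base, which preserves the four-fold family) with probability
    ``d`` outside the truth mask and ``d*r`` inside; all other positions
    are copied unchanged.  ``d``/``r`` default to the spec's divergence
    parameters.
    """
    if spec is not None:
        d = spec.divergence_rate if d is None else d
        r = spec.ese_rate_multiplier if r is None else r
    if d is None or r is None:
        raise ValueError("divergence rate d and multiplier r are required")
    if not 0 <= d <= 1 or r < 0 or d * max(1.0, r) > 1:
        raise ValueError("invalid divergence rates")
    rng = np.random.default_rng(seed)
    pairs = []
    for exon in exons:
        seq = exon.exon_seq
        mask = mask_ese_positions(seq, pool)
        n_codons = len(seq) // 3
        h_codons, m_codons = [], []
        for j in range(n_codons):
            codon = seq[3 * j:3 * j + 3]
            h_codons.append(codon)
            if codon[:2] in FOURFOLD_PREFIXES:
                pos = 3 * j + 2
                p = d * r if mask[pos] else d
                if rng.random() < p:
                    alt = _OTHER_BASES[codon[2]][rng.integers(3)]
                    codon = codon[:2] + alt
            m_codons.append(codon)
        pairs.append(
            OrthologExonPair(exon.gene_id, exon.exon_index, tuple(h_codons), tuple(m_codons))
        )
    return pairs


def gen_snps(
    exons: Sequence[ExonRecord],
    pool: HexamerSet,
    s: Optional[float] = None,
    q: Optional[float] = None,
    seed: Optional[int] = None,
    spec: Optional[SyntheticSpec] = None,
) -> SNPTable:
    """SNP positions with an in-enhancer density deficit.

    Each exonic site carries a SNP with probability ``s`` outside the truth
    mask and ``s*q`` inside.
    """
    if spec is not None:
        s = spec.snp_rate if s is None else s
        q = spec.snp_ese_multiplier if q is None else q
    if s is None or q is None:
        raise ValueError("SNP rate s and multiplier q are required")
    if not 0 <= s <= 1 or q < 0 or s * max(1.0, q) > 1:
        raise ValueError("invalid SNP rates")
    rng = np.random.default_rng(seed)
    table = SNPTable()
    for exon in exons:
        mask = mask_ese_positions(exon.exon_seq, pool)
        probs = np.where(mask, s * q, s)
        hits = np.flatnonzero(rng.random(len(probs)) < probs)
        for off in hits:
            table.add(exon.exon_id, int(off))
    return table


_VIOLATIONS = (
    "not_one2one",
    "duplicate_gene",
    "no_start_atg",
    "no_stop",
    "not_multiple_of_3",
    "internal_stop",
    "nonstandard_base",
    "exon_count_mismatch",
    "exon_length_gt_5pct",
)


def gen_ortholog_genes(
    n_genes: int,
    seed: Optional[int] = None,
    violations: Optional[dict] = None,
) -> tuple:
    """Ortholog gene pairs with known filter violations.

    Builds ``n_genes`` valid gene pairs (ATG start, stop end, in-frame, 3-6
    exons tiling the CDS at arbitrary nucleotide boundaries, identical
    structures in the two species) and then injects the requested number of
    each violation into distinct genes.  Returns
    ``(gene_pairs, expected_tally)`` where the tally matches what
    :func:`~esekit.sequence_model.filter_ortholog_exons` should report.
    """
    violations = dict(violations or {})
    unknown = set(violations) - set(_VIOLATIONS)
    if unknown:
        raise ValueError(f"unknown violations: {sorted(unknown)}")
    if sum(violations.values()) > n_genes:
        raise ValueError("more violations than genes")
    rng = np.random.default_rng(seed)
    non_stop = [c for c in SENSE_CODONS]

    def make_valid(gene_id: str) -> GenePair:
        n_exons = int(rng.integers(3, 7))
        n_body = int(rng.integers(40, 120))
        body = [non_stop[j] for j in rng.integers(0, 61, n_body)]
        stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
        cds = "ATG" + "".join(body) + stop
        total = len(cds)
        # cut the CDS at arbitrary nucleotide boundaries, each exon >= 12 nt
        while True:
            cuts = np.sort(rng.integers(1, total, n_exons - 1))
            lengths = np.diff(np.concatenate([[0], cuts, [total]]))
            if (lengths >= 12).all():
                break
        lengths = tuple(int(x) for x in lengths)
        return GenePair(gene_id, cds, cds, lengths, lengths)

    genes = [make_valid(f"gene{i:04d}") for i in range(n_genes)]
    order = list(rng.permutation(n_genes))
    tally: dict = {}
    extra: list = []

    def take() -> int:
        return order.pop()

    for reason, count in violations.items():
        for _ in range(count):
            i = take()
            gp = genes[i]
            if reason == "not_one2one":
                genes[i] = GenePair(
                    gp.gene_id, gp.human_cds, gp.mouse_cds,
                    gp.human_exon_lengths, gp.mouse_exon_lengths,
                    ortholog_type="one2many",
                )
            elif reason == "duplicate_gene":
                # a shorter duplicate transcript; the original survives
                short = make_valid(gp.gene_id)
                while len(short.human_cds) >= len(gp.human_cds):
                    short = make_valid(gp.gene_id)
                extra.append(short)
            elif reason == "no_start_atg":
                genes[i] = GenePair(
                    gp.gene_id, "GTG" + gp.human_cds[3:], gp.mouse_cds,
                    gp.human_exon_lengths, gp.mouse_exon_lengths,
                )
            elif reason == "no_stop":
                genes[i] = GenePair(
                    gp.gene_id, gp.human_cds[:-3] + "AAA", gp.mouse_cds,
                    gp.human_exon_lengths, gp.mouse_exon_lengths,
                )
            elif reason == "not_multiple_of_3":
                lens = list(gp.human_exon_lengths)
                lens[-1] += 1
                genes[i] = GenePair(
                    gp.gene_id, gp.human_cds + "A", gp.mouse_cds,
                    tuple(lens), gp.mouse_exon_lengths,
                )
            elif reason == "internal_stop":
                k = int(rng.integers(1, len(gp.human_cds) // 3 - 1))
                cds = gp.human_cds[:3 * k] + "TAA" + gp.human_cds[3 * k + 3:]
                genes[i] = GenePair(
                    gp.gene_id, cds, gp.mouse_cds,
                    gp.human_exon_lengths, gp.mouse_exon_lengths,
                )
            elif reason == "nonstandard_base":
                k = int(rng.integers(3, len(gp.human_cds) - 3))
                cds = gp.human_cds[:k] + "N" + gp.human_cds[k + 1:]
                genes[i] = GenePair(
                    gp.gene_id, cds, gp.mouse_cds,
                    gp.human_exon_lengths, gp.mouse_exon_lengths,
                )
            elif reason == "exon_count_mismatch":
                lens = list(gp.mouse_exon_lengths)
                lens = [lens[0] + lens[1]] + lens[2:]
                genes[i] = GenePair(
                    gp.gene_id, gp.human_cds, gp.mouse_cds,
                    gp.human_exon_lengths, tuple(lens),
                )
            elif reason == "exon_length_gt_5pct":
                lens = list(gp.mouse_exon_lengths)
                j = 1  # first internal exon
                shift = int(math.ceil(0.05 * gp.human_exon_lengths[j])) + 1
                lens[j] -= shift
                lens[j + 1] += shift
                genes[i] = GenePair(
                    gp.gene_id, gp.human_cds, gp.mouse_cds,
                    gp.human_exon_lengths, tuple(lens),
                )
            tally[reason] = tally.get(reason, 0) + 1

    all_pairs = genes + extra
    rng.shuffle(all_pairs)
    return all_pairs, tally


def gen_expression(
    n_genes: int,
    n_tissues: int = 28,
    seed: Optional[int] = None,
    frac_specific: float = 0.2,
):
    """A genes x tissues expression matrix with negative-control means.

    Most genes are broadly expressed (lognormal signal everywhere); a
    ``frac_specific`` fraction is expressed in a single random tissue.
    Control means are set so that weak signals mask to zero.  Returns
    ``(expression DataFrame, control_means Series)``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    tissues = [f"tissue{j:02d}" for j in range(n_tissues)]
    genes = [f"g{i:05d}" for i in range(n_genes)]
    values = np.exp(rng.normal(0.0, 1.0, (n_genes, n_tissues)))
    specific = rng.random(n_genes) < frac_specific
    for i in np.flatnonzero(specific):
        keep = rng.integers(n_tissues)
        row = np.full(n_tissues, 0.01)
        row[keep] = values[i, keep] + 1.0
        values[i] = row
    expr = pd.DataFrame(values, index=genes, columns=tissues)
    controls = pd.Series(0.2, index=tissues)
    return expr, controls
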