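"""Codon-level statistics linking enhancer catalogues to codon usage.

A hexamer can sit in any reading frame, so a 6-mer n1..n6 fully specifies
four codons (n1n2n3, n2n3n4, n3n4n5, n4n5n6).  Summing these frame codons
over a catalogue, dropping stop triplets and renormalising gives the
codon spectrum of the catalogue.  The hexamer preference index (HPI) of a
codon is the Z-score of its observed proportion in that spectrum against
randomised catalogues of the same size, each random hexamer built by
concatenating two codons drawn in proportion to genomic codon usage.

If enhancers are denser near exon ends, codons favoured inside enhancers
(high HPI) should also be favoured near exon boundaries.  That prediction
is tested by regressing each codon's within-synonymous-family usage on
distance from the boundary and, over all 87 synonymous codon pairs,
comparing the HPI difference with the slope difference: orienting each
pair so the HPI difference is positive, a negative slope difference means
the enhancer-preferred codon rises toward the boundary.  A one-tailed
binomial sign test and a one-tailed Spearman correlation are combined with
Fisher's method.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter, defaultdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motif_sets import HexamerSet
from .sequence_model import SENSE_CODONS, STOP_CODONS, _STANDARD_TABLE, ExonRecord

logger = logging.getLogger(__name__)

#: human codon usage, occurrences per thousand codons (Kazusa-style table)
HUMAN_CODON_USAGE_PER_1000 = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3, "TAA": 1.0, "TAG": 0.8,
    "CAT": 10.9, "CAC": 15.1, "CAA": 12.3, "CAG": 34.2,
    "AAT": 17.0, "AAC": 19.1, "AAA": 24.4, "AAG": 31.9,
    "GAT": 21.8, "GAC": 25.1, "GAA": 29.0, "GAG": 39.6,
    "TGT": 10.6, "TGC": 12.6, "TGA": 1.6, "TGG": 13.2,
    "CGT": 4.5, "CGC": 10.4, "CGA": 6.2, "CGG": 11.4,
    "AGT": 12.1, "AGC": 19.5, "AGA": 12.2, "AGG": 12.0,
    "GGT": 10.8, "GGC": 22.2, "GGA": 16.5, "GGG": 16.5,
}


class CodonUsage:
    """Relative codon frequencies over the 61 sense codons.

    Stop codons in the input are removed and the remaining frequencies
    renormalised to sum to 1.
    """

    def __init__(self, frequencies: Mapping[str, float]) -> None:
        sense = {
            c.upper(): float(f)
            for c, f in frequencies.items()
            if c.upper() not in STOP_CODONS
        }
        missing = set(SENSE_CODONS) - set(sense)
        if missing:
            raise ValueError(f"missing sense codons: {sorted(missing)[:5]} ...")
        if any(f < 0 for f in sense.values()):
            raise ValueError("codon frequencies must be non-negative")
        total = sum(sense.values())
        if total <= 0:
            raise ValueError("codon frequencies sum to zero")
        self._freq = {c: sense[c] / total for c in SENSE_CODONS}

    @classmethod
    def human_genome(cls) -> "CodonUsage":
        """Genome-wide human codon usage (per-thousand reference table)."""
        return cls(HUMAN_CODON_USAGE_PER_1000)

    @classmethod
    def from_tsv(cls, path) -> "CodonUsage":
        """Two-column TSV: codon, relative frequency (header optional)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if not str(df.iloc[0, 0]).upper().strip() in HUMAN_CODON_USAGE_PER_1000:
            df = df.iloc[1:]
        return cls(dict(zip(df.iloc[:, 0].str.upper(), df.iloc[:, 1].astype(float))))

    def __getitem__(self, codon: str) -> float:
        return self._freq[codon]

    def as_array(self) -> np.ndarray:
        """Frequencies in :data:`SENSE_CODONS` order."""
        return np.array([self._freq[c] for c in SENSE_CODONS])

    def items(self):
        return self._freq.items()


def extract_frame_codons(hexamer: str) -> list:
    """The four codons fully specified by a hexamer, one per frame offset.

    Stop triplets are retained here; they are dropped (and proportions
    renormalised) at the counting stage.
    """
    h = hexamer.strip().upper()
    if len(h) != 6 or set(h) - set("ACGT"):
        raise ValueError(f"{hexamer!r} is not an ACGT hexamer")
    return [h[0:3], h[1:4], h[2:5], h[3:6]]


def observed_codon_proportions(hexamers: HexamerSet) -> np.ndarray:
    """Non-stop frame-codon proportions of a catalogue (SENSE_CODONS order)."""
    counts = Counter()
    for motif in hexamers:
        for codon in extract_frame_codons(motif):
            if codon not in STOP_CODONS:
                counts[codon] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("catalogue contributes no sense frame codons")
    return np.array([counts.get(c, 0) / total for c in SENSE_CODONS])


def _pair_count_matrix() -> np.ndarray:
    """(61*61, 61) matrix: non-stop frame-codon counts of every codon-pair
    hexamer.  Row p = 61*i + j is the hexamer SENSE_CODONS[i] + SENSE_CODONS[j]."""
    idx = {c: k for k, c in enumerate(SENSE_CODONS)}
    M = np.zeros((61 * 61, 61), dtype=np.int8)
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            h = c1 + c2
            for codon in (h[0:3], h[1:4], h[2:5], h[3:6]):
                if codon not in STOP_CODONS:
                    M[61 * i + j, idx[codon]] += 1
    return M


def sample_pair_indices(
    rng: np.random.Generator, usage: CodonUsage, reps: int, size: int
) -> np.ndarray:
    """Draw (reps, size) codon-pair indices for random hexamers.

    Each random hexamer is the concatenation of two sense codons drawn
    independently in proportion to ``usage``; the pair index is
    ``61*i + j`` over :data:`SENSE_CODONS` order.  Sampling is by inverse
    CDF on a flat uniform draw, so an independent implementation can
    reproduce the stream exactly from the same generator state.
    """
    p = usage.as_array()
    pair_probs = np.outer(p, p).ravel()
    cum = np.cumsum(pair_probs)
    cum[-1] = 1.0
    u = rng.random((reps, size))
    return np.searchsorted(cum, u, side="right")


def hpi(
    hexamers: HexamerSet,
    usage: Optional[CodonUsage] = None,
    reps: int = 10_000,
    seed: Optional[int] = None,
    sd_ddof: int = 1,
) -> pd.DataFrame:
    """Hexamer preference index for each sense codon.

    Observed codon proportions come from all frame codons of the catalogue
    with stops removed; the null redraws ``reps`` random catalogues of the
    same size, each hexamer a concatenation of two usage-weighted sense
    codons, parsed identically.  Returns a DataFrame indexed by codon with
    ``observed``, ``null_mean``, ``null_sd`` and ``hpi`` columns; codons
    with zero null standard deviation get NaN with a warning.
    """
    if usage is None:
        usage = CodonUsage.human_genome()
    if len(hexamers) == 0:
        raise ValueError("empty catalogue")
    obs = observed_codon_proportions(hexamers)

    rng = np.random.default_rng(seed)
    pair_idx = sample_pair_indices(rng, usage, reps, len(hexamers))
    M = _pair_count_matrix().astype(np.float64)

    props = np.empty((reps, 61))
    chunk = max(1, min(reps, 2_000_000 // max(len(hexamers), 1)))
    for start in range(0, reps, chunk):
        block = pair_idx[start:start + chunk]
        counts = np.stack(
            [np.bincount(row, minlength=61 * 61) for row in block]
        ).astype(np.float64)
        c = counts @ M
        props[start:start + chunk] = c / c.sum(axis=1, keepdims=True)

    null_mean = props.mean(axis=0)
    null_sd = props.std(axis=0, ddof=sd_ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - null_mean) / null_sd
    degenerate = null_sd == 0
    if degenerate.any():
        bad = [SENSE_CODONS[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(f"HPI undefined (null sd = 0) for codons: {bad}")
        z[degenerate] = np.nan
    return pd.DataFrame(
        {"observed": obs, "null_mean": null_mean, "null_sd": null_sd, "hpi": z},
        index=pd.Index(SENSE_CODONS, name="codon"),
    )


_FAMILIES: dict = defaultdict(list)
for _c in SENSE_CODONS:
    _FAMILIES[_STANDARD_TABLE.forward_table[_c]].append(_c)
SYNONYMOUS_FAMILIES = {aa: tuple(codons) for aa, codons in _FAMILIES.items()}


def synonymous_pairs() -> list:
    """All 87 unordered pairs of sense codons encoding the same amino acid."""
    pairs = []
    for codons in SYNONYMOUS_FAMILIES.values():
        for i in range(len(codons)):
            for j in range(i + 1, len(codons)):
                pairs.append((codons[i], codons[j]))
    return sorted(pairs)


def codon_distance_counts(
    exons: Sequence[ExonRecord], max_distance: int = 35
) -> pd.DataFrame:
    """Codon occurrence counts by codon-index distance from the boundary.

    Exon sequences are read as consecutive codons (incomplete trailing
    triplets ignored; exons are expected to be frame-trimmed).  Each exon
    is split at its midpoint and each codon's distance is counted in
    codons into its own half, the boundary codon being distance 1, capped
    at ``max_distance``.
    """
    counts: Counter = Counter()
    for exon in exons:
        seq = exon.exon_seq
        n = len(seq) // 3
        for j in range(n):
            codon = seq[3 * j:3 * j + 3]
            if codon in STOP_CODONS or set(codon) - set("ACGT"):
                continue
            d = min(j + 1, n - j)
            if d <= max_distance:
                counts[(codon, d)] += 1
    rows = [
        {"codon": c, "distance": d, "count": n} for (c, d), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["codon", "distance", "count"])


def codon_slopes(
    exons: Sequence[ExonRecord],
    max_distance: int = 35,
    proportional: bool = True,
) -> pd.DataFrame:
    """Least-squares slope of codon usage on distance from the boundary.

    With ``proportional=True`` (default) the response at each distance is
    the codon's share of its synonymous family there -- the "relative usage
    of synonymous codons" framing; with ``proportional=False`` it is the
    codon's share of all sense codons.  Distances are codon indices within
    the exon half, boundary codon = 1.  Returns slope, stderr and the
    number of informative distance bins per codon; bins where the family is
    absent are skipped.
    """
    counts = codon_distance_counts(exons, max_distance)
    if counts.empty:
        raise ValueError("no codons counted; are the exons coding and frame-trimmed?")
    table = counts.pivot_table(
        index="codon", columns="distance", values="count", fill_value=0
    ).reindex(index=SENSE_CODONS, fill_value=0)
    dists = np.asarray(table.columns, dtype=float)
    mat = table.to_numpy(dtype=float)

    rows = []
    for i, codon in enumerate(SENSE_CODONS):
        family = SYNONYMOUS_FAMILIES[_STANDARD_TABLE.forward_table[codon]]
        fam_idx = [SENSE_CODONS.index(c) for c in family]
        denom = mat[fam_idx].sum(axis=0) if proportional else mat.sum(axis=0)
        ok = denom > 0
        if ok.sum() < 3:
            rows.append({"codon": codon, "slope": np.nan, "stderr": np.nan,
                         "n_bins": int(ok.sum())})
            continue
        prop = mat[i, ok] / denom[ok]
        res = stats.linregress(dists[ok], prop)
        rows.append(
            {
                "codon": codon,
                "slope": float(res.slope),
                "stderr": float(res.stderr),
                "n_bins": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows).set_index("codon")


def fisher_combine(p_values: Sequence[float], df: Optional[int] = None) -> tuple:
    """Fisher's method: chi2 = -2 * sum(ln p); overall P from chi-squared.

    ``df`` defaults to ``2 * len(p_values)``.  Returns ``(chi2, p)``.
    """
    ps = [float(p) for p in p_values]
    if any(p <= 0 or p > 1 for p in ps):
        raise ValueError("P values must lie in (0, 1]")
    chi2 = -2.0 * sum(math.log(p) for p in ps)
    if df is None:
        df = 2 * len(ps)
    return chi2, float(stats.chi2.sf(chi2, df))


def pair_concordance(
    hpi_table: pd.DataFrame,
    slope_table: pd.DataFrame,
    fisher_df: int = 4,
) -> dict:
    """Do enhancer-preferred codons rise in usage toward exon boundaries?

    Each synonymous pair is oriented so the HPI difference is positive
    (exact ties dropped); the slope difference then has expected negative
    sign if the catalogue predicts boundary-directed usage.  Reports the
    tally of negative/positive slope differences with a one-tailed exact
    binomial P (excess negatives under p = 0.5, zero differences dropped),
    the Spearman correlation of slope difference on HPI difference with a
    one-tailed P (alternative: negative), and Fisher's combination of the
    two P values.  The overall P is evaluated at ``fisher_df`` degrees of
    freedom (4 for two combined tests; a df = 2 value is also returned for
    comparability with analyses that used that reference).
    """
    d_hpi, d_slope = [], []
    dropped = 0
    for c1, c2 in synonymous_pairs():
        try:
            h1, h2 = float(hpi_table.loc[c1, "hpi"]), float(hpi_table.loc[c2, "hpi"])
            s1, s2 = float(slope_table.loc[c1, "slope"]), float(slope_table.loc[c2, "slope"])
        except KeyError:
            dropped += 1
            continue
        if any(math.isnan(v) for v in (h1, h2, s1, s2)):
            dropped += 1
            continue
        if h1 == h2:
            dropped += 1
            logger.info("pair (%s, %s): tied HPI, dropped", c1, c2)
            continue
        if h1 < h2:  # orient so the first codon has the larger HPI
            c1, c2, h1, h2, s1, s2 = c2, c1, h2, h1, s2, s1
        d_hpi.append(h1 - h2)
        d_slope.append(s1 - s2)
    if dropped:
        logger.info("pair_concordance: %d pairs dropped", dropped)
    d_hpi_arr = np.asarray(d_hpi)
    d_slope_arr = np.asarray(d_slope)

    nonzero = d_slope_arr[d_slope_arr != 0]
    negatives = int((nonzero < 0).sum())
    positives = int((nonzero > 0).sum())
    p_binom = float(
        stats.binomtest(negatives, negatives + positives, 0.5,
                        alternative="greater").pvalue
    )
    rho_res = stats.spearmanr(d_hpi_arr, d_slope_arr)
    rho = float(rho_res.statistic)
    p_two = float(rho_res.pvalue)
    p_rho = p_two / 2 if rho < 0 else 1 - p_two / 2
    # a perfect rank correlation yields P = 0 exactly; floor it so the
    # Fisher combination stays finite
    floored = [max(p_binom, 1e-300), max(p_rho, 1e-300)]
    chi2, p_overall = fisher_combine(floored, df=fisher_df)
    _, p_overall_df2 = fisher_combine(floored, df=2)
    return {
        "n_pairs": len(d_hpi),
        "negatives": negatives,
        "positives": positives,
        "p_binomial": p_binom,
        "rho": rho,
        "p_rho": p_rho,
        "chi2": chi2,
        "p_overall": p_overall,
        "p_overall_df2": p_overall_df2,
    }
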