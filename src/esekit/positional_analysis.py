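"""ESE density profiles across the intron-exon-intron layout.

Enhancer motifs are expected to concentrate in exons (versus introns) and
near exon ends (versus exon cores).  These analyses score every position of
a merged intron|exon|intron composite as ESE or not (coverage by any motif
of the catalogue), aggregate coverage by region and by distance from the
splice sites, and test the region contrasts:

* exon vs intron and ends vs core across exons (unpaired rank tests);
* flank vs core within the same long exons (paired one-sided Wilcoxon and
  a sign test), which is robust to composition differences between long
  and short exons;
* purine content inside versus outside the ESE mask within the 50-nt exon
  end windows.

"Density" throughout is coverage fraction: the fraction of nucleotide
positions covered by at least one motif occurrence.  The per-hexamer
normalisation divides a density by the catalogue size, so catalogues of
very different sizes can be compared; both the median density divided by
set size and the median of per-position per-hexamer densities are emitted,
since the two differ slightly and published tables are ambiguous about
which was used.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motif_sets import HexamerSet
from .sequence_model import (
    ExonRecord,
    ProfileSkip,
    mask_ese_positions,
    merged_profile_sequence,
)

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")


def _composite_mask(exon: ExonRecord, hexamers: HexamerSet, **kwargs):
    """Composite layout plus its ESE mask (mask computed on the continuous
    flank+exon+flank sequence so motifs spanning boundaries count)."""
    comp = merged_profile_sequence(exon, **kwargs)
    full_mask = mask_ese_positions(comp.full_sequence, hexamers)
    return comp, full_mask[comp.source_offsets]


def profile_density(
    exons: Sequence[ExonRecord], hexamers: HexamerSet, **kwargs
) -> pd.DataFrame:
    """Per-position ESE coverage fraction across exons.

    Positions are keyed by (region, distance-from-nearest-splice-site);
    ``coverage`` is the fraction of contributing exons whose ESE mask is
    True there, and ``coverage_per_hexamer`` divides by the catalogue size.
    Exons failing the composite preconditions are skipped with a log entry.
    """
    totals: dict = {}
    covered: dict = {}
    n_used = 0
    for exon in exons:
        try:
            comp, mask = _composite_mask(exon, hexamers, **kwargs)
        except ProfileSkip as exc:
            logger.info("profile: skipped %s", exc)
            continue
        n_used += 1
        for region, dist, flag in zip(comp.region, comp.distance, mask):
            key = (region, int(dist))
            totals[key] = totals.get(key, 0) + 1
            if flag:
                covered[key] = covered.get(key, 0) + 1
    if n_used == 0:
        raise ValueError("no exon qualified for the positional profile")
    rows = [
        {
            "region": region,
            "distance": dist,
            "n_exons": totals[(region, dist)],
            "coverage": covered.get((region, dist), 0) / totals[(region, dist)],
        }
        for (region, dist) in sorted(totals)
    ]
    df = pd.DataFrame(rows)
    df["coverage_per_hexamer"] = df["coverage"] / len(hexamers)
    return df


_EXON_REGIONS = ("exon_5_flank", "exon_core", "exon_3_flank")
_END_REGIONS = ("exon_5_flank", "exon_3_flank")
_INTRON_REGIONS = ("intron_5", "intron_3")


def per_exon_region_densities(
    exons: Sequence[ExonRecord], hexamers: HexamerSet, **kwargs
) -> pd.DataFrame:
    """Per-exon coverage densities for intron / exon / ends / core regions.

    ``core`` is NaN for exons without a core window (length <= 200 nt with
    default windows).  Exons failing composite preconditions are skipped.
    """
    rows = []
    for exon in exons:
        try:
            comp, mask = _composite_mask(exon, hexamers, **kwargs)
        except ProfileSkip as exc:
            logger.info("region densities: skipped %s", exc)
            continue
        region = np.asarray(comp.region)

        def density(names) -> float:
            sel = np.isin(region, names)
            return float(mask[sel].mean()) if sel.any() else np.nan

        rows.append(
            {
                "exon_id": exon.exon_id,
                "intron": density(_INTRON_REGIONS),
                "exon": density(_EXON_REGIONS),
                "ends": density(_END_REGIONS),
                "core": density(("exon_core",)),
            }
        )
    return pd.DataFrame(rows)


def region_densities(
    exons: Sequence[ExonRecord], hexamers: HexamerSet, **kwargs
) -> dict:
    """Region density medians and the two unpaired region contrasts.

    Returns medians (and per-hexamer medians, both conventions) for each
    region plus two-sided Mann-Whitney P values for exon-vs-intron and
    ends-vs-core across exons.  Regions may come from different exons; see
    :func:`paired_flank_core_test` for the matched within-exon version.
    """
    dens = per_exon_region_densities(exons, hexamers, **kwargs)
    if dens.empty:
        raise ValueError("no exon qualified for region densities")
    size = len(hexamers)
    out: dict = {"n_exons": len(dens)}
    for region in ("intron", "exon", "ends", "core"):
        vals = dens[region].dropna()
        med = float(vals.median()) if len(vals) else np.nan
        out[f"{region}_median"] = med
        out[f"{region}_median_per_hexamer"] = med / size
        out[f"{region}_median_of_per_hexamer"] = (
            float((vals / size).median()) if len(vals) else np.nan
        )
    exon_vals = dens["exon"].dropna()
    intron_vals = dens["intron"].dropna()
    ends_vals = dens["ends"].dropna()
    core_vals = dens["core"].dropna()
    out["p_exon_vs_intron"] = float(
        stats.mannwhitneyu(exon_vals, intron_vals, alternative="two-sided").pvalue
    )
    if len(core_vals) >= 1 and len(ends_vals) >= 1:
        out["p_ends_vs_core"] = float(
            stats.mannwhitneyu(ends_vals, core_vals, alternative="two-sided").pvalue
        )
    else:
        out["p_ends_vs_core"] = np.nan
    return out


def paired_flank_core_test(
    exons: Sequence[ExonRecord],
    hexamers: HexamerSet,
    end_window: int = 50,
    core_window: int = 100,
) -> dict:
    """Matched flank-vs-core contrast within long exons.

    For every exon longer than ``2*end_window + core_window`` nt, the flank
    density pools the two terminal ``end_window`` windows and the core
    density covers the central ``core_window`` nt of the same exon.  The
    one-sided paired Wilcoxon signed-rank test (alternative: flank > core)
    and a binomial sign test over the signs of (flank - core), zeros
    dropped, are returned along with the per-exon densities.
    """
    flanks, cores = [], []
    for exon in exons:
        L = len(exon.exon_seq)
        if L <= 2 * end_window + core_window:
            continue
        mask = mask_ese_positions(exon.exon_seq, hexamers)
        flank_idx = np.r_[0:end_window, L - end_window:L]
        core_start = (L - core_window) // 2
        flanks.append(float(mask[flank_idx].mean()))
        cores.append(float(mask[core_start:core_start + core_window].mean()))
    n = len(flanks)
    if n < 10:
        raise ValueError(f"only {n} qualifying exons (need >= 10)")
    flanks_arr = np.asarray(flanks)
    cores_arr = np.asarray(cores)
    diff = flanks_arr - cores_arr
    nonzero = diff[diff != 0]
    result = {
        "n_exons": n,
        "flank_median": float(np.median(flanks_arr)),
        "core_median": float(np.median(cores_arr)),
    }
    if nonzero.size == 0:
        warnings.warn("all flank-core differences are zero; P = 1")
        result["p_wilcoxon"] = 1.0
        result["p_sign"] = 1.0
        return result
    mode = "exact" if nonzero.size < 25 else "approx"
    res = stats.wilcoxon(
        flanks_arr, cores_arr, alternative="greater", correction=True, method=mode
    )
    result["p_wilcoxon"] = float(res.pvalue)
    n_pos = int((nonzero > 0).sum())
    result["p_sign"] = float(
        stats.binomtest(n_pos, nonzero.size, 0.5, alternative="greater").pvalue
    )
    return result


def flank_purine_split(
    exons: Sequence[ExonRecord], hexamers: HexamerSet, end_window: int = 50
) -> dict:
    """Purine content inside vs outside the ESE mask in exon-end windows.

    Per exon, the purine (A or G) fraction is computed separately over the
    masked and unmasked positions of the terminal ``end_window`` windows
    (overlapping windows deduplicated for short exons); means and medians
    across exons are reported.  An exon whose flank is entirely masked (or
    entirely unmasked) contributes only to the defined side.
    """
    ese_fracs, non_fracs = [], []
    for exon in exons:
        L = len(exon.exon_seq)
        mask = mask_ese_positions(exon.exon_seq, hexamers)
        idx = np.unique(np.r_[0:min(end_window, L), max(0, L - end_window):L])
        purine = np.fromiter(
            (exon.exon_seq[i] in PURINES for i in idx), dtype=bool, count=len(idx)
        )
        m = mask[idx]
        if m.any():
            ese_fracs.append(float(purine[m].mean()))
        if (~m).any():
            non_fracs.append(float(purine[~m].mean()))
    if not ese_fracs and not non_fracs:
        raise ValueError("no exons supplied")
    return {
        "n_exons_ese": len(ese_fracs),
        "n_exons_non": len(non_fracs),
        "mean_ese": float(np.mean(ese_fracs)) if ese_fracs else np.nan,
        "mean_non_ese": float(np.mean(non_fracs)) if non_fracs else np.nan,
        "median_ese": float(np.median(ese_fracs)) if ese_fracs else np.nan,
        "median_non_ese": float(np.median(non_fracs)) if non_fracs else np.nan,
    }
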