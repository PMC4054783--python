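"""Associations between enhancer density and exon-level covariates.

Enhancers are thought to compensate for weak splice sites and for the
harder search problem posed by long flanking introns.  These analyses
correlate per-exon flank ESE density with splice-site strength scores,
flanking intron length, exon class labels (alternative/constitutive,
conserved/non-conserved) and gene expression summaries.  All correlations
are rank-based (Spearman), including a partial Spearman correlation that
residualises rank-transformed variables on covariates, so every test is
invariant to monotone transforms of the inputs.

Flank density for the splice-strength analysis uses the terminal 50 nt of
the exon omitting the terminal 3 nt (those overlap the splice consensus
itself); class comparisons use the terminal 100 nt.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motif_sets import HexamerSet
from .sequence_model import ExonRecord, mask_ese_positions

logger = logging.getLogger(__name__)


def flank_density(
    exon: ExonRecord,
    hexamers: HexamerSet,
    end: int,
    width: int = 50,
    omit_terminal: int = 0,
    mask: Optional[np.ndarray] = None,
) -> float:
    """ESE coverage fraction of one exon-end window.

    ``end`` is 5 or 3; the window spans ``width`` nt from that end of the
    exon, excluding the outermost ``omit_terminal`` nt.  Windows are
    clipped to the exon.
    """
    if end not in (5, 3):
        raise ValueError("end must be 5 or 3")
    if mask is None:
        mask = mask_ese_positions(exon.exon_seq, hexamers)
    L = len(exon.exon_seq)
    if end == 5:
        lo, hi = omit_terminal, min(width, L)
    else:
        lo, hi = max(0, L - width), L - omit_terminal
    if hi <= lo:
        return np.nan
    return float(mask[lo:hi].mean())


def covariates_table(
    exons: Sequence[ExonRecord],
    hexamers: HexamerSet,
    strength_width: int = 50,
    omit_terminal: int = 3,
    class_width: int = 100,
) -> pd.DataFrame:
    """Per-exon covariates for all association analyses.

    Columns: the terminal-window densities used by the splice-strength
    analysis (``density5``/``density3``: ``strength_width`` nt minus the
    ``omit_terminal`` outermost), the ``class_width``-nt densities used by
    the class comparisons (``density100_5``/``density100_3``), splice
    scores, flanking intron lengths, exon length, gene id and class labels.
    """
    rows = []
    for exon in exons:
        mask = mask_ese_positions(exon.exon_seq, hexamers)
        rows.append(
            {
                "exon_id": exon.exon_id,
                "gene_id": exon.gene_id,
                "density5": flank_density(
                    exon, hexamers, 5, strength_width, omit_terminal, mask
                ),
                "density3": flank_density(
                    exon, hexamers, 3, strength_width, omit_terminal, mask
                ),
                "density100_5": flank_density(exon, hexamers, 5, class_width, 0, mask),
                "density100_3": flank_density(exon, hexamers, 3, class_width, 0, mask),
                "splice5_score": exon.splice5_score,
                "splice3_score": exon.splice3_score,
                "intron5_len": exon.upstream_intron_len,
                "intron3_len": exon.downstream_intron_len,
                "exon_len": len(exon.exon_seq),
                "inclusion": exon.inclusion,
                "conservation": exon.conservation,
            }
        )
    return pd.DataFrame(rows).set_index("exon_id")


def strength_density_correlation(cov: pd.DataFrame, end: int) -> tuple:
    """Spearman correlation of splice-site strength with flank ESE density.

    ``end`` is 5 or 3.  Returns ``(rho, p)``; NaN with a warning when
    either variable is constant.
    """
    if end not in (5, 3):
        raise ValueError("end must be 5 or 3")
    sub = cov[[f"splice{end}_score", f"density{end}"]].dropna()
    if len(sub) < 10:
        raise ValueError(f"only {len(sub)} exons with defined score and density")
    x = sub.iloc[:, 0].astype(float)
    y = sub.iloc[:, 1].astype(float)
    if x.nunique() < 2 or y.nunique() < 2:
        warnings.warn("constant score or density; correlation undefined")
        return np.nan, np.nan
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


_CLASS_LEVELS = {
    "inclusion": ("alternative", "constitutive"),
    "conservation": ("conserved", "non_conserved"),
}


def class_comparison(cov: pd.DataFrame, label: str) -> pd.DataFrame:
    """Rank-sum comparison of flank ESE density between two exon classes.

    ``label`` is ``inclusion`` (alternative vs constitutive) or
    ``conservation`` (conserved vs non-conserved).  For each exon end the
    Mann-Whitney two-tailed P plus both one-tailed P values on the
    ``class_width`` flank densities are reported.
    """
    if label not in _CLASS_LEVELS:
        raise ValueError(f"unknown label {label!r}")
    a_level, b_level = _CLASS_LEVELS[label]
    rows = []
    for end in (5, 3):
        col = f"density100_{end}"
        sub = cov[[label, col]].dropna()
        a = sub.loc[sub[label] == a_level, col].astype(float)
        b = sub.loc[sub[label] == b_level, col].astype(float)
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"empty class at end {end}")
        if min(len(a), len(b)) < 5:
            warnings.warn(f"class with fewer than 5 exons at end {end}")
        rows.append(
            {
                "end": end,
                "n_" + a_level: len(a),
                "n_" + b_level: len(b),
                "p_two_sided": float(
                    stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                ),
                f"p_{a_level}_greater": float(
                    stats.mannwhitneyu(a, b, alternative="greater").pvalue
                ),
                f"p_{a_level}_less": float(
                    stats.mannwhitneyu(a, b, alternative="less").pvalue
                ),
            }
        )
    return pd.DataFrame(rows).set_index("end")


def intron_length_correlation(
    cov: pd.DataFrame,
    max_intron: Optional[int] = None,
    method: str = "spearman",
) -> tuple:
    """Correlation of flank ESE density with flanking intron length.

    Each exon end is paired with its own flanking intron and both ends are
    pooled; ``max_intron`` (e.g. 1501) restricts to introns strictly below
    that length.  ``method`` is ``spearman`` (default, rank-based) or
    ``pearson``.  Returns ``(r, p)``.
    """
    frames = []
    for end, intron_col in ((5, "intron5_len"), (3, "intron3_len")):
        sub = cov[[f"density{end}", intron_col]].dropna()
        sub.columns = ["density", "intron_len"]
        frames.append(sub)
    pooled = pd.concat(frames, ignore_index=True)
    if max_intron is not None:
        pooled = pooled[pooled["intron_len"] < max_intron]
    if pooled.empty:
        raise ValueError("no exon ends left after the intron-length filter")
    if method == "spearman":
        res = stats.spearmanr(pooled["density"], pooled["intron_len"])
        return float(res.statistic), float(res.pvalue)
    if method == "pearson":
        res = stats.pearsonr(pooled["density"], pooled["intron_len"])
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def partial_spearman(
    df: pd.DataFrame,
    response: str,
    predictor: str,
    covariates: Sequence[str] = (),
) -> tuple:
    """Partial Spearman correlation of response and predictor given covariates.

    All variables are rank-transformed; response and predictor ranks are
    residualised on the covariate ranks (least squares with intercept) and
    the Pearson correlation of the residuals is returned with a t-test P at
    ``n - 2 - k`` degrees of freedom.  With no covariates this equals the
    plain Spearman correlation.  Collinear covariates raise a ValueError
    naming the offending pair.
    """
    cols = list(dict.fromkeys([response, predictor, *covariates]))
    sub = df[cols].dropna().astype(float)
    n = len(sub)
    k = len(covariates)
    if n < k + 10:
        raise ValueError(f"only {n} complete cases for {k} covariates")
    ranks = sub.apply(stats.rankdata)
    if covariates:
        X = np.column_stack(
            [np.ones(n)] + [ranks[c].to_numpy() for c in covariates]
        )
        rank_x = np.linalg.matrix_rank(X)
        if rank_x < X.shape[1]:
            corr = ranks[list(covariates)].corr()
            for i, ci in enumerate(covariates):
                for cj in covariates[i + 1:]:
                    if abs(corr.loc[ci, cj]) > 1 - 1e-10:
                        raise ValueError(f"collinear covariates: {ci} and {cj}")
            raise ValueError("collinear covariate design")
        resid_r = ranks[response].to_numpy() - X @ np.linalg.lstsq(
            X, ranks[response].to_numpy(), rcond=None
        )[0]
        resid_p = ranks[predictor].to_numpy() - X @ np.linalg.lstsq(
            X, ranks[predictor].to_numpy(), rcond=None
        )[0]
    else:
        resid_r = ranks[response].to_numpy() - ranks[response].mean()
        resid_p = ranks[predictor].to_numpy() - ranks[predictor].mean()
    # residuals that vanish to numerical noise (e.g. the predictor included
    # among the covariates) carry no signal
    tol = 1e-8 * n ** 1.5
    if (resid_r ** 2).sum() < tol or (resid_p ** 2).sum() < tol:
        return 0.0, 1.0
    denom = np.sqrt((resid_r ** 2).sum() * (resid_p ** 2).sum())
    rho = float((resid_r * resid_p).sum() / denom)
    dof = n - 2 - k
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(dof / (1 - rho ** 2))
    p = float(2 * stats.t.sf(abs(t), dof))
    return rho, p


def expression_summaries(
    expression: pd.DataFrame,
    control_means: pd.Series,
) -> pd.DataFrame:
    """Per-gene expression summaries from a genes x tissues matrix.

    Values below the per-tissue negative-control mean are masked to zero;
    genes that are zero in every tissue after masking are dropped; each
    tissue is normalised by its total remaining signal.  Reported per gene:
    breadth (fraction of tissues with nonzero signal), tau (expression
    specificity, 0 = uniform, 1 = single-tissue), mean and median over
    tissues.
    """
    if (expression < 0).any().any():
        raise ValueError("expression matrix must be non-negative")
    expr = expression.copy().astype(float)
    aligned = control_means.reindex(expr.columns)
    if aligned.isna().any():
        raise ValueError("control means missing for some tissues")
    expr = expr.where(expr.ge(aligned, axis=1), 0.0)
    expr = expr.loc[(expr > 0).any(axis=1)]
    totals = expr.sum(axis=0)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValueError(f"tissues with zero total signal after masking: {zero}")
    norm = expr.div(totals, axis=1)
    n_tissues = norm.shape[1]
    x_max = norm.max(axis=1)
    tau = (1 - norm.div(x_max, axis=0)).sum(axis=1) / (n_tissues - 1)
    return pd.DataFrame(
        {
            "breadth": (norm > 0).sum(axis=1) / n_tissues,
            "tau": tau,
            "mean": norm.mean(axis=1),
            "median": norm.median(axis=1),
        }
    )
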