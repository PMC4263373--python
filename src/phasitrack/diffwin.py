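"""Windowed differential small-RNA abundance between two genotypes.

Counts are tallied per size class in non-overlapping windows tiling each
sequence from coordinate 0; a read belongs to the window containing its
strand-aware 5' end. Differential windows are called with an exact
negative-binomial test under a single common dispersion shared across
windows, the small-replicate design the paper's cited count methodology
(edgeR's classic exact test) is built for, followed by Benjamini-Hochberg
FDR control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import nbinom, ttest_ind
from statsmodels.stats.multitest import multipletests

from .srio import AlignmentRecord, Library

logger = logging.getLogger("phasitrack")

WINDOW_LEN = 500
MIN_WINDOW_TOTAL = 10
MIN_FOLD = 2.0
MAX_Q = 0.05
SIZE_CLASSES = (21, 22, 24)


def count_windows(
    records_by_library: Mapping[str, Sequence[AlignmentRecord]],
    window_len: int = WINDOW_LEN,
    size_class: int = 21,
) -> pd.DataFrame:
    """Count size-``size_class`` reads per non-overlapping window.

    Returns a DataFrame indexed by (chrom, window start) with one integer
    column per library; both strands are pooled and each read counts its
    full ``copies`` in the single window holding its 5' end.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    cols = {}
    for lib, records in records_by_library.items():
        counts: dict[tuple[str, int], int] = {}
        for r in records:
            if r.length != size_class:
                continue
            w = (r.five_prime // window_len) * window_len
            key = (r.chrom, w)
            counts[key] = counts.get(key, 0) + r.copies
        cols[lib] = counts
    df = pd.DataFrame(cols).fillna(0).astype(int)
    if df.empty:
        df = pd.DataFrame(columns=list(records_by_library), dtype=int)
        df.index = pd.MultiIndex.from_arrays([[], []], names=["chrom", "start"])
        return df
    df.index = pd.MultiIndex.from_tuples(df.index, names=["chrom", "start"])
    return df.sort_index()


def filter_low_windows(matrix: pd.DataFrame, min_total: int = MIN_WINDOW_TOTAL) -> pd.DataFrame:
    """Drop windows with fewer than ``min_total`` reads summed over all libraries."""
    if matrix.shape[1] < 1:
        raise ValueError("matrix needs at least one library")
    kept = matrix[matrix.sum(axis=1) >= min_total]
    if kept.empty and not matrix.empty:
        logger.warning("all %d windows fell below min_total=%d", len(matrix), min_total)
    return kept


# ---------------------------------------------------------------------------
# common-dispersion exact NB test


def _cml_neg_loglik(log_phi: float, groups: list[np.ndarray]) -> float:
    """Negative conditional log-likelihood of a common dispersion.

    For equal-size libraries the NB likelihood conditional on each
    window/group sum depends only on the dispersion, so a single phi can
    be profiled out across all windows (qCML).
    """
    r = 1.0 / np.exp(log_phi)
    ll = 0.0
    for y in groups:  # y: windows x libs within one group
        n = y.shape[1]
        s = y.sum(axis=1)
        ll += (
            gammaln(y + r).sum()
            - y.shape[0] * n * gammaln(r)
            + y.shape[0] * gammaln(n * r)
            - gammaln(s + n * r).sum()
        )
    return -ll


def estimate_common_dispersion(
    matrix: pd.DataFrame, design: Mapping[str, str], size_factors: Mapping[str, float] | None = None
) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Counts are scaled to a common library size (and rounded) before
    conditioning, a quantile-adjustment surrogate that is exact when the
    size factors are equal.
    """
    sf = _size_factors(matrix.columns, size_factors)
    scaled = np.rint(matrix.to_numpy(float) / sf).astype(float)
    genos = np.array([design[c] for c in matrix.columns])
    groups = [scaled[:, genos == g] for g in np.unique(genos)]
    res = minimize_scalar(
        _cml_neg_loglik, bounds=(np.log(1e-6), np.log(10.0)), args=(groups,), method="bounded"
    )
    phi = float(np.exp(res.x))
    if phi <= 0:
        logger.warning("non-positive dispersion estimate clamped to 1e-6")
        phi = 1e-6
    return phi


def _size_factors(columns, size_factors) -> np.ndarray:
    if size_factors is None:
        return np.ones(len(columns))
    sf = np.array([size_factors[c] for c in columns], dtype=float)
    return sf / np.exp(np.mean(np.log(sf)))  # geometric-mean centred


def _exact_nb_pvalue(ya: float, yb: float, na: int, nb_: int, mu: float, phi: float) -> float:
    """Two-sided exact NB test conditional on the two group sums' total.

    Group sums of n iid NB(mu, phi) counts are NB with mean n*mu and
    dispersion phi/n. Conditional on ya + yb, the p-value sums the
    probabilities of all splits no more likely than the observed one.
    """
    s = int(round(ya + yb))
    if s == 0:
        return 1.0
    ra, rb = na / phi, nb_ / phi
    pa = ra / (ra + na * mu)
    pb = rb / (rb + nb_ * mu)
    y = np.arange(s + 1)
    with np.errstate(divide="ignore"):
        logp = nbinom.logpmf(y, ra, pa) + nbinom.logpmf(s - y, rb, pb)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[int(round(ya))]
    return float(min(1.0, p[p <= obs * (1 + 1e-10)].sum()))


@dataclass
class DiffResult:
    """Per-window differential call (mutant vs wild-type)."""

    chrom: str
    start: int
    log2fc: float
    pvalue: float
    qvalue: float = np.nan
    direction: str = ""
    passes: bool = False
    reason: str = ""


def nb_test(
    matrix: pd.DataFrame,
    design: Mapping[str, str],
    size_factors: Mapping[str, float] | None = None,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Exact NB test of genotype effect per window, common dispersion.

    Parameters
    ----------
    matrix
        Raw counts, windows x libraries (from :func:`count_windows`).
    design
        Library name -> 'wildtype' | 'mutant'.
    size_factors
        Library name -> genome-matched total (normalization denominator).
    dispersion
        Fixed common dispersion; estimated from the data when None.

    Returns
    -------
    DataFrame with log2fc (mutant vs wild-type, 0.5 pseudo-count on the
    size-factor-normalized group means), two-sided p-value, and direction.
    """
    genos = np.array([design[c] for c in matrix.columns])
    n_wt = int((genos == "wildtype").sum())
    n_mut = int((genos == "mutant").sum())
    if n_wt == 0 or n_mut == 0:
        raise ValueError("each genotype needs at least one library")
    sf = _size_factors(matrix.columns, size_factors)
    if dispersion is None:
        phi = estimate_common_dispersion(matrix, design, size_factors)
    else:
        phi = dispersion
    if phi <= 0:
        logger.warning("dispersion %g clamped to 1e-6", phi)
        phi = 1e-6

    norm = matrix.to_numpy(float) / sf
    pseudo = np.rint(norm)
    wt_mask = genos == "wildtype"
    mut_mask = ~wt_mask
    rows = []
    for i, (chrom, start) in enumerate(matrix.index):
        ya = pseudo[i, mut_mask].sum()
        yb = pseudo[i, wt_mask].sum()
        mu = (ya + yb) / (n_mut + n_wt)
        p = _exact_nb_pvalue(ya, yb, n_mut, n_wt, max(mu, 1e-12), phi)
        mut_mean = norm[i, mut_mask].mean()
        wt_mean = norm[i, wt_mask].mean()
        lfc = np.log2((mut_mean + 0.5) / (wt_mean + 0.5))
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "log2fc": lfc,
                "pvalue": p,
                "direction": "up_in_mutant" if lfc >= 0 else "down_in_mutant",
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["dispersion"] = phi
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    results: pd.DataFrame,
    min_fold: float = MIN_FOLD,
    max_q: float = MAX_Q,
    exclude: Iterable[tuple[str, int, int]] | None = None,
    window_len: int = WINDOW_LEN,
) -> pd.DataFrame:
    """Flag windows passing the fold-change and FDR thresholds.

    A window passes iff |log2fc| >= log2(min_fold), q < max_q, and it does
    not overlap an excluded interval (e.g. a mutant introgression region).
    """
    out = results.copy()
    if "qvalue" not in out.columns:
        out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    fold_ok = np.abs(out["log2fc"]) >= np.log2(min_fold)
    q_ok = out["qvalue"] < max_q
    excluded = np.zeros(len(out), dtype=bool)
    if exclude is not None:
        ex = list(exclude)
        for i, row in enumerate(out.itertuples()):
            ws, we = row.start, row.start + window_len
            excluded[i] = any(
                c == row.chrom and ws < e and s < we for c, s, e in ex
            )
    out["passes"] = fold_ok & q_ok & ~excluded
    reason = np.where(~fold_ok, "fold", np.where(~q_ok, "fdr", ""))
    out["reason"] = np.where(excluded & fold_ok & q_ok, "excluded_region", reason)
    return out


def size_class_ttest(
    totals: pd.DataFrame, design: Mapping[str, str]
) -> pd.DataFrame:
    """Welch two-sided t-test on per-library read totals, per size class.

    ``totals`` is size classes x libraries (e.g. rows 18..26). Requires at
    least two libraries per genotype.
    """
    genos = np.array([design[c] for c in totals.columns])
    wt = totals.loc[:, genos == "wildtype"].to_numpy(float)
    mut = totals.loc[:, genos == "mutant"].to_numpy(float)
    if wt.shape[1] < 2 or mut.shape[1] < 2:
        raise ValueError("need >= 2 libraries per genotype for the t-test")
    with warnings.catch_warnings():
        # constant groups are handled explicitly below
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        stat, p = ttest_ind(mut, wt, axis=1, equal_var=False)
    # both groups constant: no evidence either way
    degenerate = (wt.std(axis=1) == 0) & (mut.std(axis=1) == 0)
    equal_means = np.isclose(wt.mean(axis=1), mut.mean(axis=1))
    p = np.where(degenerate & equal_means, 1.0, p)
    stat = np.where(degenerate & equal_means, 0.0, stat)
    return pd.DataFrame({"t": stat, "pvalue": p}, index=totals.index)


def size_totals(
    records_by_library: Mapping[str, Sequence[AlignmentRecord]],
    sizes: Sequence[int] = tuple(range(18, 27)),
) -> pd.DataFrame:
    """Per-library total read counts for each read length."""
    data = {
        lib: {
            k: sum(r.copies for r in recs if r.length == k) for k in sizes
        }
        for lib, recs in records_by_library.items()
    }
    return pd.DataFrame(data).reindex(sizes).fillna(0).astype(int)
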