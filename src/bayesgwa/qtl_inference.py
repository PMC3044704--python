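"""Window statistics, bootstrap significance, PFP, and LD utilities.

Single-SNP model frequency dilutes when several SNPs tag the same QTL,
so QTL evidence is aggregated over sliding windows of 5 consecutive
mapped SNPs (step 1, never crossing a chromosome): the *window model
frequency* counts an iteration if any member SNP is in the model, and
the *window breeding-value variance* is the across-animal variance of
the window's dosage-weighted posterior mean effects, compared with the
variance of the genome-wide breeding value.

Significance of a candidate window comes from a parametric bootstrap
under the no-QTL null: replicate phenotypes are rebuilt from the
posterior means of the fixed effects and of every SNP *outside* the
window, plus fresh Gaussian residuals, and each replicate is refitted
with the same Bayes C model.  With m of N replicate window variances
strictly exceeding the observed one, the comparison-wise p-value is
reported as the interval (m/N, (m+1)/N).  Multiple testing is summarized
by the proportion of false positives (PFP).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from bayesgwa.genotype_data import MISSING, chromosome_sort_key
from bayesgwa.bayesc_engine import ModelSpec, PosteriorSummary, run_chain


class QtlError(ValueError):
    """Invalid input to a QTL-inference operation."""


@dataclass
class WindowResult:
    """One SNP window and its association statistics."""

    window_id: int
    chromosome: str
    start_idx: int  # inclusive column index into the genome-ordered panel
    end_idx: int  # exclusive
    window_freq: float | None = None
    variance: float | None = None
    proportion: float | None = None
    p_interval: tuple[float, float] | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start_idx, self.end_idx)


@dataclass
class Region:
    """Merged run of overlapping candidate windows."""

    chromosome: str
    start_idx: int
    end_idx: int
    best_window: WindowResult

    @property
    def variance(self) -> float:
        return self.best_window.variance


@dataclass
class BootstrapResult:
    """Parametric-bootstrap test of one window."""

    window: WindowResult
    observed: float
    replicates: np.ndarray
    m_exceed: int
    p_interval: tuple[float, float]

    @property
    def n_replicates(self) -> int:
        return self.replicates.size


def make_windows(
    chromosomes, size: int = 5, step: int = 1
) -> list[WindowResult]:
    """Sliding windows of ``size`` consecutive SNPs within each chromosome.

    ``chromosomes`` is the per-SNP chromosome label in panel column
    order (assumed genome-sorted; unmapped SNPs form their own trailing
    block and are windowed among themselves).  Chromosomes shorter than
    ``size`` contribute one whole-chromosome window.
    """
    chroms = [str(c) for c in chromosomes]
    if step < 1 or size < 1:
        raise QtlError("window size and step must be >= 1")
    windows: list[WindowResult] = []
    wid = 0
    start = 0
    while start < len(chroms):
        end = start
        while end < len(chroms) and chroms[end] == chroms[start]:
            end += 1
        block = range(start, max(end - size, start) + 1, step)
        for s in block:
            e = min(s + size, end)
            windows.append(WindowResult(wid, chroms[start], s, e))
            wid += 1
        start = end
    return windows


def window_model_frequency(delta_trace: np.ndarray, span: tuple[int, int]) -> float:
    """Fraction of kept iterations with >=1 included SNP in the span."""
    s, e = span
    trace = np.asarray(delta_trace, dtype=bool)
    if not 0 <= s < e <= trace.shape[1]:
        raise QtlError(f"span {span} outside trace with {trace.shape[1]} SNPs")
    return float(trace[:, s:e].any(axis=1).mean())


def breeding_values(
    Z: np.ndarray, effects: np.ndarray, span: tuple[int, int] | None = None
) -> np.ndarray:
    """Per-animal breeding value: dosage times posterior mean effect.

    With a span this is the window breeding value (WBV); with
    ``span=None`` it is the genomic breeding value (GBV) over all SNPs.
    """
    Z = np.asarray(Z, dtype=float)
    effects = np.asarray(effects, dtype=float)
    if span is None:
        return Z @ effects
    s, e = span
    return Z[:, s:e] @ effects[s:e]


def window_variance(wbv: np.ndarray) -> float:
    """Across-animal sample variance (n-1 denominator) of breeding values."""
    wbv = np.asarray(wbv, dtype=float)
    if wbv.size < 2:
        raise QtlError("window variance needs at least two animals")
    return float(wbv.var(ddof=1))


def proportion_of_gbv(wbv: np.ndarray, gbv: np.ndarray) -> float:
    """Var(WBV) / Var(GBV), the window's share of genomic variance."""
    vg = window_variance(gbv)
    if vg == 0.0:
        raise QtlError("Var(GBV) is zero; proportion undefined")
    return window_variance(wbv) / vg


def score_windows(
    summary: PosteriorSummary,
    Z: np.ndarray,
    chromosomes,
    size: int = 5,
    step: int = 1,
) -> list[WindowResult]:
    """Compute frequency, variance and GBV proportion for every window."""
    windows = make_windows(chromosomes, size=size, step=step)
    trace = summary.unpack_delta()
    gbv = breeding_values(Z, summary.effect_mean)
    vg = window_variance(gbv)
    for w in windows:
        w.window_freq = window_model_frequency(trace, w.span)
        wbv = breeding_values(Z, summary.effect_mean, w.span)
        w.variance = window_variance(wbv)
        w.proportion = w.variance / vg if vg > 0 else np.nan
    return windows


def rank_windows(results: list[WindowResult]) -> list[Region]:
    """Rank windows by variance and merge overlapping ones into regions.

    Windows are sorted by breeding-value variance descending (ties by
    genome order); a window overlapping an existing region on the same
    chromosome extends it, otherwise it opens a new region carrying the
    window as the region's best.  Regions come back ordered by their
    best window's variance.
    """
    if any(w.variance is None for w in results):
        raise QtlError("all windows must be scored before ranking")
    order = sorted(
        results, key=lambda w: (-w.variance, w.start_idx)
    )
    regions: list[Region] = []
    for w in order:
        merged = False
        for reg in regions:
            if (
                reg.chromosome == w.chromosome
                and w.start_idx < reg.end_idx
                and reg.start_idx < w.end_idx
            ):
                reg.start_idx = min(reg.start_idx, w.start_idx)
                reg.end_idx = max(reg.end_idx, w.end_idx)
                merged = True
                break
        if not merged:
            regions.append(Region(w.chromosome, w.start_idx, w.end_idx, w))
    return regions


def bootstrap_sample(
    summary: PosteriorSummary,
    X: np.ndarray | None,
    Z: np.ndarray,
    span: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """One null phenotype vector: fitted means minus the window, plus noise.

    ``y* = X b_hat + sum_{j not in span} Z_j u_hat_j + sigma_hat_e z``
    with ``z`` i.i.d. standard normal per animal -- the no-QTL-in-window
    null, everything else held at its posterior mean.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    mean = np.zeros(n)
    if X is not None and X.size:
        mean += np.asarray(X, dtype=float) @ summary.b_mean
    u = summary.effect_mean.copy()
    s, e = span
    u[s:e] = 0.0
    mean += Z @ u
    sigma_e = np.sqrt(summary.var_e_mean)
    return mean + sigma_e * rng.standard_normal(n)


def bootstrap_pvalue(
    observed: float, replicates: np.ndarray
) -> tuple[float, float]:
    """Comparison-wise p-value interval (m/N, (m+1)/N).

    ``m`` counts replicate statistics strictly exceeding the observed
    one (ties count as non-exceeding), so one exceedance in 1,000
    replicates reports 0.001 < p < 0.002.  When every replicate exceeds
    the observed value the interval is clamped to ((N-1)/N, 1).
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.size == 0:
        raise QtlError("bootstrap p-value needs at least one replicate")
    m = int((reps > observed).sum())
    n = reps.size
    return (min(m, n - 1) / n, min(m + 1, n) / n)


def bootstrap_window_test(
    summary: PosteriorSummary,
    X: np.ndarray | None,
    Z: np.ndarray,
    window: WindowResult,
    n_replicates: int = 100,
    seed: int = 0,
    spec: ModelSpec | None = None,
) -> BootstrapResult:
    """Parametric-bootstrap significance of one window's variance.

    Each replicate phenotype from :func:`bootstrap_sample` is refitted
    with the same Bayes C model (window SNPs retained in the mixture;
    chain seeds derived per replicate from ``seed``), and the window's
    breeding-value variance is extracted.  The observed statistic is the
    window variance of the original fit.
    """
    spec = spec if spec is not None else summary.spec
    Z = np.asarray(Z, dtype=float)
    span = window.span
    observed = window_variance(breeding_values(Z, summary.effect_mean, span))
    rng = np.random.default_rng(seed)
    reps = np.empty(n_replicates)
    for i in range(n_replicates):
        y_star = bootstrap_sample(summary, X, Z, span, rng)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rep_fit = run_chain(y_star, X, Z, replace(spec, seed=rep_seed))
        reps[i] = window_variance(breeding_values(Z, rep_fit.effect_mean, span))
    m = int((reps > observed).sum())
    result = BootstrapResult(
        window=window,
        observed=observed,
        replicates=reps,
        m_exceed=m,
        p_interval=bootstrap_pvalue(observed, reps),
    )
    window.p_interval = result.p_interval
    return result


def pfp(alpha: float, power: float, pi0_null_fraction: float) -> float:
    """Proportion of false positives among declared positives.

    ``PFP = pi0 * alpha / (pi0 * alpha + (1 - pi0) * power)`` -- the
    expected share of significant windows that are true nulls, given the
    comparison-wise threshold ``alpha``, the power to detect a real QTL,
    and the fraction ``pi0`` of windows with no QTL.
    """
    for name, v in (("alpha", alpha), ("power", power), ("pi0", pi0_null_fraction)):
        if not 0.0 < v <= 1.0:
            raise QtlError(f"{name}={v} outside (0, 1]")
    denom = pi0_null_fraction * alpha + (1.0 - pi0_null_fraction) * power
    if denom <= 0.0:
        raise QtlError("degenerate denominator in PFP")
    return pi0_null_fraction * alpha / denom


def ld_r2(snp_a: np.ndarray, snp_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns (composite LD)."""
    a = np.asarray(snp_a, dtype=float)
    b = np.asarray(snp_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        raise QtlError("fewer than two jointly called animals")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise QtlError("zero-variance SNP; r^2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def place_unmapped(
    unmapped_calls: np.ndarray,
    mapped_calls: np.ndarray,
    mapped_meta: pd.DataFrame,
) -> dict:
    """Deduce an unmapped SNP's likely position from LD with mapped SNPs.

    Returns the mapped SNP with maximal r-squared against the unmapped
    column, with its chromosome, position and the r-squared value.
    Mapped SNPs with undefined r-squared (e.g. monomorphic) are skipped.
    """
    mapped_calls = np.asarray(mapped_calls)
    best_j, best_r2 = -1, -1.0
    for j in range(mapped_calls.shape[1]):
        try:
            r2 = ld_r2(unmapped_calls, mapped_calls[:, j])
        except QtlError:
            continue
        if r2 > best_r2:
            best_j, best_r2 = j, r2
    if best_j < 0:
        raise QtlError("no mapped SNP with defined r^2")
    row = mapped_meta.iloc[best_j]
    return {
        "snp_id": row["snp_id"],
        "chromosome": row["chromosome"],
        "position_bp": None if pd.isna(row["position_bp"]) else int(row["position_bp"]),
        "r2": best_r2,
    }


def windows_to_tsv(
    windows: list[WindowResult], snps: pd.DataFrame, path: str | Path
) -> None:
    """Write scored windows as TSV (1-based inclusive bp coordinates)."""
    rows = []
    for w in windows:
        sub = snps.iloc[w.start_idx : w.end_idx]
        bp = sub["position_bp"]
        lo, hi = w.p_interval if w.p_interval else (np.nan, np.nan)
        rows.append(
            {
                "window_id": w.window_id,
                "chrom": w.chromosome,
                "start_bp": bp.min() if bp.notna().any() else np.nan,
                "end_bp": bp.max() if bp.notna().any() else np.nan,
                "snp_ids": ",".join(sub["snp_id"]),
                "window_freq": w.window_freq,
                "variance": w.variance,
                "proportion": w.proportion,
                "p_low": lo,
                "p_high": hi,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def regions_to_bed(
    regions: list[Region], snps: pd.DataFrame, path: str | Path
) -> None:
    """Write merged regions as BED (0-based half-open, sorted by genome)."""
    rows = []
    for reg in regions:
        sub = snps.iloc[reg.start_idx : reg.end_idx]
        bp = sub["position_bp"].dropna()
        if bp.empty:
            continue
        rows.append((reg.chromosome, int(bp.min()) - 1, int(bp.max()), reg.variance))
    rows.sort(key=lambda r: (chromosome_sort_key(r[0]), r[1]))
    with open(path, "w") as fh:
        for chrom, s, e, v in rows:
            fh.write(f"{chrom}\t{s}\t{e}\twindow_variance={v:.6g}\n")
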