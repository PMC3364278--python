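"""Per-subject and cohort analysis pipelines.

``analyze_subject`` runs the full single-record workflow: greedy mixture fit
on the per-beat bpm values, uniform resampling, Welch spectrum, VLF/LF/HF
band powers and the log-log spectral slope.  ``cohort_analysis`` aggregates
subject results: rank-aligned averages of the mixture parameters (components
sorted by decreasing weight, rank 1 = largest), the average spectral slope,
and the correlation across subjects between the rank-k component variances
and the band powers — the quantity that links mixture structure to
sympathetic (LF) and parasympathetic (HF) modulation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mixture import (
    DEFAULT_DOMINANCE_THRESHOLD,
    GaussianMixture,
    sample_mixture,
)
from .model import HeartRateMixture, HeartRateMixtureResults
from .series import HeartRateSeries
from .spectral import (
    DEFAULT_BANDS,
    DEFAULT_RESAMPLE_HZ,
    DEFAULT_SLOPE_RANGE,
    BandPowers,
    SlopeFit,
    band_powers,
    fit_loglog_slope,
    power_spectrum,
    resample_uniform,
)

__all__ = [
    "AnalysisConfig",
    "SubjectResult",
    "CohortSummary",
    "analyze_subject",
    "cohort_analysis",
    "generate_from_fit",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the per-subject pipeline, with field-standard defaults."""

    k_max: int = 15
    tol: float = 1e-5
    dominance_threshold: float = DEFAULT_DOMINANCE_THRESHOLD
    seed: Optional[int] = None
    resample_hz: float = DEFAULT_RESAMPLE_HZ
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    slope_range: tuple[float, float] = DEFAULT_SLOPE_RANGE
    segment_length: Optional[int] = None
    min_samples: int = 1000


@dataclass
class SubjectResult:
    """Everything the cohort stage needs about one record."""

    subject_id: str
    results: HeartRateMixtureResults
    bands: BandPowers
    slope: Optional[SlopeFit]
    n_samples: int
    mean_bpm: float
    var_bpm: float

    @property
    def mixture(self) -> GaussianMixture:
        return self.results.mixture

    @property
    def n_dominant(self) -> int:
        return self.results.n_dominant


@dataclass
class CohortSummary:
    """Rank-aligned cohort averages and the variance-band correlation table."""

    n_subjects: int
    rank_table: pd.DataFrame
    correlations: pd.DataFrame
    mean_slope: Optional[float]
    se_slope: Optional[float]
    n_excluded_from_correlations: int
    dominant_counts: dict[int, int]

    @property
    def modal_dominant_count(self) -> int:
        """Most frequent number of dominant components across subjects."""
        return max(self.dominant_counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]

    def to_json(self, path) -> None:
        doc = {
            "n_subjects": self.n_subjects,
            "rank_table": self.rank_table.reset_index().to_dict(orient="records"),
            "correlations": self.correlations.reset_index().to_dict(orient="records"),
            "mean_slope": self.mean_slope,
            "se_slope": self.se_slope,
            "n_excluded_from_correlations": self.n_excluded_from_correlations,
            "dominant_counts": {str(k): v for k, v in self.dominant_counts.items()},
            "modal_dominant_count": self.modal_dominant_count,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, default=float)


def analyze_subject(
    hr: HeartRateSeries,
    config: Optional[AnalysisConfig] = None,
    subject_id: str = "subject",
) -> SubjectResult:
    """Fit the mixture and compute spectral summaries for one record."""
    config = config or AnalysisConfig()
    if len(hr) < config.min_samples:
        raise ValueError(
            f"{subject_id}: series has {len(hr)} samples, "
            f"need at least {config.min_samples}"
        )
    try:
        res = HeartRateMixture.from_series(hr).fit(
            k_max=config.k_max,
            tol=config.tol,
            seed=config.seed,
            dominance_threshold=config.dominance_threshold,
        )
        uniform = resample_uniform(hr, fs=config.resample_hz)
        ps = power_spectrum(uniform, segment_length=config.segment_length)
        bands = band_powers(ps, config.bands)
        try:
            slope = fit_loglog_slope(ps, *config.slope_range)
        except ValueError:
            logger.info("%s: slope fit skipped (too few usable points)", subject_id)
            slope = None
    except ValueError as exc:
        raise ValueError(f"{subject_id}: {exc}") from exc
    logger.info(
        "%s: K=%d dominant=%d loglik=%.2f stop=%s",
        subject_id, res.k, res.n_dominant, res.llf, res.trace.stopping_reason,
    )
    return SubjectResult(
        subject_id=subject_id,
        results=res,
        bands=bands,
        slope=slope,
        n_samples=len(hr),
        mean_bpm=float(hr.values.mean()),
        var_bpm=float(hr.values.var()),
    )


def _rank_frame(results: Sequence[SubjectResult], max_rank: int) -> pd.DataFrame:
    """Long table (subject, rank, weight, mean, variance) over fitted components."""
    rows = []
    for r in results:
        for rank, comp in enumerate(r.mixture.components, start=1):
            if rank > max_rank:
                break
            rows.append(
                {
                    "subject": r.subject_id,
                    "rank": rank,
                    "weight": comp.weight,
                    "mean": comp.mean,
                    "variance": comp.variance,
                }
            )
    return pd.DataFrame(rows)


def cohort_analysis(
    results: Sequence[SubjectResult],
    correlation: Literal["pearson", "spearman", "both"] = "both",
    max_rank: int = 6,
) -> CohortSummary:
    """Aggregate subject fits into rank-wise averages and correlation tables.

    The rank table reports, per weight rank, the cross-subject average and
    standard error of the mean of weight, mean and variance.  The correlation
    table crosses the variances of the first three ranks with the VLF/LF/HF
    band powers; only subjects with at least three dominant components enter,
    and unadjusted as well as Holm-adjusted p-values are reported.
    """
    if len(results) < 3:
        raise ValueError("cohort analysis needs at least 3 subjects")
    long = _rank_frame(results, max_rank)
    grouped = long.groupby("rank")[["weight", "mean", "variance"]]
    mean_tbl = grouped.mean()
    sem_tbl = grouped.sem(ddof=1)
    count = grouped.size()
    rank_table = pd.concat(
        {"mean": mean_tbl, "sem": sem_tbl}, axis=1
    ).swaplevel(axis=1).sort_index(axis=1)
    rank_table["n_subjects"] = count

    # correlations: rank-k variance vs band power, subjects with >= 3 dominant
    eligible = [r for r in results if r.n_dominant >= 3 and r.mixture.k >= 3]
    excluded = len(results) - len(eligible)
    if excluded:
        logger.info("cohort: %d subject(s) excluded from correlations", excluded)
    corr_rows = []
    if len(eligible) >= 3:
        var_cols = {
            k: np.array([r.mixture.components[k - 1].variance for r in eligible])
            for k in (1, 2, 3)
        }
        band_cols = {
            "vlf": np.array([r.bands.vlf for r in eligible]),
            "lf": np.array([r.bands.lf for r in eligible]),
            "hf": np.array([r.bands.hf for r in eligible]),
        }
        methods = ("pearson", "spearman") if correlation == "both" else (correlation,)
        for method in methods:
            cells = []
            for k, v in var_cols.items():
                for band, bp in band_cols.items():
                    if np.std(v) == 0 or np.std(bp) == 0:
                        r_val, p_val = np.nan, np.nan
                    elif method == "pearson":
                        r_val, p_val = stats.pearsonr(v, bp)
                    else:
                        r_val, p_val = stats.spearmanr(v, bp)
                    cells.append((method, k, band, r_val, p_val))
            pvals = np.array([c[4] for c in cells])
            finite = np.isfinite(pvals)
            holm = np.full_like(pvals, np.nan)
            if finite.any():
                holm[finite] = _holm(pvals[finite])
            for (method_, k, band, r_val, p_val), p_h in zip(cells, holm):
                corr_rows.append(
                    {
                        "method": method_,
                        "variance_rank": k,
                        "band": band,
                        "r": r_val,
                        "p": p_val,
                        "p_holm": p_h,
                        "n": len(eligible),
                    }
                )
    correlations = pd.DataFrame(
        corr_rows, columns=["method", "variance_rank", "band", "r", "p", "p_holm", "n"]
    ).set_index(["method", "variance_rank", "band"]) if corr_rows else pd.DataFrame(
        columns=["method", "variance_rank", "band", "r", "p", "p_holm", "n"]
    ).set_index(["method", "variance_rank", "band"])

    slopes = np.array([r.slope.beta for r in results if r.slope is not None])
    mean_slope = float(slopes.mean()) if slopes.size else None
    se_slope = float(slopes.std(ddof=1) / np.sqrt(slopes.size)) if slopes.size > 1 else None

    counts: dict[int, int] = {}
    for r in results:
        counts[r.n_dominant] = counts.get(r.n_dominant, 0) + 1
    return CohortSummary(
        n_subjects=len(results),
        rank_table=rank_table,
        correlations=correlations,
        mean_slope=mean_slope,
        se_slope=se_slope,
        n_excluded_from_correlations=excluded,
        dominant_counts=counts,
    )


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (via statsmodels when available)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="holm")[1]


def generate_from_fit(
    m: GaussianMixture, n: int, seed: Optional[int] = None, fs: float = 1.0
) -> HeartRateSeries:
    """Generative i.i.d. sampling from a (typically dominant, renormalized)
    mixture, packaged as a series on a uniform nominal time axis at ``fs`` Hz.

    The samples are independent draws from the marginal: the procedure
    reproduces the amplitude distribution of the record, not its temporal
    ordering.
    """
    values, _ = sample_mixture(m, n, seed=seed)
    # a physical series must be positive; clip the negligible negative mass
    values = np.maximum(values, np.finfo(float).tiny)
    times = np.arange(n) / fs
    return HeartRateSeries(times=times, values=values)
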