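"""Quality control for targeted bisulfite-sequencing count data.

QC runs sample-first, then site-wise over the retained samples:

* a sample is dropped when its bisulfite conversion rate (estimated
  from non-CpG cytosine counts) is below 98%, or when more than 30% of
  its sites have zero coverage;
* a site is kept when its mean coverage over retained samples exceeds
  20x and at most 20% of retained samples lack coverage at it.

Site statistics are computed over retained samples only, so an excluded
sample cannot penalise a site.  Every excluded sample or site carries
exactly one primary exclusion reason (conversion is checked before
missingness).  Re-running QC on its own output changes nothing
(idempotence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientEvidenceError, StratumError
from .simulate import CountTable

DEFAULT_MIN_CONVERSION = 0.98
DEFAULT_MAX_SAMPLE_MISSING = 0.30
DEFAULT_MIN_MEAN_COVERAGE = 20.0
DEFAULT_MAX_SITE_MISSING = 0.20


@dataclass
class QCReport:
    """Per-sample and per-site QC statistics plus retention decisions."""

    sample_stats: pd.DataFrame = None   # conversion_rate, missing_rate, retained, reason
    site_stats: pd.DataFrame = None     # mean_coverage, missing_rate, retained, reason
    retained_samples: list[str] = field(default_factory=list)
    retained_sites: list[tuple] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "thresholds": self.thresholds,
            "retained_samples": self.retained_samples,
            "retained_sites": [list(s) for s in self.retained_sites],
            "samples": {
                str(s): {
                    "conversion_rate": float(r.conversion_rate),
                    "missing_rate": float(r.missing_rate),
                    "retained": bool(r.retained),
                    "reason": r.reason,
                }
                for s, r in self.sample_stats.iterrows()
            },
            "sites": {
                f"{c}:{p}": {
                    "mean_coverage": float(r.mean_coverage),
                    "missing_rate": float(r.missing_rate),
                    "retained": bool(r.retained),
                    "reason": r.reason,
                }
                for (c, p), r in self.site_stats.iterrows()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def estimate_conversion_rate(non_cpg_converted: int, non_cpg_total: int) -> float:
    """Fraction of non-CpG cytosines read as converted (C-to-T)."""
    if non_cpg_total <= 0:
        raise InsufficientEvidenceError(
            "no non-CpG cytosine counts to estimate conversion from")
    if non_cpg_converted > non_cpg_total or non_cpg_converted < 0:
        raise InsufficientEvidenceError(
            "converted count must lie in [0, total]")
    return non_cpg_converted / non_cpg_total


def qc_samples(
    table: CountTable,
    min_conversion: float = DEFAULT_MIN_CONVERSION,
    max_sample_missing: float = DEFAULT_MAX_SAMPLE_MISSING,
) -> tuple[list[str], pd.DataFrame]:
    """Drop samples with conversion < 98% or missing rate > 30% (strict).

    A site is missing for a sample when its total count is zero.
    Returns (retained sample ids, per-sample stats table).
    """
    samples = list(table.total.columns)
    conv = np.array([
        estimate_conversion_rate(int(table.conversion.loc[s, "converted"]),
                                 int(table.conversion.loc[s, "total"]))
        for s in samples
    ])
    missing = (table.total == 0).mean(axis=0).to_numpy()

    retained, reasons = [], []
    for c, m in zip(conv, missing):
        if c < min_conversion:
            retained.append(False)
            reasons.append("conversion")
        elif m > max_sample_missing:
            retained.append(False)
            reasons.append("missingness")
        else:
            retained.append(True)
            reasons.append("")
    stats = pd.DataFrame(
        {
            "conversion_rate": conv,
            "missing_rate": missing,
            "retained": retained,
            "reason": reasons,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    kept = [s for s, r in zip(samples, retained) if r]
    return kept, stats


def qc_sites(
    table: CountTable,
    retained_samples: list[str],
    min_mean_coverage: float = DEFAULT_MIN_MEAN_COVERAGE,
    max_site_missing: float = DEFAULT_MAX_SITE_MISSING,
) -> tuple[list[tuple], pd.DataFrame]:
    """Keep sites with mean coverage > 20x (strict) and missing rate <= 20%.

    Statistics are computed over the retained samples only.
    """
    if not retained_samples:
        raise StratumError("no retained samples to compute site QC over")
    total = table.total[retained_samples]
    mean_cov = total.mean(axis=1).to_numpy()
    missing = (total == 0).mean(axis=1).to_numpy()

    retained, reasons = [], []
    for cov, m in zip(mean_cov, missing):
        if not cov > min_mean_coverage:
            retained.append(False)
            reasons.append("coverage")
        elif m > max_site_missing:
            retained.append(False)
            reasons.append("missingness")
        else:
            retained.append(True)
            reasons.append("")
    stats = pd.DataFrame(
        {
            "mean_coverage": mean_cov,
            "missing_rate": missing,
            "retained": retained,
            "reason": reasons,
        },
        index=table.total.index,
    )
    kept = [site for site, r in zip(table.total.index, retained) if r]
    return kept, stats


def run_qc(
    table: CountTable,
    min_conversion: float = DEFAULT_MIN_CONVERSION,
    max_sample_missing: float = DEFAULT_MAX_SAMPLE_MISSING,
    min_mean_coverage: float = DEFAULT_MIN_MEAN_COVERAGE,
    max_site_missing: float = DEFAULT_MAX_SITE_MISSING,
) -> tuple[CountTable, QCReport]:
    """Sample-then-site QC; returns the filtered table and a full report."""
    kept_samples, sample_stats = qc_samples(
        table, min_conversion, max_sample_missing)
    kept_sites, site_stats = qc_sites(
        table, kept_samples, min_mean_coverage, max_site_missing)

    filtered = CountTable(
        meth=table.meth.loc[kept_sites, kept_samples].copy(),
        total=table.total.loc[kept_sites, kept_samples].copy(),
        conversion=table.conversion.loc[kept_samples].copy(),
    )
    report = QCReport(
        sample_stats=sample_stats,
        site_stats=site_stats,
        retained_samples=kept_samples,
        retained_sites=[tuple(s) for s in kept_sites],
        thresholds={
            "min_conversion": min_conversion,
            "max_sample_missing": max_sample_missing,
            "min_mean_coverage": min_mean_coverage,
            "max_site_missing": max_site_missing,
        },
    )
    return filtered, report


def site_fractions(table: CountTable) -> pd.DataFrame:
    """Per-site per-sample methylation fractions; zero-total entries are NaN."""
    total = table.total.to_numpy(dtype=float)
    meth = table.meth.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, meth / np.where(total > 0, total, 1), np.nan)
    return pd.DataFrame(frac, index=table.total.index,
                        columns=table.total.columns)
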