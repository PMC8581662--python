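"""Methylation-region construction and the DMR filter cascade.

A methylation region (MR) is a window of consecutive CpG sites on one
chromosome containing at least ``min_sites`` sites within a span of less
than ``max_span`` base pairs (defaults: 6 sites, 1,000 bp — methylation
linkage decays beyond ~1 kb).  :func:`find_methylation_regions` returns
every *containment-maximal* such window via a two-pointer sweep; windows
contained in a larger qualifying window are redundant for region-level
means and are not emitted.

Candidate differentially methylated regions (DMRs) are then selected by
a cascade of filters:

1. Wilcoxon rank-sum test, tumors vs para-tumor controls, per region,
   with Benjamini–Hochberg FDR correction across regions.
2. Group-mean thresholds: McaM > 0.50 (tumors), MadM > 0.50 (adenomas)
   and McoM < 0.30 (para-tumors), strict inequalities.
3. Blood-leakage filter: region mean < 0.10 in the whole-blood, PBMC
   and PBL reference compartments (all three by default; a disjunctive
   mode is available), so that circulating-DNA assays are not confounded
   by blood-derived methylation.
4. Per-gene selection: one region per gene, the one with the smallest
   FDR (ties: larger McaM − McoM, then leftmost).
5. Expression-correlation filter: region methylation must correlate
   negatively (Spearman, BH-adjusted one-sided p < 0.05) with the
   expression of its own gene, the signature of silencing-associated
   promoter hypermethylation.

Coordinates are 1-based inclusive throughout; chromosome names are
accepted with or without a ``chr`` prefix and emitted without it.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    CoverageError,
    InputError,
    OrderingError,
    StratumError,
)
from .simulate import GROUP_ADENOMA, GROUP_CONTROL, GROUP_TUMOR, BetaMatrix

DEFAULT_MIN_SITES = 6
DEFAULT_MAX_SPAN = 1000
DEFAULT_MCA_MIN = 0.50
DEFAULT_MAD_MIN = 0.50
DEFAULT_MCO_MAX = 0.30
DEFAULT_BLOOD_MAX = 0.10


def normalize_chrom(chrom: str) -> str:
    return str(chrom).removeprefix("chr")


def _chrom_sort_key(chrom: str):
    c = normalize_chrom(chrom)
    return (0, int(c)) if c.isdigit() else (1, c)


@dataclass(frozen=True)
class MethylationRegion:
    """A window of consecutive CpG sites (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    site_ids: tuple[str, ...]
    gene: str = ""

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def region_string(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def __repr__(self):
        return (f"MethylationRegion({self.region_string}, "
                f"{self.n_sites} sites, gene={self.gene!r})")


@dataclass
class DMRRecord:
    """A methylation region with its group summaries and filter state."""

    region: MethylationRegion
    mcam: float = np.nan            # mean methylation, cases (tumors)
    madm: float = np.nan            # mean methylation, adenomas
    mcom: float = np.nan            # mean methylation, controls (para-tumors)
    blood_means: dict[str, float] = field(default_factory=dict)
    p_value: float = np.nan
    fdr: float = np.nan
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    passes_thresholds: bool = False
    passes_blood: bool = False
    selected_per_gene: bool = False
    passes_expression: bool = False


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check manifest schema and (chrom, pos) ordering; returns the input."""
    required = {"site_id", "chrom", "pos", "gene"}
    missing = required - set(manifest.columns)
    if missing:
        raise OrderingError(f"manifest missing columns: {sorted(missing)}")
    if manifest.empty:
        return manifest
    if (manifest["pos"] <= 0).any():
        raise OrderingError("manifest positions must be positive")
    if manifest["site_id"].duplicated().any():
        raise OrderingError("manifest site_ids must be unique")
    chroms = manifest["chrom"].map(normalize_chrom)
    keys = list(zip(chroms.map(_chrom_sort_key), manifest["pos"]))
    if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
        raise OrderingError("manifest is not sorted by (chrom, pos)")
    return manifest


def find_methylation_regions(
    manifest: pd.DataFrame,
    min_sites: int = DEFAULT_MIN_SITES,
    max_span: int = DEFAULT_MAX_SPAN,
    gene_filter: set[str] | None = None,
) -> list[MethylationRegion]:
    """Containment-maximal CpG windows with >= min_sites sites, span < max_span.

    The manifest must be sorted by (chrom, pos).  When ``gene_filter`` is
    given, the manifest is first restricted to sites of those genes and
    windows are built over the remaining consecutive sites.  Each
    region's gene label is the most frequent non-empty gene among its
    member sites (ties: first in coordinate order).
    """
    if min_sites < 2:
        raise InputError("min_sites must be >= 2")
    if max_span <= 0:
        raise InputError("max_span must be positive")
    validate_manifest(manifest)
    if manifest.empty:
        return []
    if gene_filter is not None:
        manifest = manifest[manifest["gene"].isin(gene_filter)]
        if manifest.empty:
            return []

    regions: list[MethylationRegion] = []
    chroms = manifest["chrom"].map(normalize_chrom)
    for chrom, block in manifest.groupby(chroms, sort=False):
        pos = block["pos"].to_numpy()
        ids = block["site_id"].to_numpy()
        genes = block["gene"].to_numpy()
        n = len(pos)
        j_prev = -1
        j = 0
        for i in range(n):
            j = max(j, i)
            while j + 1 < n and pos[j + 1] - pos[i] < max_span:
                j += 1
            # maximal to the right by construction; maximal to the left
            # iff the previous start could not reach this right edge
            if j - i + 1 >= min_sites and j > j_prev:
                members = ids[i:j + 1]
                member_genes = [g for g in genes[i:j + 1] if g]
                gene = ""
                if member_genes:
                    counts = Counter(member_genes)
                    top = max(counts.values())
                    gene = next(g for g in member_genes if counts[g] == top)
                regions.append(MethylationRegion(
                    chrom=chrom, start=int(pos[i]), end=int(pos[j]),
                    site_ids=tuple(members), gene=gene))
                j_prev = j
    regions.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.start, r.end))
    return regions


def region_mean(values, region: MethylationRegion,
                samples=None) -> pd.Series:
    """Per-sample mean methylation over a region's non-missing member sites.

    ``values`` is a sites x samples DataFrame (or a :class:`BetaMatrix`).
    A sample with every member site missing yields NaN.
    """
    if isinstance(values, BetaMatrix):
        values = values.values
    present = [s for s in region.site_ids if s in values.index]
    if not present:
        raise CoverageError(
            f"no member sites of {region.region_string} present in the matrix")
    block = values.loc[present]
    if samples is not None:
        block = block[list(samples)]
    return block.mean(axis=0, skipna=True)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact enumeration for combined n <= 12 without ties; otherwise the
    normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("wilcoxon_rank_sum requires non-empty samples")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == combined.size
    method = "exact" if (combined.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_differential(
    regions: list[MethylationRegion],
    betas: BetaMatrix,
) -> list[DMRRecord]:
    """Per-region group means, Wilcoxon case-vs-control p, and BH FDR.

    Requires >= 2 tumor and >= 2 para-tumor samples; adenomas are
    optional (MadM is NaN without them, which blocks the threshold
    filter's MadM clause).
    """
    cases = betas.samples_in(GROUP_TUMOR)
    controls = betas.samples_in(GROUP_CONTROL)
    adenomas = betas.samples_in(GROUP_ADENOMA)
    if len(cases) < 2 or len(controls) < 2:
        raise StratumError(
            f"need >= 2 cases and >= 2 controls, got {len(cases)} / "
            f"{len(controls)}")

    records = []
    for region in regions:
        means = region_mean(betas.values, region)
        case_m = means[cases].dropna()
        ctrl_m = means[controls].dropna()
        rec = DMRRecord(
            region=region,
            mcam=float(case_m.mean()),
            madm=float(means[adenomas].dropna().mean()) if adenomas else np.nan,
            mcom=float(ctrl_m.mean()),
            p_value=wilcoxon_rank_sum(case_m, ctrl_m),
        )
        records.append(rec)
    if records:
        fdrs = bh_adjust([r.p_value for r in records])
        for rec, fdr in zip(records, fdrs):
            rec.fdr = float(fdr)
    return records


def filter_thresholds(
    records: list[DMRRecord],
    mca_min: float = DEFAULT_MCA_MIN,
    mad_min: float = DEFAULT_MAD_MIN,
    mco_max: float = DEFAULT_MCO_MAX,
) -> list[DMRRecord]:
    """Keep records with McaM > mca_min, MadM > mad_min, McoM < mco_max.

    All inequalities strict.  A record with no adenoma mean (NaN MadM)
    cannot pass.
    """
    out = []
    for rec in records:
        ok = (rec.mcam > mca_min
              and not np.isnan(rec.madm) and rec.madm > mad_min
              and rec.mcom < mco_max)
        rec.passes_thresholds = bool(ok)
        if ok:
            out.append(rec)
    return out


def filter_blood(
    records: list[DMRRecord],
    blood: BetaMatrix,
    max_blood: float = DEFAULT_BLOOD_MAX,
    mode: str = "all",
) -> list[DMRRecord]:
    """Keep regions lowly methylated in blood reference compartments.

    ``mode='all'`` (default) requires mean < ``max_blood`` in every one
    of WB, PBMC and PBL; ``mode='any'`` requires it in at least one.
    """
    if mode not in ("all", "any"):
        raise InputError(f"mode must be 'all' or 'any', got {mode!r}")
    compartments = ("WB", "PBMC", "PBL")
    present = set(blood.groups.unique())
    missing = [c for c in compartments if c not in present]
    if missing:
        raise InputError(f"blood matrix missing compartments: {missing}")
    out = []
    for rec in records:
        means = {}
        for comp in compartments:
            samples = blood.samples_in(comp)
            means[comp] = float(
                region_mean(blood.values, rec.region, samples).mean())
        rec.blood_means = means
        flags = [m < max_blood for m in means.values()]
        ok = all(flags) if mode == "all" else any(flags)
        rec.passes_blood = bool(ok)
        if ok:
            out.append(rec)
    return out


def select_per_gene(records: list[DMRRecord]) -> list[DMRRecord]:
    """Keep at most one record per gene: smallest FDR, ties broken by
    larger McaM − McoM, then leftmost coordinate.  Records without a
    gene label are kept as singletons."""
    by_gene: dict[object, list[DMRRecord]] = {}
    for i, rec in enumerate(records):
        key = rec.region.gene if rec.region.gene else ("", i)
        by_gene.setdefault(key, []).append(rec)

    out = []
    for group in by_gene.values():
        best = min(
            group,
            key=lambda r: (
                r.fdr,
                -(r.mcam - r.mcom),
                _chrom_sort_key(r.region.chrom),
                r.region.start,
            ),
        )
        for rec in group:
            rec.selected_per_gene = rec is best
        out.append(best)
    out.sort(key=lambda r: (_chrom_sort_key(r.region.chrom), r.region.start))
    return out


def filter_expression_correlation(
    records: list[DMRRecord],
    betas: BetaMatrix,
    expression: pd.DataFrame,
    fdr_max: float = 0.05,
) -> list[DMRRecord]:
    """Keep regions whose methylation anticorrelates with own-gene expression.

    Spearman correlation between per-sample region methylation and the
    expression of the region's gene, over the samples shared by both
    matrices.  Survivors have negative rho with BH-adjusted one-sided
    (negative-alternative) p < ``fdr_max``.  Records whose gene is
    absent from the expression matrix are skipped with a warning.
    """
    shared = [s for s in betas.values.columns if s in expression.columns]
    if len(shared) < 3:
        raise InputError("need >= 3 paired methylation/expression samples")

    tested, rhos, pvals = [], [], []
    for rec in records:
        gene = rec.region.gene
        if not gene or gene not in expression.index:
            warnings.warn(
                f"gene {gene!r} absent from expression matrix; region "
                f"{rec.region.region_string} skipped by expression filter",
                stacklevel=2,
            )
            rec.passes_expression = False
            continue
        meth = region_mean(betas.values, rec.region, shared)
        expr = expression.loc[gene, shared]
        mask = meth.notna() & expr.notna()
        if mask.sum() < 3:
            rec.passes_expression = False
            continue
        rho, p = stats.spearmanr(meth[mask], expr[mask],
                                 alternative="less")
        tested.append(rec)
        rhos.append(rho)
        pvals.append(p)

    out = []
    if tested:
        fdrs = bh_adjust(pvals)
        for rec, rho, fdr in zip(tested, rhos, fdrs):
            ok = rho < 0 and fdr < fdr_max
            rec.passes_expression = bool(ok)
            if ok:
                out.append(rec)
    return out


def run_cascade(
    manifest: pd.DataFrame,
    betas: BetaMatrix,
    blood: BetaMatrix | None = None,
    expression: pd.DataFrame | None = None,
    min_sites: int = DEFAULT_MIN_SITES,
    max_span: int = DEFAULT_MAX_SPAN,
    gene_filter: set[str] | None = None,
    mca_min: float = DEFAULT_MCA_MIN,
    mad_min: float = DEFAULT_MAD_MIN,
    mco_max: float = DEFAULT_MCO_MAX,
    blood_max: float = DEFAULT_BLOOD_MAX,
    blood_mode: str = "all",
    expression_fdr_max: float = 0.05,
) -> dict:
    """Run the full discovery cascade; returns stage outputs and counts.

    Stages without the data they need (no blood matrix, no expression
    matrix) are pass-through, so the cascade degrades gracefully on
    partial inputs.
    """
    regions = find_methylation_regions(manifest, min_sites, max_span,
                                       gene_filter)
    records = test_differential(regions, betas)
    after_thresholds = filter_thresholds(records, mca_min, mad_min, mco_max)
    if blood is not None:
        after_blood = filter_blood(after_thresholds, blood, blood_max,
                                   blood_mode)
    else:
        after_blood = after_thresholds
        for rec in after_blood:
            rec.passes_blood = True
    after_gene = select_per_gene(after_blood)
    if expression is not None:
        survivors = filter_expression_correlation(
            after_gene, betas, expression, expression_fdr_max)
    else:
        survivors = after_gene
        for rec in survivors:
            rec.passes_expression = True
    return {
        "regions": regions,
        "records": records,
        "after_thresholds": after_thresholds,
        "after_blood": after_blood,
        "after_gene": after_gene,
        "survivors": survivors,
        "counts": {
            "regions": len(regions),
            "tested": len(records),
            "after_thresholds": len(after_thresholds),
            "after_blood": len(after_blood),
            "after_gene": len(after_gene),
            "survivors": len(survivors),
        },
    }
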