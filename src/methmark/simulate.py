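"""Synthetic methylation cohorts with known planted truth.

Two kinds of data are emulated, mirroring the two arms of a tissue
biomarker study:

* **Array-style discovery cohorts** — a CpG manifest plus a beta-value
  matrix (sites x samples, fractions in [0,1]) for tumor, adenoma and
  para-tumor (adjacent normal) tissue, and a separate blood reference
  (whole blood / PBMC / PBL).  Background CpGs are lowly methylated in
  every group; planted regions are hypermethylated in tumors and
  adenomas only.

* **Targeted bisulfite-sequencing replication cohorts** — per-CpG
  (methylated, total) read counts for paired tumor / para-tumor samples,
  with negative-binomial coverage, binomial methylated counts observed
  through an imperfect bisulfite conversion, and per-sample non-CpG
  cytosine counts as conversion-rate evidence.

Tumor heterogeneity is modelled through KRAS mutation status: KRAS+
tumors are uniformly hypermethylated at the panel regions, while KRAS-
tumors are a two-component mixture of hypermethylated and control-like
epigenomes.  This mixture is what produces the KRAS+ vs KRAS- gap in
downstream diagnostic performance.

Beta values are drawn from Beta distributions parameterised by mean
``m`` and precision ``k`` (shape parameters ``m*k`` and ``(1-m)*k``),
which matches the bounded, overdispersed character of methylation
fractions.  All outputs are deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError

GROUP_TUMOR = "tumor"
GROUP_ADENOMA = "adenoma"
GROUP_CONTROL = "para-tumor"
BLOOD_COMPARTMENTS = ("WB", "PBMC", "PBL")

#: latent per-tumor epigenetic states
STATE_HYPER = "hypermethylated"
STATE_CONTROL_LIKE = "control-like"


@dataclass(frozen=True)
class PlantedRegionSpec:
    """A region to plant into the synthetic manifest.

    ``n_sites``/``span_bp`` default to a compact CpG-island-like block
    that satisfies the methylation-region definition (>= 6 sites within
    < 1000 bp).  ``negative_control=True`` marks a deliberately invalid
    or null region; ``blood_contaminated=True`` gives the region a high
    blood methylation level so that the blood-leakage filter has a true
    positive to remove.
    """

    n_sites: int = 8
    span_bp: int = 400
    gene: str = ""
    blood_contaminated: bool = False
    negative_control: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a desk-scale cohort: 100 samples per tissue group,
    5,000 background CpGs and 20 planted hypermethylated regions, with
    group beta means of 0.60 (hypermethylated tumor/adenoma), 0.06
    (background / para-tumor) and 0.05 (blood).  Targeted coverage is
    negative-binomial with mean 100 and dispersion 5, bisulfite
    conversion is 99% efficient, and KRAS- tumors are hypermethylated
    with probability ``kras_neg_methylated_fraction``.
    """

    n_tumor: int = 100
    n_adenoma: int = 100
    n_paratumor: int = 100
    n_blood: int = 100
    n_cpg_background: int = 5000
    planted_regions: tuple[PlantedRegionSpec, ...] = tuple(
        PlantedRegionSpec(n_sites=8, span_bp=400, gene=f"ZFG{i + 1:03d}")
        for i in range(20)
    )
    # Beta-distribution parameters (mean, precision = a + b)
    background_mean: float = 0.06
    background_precision: float = 20.0
    hyper_mean_tumor: float = 0.60
    hyper_mean_adenoma: float = 0.60
    hyper_precision: float = 10.0
    blood_mean: float = 0.05
    blood_contaminated_mean: float = 0.30
    # KRAS structure of the targeted cohort
    kras_pos_fraction: float = 0.48
    kras_neg_methylated_fraction: float = 0.65
    # Targeted sequencing
    coverage_mean: float = 100.0
    coverage_dispersion: float = 5.0
    conversion_rate: float = 0.99
    non_cpg_depth: int = 20000
    # Data imperfections
    site_missing_rate: float = 0.05
    sample_dropout_rate: float = 0.05
    dropout_missing_fraction: float = 0.40
    seed: int = 0

    def __post_init__(self):
        for name in ("n_tumor", "n_adenoma", "n_paratumor", "n_blood"):
            if getattr(self, name) < 1:
                raise ParameterError(name, "sample counts must be positive")
        if self.n_cpg_background < 0:
            raise ParameterError("n_cpg_background", "must be non-negative")
        fractions = (
            "background_mean", "hyper_mean_tumor", "hyper_mean_adenoma",
            "blood_mean", "blood_contaminated_mean", "kras_pos_fraction",
            "kras_neg_methylated_fraction", "site_missing_rate",
            "sample_dropout_rate", "dropout_missing_fraction",
        )
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(name, f"must lie in [0, 1], got {v}")
        if not 0.9 < self.conversion_rate <= 1.0:
            raise ParameterError(
                "conversion_rate",
                f"must lie in (0.9, 1], got {self.conversion_rate}",
            )
        for name in ("background_precision", "hyper_precision",
                     "coverage_mean", "coverage_dispersion"):
            if getattr(self, name) <= 0:
                raise ParameterError(name, "must be positive")
        if self.non_cpg_depth < 1:
            raise ParameterError("non_cpg_depth", "must be positive")
        for spec in self.planted_regions:
            if not spec.negative_control:
                if spec.n_sites < 6 or spec.span_bp >= 1000:
                    raise ParameterError(
                        "planted_regions",
                        f"region {spec.gene!r} violates the MR definition "
                        "(needs >= 6 sites within < 1000 bp) and is not "
                        "flagged negative_control",
                    )
            if spec.n_sites < 1 or spec.span_bp < 1:
                raise ParameterError(
                    "planted_regions", "n_sites and span_bp must be positive"
                )

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class BetaMatrix:
    """Sites x samples methylation fractions with per-sample group labels."""

    values: pd.DataFrame          # index: site_id, columns: sample_id
    groups: pd.Series             # index: sample_id -> group label

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass
class CountTable:
    """Targeted bisulfite-sequencing counts.

    ``meth`` and ``total`` are aligned DataFrames indexed by (chrom, pos)
    with one column per sample; a zero total marks a missing observation.
    ``conversion`` holds per-sample non-CpG cytosine evidence as
    (converted, total) counts.
    """

    meth: pd.DataFrame
    total: pd.DataFrame
    conversion: pd.DataFrame      # index: sample_id, columns: converted, total

    def __post_init__(self):
        if (self.meth.to_numpy() > self.total.to_numpy()).any():
            raise InputError("methylated counts exceed total counts")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream verification."""

    # (chrom, start, end, gene) -> label: planted-dmr | background | negative-control
    region_labels: pd.DataFrame   # columns: chrom, start, end, gene, label
    sample_states: dict[str, str] = field(default_factory=dict)
    kras_status: dict[str, str] = field(default_factory=dict)

    def planted(self) -> pd.DataFrame:
        return self.region_labels[self.region_labels["label"] == "planted-dmr"]


def _beta_draw(rng: np.random.Generator, mean: float, precision: float,
               size) -> np.ndarray:
    return rng.beta(mean * precision, (1.0 - mean) * precision, size=size)


def _chrom_sort_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def _build_manifest(config: SimulationConfig, rng: np.random.Generator):
    """Lay out planted regions and background CpG clusters on chromosomes.

    Units (planted regions and background clusters) are placed left to
    right on randomly assigned chromosomes with inter-unit gaps >= 2000 bp,
    so no sliding window can bridge two units.  Background clusters are a
    mixture of small (1-4 sites) and large (6-12 sites) blocks so that
    the window search yields true-negative regions as well.
    """
    units = []  # (kind, gene, positions-offsets, spec or None)
    for spec in config.planted_regions:
        if spec.n_sites == 1:
            offsets = np.array([0])
        else:
            offsets = np.round(
                np.linspace(0, spec.span_bp, spec.n_sites)
            ).astype(int)
            offsets = np.unique(offsets)
        units.append(("planted", spec.gene, offsets, spec))

    n_placed = 0
    k = 0
    while n_placed < config.n_cpg_background:
        if rng.random() < 0.5:
            size = int(rng.integers(1, 5))
        else:
            size = int(rng.integers(6, 13))
        size = min(size, config.n_cpg_background - n_placed)
        gaps = rng.integers(20, 121, size=max(size - 1, 0))
        offsets = np.concatenate([[0], np.cumsum(gaps)]).astype(int)
        units.append(("background", f"BG{k:05d}", offsets, None))
        n_placed += size
        k += 1

    order = rng.permutation(len(units))
    chroms = rng.integers(1, 23, size=len(units))
    cursors: dict[str, int] = {}
    rows = []
    truth_rows = []
    for idx, unit_i in enumerate(order):
        kind, gene, offsets, spec = units[unit_i]
        chrom = str(chroms[idx])
        start = cursors.get(chrom, 10_000)
        positions = start + offsets
        for pos in positions:
            rows.append((chrom, int(pos), "+", gene, kind, spec))
        cursors[chrom] = int(positions[-1]) + int(rng.integers(2000, 6001))
        if kind == "planted":
            label = ("negative-control" if spec.negative_control
                     else "planted-dmr")
            truth_rows.append((chrom, int(positions[0]), int(positions[-1]),
                               gene, label, spec))

    rows.sort(key=lambda r: (_chrom_sort_key(r[0]), r[1]))
    manifest = pd.DataFrame(
        {
            "site_id": [f"cg{i:08d}" for i in range(len(rows))],
            "chrom": [r[0] for r in rows],
            "pos": [r[1] for r in rows],
            "strand": [r[2] for r in rows],
            "gene": [r[3] for r in rows],
        }
    )
    site_kind = np.array([r[4] for r in rows])
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "gene", "label", "spec"]
    )
    return manifest, site_kind, truth


def generate_array_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, BetaMatrix, GroundTruth]:
    """Generate a discovery-style manifest, beta matrix and ground truth.

    Returns the CpG manifest (site_id, chrom, pos, strand, gene), a
    :class:`BetaMatrix` over tumor / adenoma / para-tumor samples, and
    the :class:`GroundTruth` locating every planted region.
    """
    rng = np.random.default_rng([config.seed, 11])
    manifest, site_kind, truth = _build_manifest(config, rng)
    n_sites = len(manifest)

    sample_ids, group_labels = [], []
    for group, n in ((GROUP_TUMOR, config.n_tumor),
                     (GROUP_ADENOMA, config.n_adenoma),
                     (GROUP_CONTROL, config.n_paratumor)):
        prefix = {GROUP_TUMOR: "T", GROUP_ADENOMA: "A", GROUP_CONTROL: "P"}[group]
        sample_ids += [f"{prefix}{i + 1:04d}" for i in range(n)]
        group_labels += [group] * n

    hyper = site_kind == "planted"
    # negative-control planted regions stay at background methylation
    neg_genes = {s.gene for s in config.planted_regions if s.negative_control}
    if neg_genes:
        hyper &= ~manifest["gene"].isin(neg_genes).to_numpy()

    values = np.empty((n_sites, len(sample_ids)))
    col = 0
    for group, n in ((GROUP_TUMOR, config.n_tumor),
                     (GROUP_ADENOMA, config.n_adenoma),
                     (GROUP_CONTROL, config.n_paratumor)):
        block = _beta_draw(rng, config.background_mean,
                           config.background_precision, (n_sites, n))
        if group in (GROUP_TUMOR, GROUP_ADENOMA):
            mean = (config.hyper_mean_tumor if group == GROUP_TUMOR
                    else config.hyper_mean_adenoma)
            block[hyper, :] = _beta_draw(
                rng, mean, config.hyper_precision, (int(hyper.sum()), n))
        values[:, col:col + n] = block
        col += n

    if config.site_missing_rate > 0:
        mask = rng.random(values.shape) < config.site_missing_rate
        values[mask] = np.nan

    betas = BetaMatrix(
        values=pd.DataFrame(values, index=manifest["site_id"].to_numpy(),
                            columns=sample_ids),
        groups=pd.Series(group_labels, index=sample_ids, name="group"),
    )
    region_labels = pd.concat(
        [
            truth[["chrom", "start", "end", "gene", "label"]],
            _background_region_labels(manifest, site_kind),
        ],
        ignore_index=True,
    )
    ground_truth = GroundTruth(region_labels=region_labels)
    return manifest, betas, ground_truth


def _background_region_labels(manifest: pd.DataFrame,
                              site_kind: np.ndarray) -> pd.DataFrame:
    """Label each background cluster (by gene tag) with its extent."""
    bg = manifest.loc[site_kind == "background"]
    if bg.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "gene", "label"])
    agg = bg.groupby("gene", sort=False).agg(
        chrom=("chrom", "first"), start=("pos", "min"), end=("pos", "max"))
    agg = agg.reset_index()[["chrom", "start", "end", "gene"]]
    agg["label"] = "background"
    return agg


def generate_blood_reference(
    config: SimulationConfig,
    manifest: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> BetaMatrix:
    """Generate WB / PBMC / PBL beta matrices over the manifest sites.

    All sites are lowly methylated (mean ``config.blood_mean``) except
    planted regions flagged ``blood_contaminated``, which receive mean
    ``config.blood_contaminated_mean`` so the blood filter has a planted
    failure to catch.
    """
    rng = np.random.default_rng([config.seed, 23])
    n_sites = len(manifest)

    contaminated_genes = {
        s.gene for s in config.planted_regions if s.blood_contaminated
    }
    contaminated = manifest["gene"].isin(contaminated_genes).to_numpy()

    sample_ids, labels, blocks = [], [], []
    for compartment in BLOOD_COMPARTMENTS:
        n = config.n_blood
        block = _beta_draw(rng, config.blood_mean,
                           config.background_precision, (n_sites, n))
        if contaminated.any():
            block[contaminated, :] = _beta_draw(
                rng, config.blood_contaminated_mean, config.hyper_precision,
                (int(contaminated.sum()), n))
        blocks.append(block)
        sample_ids += [f"{compartment}_{i + 1:04d}" for i in range(n)]
        labels += [compartment] * n

    values = np.concatenate(blocks, axis=1)
    return BetaMatrix(
        values=pd.DataFrame(values, index=manifest["site_id"].to_numpy(),
                            columns=sample_ids),
        groups=pd.Series(labels, index=sample_ids, name="group"),
    )


def generate_expression(
    config: SimulationConfig,
    manifest: pd.DataFrame,
    betas: BetaMatrix,
    truth: GroundTruth,
    anticorrelation_slope: float = 8.0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Gene x samples expression matrix paired with the array cohort.

    Planted-region genes are transcriptionally silenced by promoter
    hypermethylation: their expression is a decreasing function of the
    per-sample mean methylation over the gene's sites, plus Gaussian
    noise.  Background genes get expression independent of methylation,
    so the anticorrelation filter has true negatives to reject.
    """
    rng = np.random.default_rng([config.seed, 41])
    planted_genes = set(truth.planted()["gene"])
    samples = list(betas.values.columns)
    genes = [g for g in manifest["gene"].unique() if g]

    rows = np.empty((len(genes), len(samples)))
    for i, gene in enumerate(genes):
        noise = rng.normal(0.0, noise_sd, size=len(samples))
        if gene in planted_genes:
            sites = manifest.loc[manifest["gene"] == gene, "site_id"]
            meth = betas.values.loc[sites].mean(axis=0, skipna=True)
            meth = meth.fillna(meth.mean()).to_numpy()
            rows[i] = 10.0 - anticorrelation_slope * meth + noise
        else:
            rows[i] = 5.0 + noise
    return pd.DataFrame(rows, index=pd.Index(genes, name="gene"),
                        columns=samples)


def _targeted_site_positions(region) -> np.ndarray:
    """CpG positions assayed in a targeted region (evenly spaced)."""
    n = max(len(region.site_ids), 2)
    return np.round(np.linspace(region.start, region.end, n)).astype(int)


def generate_targeted_cohort(
    config: SimulationConfig,
    regions,
    negative_controls: frozenset[str] = frozenset(),
    cohort: str = "cohort1",
) -> tuple[CountTable, pd.DataFrame, GroundTruth]:
    """Generate paired tumor / para-tumor targeted bisulfite-seq counts.

    ``regions`` is a non-empty list of methylation regions (the validated
    marker panel).  Regions violating the >= 6 sites / < 1000 bp
    definition are rejected unless their gene label is listed in
    ``negative_controls``.  Each patient contributes one tumor and one
    para-tumor sample; tumors carry a KRAS status, and KRAS- tumors are
    hypermethylated only with probability
    ``config.kras_neg_methylated_fraction``.

    The observed methylated count at a site with latent methylation m is
    Binomial(coverage, m + (1-m)(1-c)) for conversion efficiency c:
    unconverted unmethylated cytosines read as methylated.
    """
    if not regions:
        raise InputError("regions must be non-empty")
    for region in regions:
        bad = len(region.site_ids) < 6 or (region.end - region.start) >= 1000
        if bad and region.gene not in negative_controls:
            raise InputError(
                f"region {region.chrom}:{region.start}-{region.end} violates "
                "the methylation-region definition and is not a flagged "
                "negative control"
            )

    rng = np.random.default_rng([config.seed, 37])
    n_patients = config.n_tumor

    site_index = []
    region_of_site = []
    for r_i, region in enumerate(regions):
        for pos in _targeted_site_positions(region):
            site_index.append((region.chrom, int(pos)))
            region_of_site.append(r_i)
    site_index = pd.MultiIndex.from_tuples(site_index, names=["chrom", "pos"])
    region_of_site = np.array(region_of_site)
    n_sites = len(site_index)

    # per-patient KRAS status and latent tumor state
    kras_pos = rng.random(n_patients) < config.kras_pos_fraction
    hyper_state = np.where(
        kras_pos, True, rng.random(n_patients) < config.kras_neg_methylated_fraction
    )

    sample_ids, meta_rows = [], []
    latent_means = np.empty((n_sites, 2 * n_patients))
    ages = np.clip(rng.normal(66, 8, size=n_patients), 35, 90).astype(int)
    sexes = np.where(rng.random(n_patients) < 0.68, "male", "female")
    stages = rng.choice(["I", "II", "III", "IV"], size=n_patients,
                        p=[0.17, 0.34, 0.38, 0.11])
    locations = np.where(rng.random(n_patients) < 0.53, "colon", "rectum")
    null_region = np.array([r.gene in negative_controls for r in regions])

    states: dict[str, str] = {}
    kras: dict[str, str] = {}
    for p in range(n_patients):
        pid = f"PT{p + 1:04d}"
        for tissue, suffix in (("tumor", "T"), ("para-tumor", "N")):
            sid = f"{pid}_{suffix}"
            sample_ids.append(sid)
            col = len(sample_ids) - 1
            is_hyper = tissue == "tumor" and hyper_state[p]
            if is_hyper:
                m = _beta_draw(rng, config.hyper_mean_tumor,
                               config.hyper_precision, n_sites)
                # negative-control regions stay background even in tumors
                low = null_region[region_of_site]
                if low.any():
                    m[low] = _beta_draw(rng, config.background_mean,
                                        config.background_precision,
                                        int(low.sum()))
            else:
                m = _beta_draw(rng, config.background_mean,
                               config.background_precision, n_sites)
            latent_means[:, col] = m
            if tissue == "tumor":
                states[sid] = STATE_HYPER if is_hyper else STATE_CONTROL_LIKE
                kras[sid] = "positive" if kras_pos[p] else "negative"
            meta_rows.append(
                dict(sample_id=sid, patient_id=pid, tissue=tissue,
                     kras_status=("positive" if kras_pos[p] else "negative")
                     if tissue == "tumor" else "not-applicable",
                     cohort=cohort, age=int(ages[p]), sex=sexes[p],
                     stage=stages[p], location=locations[p])
            )

    n_samples = len(sample_ids)
    # negative-binomial coverage: NB(r=dispersion, p=r/(r+mean))
    r = config.coverage_dispersion
    p_nb = r / (r + config.coverage_mean)
    total = rng.negative_binomial(r, p_nb, size=(n_sites, n_samples))

    if config.site_missing_rate > 0:
        total[rng.random(total.shape) < config.site_missing_rate] = 0
    if config.sample_dropout_rate > 0:
        dropped = rng.random(n_samples) < config.sample_dropout_rate
        for j in np.flatnonzero(dropped):
            miss = rng.random(n_sites) < config.dropout_missing_fraction
            total[miss, j] = 0

    c = config.conversion_rate
    p_obs = latent_means + (1.0 - latent_means) * (1.0 - c)
    meth = rng.binomial(total, p_obs)

    converted = rng.binomial(config.non_cpg_depth, c, size=n_samples)
    conversion = pd.DataFrame(
        {"converted": converted, "total": config.non_cpg_depth},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    table = CountTable(
        meth=pd.DataFrame(meth, index=site_index, columns=sample_ids),
        total=pd.DataFrame(total, index=site_index, columns=sample_ids),
        conversion=conversion,
    )
    meta = pd.DataFrame(meta_rows)
    truth = GroundTruth(
        region_labels=pd.DataFrame(
            {
                "chrom": [r_.chrom for r_ in regions],
                "start": [r_.start for r_ in regions],
                "end": [r_.end for r_ in regions],
                "gene": [r_.gene for r_ in regions],
                "label": ["negative-control" if r_.gene in negative_controls
                          else "planted-dmr" for r_ in regions],
            }
        ),
        sample_states=states,
        kras_status=kras,
    )
    return table, meta, truth
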