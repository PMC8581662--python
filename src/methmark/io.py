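"""Readers and writers for the pipeline's on-disk formats.

All files are UTF-8 text with mandatory headers (except BED, which is
headerless by convention).  Internal coordinates are 1-based inclusive;
BED output is converted to 0-based half-open (start-1, end).  Malformed
rows raise :class:`~methmark.errors.SchemaError` with the line number.

Formats
-------
manifest TSV        site_id, chrom, pos, strand, gene
beta CSV            sites x samples matrix, first column ``site_id``,
                    plus a sidecar ``*.groups.csv`` (sample_id, group)
bismark coverage    one ``<sample>.cov`` per sample: chrom, start, end,
                    methylation_pct, count_methylated, count_unmethylated
                    (1-based, start == end for a CpG), plus
                    ``conversion.csv`` (sample_id, converted, total)
regions TSV         region (chrom:start-end), gene, n_sites, site_ids
DMR TSV             regions TSV columns + group means, p, fdr, flags
results TSV         stratum, region, gene, McaM, McoM, p, FDR, OR, CI,
                    cutoff, sens, spec, AUC
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .regions import DMRRecord, MethylationRegion, normalize_chrom
from .simulate import BetaMatrix, CountTable

MANIFEST_COLUMNS = ["site_id", "chrom", "pos", "strand", "gene"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# manifest

def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False, columns=MANIFEST_COLUMNS)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str},
                     keep_default_na=False)
    _require_columns(df, MANIFEST_COLUMNS, path)
    bad = pd.to_numeric(df["pos"], errors="coerce").isna()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2   # header is line 1
        raise SchemaError(f"{path}: non-numeric position at line {line}")
    df["pos"] = df["pos"].astype(int)
    return df


# ---------------------------------------------------------------------------
# beta matrices

def write_beta_matrix(betas: BetaMatrix, path) -> None:
    path = Path(path)
    out = betas.values.copy()
    out.index.name = "site_id"
    out.to_csv(path)
    sidecar = path.with_suffix(".groups.csv")
    betas.groups.rename("group").rename_axis("sample_id").to_csv(sidecar)


def read_beta_matrix(path) -> BetaMatrix:
    path = Path(path)
    values = pd.read_csv(path, index_col="site_id")
    sidecar = path.with_suffix(".groups.csv")
    groups_df = pd.read_csv(sidecar)
    _require_columns(groups_df, ["sample_id", "group"], sidecar)
    groups = groups_df.set_index("sample_id")["group"]
    extra = set(values.columns) - set(groups.index)
    if extra:
        raise SchemaError(f"{sidecar}: samples without group label: "
                          f"{sorted(extra)[:5]}")
    bad = values.to_numpy(dtype=float)
    if np.nanmin(bad) < 0 or np.nanmax(bad) > 1:
        raise SchemaError(f"{path}: beta values must lie in [0, 1]")
    return BetaMatrix(values=values, groups=groups.loc[list(values.columns)])


# ---------------------------------------------------------------------------
# bismark-coverage dialect

def write_count_table(table: CountTable, directory) -> None:
    """One ``<sample>.cov`` per sample; sites with zero total are omitted
    (uncovered), matching the coverage-file convention."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sample in table.total.columns:
        total = table.total[sample]
        meth = table.meth[sample]
        covered = total > 0
        with np.errstate(invalid="ignore"):
            pct = np.where(covered, 100.0 * meth / total.where(covered, 1), np.nan)
        df = pd.DataFrame({
            "chrom": [c for c, _ in table.total.index],
            "start": [p for _, p in table.total.index],
            "end": [p for _, p in table.total.index],
            "methylation_pct": np.round(pct, 6),
            "count_methylated": meth.to_numpy(),
            "count_unmethylated": (total - meth).to_numpy(),
        })
        df[covered.to_numpy()].to_csv(directory / f"{sample}.cov", sep="\t",
                                      index=False)
    table.conversion.reset_index().to_csv(directory / "conversion.csv",
                                          index=False)


def read_count_table(directory) -> CountTable:
    """Read every ``*.cov`` in a directory plus ``conversion.csv``.

    The site universe is the union of covered sites across samples;
    a site absent from a sample's file is a missing observation
    (total 0), as is an explicit row with zero counts.
    """
    directory = Path(directory)
    conv_path = directory / "conversion.csv"
    if not conv_path.exists():
        raise SchemaError(f"{conv_path}: conversion evidence file not found")
    conv = pd.read_csv(conv_path)
    _require_columns(conv, ["sample_id", "converted", "total"], conv_path)
    conv = conv.set_index("sample_id")[["converted", "total"]]

    meth_cols, total_cols = {}, {}
    cov_files = sorted(directory.glob("*.cov"))
    if not cov_files:
        raise SchemaError(f"{directory}: no .cov files found")
    for f in cov_files:
        sample = f.stem
        df = pd.read_csv(f, sep="\t", dtype={"chrom": str})
        _require_columns(
            df, ["chrom", "start", "end", "count_methylated",
                 "count_unmethylated"], f)
        for col in ("start", "count_methylated", "count_unmethylated"):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            if bad.any():
                line = int(np.flatnonzero(bad)[0]) + 2
                raise SchemaError(f"{f}: non-numeric {col} at line {line}")
        idx = pd.MultiIndex.from_arrays(
            [df["chrom"], df["start"].astype(int)], names=["chrom", "pos"])
        meth_cols[sample] = pd.Series(
            df["count_methylated"].astype(int).to_numpy(), index=idx)
        total_cols[sample] = pd.Series(
            (df["count_methylated"] + df["count_unmethylated"])
            .astype(int).to_numpy(), index=idx)

    meth = pd.DataFrame(meth_cols).fillna(0).astype(int)
    total = pd.DataFrame(total_cols).fillna(0).astype(int)
    meth = meth.sort_index()
    total = total.sort_index()
    missing_conv = set(meth.columns) - set(conv.index)
    if missing_conv:
        raise SchemaError(
            f"{conv_path}: no conversion evidence for {sorted(missing_conv)[:5]}")
    return CountTable(meth=meth, total=total,
                      conversion=conv.loc[list(meth.columns)])


# ---------------------------------------------------------------------------
# metadata

def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"stage": str})
    _require_columns(df, ["sample_id", "patient_id", "tissue", "kras_status"],
                     path)
    return df


# ---------------------------------------------------------------------------
# regions

def region_to_string(region: MethylationRegion) -> str:
    return region.region_string


def parse_region_string(s: str) -> tuple[str, int, int]:
    try:
        chrom, span = s.split(":")
        start, end = span.split("-")
        return normalize_chrom(chrom), int(start), int(end)
    except ValueError as exc:
        raise SchemaError(f"malformed region string {s!r}") from exc


def write_regions_tsv(regions: list[MethylationRegion], path) -> None:
    pd.DataFrame({
        "region": [r.region_string for r in regions],
        "gene": [r.gene for r in regions],
        "n_sites": [r.n_sites for r in regions],
        "site_ids": [",".join(r.site_ids) for r in regions],
    }).to_csv(path, sep="\t", index=False)


def read_regions_tsv(path) -> list[MethylationRegion]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    _require_columns(df, ["region", "gene", "site_ids"], path)
    regions = []
    for i, row in df.iterrows():
        chrom, start, end = parse_region_string(row["region"])
        regions.append(MethylationRegion(
            chrom=chrom, start=start, end=end,
            site_ids=tuple(str(row["site_ids"]).split(",")),
            gene=str(row["gene"])))
    return regions


def write_regions_bed(regions: list[MethylationRegion], path) -> None:
    """BED (0-based half-open): start = internal start - 1, end = end."""
    with open(path, "w") as fh:
        for r in regions:
            name = r.gene or r.region_string
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\t"
                     f"{r.n_sites}\t+\n")


# ---------------------------------------------------------------------------
# DMR records and diagnostic results

def write_dmr_records(records: list[DMRRecord], path) -> None:
    rows = []
    for rec in records:
        row = {
            "region": rec.region.region_string,
            "gene": rec.region.gene,
            "n_sites": rec.region.n_sites,
            "site_ids": ",".join(rec.region.site_ids),
            "McaM": rec.mcam, "MadM": rec.madm, "McoM": rec.mcom,
            "p_value": rec.p_value, "fdr": rec.fdr,
            "passes_thresholds": rec.passes_thresholds,
            "passes_blood": rec.passes_blood,
            "selected_per_gene": rec.selected_per_gene,
            "passes_expression": rec.passes_expression,
        }
        for comp in ("WB", "PBMC", "PBL"):
            row[f"blood_{comp}"] = rec.blood_means.get(comp, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_dmr_records(path) -> list[DMRRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     na_values=[""], dtype={"gene": str})
    _require_columns(df, ["region", "gene", "site_ids", "McaM", "McoM",
                          "p_value", "fdr"], path)
    records = []
    for _, row in df.iterrows():
        chrom, start, end = parse_region_string(row["region"])
        gene = row["gene"] if isinstance(row["gene"], str) else ""
        region = MethylationRegion(
            chrom=chrom, start=start, end=end,
            site_ids=tuple(str(row["site_ids"]).split(",")), gene=gene)
        records.append(DMRRecord(
            region=region,
            mcam=float(row["McaM"]),
            madm=float(row["MadM"]) if not pd.isna(row.get("MadM")) else np.nan,
            mcom=float(row["McoM"]),
            blood_means={
                comp: float(row[f"blood_{comp}"])
                for comp in ("WB", "PBMC", "PBL")
                if f"blood_{comp}" in row and not pd.isna(row[f"blood_{comp}"])
            },
            p_value=float(row["p_value"]),
            fdr=float(row["fdr"]),
            passes_thresholds=bool(row.get("passes_thresholds", False)),
            passes_blood=bool(row.get("passes_blood", False)),
            selected_per_gene=bool(row.get("selected_per_gene", False)),
            passes_expression=bool(row.get("passes_expression", False)),
        ))
    return records


def write_results_tsv(results, path) -> None:
    """Diagnostic results in the stratum x region panel layout."""
    rows = []
    for r in results:
        rows.append({
            "stratum": r.stratum,
            "region": r.region.region_string,
            "gene": r.region.gene,
            "n_cases": r.n_cases, "n_controls": r.n_controls,
            "McaM": round(r.mcam, 6), "McoM": round(r.mcom, 6),
            "p_value": r.p_value, "fdr": r.fdr,
            "OR": r.odds_ratio, "CI_low": r.ci_low, "CI_high": r.ci_high,
            "cutoff": r.cutoff,
            "sensitivity": r.sensitivity, "specificity": r.specificity,
            "AUC": r.auc, "separated": r.separated,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_run_manifest(path, config: dict, seed: int, counters: dict) -> None:
    with open(path, "w") as fh:
        json.dump({"config": config, "seed": seed, "counters": counters},
                  fh, indent=1, default=str)


def write_truth(truth, path) -> None:
    payload = {
        "region_labels": truth.region_labels.to_dict(orient="records"),
        "sample_states": truth.sample_states,
        "kras_status": truth.kras_status,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
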