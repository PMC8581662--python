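import numpy as np
import pandas as pd
import pytest

import methmark as mm


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort that still exercises every pipeline stage:
    8 clean planted regions, one blood-contaminated region, 1,500
    background CpGs, 60 samples per tissue group."""
    planted = tuple(
        mm.PlantedRegionSpec(n_sites=8, span_bp=400, gene=f"ZFG{i + 1:03d}")
        for i in range(8)
    ) + (
        mm.PlantedRegionSpec(n_sites=8, span_bp=400, gene="ZFGBLD",
                             blood_contaminated=True),
    )
    return mm.SimulationConfig(
        n_tumor=60, n_adenoma=60, n_paratumor=60, n_blood=40,
        n_cpg_background=1500, planted_regions=planted, seed=11,
    )


@pytest.fixture(scope="session")
def array_cohort(small_config):
    manifest, betas, truth = mm.generate_array_cohort(small_config)
    return manifest, betas, truth


@pytest.fixture(scope="session")
def blood_reference(small_config, array_cohort):
    manifest, _, truth = array_cohort
    return mm.generate_blood_reference(small_config, manifest, truth)


@pytest.fixture(scope="session")
def cascade(small_config, array_cohort, blood_reference):
    manifest, betas, _ = array_cohort
    return mm.run_cascade(manifest, betas, blood_reference)


@pytest.fixture(scope="session")
def marker_panel():
    """A synthetic five-marker panel of valid methylation regions."""
    return [
        mm.MethylationRegion(
            chrom=str(i + 1), start=50_000, end=50_000 + 420,
            site_ids=tuple(f"pm{i}_{k}" for k in range(8)),
            gene=f"ZFG{i + 1:03d}")
        for i in range(5)
    ]


@pytest.fixture(scope="session")
def targeted_bundle(marker_panel):
    cfg = mm.SimulationConfig(n_tumor=100, seed=5)
    table, meta, truth = mm.generate_targeted_cohort(cfg, marker_panel)
    return cfg, table, meta, truth


def fraction_matrix(table, panel):
    """Targeted site fractions keyed by chrom:pos, with regions re-keyed
    onto the assayed positions (test-side copy of the CLI helper)."""
    frac = mm.site_fractions(table)
    frac = frac.copy()
    frac.index = [f"{c}:{p}" for c, p in frac.index]
    regions = []
    for region in panel:
        ids = tuple(s for s in frac.index
                    if s.startswith(f"{region.chrom}:")
                    and region.start <= int(s.split(":")[1]) <= region.end)
        if ids:
            regions.append(mm.MethylationRegion(
                chrom=region.chrom, start=region.start, end=region.end,
                site_ids=ids, gene=region.gene))
    return frac, regions
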