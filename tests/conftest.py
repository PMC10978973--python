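"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sibline.hetmetrics import VariantTable
from sibline.simulate import (
    ChromosomeSpec,
    SimConfig,
    SyntheticGenome,
    SitePanel,
    simulate_dataset,
    synthesize_genome,
)


def make_table(
    chrom, pos, ref, alt, gt, dp=None, info=None, samples=None
) -> VariantTable:
    """Hand-build a VariantTable for targeted unit tests."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    if dp is None:
        dp = np.full_like(gt, 30, dtype=np.int32)
    if info is None:
        info = pd.DataFrame(
            {
                k: [np.nan] * n_sites
                for k in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")
            }
        )
    return VariantTable(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        info=info,
        gt=gt,
        dp=np.asarray(dp, dtype=np.int32),
        samples=list(samples),
    )


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Two 500-kb chromosomes, ~1 SNP/kb: enough structure, fast."""
    return SimConfig(
        chromosomes=(
            ChromosomeSpec("chr1", 500_000, 50.0),
            ChromosomeSpec("chr2", 500_000, 50.0),
        ),
        generations=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genome(small_config) -> SyntheticGenome:
    return synthesize_genome(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    """One emitted FASTA/GFF3/VCF trio from a 5-generation line."""
    out = tmp_path_factory.mktemp("dataset")
    result, paths, cohort = simulate_dataset(small_config, out)
    return {"result": result, "paths": paths, "cohort": cohort}


def flat_panel_genome(positions, ref, alt, length=1000, chrom="chr1") -> SyntheticGenome:
    """Minimal genome (no genes) around an explicit site panel."""
    seq = ["A"] * length
    for p, r in zip(positions, ref):
        seq[p - 1] = r
    spec = ChromosomeSpec(chrom, length, 0.0)
    panel = SitePanel(
        positions={chrom: np.asarray(positions, dtype=np.int64)},
        ref={chrom: np.asarray(ref, dtype=object)},
        alt={chrom: np.asarray(alt, dtype=object)},
    )
    return SyntheticGenome(
        chromosomes=(spec,),
        reference={chrom: "".join(seq)},
        transcripts=[],
        panel=panel,
    )
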