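"""Heterozygosity statistics on multi-sample SNP VCFs.

Implements the homogeneity/heterogeneity accounting used to
characterise inbred-line genomes: GATK-style hard filtering of raw
SNPs, per-sample heterozygous/homozygous genotype counts, two
heterogeneity percentages (per whole-genome nucleotide and per union
SNP position), a fixed-width windowed heterozygosity scan (default
100 kb), and run-based flagging of windows that stay heterozygous —
the "hotspot" signature of linked lethals balanced in repulsion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GT_HOM_REF",
    "GT_HET",
    "GT_HOM_ALT",
    "GT_MISSING",
    "GENOME_LENGTH_GRCZ11",
    "FilterThresholds",
    "VariantTable",
    "WindowScan",
    "read_vcf",
    "apply_hard_filters",
    "heterogeneity_report",
    "union_snp_positions",
    "window_scan",
    "flag_het_regions",
]

GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING = 0, 1, 2, -1

#: GRCz11 chromosome 1-25 total used as the whole-genome denominator.
GENOME_LENGTH_GRCZ11 = 1_345_101_831

INFO_FIELDS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_CYVCF2_GT_MAP = np.array([GT_HOM_REF, GT_HET, GT_MISSING, GT_HOM_ALT], dtype=np.int8)


@dataclass(frozen=True)
class FilterThresholds:
    """GATK-style hard-filter cutoffs for raw SNPs.

    A site is removed when any *present* annotation violates its
    threshold: QD < qd_min, FS > fs_max, MQ < mq_min,
    MQRankSum < mqranksum_min, ReadPosRankSum < readposranksum_min.
    DP is applied per sample: genotypes with DP < dp_min are set to
    missing rather than the whole site being dropped.
    """

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 60.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    dp_min: int = 10


@dataclass
class VariantTable:
    """Column-oriented container for biallelic SNP records.

    ``gt`` holds genotype classes (0 hom-ref, 1 het, 2 hom-alt, -1
    missing) as an (n_sites, n_samples) int8 matrix; ``dp`` the
    matching per-genotype depths (-1 when absent).  ``info`` has one
    float column per hard-filter annotation, NaN when the annotation
    is absent from the record.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    info: pd.DataFrame
    gt: np.ndarray
    dp: np.ndarray
    samples: list[str]
    n_rejected: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            info=self.info.loc[mask].reset_index(drop=True),
            gt=self.gt[mask],
            dp=self.dp[mask],
            samples=list(self.samples),
            n_rejected=self.n_rejected,
        )


def read_vcf(path: str) -> VariantTable:
    """Read a VCF into a :class:`VariantTable`.

    Only biallelic SNP records are kept; multiallelic or non-SNP
    records are counted in ``n_rejected``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    infos: dict[str, list[float]] = {k: [] for k in INFO_FIELDS}
    gts, dps = [], []
    rejected = 0
    for v in vcf:
        if (not v.is_snp) or len(v.ALT) != 1 or len(v.REF) != 1:
            rejected += 1
            continue
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        for k in INFO_FIELDS:
            val = v.INFO.get(k)
            infos[k].append(np.nan if val is None else float(val))
        gts.append(_CYVCF2_GT_MAP[np.asarray(v.gt_types)])
        dps.append(np.asarray(v.gt_depths, dtype=np.int32))
    vcf.close()
    n = len(poss)
    return VariantTable(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        info=pd.DataFrame(infos),
        gt=(np.vstack(gts) if n else np.empty((0, len(samples)), np.int8)),
        dp=(np.vstack(dps) if n else np.empty((0, len(samples)), np.int32)),
        samples=samples,
        n_rejected=rejected,
    )


def apply_hard_filters(
    table: VariantTable, thresholds: FilterThresholds | None = None
) -> tuple[VariantTable, dict[str, int]]:
    """Hard-filter sites and depth-mask genotypes.

    Returns the retained table and a tally of how many sites violated
    each site-level criterion (a site can violate several) plus how
    many genotypes were masked by the per-sample DP cutoff.  Absent
    annotations never cause removal; their count is tallied under
    ``absent_annotation`` for auditability.
    """
    th = thresholds or FilterThresholds()
    info = table.info
    viol = {
        "QD": (info["QD"] < th.qd_min).to_numpy(),
        "FS": (info["FS"] > th.fs_max).to_numpy(),
        "MQ": (info["MQ"] < th.mq_min).to_numpy(),
        "MQRankSum": (info["MQRankSum"] < th.mqranksum_min).to_numpy(),
        "ReadPosRankSum": (info["ReadPosRankSum"] < th.readposranksum_min).to_numpy(),
    }
    tally = {k: int(v.sum()) for k, v in viol.items()}
    tally["absent_annotation"] = int(info.isna().any(axis=1).sum())
    remove = np.zeros(table.n_sites, dtype=bool)
    for v in viol.values():
        remove |= v
    kept = table.subset(~remove)
    tally["sites_removed"] = int(remove.sum())

    low_dp = (kept.dp >= 0) & (kept.dp < th.dp_min) & (kept.gt != GT_MISSING)
    tally["DP_genotypes_masked"] = int(low_dp.sum())
    if low_dp.any():
        gt = kept.gt.copy()
        gt[low_dp] = GT_MISSING
        kept = replace(kept, gt=gt)
    return kept, tally


def union_snp_positions(table: VariantTable) -> int:
    """Distinct (chrom, pos) variant (het or hom-alt) in >=1 sample."""
    variant = ((table.gt == GT_HET) | (table.gt == GT_HOM_ALT)).any(axis=1)
    if not variant.any():
        return 0
    df = pd.DataFrame({"chrom": table.chrom[variant], "pos": table.pos[variant]})
    return int(len(df.drop_duplicates()))


def heterogeneity_report(
    table: VariantTable,
    genome_length: int = GENOME_LENGTH_GRCZ11,
    union_snp_count: int | None = None,
) -> pd.DataFrame:
    """Per-sample heterogeneity percentages under both denominators.

    ``whole_genome_percent`` = 100 * het genotypes / genome_length
    (heterozygous nucleotides per whole-genome nucleotide);
    ``snpset_percent`` = 100 * het genotypes / union SNP positions.
    Missing genotypes never enter the numerators.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if union_snp_count is None:
        union_snp_count = union_snp_positions(table)
    het = (table.gt == GT_HET).sum(axis=0).astype(int)
    hom_alt = (table.gt == GT_HOM_ALT).sum(axis=0).astype(int)
    if union_snp_count <= 0:
        raise ValueError("union SNP count must be positive")
    if union_snp_count < int((het + hom_alt).max(initial=0)):
        raise ValueError("union SNP count smaller than a per-sample variant count")
    return pd.DataFrame(
        {
            "het_count": het,
            "hom_alt_count": hom_alt,
            "whole_genome_percent": 100.0 * het / genome_length,
            "snpset_percent": 100.0 * het / union_snp_count,
        },
        index=pd.Index(table.samples, name="sample"),
    )


@dataclass
class WindowScan:
    """Fixed-width heterozygosity scan.

    Window k on a chromosome covers [(k-1)*W + 1, k*W]; the final
    partial window is kept.  ``frame`` has one row per (chrom, window)
    with ``n_sites`` plus ``n_het_<sample>`` and ``pct_het_<sample>``
    columns; empty windows report 0% with ``n_sites = 0``.
    """

    window_size: int
    samples: list[str]
    frame: pd.DataFrame = field(repr=False)


def window_scan(
    table: VariantTable,
    window_size: int = 100_000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> WindowScan:
    """Count sites and het genotypes per fixed-width genomic window.

    With ``chrom_lengths`` given, every window up to the chromosome
    end is emitted (including empty ones); otherwise only windows up
    to the last observed site on each observed chromosome.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    W = int(window_size)
    win_idx = (table.pos - 1) // W + 1
    het = (table.gt == GT_HET).astype(np.int64)

    df = pd.DataFrame({"chrom": table.chrom, "window": win_idx})
    for j, s in enumerate(table.samples):
        df[f"n_het_{s}"] = het[:, j]
    df["n_sites"] = 1
    agg = df.groupby(["chrom", "window"], sort=False).sum().reset_index()

    if chrom_lengths is not None:
        chroms = list(chrom_lengths)
        full = pd.concat(
            [
                pd.DataFrame(
                    {
                        "chrom": c,
                        "window": np.arange(1, (chrom_lengths[c] - 1) // W + 2),
                    }
                )
                for c in chroms
            ],
            ignore_index=True,
        )
    else:
        chroms = list(dict.fromkeys(table.chrom.tolist()))
        if chroms:
            last = agg.groupby("chrom")["window"].max()
            full = pd.concat(
                [
                    pd.DataFrame({"chrom": c, "window": np.arange(1, last[c] + 1)})
                    for c in chroms
                ],
                ignore_index=True,
            )
        else:
            full = pd.DataFrame({"chrom": [], "window": []})
    out = full.merge(agg, on=["chrom", "window"], how="left").fillna(0)
    count_cols = ["n_sites"] + [f"n_het_{s}" for s in table.samples]
    out[count_cols] = out[count_cols].astype(np.int64)
    out["start"] = (out["window"] - 1) * W + 1
    out["end"] = out["window"] * W
    with np.errstate(invalid="ignore", divide="ignore"):
        for s in table.samples:
            pct = 100.0 * out[f"n_het_{s}"] / out["n_sites"]
            out[f"pct_het_{s}"] = pct.fillna(0.0)  # empty windows report 0%
    cols = ["chrom", "window", "start", "end", "n_sites"]
    cols += [f"n_het_{s}" for s in table.samples]
    cols += [f"pct_het_{s}" for s in table.samples]
    return WindowScan(window_size=W, samples=list(table.samples), frame=out[cols])


def flag_het_regions(
    scan: WindowScan,
    percent_threshold: float = 25.0,
    min_consecutive: int = 1,
) -> pd.DataFrame:
    """Maximal runs of consecutive high-heterozygosity windows per sample.

    A window enters a run when its ``pct_het`` is at or above
    ``percent_threshold``; runs shorter than ``min_consecutive``
    windows are dropped.  Returns one row per flagged region with its
    genomic extent and mean window percentage.
    """
    rows = []
    frame = scan.frame
    for s in scan.samples:
        pct_col = f"pct_het_{s}"
        for chrom, sub in frame.groupby("chrom", sort=False):
            sub = sub.sort_values("window")
            hot = (sub[pct_col] >= percent_threshold).to_numpy()
            windows = sub["window"].to_numpy()
            i = 0
            while i < len(hot):
                if not hot[i]:
                    i += 1
                    continue
                j = i
                while (
                    j + 1 < len(hot)
                    and hot[j + 1]
                    and windows[j + 1] == windows[j] + 1
                ):
                    j += 1
                if j - i + 1 >= min_consecutive:
                    block = sub.iloc[i : j + 1]
                    rows.append(
                        (
                            s,
                            chrom,
                            int(windows[i]),
                            int(windows[j]),
                            int(block["start"].iloc[0]),
                            int(block["end"].iloc[-1]),
                            j - i + 1,
                            float(block[pct_col].mean()),
                        )
                    )
                i = j + 1
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "chrom", "first_window", "last_window",
            "start", "end", "n_windows", "mean_pct_het",
        ],
    )


def plot_window_tracks(scan: WindowScan, path: str, samples=None) -> None:
    """Per-sample windowed-heterozygosity tracks (one panel per sample)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    samples = list(samples or scan.samples)
    frame = scan.frame.reset_index(drop=True)
    fig, axes = plt.subplots(
        len(samples), 1, figsize=(10, 1.6 * len(samples)), sharex=True, squeeze=False
    )
    x = np.arange(len(frame))
    for ax, s in zip(axes[:, 0], samples):
        ax.fill_between(x, frame[f"pct_het_{s}"], step="mid", color="#336699")
        ax.set_ylabel(s, rotation=0, ha="right", fontsize=8)
        ax.set_ylim(0, 100)
    boundaries = np.nonzero(frame["chrom"].ne(frame["chrom"].shift()))[0]
    for ax in axes[:, 0]:
        for b in boundaries[1:]:
            ax.axvline(b, color="0.7", lw=0.5)
    axes[-1, 0].set_xlabel(f"{scan.window_size // 1000} kb windows")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
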