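"""Hypermutable-ssDNA estimates and genome-distribution summaries.

Cluster calls are converted into a minimum estimate of the single-stranded
DNA transiently exposed during repair: only CG clusters with more than
three mutations count (smaller clusters are too easily random
colocalization), their bordering-mutation distances are summed, and the sum
is expressed as a percentage of total genome bases at the sample's ploidy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import DISPLAY_CLASS, DEFAULT_MIN_MUTATIONS, classify_cluster
from .detect import Cluster
from .io import GenomeModel


@dataclass(frozen=True)
class SsdnaSummary:
    """Per-sample hypermutable-ssDNA estimate from CG >3-mutation clusters."""

    sample_id: str
    sum_cluster_length: int
    percent_ssdna: float
    n_clusters: int
    median_density: float  # mutations per kb, median over included clusters


def cluster_density(cluster: Cluster) -> float:
    """Raw mutations per kb of cluster length."""
    if cluster.length <= 0:
        raise ValueError("cluster has zero length")
    return cluster.n_mutations * 1000.0 / cluster.length


def _included(clusters: Sequence[Cluster], min_mutations: int) -> list[Cluster]:
    return [cl for cl in clusters if classify_cluster(cl, min_mutations) in DISPLAY_CLASS]


def ssdna_fraction(
    clusters: Sequence[Cluster],
    genome: GenomeModel,
    sample_id: str | None = None,
    min_mutations: int = DEFAULT_MIN_MUTATIONS,
) -> SsdnaSummary:
    """Percent of the genome that persisted as hypermutable ssDNA.

    ``100 * sum(cluster lengths) / total_bases`` over CG clusters with
    >= ``min_mutations`` mutations; ``total_bases`` reflects ploidy, so a
    diploid denominator is twice the reference length.
    """
    included = _included(clusters, min_mutations)
    if sample_id is None:
        sample_id = included[0].sample_id if included else (clusters[0].sample_id if clusters else "")
    total_len = sum(cl.length for cl in included)
    densities = [cluster_density(cl) for cl in included]
    return SsdnaSummary(
        sample_id=sample_id,
        sum_cluster_length=total_len,
        percent_ssdna=100.0 * total_len / genome.total_bases,
        n_clusters=len(included),
        median_density=float(np.median(densities)) if densities else float("nan"),
    )


def ssdna_table(
    clusters: Sequence[Cluster],
    genome: GenomeModel,
    min_mutations: int = DEFAULT_MIN_MUTATIONS,
) -> pd.DataFrame:
    """Per-sample summary table (sum length, percent ssDNA, counts, density)."""
    by_sample: dict[str, list[Cluster]] = {}
    for cl in clusters:
        by_sample.setdefault(cl.sample_id, []).append(cl)
    rows = []
    for sample_id in sorted(by_sample):
        s = ssdna_fraction(by_sample[sample_id], genome, sample_id, min_mutations)
        rows.append(
            {
                "sample_id": s.sample_id,
                "sum_cluster_length": s.sum_cluster_length,
                "percent_ssdna_per_genome": s.percent_ssdna,
                "n_cg_clusters": s.n_clusters,
                "median_density_per_kb": s.median_density,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "sum_cluster_length",
            "percent_ssdna_per_genome",
            "n_cg_clusters",
            "median_density_per_kb",
        ],
    )


def chromosome_distribution(
    clusters: Sequence[Cluster], genome: GenomeModel
) -> tuple[pd.DataFrame, "stats._stats_mstats_common.LinregressResult | None"]:
    """Cluster counts per chromosome and their regression on chromosome length.

    Proportional spread (no hotspot chromosome) shows as a positive slope
    with intercept near zero. Degenerate input (clusters on fewer than two
    chromosomes) returns ``None`` for the regression.
    """
    counts = {name: 0 for name in genome.chrom_names}
    for cl in clusters:
        counts[cl.chrom] += 1
    table = pd.DataFrame(
        {
            "chrom": genome.chrom_names,
            "length_bp": [genome.chrom_lengths[c] for c in genome.chrom_names],
            "n_clusters": [counts[c] for c in genome.chrom_names],
        }
    )
    if (table["n_clusters"] > 0).sum() < 2:
        return table, None
    reg = stats.linregress(table["length_bp"], table["n_clusters"])
    return table, reg


def cohort_summaries(
    clusters: Sequence[Cluster],
    metadata: pd.DataFrame,
    stratum_key: str = "stratum",
) -> dict[str, pd.DataFrame]:
    """Cohort-level incidence, per-isolate counts and feature correlations.

    ``metadata`` must carry one row per sample with columns ``sample_id``
    and ``stratum_key``; samples without clusters still count in
    incidence denominators. Returns:

    * ``incidence`` — percent of isolates with >= 1 nonselected cluster per
      stratum;
    * ``per_isolate`` — cluster counts per sample;
    * ``comparisons`` — pairwise Fisher exact tests on incidence and
      rank-sum tests on per-isolate nonselected-cluster counts;
    * ``correlations`` — Pearson correlations between per-isolate number of
      clustered mutations, total cluster length and mean density.
    """
    if "sample_id" not in metadata.columns or stratum_key not in metadata.columns:
        raise ValueError(f"metadata needs columns 'sample_id' and {stratum_key!r}")
    meta = metadata.drop_duplicates("sample_id").set_index("sample_id")
    by_sample: dict[str, list[Cluster]] = {sid: [] for sid in meta.index}
    for cl in clusters:
        if cl.sample_id not in by_sample:
            raise ValueError(f"cluster sample {cl.sample_id!r} missing from metadata")
        by_sample[cl.sample_id].append(cl)

    per_isolate = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "stratum": meta.loc[sid, stratum_key],
                "n_clusters": len(cls),
                "n_nonselected": sum(1 for c in cls if not c.selected),
                "n_selected": sum(1 for c in cls if c.selected),
                "n_clustered_mutations": sum(c.n_mutations for c in cls),
                "sum_cluster_length": sum(c.length for c in cls),
                "mean_density_per_kb": (
                    float(np.mean([cluster_density(c) for c in cls])) if cls else np.nan
                ),
            }
            for sid, cls in by_sample.items()
        ]
    ).sort_values("sample_id", ignore_index=True)

    incidence_rows = []
    for stratum, sub in per_isolate.groupby("stratum"):
        n = len(sub)
        with_cluster = int((sub["n_nonselected"] >= 1).sum())
        incidence_rows.append(
            {
                "stratum": stratum,
                "n_isolates": n,
                "n_with_nonselected_cluster": with_cluster,
                "percent_with_nonselected_cluster": 100.0 * with_cluster / n,
            }
        )
    incidence = pd.DataFrame(incidence_rows)

    comp_rows = []
    for a, b in itertools.combinations(sorted(per_isolate["stratum"].unique()), 2):
        sa = per_isolate[per_isolate["stratum"] == a]
        sb = per_isolate[per_isolate["stratum"] == b]
        table22 = [
            [int((sa["n_nonselected"] >= 1).sum()), int((sa["n_nonselected"] == 0).sum())],
            [int((sb["n_nonselected"] >= 1).sum()), int((sb["n_nonselected"] == 0).sum())],
        ]
        _, fisher_p = stats.fisher_exact(table22)
        if len(sa) and len(sb):
            mw = stats.mannwhitneyu(sa["n_nonselected"], sb["n_nonselected"], alternative="two-sided")
            mw_p = float(mw.pvalue)
        else:
            mw_p = np.nan
        comp_rows.append(
            {"stratum_a": a, "stratum_b": b, "fisher_p_incidence": float(fisher_p), "ranksum_p_counts": mw_p}
        )
    comparisons = pd.DataFrame(
        comp_rows, columns=["stratum_a", "stratum_b", "fisher_p_incidence", "ranksum_p_counts"]
    )

    feats = per_isolate[["n_clustered_mutations", "sum_cluster_length", "mean_density_per_kb"]]
    correlations = feats.corr(method="pearson")

    return {
        "incidence": incidence,
        "per_isolate": per_isolate,
        "comparisons": comparisons,
        "correlations": correlations,
    }
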