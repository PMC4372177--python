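"""Calling age-associated differentially methylated clusters (aDMCs).

A positional "bump-hunting" pass over the genome-wide results: significant
probes on each chromosome are grouped into maximal runs in which every
consecutive pair lies within ``max_gap`` (10 kb) of each other. A candidate
run becomes an aDMC when, correcting for array design density, the inclusive
genomic span of its members contains at least ``min_probes_in_span`` (10)
probes from the full post-QC probe set, of which at least
``min_significant_fraction`` (50%) are genome-wide significant.

Each cluster is labeled ``positive`` or ``negative`` when every significant
member's age slope has that sign, and ``varying`` otherwise; the three labels
partition the cluster set.

The chained consecutive-gap rule is the default adjacency; an all-pairs
variant (every pair of members within ``max_gap``, i.e. total span bounded)
is available via ``all_pairs=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClusterCriteria",
    "ClusterRecord",
    "gap_cluster",
    "filter_admc",
    "direction_label",
    "call_admcs",
    "clusters_to_bed",
]


@dataclass
class ClusterCriteria:
    max_gap: int = 10_000          # bp between consecutive significant sites
    min_probes_in_span: int = 10   # post-QC probes inside the cluster span
    min_significant_fraction: float = 0.5

    def __post_init__(self):
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")
        if not 0.0 < self.min_significant_fraction <= 1.0:
            raise ValueError("min_significant_fraction must be in (0,1]")


@dataclass
class ClusterRecord:
    cluster_id: str
    chromosome: str
    start: int  # 1-based position of first significant member
    end: int    # 1-based position of last significant member
    member_probe_ids: list[str]
    n_probes_in_span: int  # from the full post-QC set, inclusive span
    n_significant: int
    direction: str  # positive | negative | varying
    genes: list[str] = field(default_factory=list)

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------

def gap_cluster(
    sig_probes: pd.DataFrame, max_gap: int = 10_000, all_pairs: bool = False
) -> list[pd.DataFrame]:
    """Group probes into positional candidate clusters, per chromosome.

    ``sig_probes`` needs ``chromosome`` and ``position`` columns (1-based bp)
    indexed by probe id; it is sorted internally. Default rule: a new cluster
    starts whenever the gap to the previous probe exceeds ``max_gap``. With
    ``all_pairs=True`` a cluster is additionally split so that its total span
    never exceeds ``max_gap`` (every pair within the gap). Singletons are
    legitimate candidates at this stage.
    """
    out: list[pd.DataFrame] = []
    df = sig_probes.sort_values(["chromosome", "position"], kind="stable")
    for _, chrom_df in df.groupby("chromosome", sort=True):
        pos = chrom_df["position"].to_numpy()
        breaks = [0]
        anchor = 0  # first index of the open cluster (for all-pairs span rule)
        for i in range(1, len(pos)):
            if pos[i] - pos[i - 1] > max_gap or (
                all_pairs and pos[i] - pos[anchor] > max_gap
            ):
                breaks.append(i)
                anchor = i
        breaks.append(len(pos))
        for a, b in zip(breaks[:-1], breaks[1:]):
            out.append(chrom_df.iloc[a:b])
    return out


def direction_label(slopes) -> str:
    """positive iff all slopes > 0, negative iff all < 0, else varying."""
    s = np.asarray(list(slopes), dtype=float)
    if len(s) == 0:
        raise ValueError("direction undefined for an empty slope set")
    if np.any(s == 0):
        warnings.warn("zero slope in cluster counted as neither sign", stacklevel=2)
    if np.all(s > 0):
        return "positive"
    if np.all(s < 0):
        return "negative"
    return "varying"


def filter_admc(
    candidates: list[pd.DataFrame],
    all_probes: pd.DataFrame,
    results: pd.DataFrame,
    crit: ClusterCriteria | None = None,
) -> list[ClusterRecord]:
    """Apply the density criteria to candidate clusters.

    ``all_probes`` is the post-QC probe annotation (chromosome, position,
    gene); ``results`` the per-probe association table with ``beta_age``.
    For each candidate the probe count is taken over the full post-QC set
    within the inclusive [min, max] span of the candidate's members (the
    array-density correction), and the cluster is retained when that count
    reaches ``min_probes_in_span`` and the significant fraction reaches
    ``min_significant_fraction``.
    """
    crit = crit or ClusterCriteria()
    records: list[ClusterRecord] = []
    k = 0
    for cand in candidates:
        chrom = str(cand["chromosome"].iloc[0])
        start = int(cand["position"].min())
        end = int(cand["position"].max())
        chrom_probes = all_probes[all_probes["chromosome"].astype(str) == chrom]
        in_span = chrom_probes[
            (chrom_probes["position"] >= start) & (chrom_probes["position"] <= end)
        ]
        n_span = int(in_span.shape[0])
        n_sig = int(cand.shape[0])
        if n_span < crit.min_probes_in_span:
            continue
        if n_sig / n_span < crit.min_significant_fraction:
            continue
        slopes = results.loc[cand.index, "beta_age"]
        genes = sorted(
            {g for g in in_span.get("gene", pd.Series(dtype=str)).fillna("") if g}
        )
        k += 1
        records.append(
            ClusterRecord(
                cluster_id=f"aDMC{k:04d}",
                chromosome=chrom,
                start=start,
                end=end,
                member_probe_ids=[str(i) for i in cand.index],
                n_probes_in_span=n_span,
                n_significant=n_sig,
                direction=direction_label(slopes),
                genes=genes,
            )
        )
    return records


def call_admcs(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    crit: ClusterCriteria | None = None,
    all_pairs: bool = False,
) -> list[ClusterRecord]:
    """End-to-end aDMC calling from an EWAS results table.

    ``results`` must carry ``significant`` and ``beta_age``; ``annotation``
    maps every post-QC probe to chromosome/position/gene. Only probes present
    in both tables are considered.
    """
    crit = crit or ClusterCriteria()
    shared = results.index.intersection(annotation.index, sort=False)
    ann = annotation.loc[shared]
    res = results.loc[shared]
    sig = ann[res["significant"].astype(bool)]
    candidates = gap_cluster(sig, max_gap=crit.max_gap, all_pairs=all_pairs)
    return filter_admc(candidates, ann, res, crit)


def clusters_to_bed(records: list[ClusterRecord]) -> pd.DataFrame:
    """BED-like table (0-based start) summarizing called clusters."""
    return pd.DataFrame(
        {
            "chrom": [r.chromosome for r in records],
            "start": [r.start - 1 for r in records],  # BED half-open convention
            "end": [r.end for r in records],
            "cluster_id": [r.cluster_id for r in records],
            "n_probes_in_span": [r.n_probes_in_span for r in records],
            "n_significant": [r.n_significant for r in records],
            "direction": [r.direction for r in records],
            "genes": [";".join(r.genes) for r in records],
        }
    )
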