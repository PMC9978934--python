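"""Feature-table analytics: relative abundance, "others" aggregation,
rarefaction, observed richness and Shannon diversity.

The unit of analysis is a taxon-by-sample count table from 16S amplicon
sequencing of fermentation fluid, with per-sample metadata (batch, day, pH,
ORP, optionally dyeing intensity).  Minor taxa are collapsed into a single
"Others" row: a taxon is retained iff its relative abundance reaches the
cutoff (default 4.1%) in at least one sample of the analysis window.
Alpha diversity is computed at a fixed rarefaction depth (default 8,825
reads) by repeated subsampling without replacement.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

OTHERS_LABEL = "Others"

__all__ = [
    "FeatureTable",
    "AnalysisThresholds",
    "relative_abundance",
    "aggregate_others",
    "rarefy",
    "observed_features",
    "shannon",
    "alpha_diversity_series",
    "expected_richness",
    "mean_reads_per_sample",
    "derive_seed",
    "OTHERS_LABEL",
]


def derive_seed(master_seed: int, *labels) -> int:
    """Stable per-stream seed below 2**31, from a master seed and labels.

    Hash-based so adding a new stream never perturbs existing ones.
    """
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for lab in labels:
        h.update(b"\x00")
        h.update(str(lab).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


@dataclass
class FeatureTable:
    """Taxon-by-sample integer counts plus per-sample metadata.

    ``counts``: DataFrame indexed by taxon id, columns are sample ids.
    ``sample_meta``: DataFrame indexed by sample id with at least
    ``batch_id`` and ``day`` columns.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        vals = self.counts.to_numpy()
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "taxon_id"
        self.sample_meta.index.name = "sample_id"
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        for col in ("batch_id", "day"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample metadata lacks required column {col!r}")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, samples) -> "FeatureTable":
        samples = list(samples)
        return FeatureTable(self.counts[samples], self.sample_meta.loc[samples])

    def window(self, day_min: float, day_max: float) -> "FeatureTable":
        """Samples whose day lies in [day_min, day_max]."""
        meta = self.sample_meta.loc[self.samples]
        keep = meta.index[(meta["day"] >= day_min) & (meta["day"] <= day_max)]
        return self.subset_samples(keep)


@dataclass(frozen=True)
class AnalysisThresholds:
    """The screening thresholds used throughout the pipeline.

    Defaults follow the study conditions: minor taxa collapsed below a 4.1%
    max relative abundance, alpha diversity at 8,825 reads, network edges at
    Spearman |rs| > 0.6 with p < 0.05, KO-phenotype hits at r >= 0.69, and
    subpathway enrichment at ratio > 1.05.
    """

    others_cutoff: float = 0.041
    rarefaction_depth: int = 8825
    rs_min: float = 0.6
    alpha: float = 0.05
    ko_r_min: float = 0.69
    pathway_ratio_min: float = 1.05

    def __post_init__(self) -> None:
        if not (0.0 < self.others_cutoff < 1.0):
            raise ValueError("others_cutoff must lie in (0, 1)")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


def mean_reads_per_sample(total_reads: int, n_samples: int) -> int:
    """Per-sample sequencing average as reported in run summaries:
    total / n, rounded to the nearest read."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return int(round(total_reads / n_samples))


def relative_abundance(table: FeatureTable) -> pd.DataFrame:
    """Per-sample proportions: each column divided by its sum."""
    sums = table.counts.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise ValueError(f"zero-sum sample(s): {zero}")
    return table.counts / sums


def aggregate_others(rel: pd.DataFrame, cutoff: float = 0.041) -> pd.DataFrame:
    """Collapse minor taxa into an ``Others`` row.

    A taxon is retained iff its maximum proportion over the table's samples
    is >= cutoff (the "in any sample" rule; the boundary is retained).
    Column sums are preserved.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff!r}")
    keep = rel.max(axis=1) >= cutoff
    retained = rel.loc[keep]
    others = rel.loc[~keep].sum(axis=0)
    others.name = OTHERS_LABEL
    return pd.concat([retained, others.to_frame().T])


def rarefy(counts, depth: int, seed: int) -> np.ndarray:
    """Subsample one sample's counts without replacement to ``depth`` reads.

    Multivariate hypergeometric draw; the result sums exactly to ``depth``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds sample total {total}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def observed_features(counts) -> int:
    """Number of taxa with count > 0."""
    return int((np.asarray(counts) > 0).sum())


def shannon(counts, log_base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base(p_i) over taxa with p_i > 0.

    Base 2 (bits) by default, matching the common amplicon-workflow default.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    p = counts[counts > 0] / total
    return float(-(p * (np.log(p) / np.log(log_base))).sum())


def expected_richness(counts, depth: int) -> float:
    """Expected number of taxa observed in a without-replacement subsample.

    E[S] = sum_i [1 - C(N - N_i, d) / C(N, d)], evaluated in log space.
    Analytic mean of the hypergeometric rarefaction draw.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if depth > N:
        raise ValueError(f"depth {depth} exceeds total {N}")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = 0.0
    for n_i in counts:
        if N - n_i < depth:
            out += 1.0  # the taxon cannot be missed
        else:
            out += 1.0 - np.exp(log_choose(N - n_i, depth) - log_choose(N, depth))
    return float(out)


def alpha_diversity_series(
    table: FeatureTable,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
    replicates: int = 10,
    seed: int = 0,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Per-sample observed richness and Shannon index at a fixed depth.

    Each sample is rarefied ``replicates`` times (per-sample substreams
    derived from the master seed and the sample id) and the metrics are
    averaged.  Samples shallower than the depth are excluded with a warning,
    mirroring fixed-depth alpha-diversity practice.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    depth = thresholds.rarefaction_depth
    rows = {}
    for sample in table.samples:
        counts = table.counts[sample].to_numpy()
        total = int(counts.sum())
        if total < depth:
            logger.warning(
                "sample %s excluded from alpha diversity: %d reads < depth %d",
                sample, total, depth,
            )
            continue
        obs, sh = [], []
        for r in range(replicates):
            sub = rarefy(counts, depth, derive_seed(seed, "rarefy", sample, r))
            obs.append(observed_features(sub))
            sh.append(shannon(sub, log_base=log_base))
        rows[sample] = {"observed": float(np.mean(obs)), "shannon": float(np.mean(sh))}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")
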