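"""Sample-level QC gates, qPCR exclusion rules, pooling plan, saturation.

Two QC layers guard a multiplexed cfRNA experiment: qPCR gates applied
before library preparation (RNA content via ACTB exon-exon Ct, residual DNA
via ACTB intron Ct, bacterial contamination via the ACTB-ee minus 16S-V4
Ct difference) and sequencing-metric gates applied after (read counts,
rRNA/mtRNA fractions, aligned and deduplicated read counts). Samples that
survive the qPCR gates are pooled 3- to 5-plex with similar cDNA content
(Ct range < 1 cycle) so per-sample read yields stay balanced. All
thresholds are strict inequalities; boundary values fail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QCMetrics:
    """Per-sample pipeline metrics and qPCR Ct values (absent = None)."""

    sample_id: str
    raw_reads: Optional[int] = None
    clean_reads: Optional[int] = None
    genome_aligned_reads: Optional[int] = None
    dedup_reads: Optional[int] = None
    rrna_fraction: Optional[float] = None
    mtrna_fraction: Optional[float] = None
    ct_actb_ee: Optional[float] = None
    ct_actb_i: Optional[float] = None
    ct_16s_v4: Optional[float] = None

    def __post_init__(self):
        for name in ("raw_reads", "clean_reads", "genome_aligned_reads", "dedup_reads"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.sample_id}: negative count {name}={v}")
        for name in ("rrna_fraction", "mtrna_fraction"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{self.sample_id}: {name}={v} outside [0,1]")

    @property
    def delta_ct_16s(self) -> Optional[float]:
        if self.ct_actb_ee is None or self.ct_16s_v4 is None:
            return None
        return self.ct_actb_ee - self.ct_16s_v4


# (rule name, metric attribute, comparator, threshold); all strict.
SEQ_QC_RULES = (
    ("raw_reads", "raw_reads", ">", 4_000_000),
    ("clean_reads", "clean_reads", ">", 3_800_000),
    ("rrna_fraction", "rrna_fraction", "<", 0.20),
    ("mtrna_fraction", "mtrna_fraction", "<", 0.20),
    ("genome_aligned_reads", "genome_aligned_reads", ">", 2_000_000),
    ("dedup_reads", "dedup_reads", ">", 100_000),
)


@dataclass
class QCReport:
    """Per-sample verdicts plus cohort summary counts."""

    verdicts: dict[str, bool]                 # sample -> pass
    failed_rules: dict[str, list[str]]        # sample -> ordered failed rules
    n_pass: int = 0
    n_fail: int = 0

    def __post_init__(self):
        self.n_pass = sum(self.verdicts.values())
        self.n_fail = len(self.verdicts) - self.n_pass

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"sample_id": s, "pass": self.verdicts[s],
             "failed_rules": ",".join(self.failed_rules[s])}
            for s in self.verdicts
        ])


def qc_samples(metrics: Sequence[QCMetrics]) -> QCReport:
    """Apply the six sequencing-metric gates to every sample.

    All six rules are evaluated independently (no short-circuit) and every
    verdict recorded; a missing metric makes its rule not-evaluable and
    fails the sample defensively (reported as ``<rule>:missing``).
    """
    verdicts: dict[str, bool] = {}
    failed: dict[str, list[str]] = {}
    for m in metrics:
        fails: list[str] = []
        for rule, attr, op, threshold in SEQ_QC_RULES:
            value = getattr(m, attr)
            if value is None:
                fails.append(f"{rule}:missing")
                continue
            ok = value > threshold if op == ">" else value < threshold
            if not ok:
                fails.append(rule)
        verdicts[m.sample_id] = not fails
        failed[m.sample_id] = fails
    return QCReport(verdicts=verdicts, failed_rules=failed)


def qpcr_exclude(metrics: Sequence[QCMetrics]) -> dict[str, list[str]]:
    """qPCR-based exclusion flags per sample (empty list = keep).

    Excluded iff any of: low RNA content (ACTB-ee Ct > 32), high DNA
    contamination (ACTB-intron Ct < 35), high bacterial contamination
    (ACTB-ee minus 16S-V4 Ct difference > 5). Rules with missing Ct values
    are skipped (no measurement, no exclusion).
    """
    out: dict[str, list[str]] = {}
    for m in metrics:
        reasons: list[str] = []
        if m.ct_actb_ee is not None and m.ct_actb_ee > 32:
            reasons.append("low_rna_content")
        if m.ct_actb_i is not None and m.ct_actb_i < 35:
            reasons.append("dna_contamination")
        d = m.delta_ct_16s
        if d is not None and d > 5:
            reasons.append("bacterial_contamination")
        out[m.sample_id] = reasons
    return out


def plan_pooling(ct_values: dict[str, float], max_delta: float = 1.0,
                 min_plex: int = 3, max_plex: int = 5
                 ) -> tuple[list[list[str]], list[str]]:
    """Group samples with similar cDNA content into 3- to 5-plex pools.

    Samples are sorted by ACTB-ee Ct and chunked greedily: a sample joins
    the current group while the group's Ct range stays < ``max_delta`` and
    the group holds fewer than ``max_plex`` samples; otherwise the group is
    closed (emitted as a pool if it reached ``min_plex``, else its samples
    are reported unpooled) and a new group starts. Deterministic; ties on
    Ct are ordered by sample id. Returns (pools, unpooled).
    """
    ordered = sorted(ct_values, key=lambda s: (ct_values[s], s))
    pools: list[list[str]] = []
    unpooled: list[str] = []
    group: list[str] = []

    def close():
        if len(group) >= min_plex:
            pools.append(list(group))
        else:
            unpooled.extend(group)
        group.clear()

    for s in ordered:
        if group and (len(group) == max_plex
                      or ct_values[s] - ct_values[group[0]] >= max_delta):
            close()
        group.append(s)
    if group:
        close()
    return pools, unpooled


def saturation_curve(read_table: pd.DataFrame, depths: Sequence[float],
                     seed: int = 0) -> pd.DataFrame:
    """Genes and UMIs detected at nested random subsamples of the reads.

    ``read_table`` has columns read_id, gene_id (NA for reads without a
    gene) and umi. Reads are shuffled once (seeded) and each depth takes
    the first round(depth * n) reads, so subsamples are nested and both
    curves are monotone non-decreasing by construction. Genes detected =
    distinct gene ids with >= 1 read; UMIs detected = distinct (gene, UMI)
    pairs.
    """
    for d in depths:
        if not 0 <= d <= 1:
            raise ValueError(f"depth {d} outside [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(read_table)
    order = rng.permutation(n)
    shuffled = read_table.iloc[order].reset_index(drop=True)
    rows = []
    for d in sorted(depths):
        k = int(round(d * n))
        sub = shuffled.iloc[:k]
        with_gene = sub.dropna(subset=["gene_id"])
        genes = with_gene["gene_id"].nunique()
        umis = with_gene[["gene_id", "umi"]].drop_duplicates().shape[0]
        rows.append({"depth": d, "reads": k, "genes": int(genes),
                     "umis": int(umis)})
    return pd.DataFrame(rows)


def metrics_from_tsv(path) -> list[QCMetrics]:
    """Load QCMetrics rows from a TSV (column names match field names)."""
    df = pd.read_csv(path, sep="\t")
    fields = ("raw_reads", "clean_reads", "genome_aligned_reads", "dedup_reads",
              "rrna_fraction", "mtrna_fraction", "ct_actb_ee", "ct_actb_i",
              "ct_16s_v4")
    out = []
    for _, row in df.iterrows():
        kwargs = {"sample_id": str(row["sample_id"])}
        for f in fields:
            if f in df.columns and not (isinstance(row[f], float) and math.isnan(row[f])):
                v = row[f]
                kwargs[f] = int(v) if f.endswith("reads") else float(v)
        out.append(QCMetrics(**kwargs))
    return out
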