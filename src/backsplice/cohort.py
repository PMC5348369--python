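"""Cohort-level circRNA statistics across many samples.

Given per-sample circRNA reports plus group labels (e.g. tumor vs
normal-adjacent), this module counts unique circRNAs (a coordinate counted
once however many samples carry it), per-sample ratios, recurrence at a
sample-fraction threshold, and tumor-specific circles under a containment
rule: a tumor circle identical to — or fully contained within — a normal
circle on the same chromosome is considered common to both tissues, on the
assumption that circles from the same genomic region share regulatory
function; everything else is tumor-specific.

Sample circRNA counts can be normalized per million unmapped reads for
cross-library comparison, correlated against a proliferation score (the mean
z-score of an 11-gene proliferation panel, a proxy for the risk-of-relapse
proliferation summary), and compared between groups with paired or Welch t
tests.  Cross-sample coordinate identity ignores strand.
"""

from __future__ import annotations

import bisect
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .report import SampleResult, read_report

__all__ = [
    "PROLIFERATION_GENES",
    "CohortTable",
    "ProliferationPanel",
    "compare_groups",
    "correlate",
    "normalize_counts",
    "proliferation_score",
    "ratio_to_samples",
    "read_expression",
    "read_labels",
    "recurrence_set",
    "split_specific",
    "summarize_cohort",
    "unique_circles",
]

logger = logging.getLogger(__name__)

Coord = Tuple[str, int, int]

#: 11-gene proliferation panel (all members of the PAM50 gene set).
PROLIFERATION_GENES = (
    "BIRC5", "CCNB1", "CDC20", "CEP55", "MKI67", "NDC80",
    "NUF2", "PTTG1", "RRM2", "TYMS", "UBE2C",
)


@dataclass
class CohortTable:
    samples: List[SampleResult]
    group_labels: Dict[str, str] = field(default_factory=dict)
    pairs: Optional[List[Tuple[str, str]]] = None  # (tumor_id, normal_id)

    def __post_init__(self) -> None:
        ids = {s.sample_id for s in self.samples}
        missing = sorted(set(self.group_labels) - ids)
        if missing:
            raise ValueError(f"labels refer to absent samples: {missing}")
        if self.pairs:
            for a, b in self.pairs:
                if self.group_labels.get(a) == self.group_labels.get(b):
                    raise ValueError(f"pair ({a}, {b}) members share a group label")

    def by_group(self, group: str) -> List[SampleResult]:
        return [s for s in self.samples if self.group_labels.get(s.sample_id) == group]

    def sample(self, sample_id: str) -> SampleResult:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


@dataclass
class ProliferationPanel:
    """Expression of the proliferation panel: genes x samples DataFrame."""

    expression: pd.DataFrame
    genes: Sequence[str] = PROLIFERATION_GENES

    def __post_init__(self) -> None:
        missing = [g for g in self.genes if g not in self.expression.index]
        if missing:
            raise ValueError(f"panel genes absent from expression matrix: {missing}")
        if self.expression.loc[list(self.genes)].isna().any().any():
            raise ValueError("expression matrix contains missing values for panel genes")


def unique_circles(samples: Iterable[SampleResult]) -> Tuple[Set[Coord], int]:
    """Deduplicated (chrom, start, end) set across samples, plus the total count."""
    unique: Set[Coord] = set()
    total = 0
    for sample in samples:
        for record in sample.records:
            unique.add(record.coord)
            total += 1
    return unique, total


def ratio_to_samples(unique_count: int, n_samples: int) -> float:
    """Unique circRNAs per sample, unrounded."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return unique_count / n_samples


def recurrence_set(
    samples: Sequence[SampleResult], fraction: float = 0.10
) -> Set[Coord]:
    """Coordinates present in at least ``fraction`` of the samples (inclusive)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(samples)
    counts: Counter = Counter()
    for sample in samples:
        for coord in {r.coord for r in sample.records}:
            counts[coord] += 1
    return {coord for coord, c in counts.items() if c / n >= fraction}


def split_specific(
    tumor_set: Iterable[Coord], normal_set: Iterable[Coord]
) -> Tuple[Set[Coord], Set[Coord]]:
    """Partition tumor circles into (common, tumor_specific) by containment.

    A tumor circle is common when its interval is identical to, or fully
    contained within, some normal circle on the same chromosome; otherwise it
    is tumor-specific.
    """
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end in normal_set:
        by_chrom.setdefault(chrom, []).append((start, end))
    # sort by start; prefix-max of ends answers "any normal with start <= s
    # and end >= e" in O(log n)
    prepared: Dict[str, Tuple[List[int], List[int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = [s for s, _ in ivs]
        max_ends: List[int] = []
        running = 0
        for _, e in ivs:
            running = max(running, e)
            max_ends.append(running)
        prepared[chrom] = (starts, max_ends)
    common: Set[Coord] = set()
    specific: Set[Coord] = set()
    for coord in tumor_set:
        chrom, start, end = coord
        entry = prepared.get(chrom)
        contained = False
        if entry is not None:
            starts, max_ends = entry
            i = bisect.bisect_right(starts, start)
            contained = i > 0 and max_ends[i - 1] >= end
        (common if contained else specific).add(coord)
    return common, specific


def normalize_counts(
    circ_count: int, unmapped_reads: int, scale: float = 1e6
) -> float:
    """circRNA count per ``scale`` (default per million) unmapped reads."""
    if unmapped_reads <= 0:
        raise ValueError("unmapped_reads must be positive")
    return circ_count / unmapped_reads * scale


def proliferation_score(
    panel: ProliferationPanel, sample_id: Optional[str] = None
):
    """Mean per-gene z-score over the proliferation panel.

    Each panel gene is centered and scaled across the cohort's samples
    (population standard deviation); a zero-variance gene contributes 0 and
    is logged.  With ``sample_id`` the scalar score for that sample is
    returned, otherwise a Series over all samples.
    """
    expr = panel.expression.loc[list(panel.genes)].astype(float)
    mean = expr.mean(axis=1)
    std = expr.std(axis=1, ddof=0)
    zero_var = std == 0
    if zero_var.any():
        logger.warning(
            "zero-variance panel genes set to z=0: %s",
            ", ".join(expr.index[zero_var]),
        )
    z = expr.sub(mean, axis=0).div(std.where(~zero_var, 1.0), axis=0)
    z.loc[zero_var] = 0.0
    scores = z.mean(axis=0)
    if sample_id is not None:
        if sample_id not in scores.index:
            raise KeyError(f"sample {sample_id!r} not in expression matrix")
        return float(scores[sample_id])
    return scores


def correlate(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlate requires equal lengths >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlate requires nonzero variance in both vectors")
    return float(stats.pearsonr(x, y).statistic)


def compare_groups(
    a: Sequence[float], b: Sequence[float], mode: str = "welch"
) -> Tuple[float, float]:
    """Two-sided t comparison of two groups.

    ``paired`` runs a paired t test on the per-pair differences (identical
    vectors give statistic 0, p 1; constant nonzero differences are
    degenerate and raise); ``welch`` runs the unequal-variance two-sample t.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if mode == "paired":
        if len(a) != len(b):
            raise ValueError("paired mode requires equal lengths")
        diff = a - b
        if np.all(diff == 0):
            return 0.0, 1.0
        if np.std(diff, ddof=1) == 0:
            raise ValueError(
                "degenerate paired comparison: constant nonzero differences"
            )
        res = stats.ttest_rel(a, b)
    elif mode == "welch":
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            raise ValueError("degenerate comparison: both groups constant")
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cohort-level summaries and file interfaces


def read_labels(path: Union[str, Path]) -> Tuple[Dict[str, str], List[Tuple[str, str]]]:
    """Read a label TSV (sample_id, group[, pair_id]) into labels and pairs.

    Pairs are formed from rows sharing a pair_id; within a pair the sample
    whose group name contains 'tumor' (case-insensitive) is listed first,
    falling back to file order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"label file must have columns {sorted(required)}")
    labels = dict(zip(df["sample_id"], df["group"]))
    pairs: List[Tuple[str, str]] = []
    if "pair_id" in df.columns:
        for _, grp in df.dropna(subset=["pair_id"]).groupby("pair_id", sort=True):
            if len(grp) != 2:
                continue
            members = list(grp["sample_id"])
            groups = list(grp["group"])
            if "tumor" in groups[1].lower() and "tumor" not in groups[0].lower():
                members.reverse()
            pairs.append((members[0], members[1]))
    return labels, pairs


def read_expression(path: Union[str, Path]) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene symbol)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def load_cohort(
    report_paths: Sequence[Union[str, Path]],
    labels_path: Optional[Union[str, Path]] = None,
) -> CohortTable:
    samples = [read_report(p) for p in report_paths]
    labels: Dict[str, str] = {}
    pairs: Optional[List[Tuple[str, str]]] = None
    if labels_path is not None:
        labels, pairs = read_labels(labels_path)
        known = {s.sample_id for s in samples}
        unknown = sorted(set(labels) - known)
        if unknown:
            raise ValueError(f"labels refer to missing reports: {unknown}")
    return CohortTable(samples, labels, pairs or None)


def summarize_cohort(
    cohort: CohortTable,
    recurrence_fraction: float = 0.10,
    tumor_group: Optional[str] = None,
    normal_group: Optional[str] = None,
) -> pd.DataFrame:
    """Per-group summary: sample counts, total/unique circles, ratios,
    recurrence at the given fraction, and tumor-specific counts when a
    tumor/normal group pairing can be identified."""
    groups = sorted({g for g in cohort.group_labels.values()}) or ["all"]
    if groups == ["all"]:
        membership = {"all": cohort.samples}
    else:
        membership = {g: cohort.by_group(g) for g in groups}
    tumor_group, normal_group = _resolve_groups(groups, tumor_group, normal_group)
    rows = []
    uniques: Dict[str, Set[Coord]] = {}
    for group in groups:
        samples = membership[group]
        unique, total = unique_circles(samples)
        uniques[group] = unique
        n = len(samples)
        rows.append(
            {
                "group": group,
                "n_samples": n,
                "total_circRNAs": total,
                "unique_circRNAs": len(unique),
                "ratio_total_to_samples": total / n if n else float("nan"),
                "ratio_unique_to_samples": len(unique) / n if n else float("nan"),
                f"unique_in_{int(recurrence_fraction * 100)}pct_or_more": len(
                    recurrence_set(samples, recurrence_fraction)
                )
                if n
                else 0,
                "tumor_specific": pd.NA,
            }
        )
    if tumor_group is not None and normal_group is not None:
        _, specific = split_specific(uniques[tumor_group], uniques[normal_group])
        for row in rows:
            if row["group"] == tumor_group:
                row["tumor_specific"] = len(specific)
    return pd.DataFrame(rows)


def _resolve_groups(groups, tumor_group, normal_group):
    if tumor_group is not None and normal_group is not None:
        return tumor_group, normal_group
    if len(groups) == 2:
        lowered = [g.lower() for g in groups]
        if "tumor" in lowered[0] and "tumor" not in lowered[1]:
            return groups[0], groups[1]
        if "tumor" in lowered[1] and "tumor" not in lowered[0]:
            return groups[1], groups[0]
    return tumor_group, normal_group


def cohort_statistics(
    cohort: CohortTable,
    panel: Optional[ProliferationPanel] = None,
    tumor_group: Optional[str] = None,
    normal_group: Optional[str] = None,
) -> dict:
    """Paired/Welch tests and proliferation correlation for a labeled cohort."""
    out: dict = {}
    groups = sorted(set(cohort.group_labels.values()))
    tumor_group, normal_group = _resolve_groups(groups, tumor_group, normal_group)
    counts = {s.sample_id: len(s.records) for s in cohort.samples}
    if cohort.pairs:
        a = [counts[t] for t, _ in cohort.pairs]
        b = [counts[n] for _, n in cohort.pairs]
        try:
            t_stat, p = compare_groups(a, b, "paired")
            out["paired_t"] = {"statistic": t_stat, "p_value": p, "n_pairs": len(a)}
        except ValueError as exc:
            out["paired_t"] = {"error": str(exc)}
        norm = []
        for t, n in cohort.pairs:
            st, sn = cohort.sample(t), cohort.sample(n)
            if st.unmapped_read_count > 0 and sn.unmapped_read_count > 0:
                norm.append(
                    (
                        normalize_counts(len(st.records), st.unmapped_read_count),
                        normalize_counts(len(sn.records), sn.unmapped_read_count),
                    )
                )
        if len(norm) >= 2:
            try:
                t_stat, p = compare_groups(
                    [x for x, _ in norm], [y for _, y in norm], "paired"
                )
                out["paired_t_normalized"] = {
                    "statistic": t_stat, "p_value": p, "n_pairs": len(norm),
                }
            except ValueError as exc:
                out["paired_t_normalized"] = {"error": str(exc)}
    if tumor_group is not None and normal_group is not None:
        a = [counts[s.sample_id] for s in cohort.by_group(tumor_group)]
        b = [counts[s.sample_id] for s in cohort.by_group(normal_group)]
        if len(a) >= 2 and len(b) >= 2:
            try:
                t_stat, p = compare_groups(a, b, "welch")
                out["welch_t"] = {
                    "statistic": t_stat,
                    "p_value": p,
                    "groups": [tumor_group, normal_group],
                }
            except ValueError as exc:
                out["welch_t"] = {"error": str(exc)}
    if panel is not None:
        scores = proliferation_score(panel)
        shared = [s.sample_id for s in cohort.samples if s.sample_id in scores.index]
        if tumor_group is not None:
            shared_t = [
                s for s in shared if cohort.group_labels.get(s) == tumor_group
            ]
        else:
            shared_t = shared
        if len(shared_t) >= 3:
            x = [float(scores[s]) for s in shared_t]
            y = [counts[s] for s in shared_t]
            try:
                out["proliferation_correlation"] = {
                    "pearson_r": correlate(x, y),
                    "n": len(x),
                    "group": tumor_group or "all",
                }
            except ValueError as exc:
                out["proliferation_correlation"] = {"error": str(exc)}
    return out
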