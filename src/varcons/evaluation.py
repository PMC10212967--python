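"""Truth comparison, precision/sensitivity/F1, subset-by-threshold sweeps,
and the germline noise table.

Comparison is keyed set arithmetic over normalized variant keys:
tp = |accepted ∩ truth|, fp = |accepted \\ truth|, fn = |truth \\ accepted|.
Precision = TP/(TP+FP), sensitivity = TP/(TP+FN), F1 their harmonic mean;
zero denominators yield 0 by a documented convention (empty call or truth
sets are degenerate, so a convention is required).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

from .consensus import combine_at_threshold, enumerate_combinations
from .errors import ConfigError
from .vcf_io import CallSet, _atomic_write
from .variant_model import VariantKey

__all__ = [
    "EvalMetrics",
    "SweepRow",
    "compare_to_truth",
    "compute_metrics",
    "threshold_sweep",
    "summarize_by_offset",
    "summarize_by_size",
    "argmax_k_per_subset",
    "noise_table",
    "noise_additional_counts",
    "pick_noisiest_caller",
    "sweep_rows_to_tsv",
]


@dataclass(frozen=True)
class EvalMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    sensitivity: float
    f1: float


@dataclass(frozen=True)
class SweepRow:
    """Metrics for one (caller subset, threshold) combination."""

    subset: tuple[str, ...]
    m: int
    k: int
    metrics: EvalMetrics
    variant_class: str = "SNV"


def compare_to_truth(
    accepted_keys: Iterable[VariantKey], truth_keys: Iterable[VariantKey]
) -> tuple[int, int, int]:
    """Set-arithmetic confusion counts (tp, fp, fn) against a truth set."""
    accepted = set(accepted_keys)
    truth = set(truth_keys)
    tp = len(accepted & truth)
    return tp, len(accepted) - tp, len(truth) - tp


def compute_metrics(tp: int, fp: int, fn: int) -> EvalMetrics:
    """Precision, sensitivity and F1 from confusion counts.

    Zero-denominator convention: a ratio with denominator 0 is 0, and F1 is
    0 whenever precision or sensitivity is 0.
    """
    if tp < 0 or fp < 0 or fn < 0:
        raise ConfigError("confusion counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    if precision and sensitivity:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        f1 = 0.0
    return EvalMetrics(tp, fp, fn, precision, sensitivity, f1)


def evaluate_keys(
    accepted_keys: Iterable[VariantKey], truth_keys: Iterable[VariantKey]
) -> EvalMetrics:
    return compute_metrics(*compare_to_truth(accepted_keys, truth_keys))


def threshold_sweep(
    callsets: Sequence[CallSet],
    truth_keys: Iterable[VariantKey],
    thresholds_rule: str = "full",
    variant_class: str = "SNV",
    allow_large: bool = False,
) -> list[SweepRow]:
    """Evaluate every caller subset at every threshold against the truth set.

    One row per (subset, k); each row's metrics equal the independent
    combine/compare/compute chain on that subset.  The support table is
    counted once over the full roster and re-projected per subset.
    """
    if not callsets:
        raise ConfigError("need at least one callset")
    truth = set(truth_keys)
    if not truth:
        raise ConfigError("truth set is empty")
    table = combine_at_threshold(callsets, 1)
    pairs = enumerate_combinations(table.roster, thresholds_rule, allow_large)

    rows: list[SweepRow] = []
    # group pairs by subset so support projection happens once per subset
    by_subset: dict[tuple[str, ...], list[int]] = {}
    for subset, k in pairs:
        by_subset.setdefault(subset, []).append(k)
    for subset, ks in by_subset.items():
        members = set(subset)
        counts: dict[VariantKey, int] = {}
        for key, callers in table.support.items():
            c = len(callers & members)
            if c:
                counts[key] = c
        for k in ks:
            accepted = {key for key, c in counts.items() if c >= k}
            rows.append(
                SweepRow(
                    subset=subset,
                    m=len(subset),
                    k=k,
                    metrics=evaluate_keys(accepted, truth),
                    variant_class=variant_class,
                )
            )
    return rows


def summarize_by_offset(
    rows: Iterable[SweepRow], min_size: int = 1
) -> dict[int, tuple[float, float]]:
    """Median and max F1 grouped by relative threshold offset m - k.

    Offset 0 is the full intersection of the subset, offset 1 the
    "all but one caller" rule, and so on.  Only subsets of at least
    *min_size* callers contribute.
    """
    grouped: dict[int, list[float]] = {}
    for row in rows:
        if row.m >= min_size:
            grouped.setdefault(row.m - row.k, []).append(row.metrics.f1)
    return {
        off: (median(f1s), max(f1s)) for off, f1s in sorted(grouped.items())
    }


def summarize_by_size(rows: Iterable[SweepRow]) -> dict[int, tuple[float, float]]:
    """Median-of-best and max F1 grouped by number of combined callers.

    For each subset, take its best F1 over thresholds; report the median
    and maximum of those bests per subset size.
    """
    best: dict[tuple[str, ...], float] = {}
    for row in rows:
        cur = best.get(row.subset)
        if cur is None or row.metrics.f1 > cur:
            best[row.subset] = row.metrics.f1
    by_m: dict[int, list[float]] = {}
    for subset, f1 in best.items():
        by_m.setdefault(len(subset), []).append(f1)
    return {m: (median(v), max(v)) for m, v in sorted(by_m.items())}


def argmax_k_per_subset(rows: Iterable[SweepRow]) -> dict[tuple[str, ...], int]:
    """F1-maximizing threshold per subset; ties resolved to the largest k
    (the most conservative acceptance)."""
    best: dict[tuple[str, ...], tuple[float, int]] = {}
    for row in rows:
        cur = best.get(row.subset)
        cand = (row.metrics.f1, row.k)
        if cur is None or cand > cur:
            best[row.subset] = cand
    return {subset: k for subset, (_, k) in best.items()}


def noise_table(
    noise_callsets_per_sample: Mapping[str, Sequence[CallSet]],
    ks: Sequence[int] | None = None,
) -> dict[str, dict[int, int]]:
    """Counts of consensus-accepted noise keys per sample and threshold.

    Input is, per sample, one already-partitioned noise callset per caller
    (same roster for every sample).  cell(sample, k) = number of noise keys
    accepted at minimum intersection k.  Counts are non-increasing in k.
    """
    rosters = {
        tuple(sorted(cs.caller_id for cs in callsets))
        for callsets in noise_callsets_per_sample.values()
    }
    if len(rosters) > 1:
        raise ConfigError(f"inconsistent caller rosters across samples: {rosters}")
    out: dict[str, dict[int, int]] = {}
    for sample, callsets in noise_callsets_per_sample.items():
        table = combine_at_threshold(list(callsets), 1)
        sample_ks = ks if ks is not None else range(1, table.n + 1)
        out[sample] = {k: len(table.at_threshold(k).accepted) for k in sample_ks}
    return out


def pick_noisiest_caller(
    noise_callsets_per_sample: Mapping[str, Sequence[CallSet]]
) -> str:
    """Heuristic: the caller with the most noise calls summed over samples."""
    totals: dict[str, int] = {}
    for callsets in noise_callsets_per_sample.values():
        for cs in callsets:
            totals[cs.caller_id] = totals.get(cs.caller_id, 0) + len(cs)
    return max(sorted(totals), key=lambda c: totals[c])


def noise_additional_counts(
    full: Mapping[str, Mapping[int, int]],
    dropped: Mapping[str, Mapping[int, int]],
    n_full: int,
    offsets: Sequence[int] = (0, 1, 2),
) -> dict[str, dict[int, int]]:
    """Additional accepted-noise counts after removing one caller.

    Rows are compared at matching relative thresholds: offset j means
    k = n - j for the full roster and k = (n-1) - j for the reduced one.
    """
    out: dict[str, dict[int, int]] = {}
    for sample in full:
        out[sample] = {}
        for j in offsets:
            k_full = n_full - j
            k_drop = n_full - 1 - j
            if k_full < 1 or k_drop < 1:
                continue
            out[sample][j] = dropped[sample][k_drop] - full[sample][k_full]
    return out


def sweep_rows_to_tsv(rows: Sequence[SweepRow], path: str) -> None:
    """Write sweep rows as TSV with a stable, documented column set."""
    lines = ["subset\tm\tk\tvariant_class\ttp\tfp\tfn\tprecision\tsensitivity\tf1"]
    for r in rows:
        mt = r.metrics
        lines.append(
            f"{','.join(r.subset)}\t{r.m}\t{r.k}\t{r.variant_class}\t"
            f"{mt.tp}\t{mt.fp}\t{mt.fn}\t"
            f"{mt.precision:.6f}\t{mt.sensitivity:.6f}\t{mt.f1:.6f}"
        )
    _atomic_write(path, "\n".join(lines) + "\n")
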