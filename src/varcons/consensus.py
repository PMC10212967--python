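"""k-of-n minimum-intersection consensus over per-caller callsets.

A variant is accepted when it is called by at least k of the n combined
callers.  k=1 is the union, k=n the full intersection.  The module also
enumerates caller subsets and thresholds for exhaustive sweeps and builds
the support histogram (how many keys are called by exactly j callers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

from .errors import ConfigError
from .vcf_io import CallSet
from .variant_model import VariantKey

__all__ = [
    "ConsensusTable",
    "combine_at_threshold",
    "support_histogram",
    "enumerate_combinations",
    "resolve_threshold",
    "MAX_ROSTER",
]

# Combinatorial guard: 2^12 subsets is the largest sweep allowed by default.
MAX_ROSTER = 12


@dataclass
class ConsensusTable:
    """Per-key caller support and the acceptance decision at threshold k."""

    roster: tuple[str, ...]
    support: dict[VariantKey, frozenset[str]]
    k: int
    accepted: set[VariantKey] = field(default_factory=set)

    @property
    def n(self) -> int:
        return len(self.roster)

    def support_count(self, key: VariantKey) -> int:
        return len(self.support.get(key, frozenset()))

    def at_threshold(self, k: int) -> "ConsensusTable":
        """Re-threshold the same support table without recounting."""
        if not 1 <= k <= self.n:
            raise ConfigError(f"threshold k={k} out of range 1..{self.n}")
        accepted = {key for key, callers in self.support.items() if len(callers) >= k}
        return ConsensusTable(self.roster, self.support, k, accepted)


def combine_at_threshold(callsets: Sequence[CallSet], k: int) -> ConsensusTable:
    """Count per-key caller support and accept keys called by >= k callers.

    Deterministic regardless of callset order.  Raises :class:`ConfigError`
    for k outside 1..n or duplicate caller ids.
    """
    if not callsets:
        raise ConfigError("need at least one callset")
    roster = tuple(cs.caller_id for cs in callsets)
    if len(set(roster)) != len(roster):
        raise ConfigError(f"duplicate caller ids in roster {roster}")
    n = len(roster)
    if not 1 <= k <= n:
        raise ConfigError(f"threshold k={k} out of range 1..{n}")

    support: dict[VariantKey, set[str]] = {}
    for cs in callsets:
        for key in cs.variants:
            support.setdefault(key, set()).add(cs.caller_id)
    frozen = {key: frozenset(callers) for key, callers in support.items()}
    accepted = {key for key, callers in frozen.items() if len(callers) >= k}
    return ConsensusTable(roster, frozen, k, accepted)


def support_histogram(callsets: Sequence[CallSet]) -> dict[int, int]:
    """Histogram over support counts 1..n: how many keys have exactly j callers."""
    table = combine_at_threshold(callsets, 1)
    hist = {j: 0 for j in range(1, table.n + 1)}
    for callers in table.support.values():
        hist[len(callers)] += 1
    return hist


def enumerate_combinations(
    roster: Sequence[str],
    thresholds_rule: str = "full",
    allow_large: bool = False,
) -> list[tuple[tuple[str, ...], int]]:
    """All (caller subset, threshold) pairs to sweep.

    ``full``: k = 1..m for every non-empty subset of size m.
    ``min2``: k = 2..m, except singletons which get k = 1.
    Ordering is deterministic: by subset size, then lexicographic position
    in the roster, then k.  Rosters larger than ``MAX_ROSTER`` are refused
    unless *allow_large* is set.
    """
    roster = tuple(roster)
    if not roster:
        raise ConfigError("empty roster")
    if len(set(roster)) != len(roster):
        raise ConfigError(f"duplicate caller ids in roster {roster}")
    if len(roster) > MAX_ROSTER and not allow_large:
        raise ConfigError(
            f"roster of {len(roster)} callers implies {2 ** len(roster) - 1} "
            "subsets; pass allow_large=True to proceed"
        )
    if thresholds_rule not in ("full", "min2"):
        raise ConfigError(f"unknown thresholds rule {thresholds_rule!r}")

    pairs: list[tuple[tuple[str, ...], int]] = []
    for m in range(1, len(roster) + 1):
        for subset in combinations(range(len(roster)), m):
            named = tuple(roster[i] for i in subset)
            if thresholds_rule == "full":
                ks = range(1, m + 1)
            else:
                ks = range(1, 2) if m == 1 else range(2, m + 1)
            for k in ks:
                pairs.append((named, k))
    return pairs


def resolve_threshold(spec: str | int, n: int) -> int:
    """Resolve a symbolic threshold (``n``, ``n-1``, ``n-2``, ``majority``,
    or an integer) against a roster of size n.

    Symbolic n-j floors at 1; ``majority`` is the strict majority
    floor(n/2) + 1.
    """
    if isinstance(spec, int):
        k = spec
    else:
        text = str(spec).strip().lower().replace(" ", "")
        if text == "majority":
            k = n // 2 + 1
        elif text == "n":
            k = n
        elif text.startswith("n-"):
            try:
                k = max(1, n - int(text[2:]))
            except ValueError:
                raise ConfigError(f"cannot parse threshold {spec!r}") from None
        else:
            try:
                k = int(text)
            except ValueError:
                raise ConfigError(f"cannot parse threshold {spec!r}") from None
    if not 1 <= k <= n:
        raise ConfigError(f"threshold {spec!r} resolves to k={k}, outside 1..{n}")
    return k


def default_threshold(n: int, variant_class: str = "SNV") -> int:
    """Recommended acceptance threshold: n-1 for SNVs, n for indels.

    For SNVs with n <= 2 this degenerates to k = max(1, n-1), which is
    outside the recommended regime of >= 3 combined callers.
    """
    if variant_class.upper() == "INDEL":
        return n
    return max(1, n - 1)
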