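"""Read per-caller VCFs with dialect-aware support extraction; write consensus VCFs.

Callers disagree wildly on how ALT-supporting read counts and allele
frequencies are encoded in FORMAT (``AD`` pairs, scalar ``AD`` + ``RD``,
``AF``/``FA`` fractions, ``FREQ`` percent strings, Strelka tier counts,
``DP4`` strand counts...).  A :class:`CallerDialect` carries an ordered list
of extraction strategies; for each of (alt_depth, total_depth, vaf) the first
strategy that yields a value wins, and anything unresolvable stays unknown —
never guessed.  Built-in presets cover MuSE, Mutect, Mutect2, Pindel,
SomaticSniper, VarDict, VarScan and Strelka; presets are data, overridable
from a small INI file without code changes.
"""

from __future__ import annotations

import configparser
import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam

from .errors import ConfigError, FormatError, InvalidVariantError
from .variant_model import (
    GenomicVariant,
    ReferenceSource,
    VariantKey,
    normalize_alleles,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Strategy",
    "CallerDialect",
    "CallSet",
    "PRESET_DIALECTS",
    "get_dialect",
    "load_dialect_config",
    "extract_support",
    "read_caller_vcf",
    "write_consensus_vcf",
    "read_consensus_vcf",
]


@dataclass(frozen=True)
class Strategy:
    """One way of pulling (alt_depth, total_depth, vaf) out of a FORMAT blob.

    kind:
      - ``af_tag``: fraction in FORMAT tag (AF, FA); yields vaf only.
      - ``ad_pair``: per-allele depth list (ref first); yields all three,
        vaf = alt/(sum of depths), 0 if the denominator is 0.
      - ``freq_percent``: percent string like ``"10%"``; yields vaf.
      - ``alt_dp``: scalar alt-depth tag plus a DP tag; vaf = alt/DP.
      - ``dp4``: ref-fwd,ref-rev,alt-fwd,alt-rev counts.
      - ``tier_counts``: Strelka SNV AU/CU/GU/TU tier-1 counts.
      - ``tier_indel``: Strelka indel TIR/TAR tier-1 counts.
      - ``dp_tag``: total depth only.
    """

    kind: str
    tag: str = ""
    dp_tag: str = "DP"


@dataclass(frozen=True)
class CallerDialect:
    caller_id: str
    plan: tuple[Strategy, ...]
    tumor_sample: str | int | None = None

    def __post_init__(self) -> None:
        if not self.plan:
            raise ConfigError(f"dialect {self.caller_id!r} has an empty plan")


# Ordered extraction plans for widely used somatic callers.  Conventional
# FORMAT fields; users can override via an INI file.
PRESET_DIALECTS: dict[str, CallerDialect] = {
    "muse": CallerDialect("muse", (Strategy("ad_pair", "AD"), Strategy("dp_tag", dp_tag="DP"))),
    "mutect": CallerDialect("mutect", (Strategy("ad_pair", "AD"), Strategy("af_tag", "FA"))),
    "mutect2": CallerDialect("mutect2", (Strategy("ad_pair", "AD"), Strategy("af_tag", "AF"))),
    "pindel": CallerDialect("pindel", (Strategy("ad_pair", "AD"),)),
    "somaticsniper": CallerDialect("somaticsniper", (Strategy("dp4", "DP4"), Strategy("dp_tag", dp_tag="DP"))),
    "vardict": CallerDialect("vardict", (Strategy("alt_dp", "VD", "DP"), Strategy("af_tag", "AF"))),
    "varscan": CallerDialect("varscan", (Strategy("freq_percent", "FREQ"), Strategy("alt_dp", "AD", "DP"))),
    "strelka": CallerDialect(
        "strelka",
        (Strategy("tier_counts"), Strategy("tier_indel"), Strategy("ad_pair", "AD")),
    ),
}

_GENERIC_PLAN = (
    Strategy("ad_pair", "AD"),
    Strategy("af_tag", "AF"),
    Strategy("freq_percent", "FREQ"),
    Strategy("dp_tag", dp_tag="DP"),
)


def get_dialect(caller_id: str, tumor_sample: str | int | None = None) -> CallerDialect:
    """Look up a preset dialect by caller name; unknown callers get a generic plan."""
    preset = PRESET_DIALECTS.get(caller_id.lower())
    if preset is None:
        return CallerDialect(caller_id, _GENERIC_PLAN, tumor_sample)
    if tumor_sample is not None:
        return CallerDialect(preset.caller_id, preset.plan, tumor_sample)
    return preset


def load_dialect_config(path: str) -> dict[str, CallerDialect]:
    """Load user dialects from an INI file, one section per caller.

    Each section holds ``plan = kind:tag, kind:tag/dp_tag, ...`` and an
    optional ``tumor_sample``.  Example::

        [mycaller]
        plan = alt_dp:VD/DP, af_tag:AF
        tumor_sample = TUMOR
    """
    parser = configparser.ConfigParser()
    if not parser.read(path):
        raise ConfigError(f"cannot read dialect config {path!r}")
    dialects: dict[str, CallerDialect] = {}
    for section in parser.sections():
        raw = parser.get(section, "plan", fallback="")
        strategies = []
        for item in (s.strip() for s in raw.split(",") if s.strip()):
            kind, _, rest = item.partition(":")
            tag, _, dp_tag = rest.partition("/")
            strategies.append(Strategy(kind, tag, dp_tag or "DP"))
        if not strategies:
            raise ConfigError(f"dialect section [{section}] has no plan")
        tumor = parser.get(section, "tumor_sample", fallback=None)
        dialects[section] = CallerDialect(section, tuple(strategies), tumor)
    return dialects


@dataclass
class CallSet:
    """One caller's set of keyed, normalized variants."""

    caller_id: str
    variants: dict[VariantKey, GenomicVariant] = field(default_factory=dict)
    source: str = ""
    records_read: int = 0
    records_retained: int = 0
    records_skipped: int = 0

    @property
    def keys(self) -> set[VariantKey]:
        return set(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.variants

    def add(self, variant: GenomicVariant) -> None:
        """Insert a normalized variant, collapsing duplicate keys.

        On a duplicate key the record with the higher alt_depth wins
        (first seen on ties; unknown counts as -1).
        """
        key = variant.key
        existing = self.variants.get(key)
        if existing is None:
            self.variants[key] = variant
            return
        old = -1 if existing.alt_depth is None else existing.alt_depth
        new = -1 if variant.alt_depth is None else variant.alt_depth
        if new > old:
            self.variants[key] = variant

    def of_class(self, variant_class: str) -> "CallSet":
        """Project onto one variant class ("SNV" or "INDEL")."""
        return CallSet(
            caller_id=self.caller_id,
            variants={
                k: v
                for k, v in self.variants.items()
                if v.variant_class == variant_class
            },
            source=self.source,
        )

    def subset(self, keys: Iterable[VariantKey]) -> "CallSet":
        wanted = set(keys) & self.keys
        return CallSet(
            caller_id=self.caller_id,
            variants={k: self.variants[k] for k in wanted},
            source=self.source,
        )


def _scalar(value) -> float | None:
    """Collapse pysam FORMAT values (tuples of length 1, bare numbers) to a float."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        if not value or value[0] is None:
            return None
        value = value[0]
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def _int_list(value) -> list[int] | None:
    if value is None:
        return None
    if not isinstance(value, (tuple, list)):
        value = (value,)
    out = []
    for v in value:
        if v is None:
            return None
        try:
            out.append(int(v))
        except (TypeError, ValueError):
            return None
    return out


def extract_support(
    sample_fields: Mapping[str, object],
    ref: str,
    alt: str,
    alt_index: int,
    plan: Sequence[Strategy],
) -> tuple[int | None, int | None, float | None]:
    """Resolve (alt_depth, total_depth, vaf) from one sample's FORMAT fields.

    Strategies are tried in plan order; for each of the three values the
    first strategy that yields it wins.  Anything no strategy can resolve is
    returned as ``None``.

    *alt_index* is the 0-based index of the ALT allele within the record's
    ALT list (relevant for ``ad_pair`` on multi-allelic records).
    """
    alt_depth: int | None = None
    total_depth: int | None = None
    vaf: float | None = None

    def fill(ad, dp, af):
        nonlocal alt_depth, total_depth, vaf
        if alt_depth is None and ad is not None:
            alt_depth = int(ad)
        if total_depth is None and dp is not None:
            total_depth = int(dp)
        if vaf is None and af is not None:
            vaf = min(max(float(af), 0.0), 1.0)

    for strat in plan:
        if alt_depth is not None and total_depth is not None and vaf is not None:
            break
        kind = strat.kind
        if kind == "af_tag":
            fill(None, None, _scalar(sample_fields.get(strat.tag)))
        elif kind == "ad_pair":
            depths = _int_list(sample_fields.get(strat.tag))
            if depths and len(depths) >= alt_index + 2:
                ad = depths[alt_index + 1]
                total = sum(depths)
                fill(ad, total, (ad / total) if total > 0 else 0.0)
        elif kind == "freq_percent":
            raw = sample_fields.get(strat.tag)
            if isinstance(raw, (tuple, list)):
                raw = raw[0] if raw else None
            if raw is not None:
                text = str(raw).strip()
                try:
                    frac = float(text.rstrip("%")) / 100.0 if text.endswith("%") else float(text)
                except ValueError:
                    frac = None
                if frac is not None:
                    fill(None, None, frac)
        elif kind == "alt_dp":
            ad = _scalar(sample_fields.get(strat.tag))
            dp = _scalar(sample_fields.get(strat.dp_tag))
            af = (ad / dp) if (ad is not None and dp is not None and dp > 0) else None
            fill(ad, dp, af)
        elif kind == "dp4":
            counts = _int_list(sample_fields.get(strat.tag))
            if counts and len(counts) == 4:
                ad = counts[2] + counts[3]
                total = sum(counts)
                fill(ad, total, (ad / total) if total > 0 else 0.0)
        elif kind == "tier_counts":
            # Strelka SNVs: per-base tier counts AU/CU/GU/TU, tier 1 first.
            if len(ref) == 1 and len(alt) == 1:
                alt_counts = _int_list(sample_fields.get(f"{alt}U"))
                ref_counts = _int_list(sample_fields.get(f"{ref}U"))
                if alt_counts and ref_counts:
                    ad = alt_counts[0]
                    total = ad + ref_counts[0]
                    fill(ad, total, (ad / total) if total > 0 else 0.0)
        elif kind == "tier_indel":
            tir = _int_list(sample_fields.get("TIR"))
            tar = _int_list(sample_fields.get("TAR"))
            if tir and tar:
                ad = tir[0]
                total = ad + tar[0]
                fill(ad, total, (ad / total) if total > 0 else 0.0)
        elif kind == "dp_tag":
            fill(None, _scalar(sample_fields.get(strat.dp_tag)), None)
        else:
            raise ConfigError(f"unknown extraction strategy {kind!r}")
    if alt_depth is not None and total_depth is not None and alt_depth > total_depth:
        total_depth = alt_depth
    return alt_depth, total_depth, vaf


def _resolve_tumor_sample(samples: Sequence[str], dialect: CallerDialect, path: str) -> int | None:
    """Pick the tumor sample index; None when the VCF carries no samples."""
    if not samples:
        return None
    sel = dialect.tumor_sample
    if sel is None:
        if len(samples) == 1:
            return 0
        for i, name in enumerate(samples):
            if name.upper() == "TUMOR":
                return i
        raise ConfigError(
            f"{path}: multiple samples {list(samples)} and no TUMOR sample; "
            "set tumor_sample explicitly"
        )
    if isinstance(sel, int):
        if not 0 <= sel < len(samples):
            raise ConfigError(f"{path}: tumor sample index {sel} out of range")
        return sel
    if sel not in samples:
        raise ConfigError(f"{path}: declared tumor sample {sel!r} not found")
    return samples.index(sel)


def read_caller_vcf(
    path: str,
    dialect: CallerDialect,
    reference: ReferenceSource | None = None,
    contig_aliases: Mapping[str, str] | None = None,
) -> CallSet:
    """Parse one caller's VCF into a normalized, keyed :class:`CallSet`.

    Multi-allelic records are decomposed per ALT; symbolic ALTs, breakends
    and spanning-deletion ``*`` alleles are skipped with a logged warning;
    alleles are trimmed (and indels left-aligned when *reference* is given);
    duplicate keys collapse keeping the record with the highest alt_depth.
    """
    callset = CallSet(caller_id=dialect.caller_id, source=path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read VCF {path!r}: {exc}") from exc
    with vcf:
        sample_idx = _resolve_tumor_sample(list(vcf.header.samples), dialect, path)
        for rec in vcf:
            callset.records_read += 1
            chrom = rec.contig
            if contig_aliases:
                chrom = contig_aliases.get(chrom, chrom)
            filters = list(rec.filter.keys())
            filter_status = ";".join(filters) if filters else "."
            alts = rec.alts or ()
            retained_any = False
            for alt_index, alt in enumerate(alts):
                if alt is None:
                    continue
                if alt == "*" or alt.startswith("<") or any(c in alt for c in "[]"):
                    logger.warning(
                        "%s:%s skipping symbolic/structural ALT %r", path, rec.pos, alt
                    )
                    continue
                if sample_idx is not None:
                    fields = dict(rec.samples[sample_idx])
                    ad, dp, vaf = extract_support(
                        fields, rec.ref, alt, alt_index, dialect.plan
                    )
                else:
                    ad, dp, vaf = None, None, None
                try:
                    parts = normalize_alleles(chrom, rec.pos, rec.ref, alt, reference)
                except InvalidVariantError as exc:
                    raise InvalidVariantError(
                        f"{path}: {exc}", line=callset.records_read
                    ) from exc
                for p, r, a in parts:
                    callset.add(
                        GenomicVariant(
                            chrom=chrom,
                            pos=p,
                            ref=r,
                            alt=a,
                            caller_id=dialect.caller_id,
                            filter_status=filter_status,
                            alt_depth=ad,
                            total_depth=dp,
                            vaf=vaf,
                        )
                    )
                    retained_any = True
            if retained_any:
                callset.records_retained += 1
            else:
                callset.records_skipped += 1
    return callset


def _contig_order(keys: Iterable[VariantKey]) -> list[str]:
    """Natural-ish sort of contig names (chr2 before chr10)."""

    def sortkey(name: str):
        stripped = name[3:] if name.lower().startswith("chr") else name
        return (0, int(stripped)) if stripped.isdigit() else (1, stripped)

    return sorted({k.chrom for k in keys}, key=sortkey)


def write_consensus_vcf(
    consensus_table,
    callsets: Sequence[CallSet],
    path: str,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write accepted consensus variants as a VCF v4.2 file.

    One record per accepted key, sorted by (contig order, pos, ref, alt),
    FILTER=PASS, with INFO fields SUPPORT (caller count), CALLERS
    (supporting caller ids) and CALLER_VAFS (``caller:vaf`` pairs).  The
    header records the threshold and roster.  Written atomically
    (temp file + rename).
    """
    by_caller = {cs.caller_id: cs for cs in callsets}
    order = _contig_order(consensus_table.accepted)
    rank = {name: i for i, name in enumerate(order)}
    accepted = sorted(
        consensus_table.accepted,
        key=lambda k: (rank[k.chrom], k.pos, k.ref, k.alt),
    )

    lines = ["##fileformat=VCFv4.2"]
    lines.append(f"##varcons_threshold={consensus_table.k}")
    lines.append(f"##varcons_callers={','.join(consensus_table.roster)}")
    for name in order:
        length = (contigs or {}).get(name)
        if length:
            lines.append(f"##contig=<ID={name},length={length}>")
        else:
            lines.append(f"##contig=<ID={name}>")
    lines.append(
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,'
        'Description="Number of callers supporting the variant">'
    )
    lines.append(
        '##INFO=<ID=CALLERS,Number=.,Type=String,'
        'Description="Supporting caller identifiers">'
    )
    lines.append(
        '##INFO=<ID=CALLER_VAFS,Number=.,Type=String,'
        'Description="Per-caller variant allele frequency as caller:vaf">'
    )
    lines.append('##FILTER=<ID=PASS,Description="Accepted by consensus threshold">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    for key in accepted:
        supporters = sorted(consensus_table.support[key])
        vaf_parts = []
        for caller in supporters:
            cs = by_caller.get(caller)
            var = cs.variants.get(key) if cs else None
            if var is not None and var.vaf is not None:
                vaf_parts.append(f"{caller}:{var.vaf:.6g}")
            else:
                vaf_parts.append(f"{caller}:.")
        info = (
            f"SUPPORT={len(supporters)};"
            f"CALLERS={','.join(supporters)};"
            f"CALLER_VAFS={','.join(vaf_parts)}"
        )
        lines.append(
            f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t{info}"
        )

    _atomic_write(path, "\n".join(lines) + "\n")


def read_consensus_vcf(path: str) -> dict[VariantKey, tuple[int, tuple[str, ...]]]:
    """Read back a consensus VCF: key -> (support count, supporting callers)."""
    out: dict[VariantKey, tuple[int, tuple[str, ...]]] = {}
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read VCF {path!r}: {exc}") from exc
    with vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                key = VariantKey(rec.contig, rec.pos, rec.ref.upper(), alt.upper())
                support = int(rec.info.get("SUPPORT", 0))
                callers = rec.info.get("CALLERS", ())
                if isinstance(callers, str):
                    callers = (callers,)
                out[key] = (support, tuple(callers))
    return out


def _atomic_write(path: str, text: str) -> None:
    """Write to a temp file in the target directory, then rename into place."""
    directory = os.path.dirname(os.path.abspath(path))
    os.makedirs(directory, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
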