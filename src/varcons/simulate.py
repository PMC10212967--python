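"""Synthetic multi-caller datasets with known truth.

Emulates the statistical structure a consensus analysis needs: a shared
truth set, independent per-caller misses, caller-private systematic false
positives ("deterministic noise"), correlated false positives shared by
groups of callers, and — in germline mode — samples whose real calls sit in
the heterozygous/homozygous VAF windows while noise calls sit outside.

Everything is driven by a single integer seed and is bit-reproducible.
Written fixtures use each caller's native FORMAT dialect so the support
extractor is exercised end to end.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .filtering import HET_WINDOW, HOM_WINDOW
from .variant_model import GenomicVariant, VariantKey
from .vcf_io import CallSet, _atomic_write

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "GermlineDataset",
    "simulate_dataset",
    "simulate_germline_samples",
    "write_fixture_vcfs",
    "write_germline_fixtures",
    "DEFAULT_CALLER_IDS",
]

DEFAULT_CALLER_IDS = (
    "mutect2",
    "varscan",
    "vardict",
    "strelka",
    "muse",
    "somaticsniper",
    "mutect",
    "pindel",
)

# VAF region used for somatic fixtures: comfortably inside the
# low-stringency filter (> 0.02) so retention bookkeeping stays exact.
_SOMATIC_REGION = (0.05, 0.95)
_NOISE_REGION = (0.05, 0.35)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the generator.

    ``shared_fp_counts`` maps group size j to the number of false-positive
    keys shared by a random group of exactly j callers.  The default mix
    (pairs, triples and quadruples) gives correlated noise that only a high
    intersection threshold removes, which is what makes the n-1 rule
    visibly optimal in sweeps; it is otherwise arbitrary.
    """

    seed: int = 0
    n_callers: int = 6
    n_true_variants: int = 1000
    snv_fraction: float = 1.0
    miss_probability: float = 0.05
    private_fp_count: int = 100
    shared_fp_counts: Mapping[int, int] | None = None
    contig: str = "chrS"
    contig_length: int = 10_000_000
    germline_mode: bool = False
    n_samples: int = 10
    noise_per_caller: int = 30
    shared_noise_count: int = 5
    het_fraction: float = 0.67
    somatic_vaf: float = 0.30
    mean_depth: int = 80
    vaf_concentration: float = 60.0
    caller_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.miss_probability <= 1:
            raise ConfigError("miss_probability must be in [0, 1]")
        if not 0 <= self.snv_fraction <= 1:
            raise ConfigError("snv_fraction must be in [0, 1]")
        if not 0 <= self.het_fraction <= 1:
            raise ConfigError("het_fraction must be in [0, 1]")
        if self.n_callers < 1:
            raise ConfigError("need at least one caller")
        if min(self.n_true_variants, self.private_fp_count, self.noise_per_caller,
               self.shared_noise_count, self.n_samples) < 0:
            raise ConfigError("counts must be non-negative")
        if self.shared_fp_counts is None:
            # default correlated-noise mix, clipped to the roster size
            object.__setattr__(
                self,
                "shared_fp_counts",
                {j: c for j, c in {2: 150, 3: 80, 4: 120}.items()
                 if j <= self.n_callers},
            )
        for j, count in dict(self.shared_fp_counts).items():
            if count < 0:
                raise ConfigError("shared FP counts must be non-negative")
            if not 2 <= j <= self.n_callers:
                raise ConfigError(
                    f"shared FP group size {j} outside 2..{self.n_callers}"
                )
        if not self.caller_ids:
            if self.n_callers <= len(DEFAULT_CALLER_IDS):
                roster = DEFAULT_CALLER_IDS[: self.n_callers]
            else:
                roster = tuple(f"caller{i}" for i in range(self.n_callers))
            object.__setattr__(self, "caller_ids", roster)
        elif len(self.caller_ids) != self.n_callers:
            raise ConfigError("caller_ids length must equal n_callers")


@dataclass
class SimulatedDataset:
    """Simulated somatic dataset with exact bookkeeping.

    ``manifest`` records, per key, whether it is truth and which callers
    carry it — everything needed to recompute tp/fp/fn independently.
    """

    config: SimulationConfig
    truth: CallSet
    callsets: list[CallSet]
    manifest: dict[VariantKey, dict]

    @property
    def truth_keys(self) -> set[VariantKey]:
        return self.truth.keys


@dataclass
class GermlineDataset:
    """Per-sample germline fixtures: real calls in-window, noise outside."""

    config: SimulationConfig
    samples: dict[str, dict]  # sample -> {"truth": CallSet, "callsets": [CallSet]}


_BASES = np.array(list("ACGT"))


def _draw_alleles(rng: np.random.Generator, n_snv: int, n_indel: int):
    """Random already-normalized allele pairs (SNVs + anchored 1-3 bp indels)."""
    pairs: list[tuple[str, str]] = []
    for _ in range(n_snv):
        ref = rng.choice(_BASES)
        alt = rng.choice([b for b in "ACGT" if b != ref])
        pairs.append((str(ref), str(alt)))
    for _ in range(n_indel):
        anchor = str(rng.choice(_BASES))
        tail = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
        if rng.random() < 0.5:
            pairs.append((anchor, anchor + tail))  # insertion
        else:
            pairs.append((anchor + tail, anchor))  # deletion
    return pairs


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    # distinct positions, spaced >= 8 apart so indel keys can never collide
    if n == 0:
        return np.array([], dtype=int)
    capacity = (length - 10) // 8
    if n > capacity:
        raise ConfigError(f"contig too short for {n} distinct variants")
    slots = rng.choice(capacity, size=n, replace=False)
    return np.sort(slots * 8 + 5)


def _draw_support(
    rng: np.random.Generator,
    target_vaf: float,
    region: tuple[float, float],
    mean_depth: int,
    concentration: float,
) -> tuple[int, int, float]:
    """Beta-binomial depth/alt draw, clamped so the realized VAF stays in
    *region* (construction guarantee used by the bookkeeping oracles)."""
    depth = max(20, int(rng.poisson(mean_depth)))
    a = max(target_vaf * concentration, 1e-3)
    b = max((1 - target_vaf) * concentration, 1e-3)
    p = rng.beta(a, b)
    alt = int(rng.binomial(depth, p))
    lo = int(np.ceil(region[0] * depth))
    hi = int(np.floor(region[1] * depth))
    lo = max(lo, 1)
    hi = max(hi, lo)
    alt = min(max(alt, lo, 4), hi, depth)
    return alt, depth, alt / depth


def _variant(
    config: SimulationConfig,
    caller_id: str,
    pos: int,
    ref: str,
    alt: str,
    rng: np.random.Generator,
    target_vaf: float,
    region: tuple[float, float],
) -> GenomicVariant:
    ad, dp, vaf = _draw_support(
        rng, target_vaf, region, config.mean_depth, config.vaf_concentration
    )
    return GenomicVariant(
        chrom=config.contig,
        pos=pos,
        ref=ref,
        alt=alt,
        caller_id=caller_id,
        filter_status="PASS",
        alt_depth=ad,
        total_depth=dp,
        vaf=vaf,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate truth plus per-caller callsets with exact bookkeeping.

    Each caller's set is (truth minus independent per-variant misses) union
    its private false positives union its share of the correlated false
    positives.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_callers
    roster = config.caller_ids

    n_shared = sum(dict(config.shared_fp_counts).values())
    n_fp_total = config.private_fp_count * n + n_shared
    n_total = config.n_true_variants + n_fp_total
    positions = _draw_positions(rng, n_total, config.contig_length)
    rng.shuffle(positions)
    n_snv = int(round(config.n_true_variants * config.snv_fraction))
    alleles = _draw_alleles(rng, n_snv, config.n_true_variants - n_snv)
    fp_alleles = _draw_alleles(rng, n_fp_total, 0)

    truth = CallSet(caller_id="truth")
    manifest: dict[VariantKey, dict] = {}
    cursor = 0
    truth_entries: list[tuple[VariantKey, str, str]] = []
    for ref, alt in alleles:
        pos = int(positions[cursor])
        cursor += 1
        var = GenomicVariant(
            chrom=config.contig, pos=pos, ref=ref, alt=alt, caller_id="truth"
        )
        truth.add(var)
        truth_entries.append((var.key, ref, alt))
        manifest[var.key] = {"truth": True, "callers": []}

    callsets = [CallSet(caller_id=c) for c in roster]

    # truth calls minus independent misses
    miss = rng.random((len(truth_entries), n)) < config.miss_probability
    for i, (key, ref, alt) in enumerate(truth_entries):
        for c in range(n):
            if miss[i, c]:
                continue
            callsets[c].add(
                _variant(
                    config, roster[c], key.pos, ref, alt, rng,
                    config.somatic_vaf, _SOMATIC_REGION,
                )
            )
            manifest[key]["callers"].append(roster[c])

    fp_cursor = 0

    def add_fp(caller_indices: Sequence[int]) -> None:
        nonlocal cursor, fp_cursor
        pos = int(positions[cursor])
        cursor += 1
        ref, alt = fp_alleles[fp_cursor]
        fp_cursor += 1
        key = VariantKey(config.contig, pos, ref, alt)
        manifest[key] = {"truth": False, "callers": []}
        for c in caller_indices:
            callsets[c].add(
                _variant(
                    config, roster[c], pos, ref, alt, rng,
                    config.somatic_vaf, _SOMATIC_REGION,
                )
            )
            manifest[key]["callers"].append(roster[c])

    # caller-private systematic false positives (disjoint by construction)
    for c in range(n):
        for _ in range(config.private_fp_count):
            add_fp([c])
    # correlated false positives shared by random groups of j callers
    for j, count in sorted(dict(config.shared_fp_counts).items()):
        for _ in range(count):
            group = rng.choice(n, size=j, replace=False)
            add_fp([int(c) for c in group])

    return SimulatedDataset(config=config, truth=truth, callsets=callsets, manifest=manifest)


def simulate_germline_samples(config: SimulationConfig) -> GermlineDataset:
    """Generate germline amplicon-like samples.

    Per sample: shared germline truth calls with het/hom VAFs inside the
    [0.4, 0.6] / [0.9, 1.0] windows (every caller sees all of them), plus
    per-caller private noise and a set of shared noise keys, all with VAFs
    outside the windows.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_callers
    roster = config.caller_ids
    samples: dict[str, dict] = {}
    for s in range(config.n_samples):
        sample_id = f"GL{s + 1}"
        n_noise = config.noise_per_caller * n + config.shared_noise_count
        n_total = config.n_true_variants + n_noise
        positions = _draw_positions(rng, n_total, config.contig_length)
        rng.shuffle(positions)
        alleles = _draw_alleles(rng, n_total, 0)
        cursor = 0

        truth = CallSet(caller_id="truth")
        callsets = [CallSet(caller_id=c) for c in roster]
        for _ in range(config.n_true_variants):
            pos = int(positions[cursor])
            ref, alt = alleles[cursor]
            cursor += 1
            is_het = rng.random() < config.het_fraction
            window = HET_WINDOW if is_het else HOM_WINDOW
            target = 0.5 if is_het else 1.0
            truth.add(GenomicVariant(chrom=config.contig, pos=pos, ref=ref, alt=alt,
                                     caller_id="truth"))
            for c in range(n):
                callsets[c].add(
                    _variant(config, roster[c], pos, ref, alt, rng, target, window)
                )
        for c in range(n):
            for _ in range(config.noise_per_caller):
                pos = int(positions[cursor])
                ref, alt = alleles[cursor]
                cursor += 1
                target = float(rng.uniform(*_NOISE_REGION))
                callsets[c].add(
                    _variant(config, roster[c], pos, ref, alt, rng, target, _NOISE_REGION)
                )
        for _ in range(config.shared_noise_count):
            pos = int(positions[cursor])
            ref, alt = alleles[cursor]
            cursor += 1
            for c in range(n):
                target = float(rng.uniform(*_NOISE_REGION))
                callsets[c].add(
                    _variant(config, roster[c], pos, ref, alt, rng, target, _NOISE_REGION)
                )
        samples[sample_id] = {"truth": truth, "callsets": callsets}
    return GermlineDataset(config=config, samples=samples)


# ---------------------------------------------------------------------------
# fixture writing: one dialect-correct VCF per caller + truth + manifest

_FORMAT_HEADERS = {
    "mutect2": [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ],
    "varscan": [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=RD,Number=1,Type=Integer,Description="Reference depth">',
        '##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Variant depth">',
        '##FORMAT=<ID=FREQ,Number=1,Type=String,Description="Variant frequency">',
    ],
    "vardict": [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=VD,Number=1,Type=Integer,Description="Variant depth">',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
    ],
    "strelka": [
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AU,Number=2,Type=Integer,Description="A tier counts">',
        '##FORMAT=<ID=CU,Number=2,Type=Integer,Description="C tier counts">',
        '##FORMAT=<ID=GU,Number=2,Type=Integer,Description="G tier counts">',
        '##FORMAT=<ID=TU,Number=2,Type=Integer,Description="T tier counts">',
        '##FORMAT=<ID=TAR,Number=2,Type=Integer,Description="Ref tier counts">',
        '##FORMAT=<ID=TIR,Number=2,Type=Integer,Description="Indel tier counts">',
    ],
    "muse": [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ],
    "somaticsniper": [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=DP4,Number=4,Type=Integer,Description="Strand read counts">',
    ],
    "mutect": [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=FA,Number=A,Type=Float,Description="Allele fraction">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ],
    "pindel": [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ],
}

_GENERIC_HEADER = _FORMAT_HEADERS["mutect2"]


def _render_sample(caller_id: str, var: GenomicVariant) -> tuple[str, str]:
    ad = var.alt_depth or 0
    dp = var.total_depth or ad
    rd = max(dp - ad, 0)
    vaf = var.vaf if var.vaf is not None else 0.0
    dialect = caller_id.lower()
    if dialect == "varscan":
        return "GT:DP:RD:AD:FREQ", f"0/1:{dp}:{rd}:{ad}:{vaf * 100:.2f}%"
    if dialect == "vardict":
        return "GT:DP:VD:AF", f"0/1:{dp}:{ad}:{vaf:.4f}"
    if dialect == "strelka":
        if var.variant_class == "SNV":
            counts = {b: "0,0" for b in "ACGT"}
            counts[var.ref] = f"{rd},{rd}"
            counts[var.alt] = f"{ad},{ad}"
            return (
                "DP:AU:CU:GU:TU",
                f"{dp}:{counts['A']}:{counts['C']}:{counts['G']}:{counts['T']}",
            )
        return "DP:TAR:TIR", f"{dp}:{rd},{rd}:{ad},{ad}"
    if dialect == "muse":
        return "GT:DP:AD", f"0/1:{dp}:{rd},{ad}"
    if dialect == "somaticsniper":
        fwd_r, fwd_a = rd // 2, ad // 2
        return "GT:DP:DP4", f"0/1:{dp}:{fwd_r},{rd - fwd_r},{fwd_a},{ad - fwd_a}"
    if dialect == "mutect":
        return "GT:AD:FA:DP", f"0/1:{rd},{ad}:{vaf:.4f}:{dp}"
    if dialect == "pindel":
        return "GT:AD", f"0/1:{rd},{ad}"
    return "GT:AD:AF:DP", f"0/1:{rd},{ad}:{vaf:.4f}:{dp}"


def _write_caller_vcf(callset: CallSet, config: SimulationConfig, path: str) -> None:
    dialect = callset.caller_id.lower()
    headers = _FORMAT_HEADERS.get(dialect, _GENERIC_HEADER)
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=varcons-simulate caller={callset.caller_id}",
        f"##contig=<ID={config.contig},length={config.contig_length}>",
        '##FILTER=<ID=PASS,Description="All filters passed">',
        *headers,
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR",
    ]
    for key in sorted(callset.variants, key=lambda k: (k.pos, k.ref, k.alt)):
        var = callset.variants[key]
        fmt, sample = _render_sample(callset.caller_id, var)
        lines.append(
            f"{var.chrom}\t{var.pos}\t.\t{var.ref}\t{var.alt}\t.\tPASS\t.\t{fmt}\t{sample}"
        )
    _atomic_write(path, "\n".join(lines) + "\n")


def _write_truth_vcf(truth: CallSet, config: SimulationConfig, path: str) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=varcons-simulate truth",
        f"##contig=<ID={config.contig},length={config.contig_length}>",
        '##FILTER=<ID=PASS,Description="All filters passed">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for key in sorted(truth.variants, key=lambda k: (k.pos, k.ref, k.alt)):
        lines.append(f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t.")
    _atomic_write(path, "\n".join(lines) + "\n")


def write_manifest(manifest: Mapping[VariantKey, dict], path: str) -> None:
    """TSV bookkeeping: one row per key with truth flag and carrying callers."""
    lines = ["chrom\tpos\tref\talt\tis_truth\tcallers"]
    for key in sorted(manifest, key=lambda k: (k.chrom, k.pos, k.ref, k.alt)):
        entry = manifest[key]
        callers = ",".join(sorted(entry["callers"])) or "."
        lines.append(
            f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t"
            f"{int(entry['truth'])}\t{callers}"
        )
    _atomic_write(path, "\n".join(lines) + "\n")


def read_manifest(path: str) -> dict[VariantKey, dict]:
    manifest: dict[VariantKey, dict] = {}
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("chrom\t"):
            raise ConfigError(f"{path} is not a fixture manifest")
        for line in handle:
            chrom, pos, ref, alt, is_truth, callers = line.rstrip("\n").split("\t")
            manifest[VariantKey(chrom, int(pos), ref, alt)] = {
                "truth": bool(int(is_truth)),
                "callers": [] if callers == "." else callers.split(","),
            }
    return manifest


def write_fixture_vcfs(dataset: SimulatedDataset, directory: str) -> dict[str, str]:
    """Write one dialect-correct VCF per caller, a truth VCF, and the manifest.

    Returns a mapping of logical name (caller id, "truth", "manifest") to
    file path.  All files are plain text and re-readable with zero skips.
    """
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}
    for cs in dataset.callsets:
        path = os.path.join(directory, f"{cs.caller_id}.vcf")
        _write_caller_vcf(cs, dataset.config, path)
        paths[cs.caller_id] = path
    truth_path = os.path.join(directory, "truth.vcf")
    _write_truth_vcf(dataset.truth, dataset.config, truth_path)
    paths["truth"] = truth_path
    manifest_path = os.path.join(directory, "manifest.tsv")
    write_manifest(dataset.manifest, manifest_path)
    paths["manifest"] = manifest_path
    config_path = os.path.join(directory, "config.json")
    cfg = {k: (dict(v) if isinstance(v, Mapping) else v)
           for k, v in vars(dataset.config).items()}
    cfg["caller_ids"] = list(dataset.config.caller_ids)
    _atomic_write(config_path, json.dumps(cfg, indent=2) + "\n")
    paths["config"] = config_path
    return paths


def write_germline_fixtures(dataset: GermlineDataset, directory: str) -> dict[str, dict[str, str]]:
    """One subdirectory per germline sample, each with per-caller VCFs."""
    out: dict[str, dict[str, str]] = {}
    for sample_id, bundle in dataset.samples.items():
        subdir = os.path.join(directory, sample_id)
        os.makedirs(subdir, exist_ok=True)
        paths: dict[str, str] = {}
        for cs in bundle["callsets"]:
            path = os.path.join(subdir, f"{cs.caller_id}.vcf")
            _write_caller_vcf(cs, dataset.config, path)
            paths[cs.caller_id] = path
        truth_path = os.path.join(subdir, "truth.vcf")
        _write_truth_vcf(bundle["truth"], dataset.config, truth_path)
        paths["truth"] = truth_path
        out[sample_id] = paths
    return out
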