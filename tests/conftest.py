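import pytest

from varcons.variant_model import GenomicVariant
from varcons.vcf_io import CallSet


def make_variant(chrom="chr1", pos=100, ref="A", alt="G", caller_id="c",
                 filter_status="PASS", alt_depth=10, total_depth=50, vaf=0.2):
    return GenomicVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, caller_id=caller_id,
        filter_status=filter_status, alt_depth=alt_depth,
        total_depth=total_depth, vaf=vaf,
    )


def callset_from_positions(caller_id, positions, **kwargs):
    """CallSet with one SNV per 1-based position (ref A, alt G)."""
    cs = CallSet(caller_id=caller_id)
    for pos in positions:
        cs.add(make_variant(pos=pos, caller_id=caller_id, **kwargs))
    return cs


@pytest.fixture
def tiny_callsets():
    """Three callsets over keys v1=pos 10, v2=pos 20, v3=pos 30:
    A={v1,v2}, B={v1,v3}, C={v1,v2}."""
    return [
        callset_from_positions("A", [10, 20]),
        callset_from_positions("B", [10, 30]),
        callset_from_positions("C", [10, 20]),
    ]


def write_vcf(path, records, samples=("TUMOR",), format_headers=(), extra_headers=()):
    """Minimal VCF writer for hand-built test inputs.

    *records* are pre-formatted data lines (tab-separated strings).
    """
    lines = ["##fileformat=VCFv4.2", '##contig=<ID=chr1,length=100000>',
             '##FILTER=<ID=PASS,Description="ok">']
    lines.extend(extra_headers)
    lines.extend(format_headers)
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        cols += "\tFORMAT\t" + "\t".join(samples)
    lines.append(cols)
    lines.extend(records)
    path.write_text("\n".join(lines) + "\n")
    return str(path)
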