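"""File formats: per-caller VCFs, AI/SEG segment tables, arm/gene tables.

VCFs are written as plain uncompressed VCF v4.2 with documented INFO keys
(VT, POPAF, PRED7, CLNSIG, FUNC, GENE) and read back through pysam.
Segment tables are TSVs: SEG-style (sample, chrom, start, end, n_markers,
log2) for log ratios and (chrom, start, end, posterior) for AI.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .cna import Segment
from .variants import PREDICTORS, Variant

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_ai_table",
    "read_ai_table",
    "write_seg_table",
    "read_seg_table",
]

_VCF_INFO_HEADER = [
    '##INFO=<ID=VT,Number=1,Type=String,Description="Variant type (SNV or indel)">',
    '##INFO=<ID=POPAF,Number=1,Type=Float,Description="Max population allele frequency">',
    '##INFO=<ID=PRED7,Number=1,Type=Integer,Description="Bitmask of 7 deleteriousness predictor verdicts">',
    '##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar significance (pathogenic/other/absent)">',
    '##INFO=<ID=FUNC,Number=1,Type=String,Description="Functional class (exonic/splicing/other)">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">',
]


def _verdict_mask(verdicts: Sequence[bool]) -> int:
    mask = 0
    for i, v in enumerate(verdicts):
        if v:
            mask |= 1 << i
    return mask


def _mask_verdicts(mask: int) -> tuple:
    return tuple(bool(mask >> i & 1) for i in range(len(PREDICTORS)))


def write_vcf(variants: Iterable[Variant], path, contigs: dict[str, int]) -> None:
    """Write variants as uncompressed VCF v4.2 (TUMOR and NORMAL samples)."""
    lines = ["##fileformat=VCFv4.2", "##source=precevo"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.extend(_VCF_INFO_HEADER)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL"
    )
    for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
        info = [f"VT={v.vtype}"]
        if v.pop_af is not None:
            info.append(f"POPAF={v.pop_af:.6g}")
        info.append(f"PRED7={_verdict_mask(v.predictor_verdicts)}")
        info.append(f"CLNSIG={v.clinvar}")
        info.append(f"FUNC={v.func_class}")
        if v.gene:
            info.append(f"GENE={v.gene}")
        tumor = f"{v.tumor_depth}:{v.tumor_depth - v.tumor_alt},{v.tumor_alt}"
        if v.normal_depth is None:
            normal = ".:."
        else:
            normal = f"{v.normal_depth}:{v.normal_depth - (v.normal_alt or 0)},{v.normal_alt or 0}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{v.quality:.2f}\tPASS\t"
            f"{';'.join(info)}\tDP:AD\t{tumor}\t{normal}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path, caller: str) -> list[Variant]:
    """Read one caller's VCF back into :class:`Variant` objects."""
    out = []
    with pysam.VariantFile(os.fspath(path)) as vf:
        for rec in vf:
            info = rec.info
            tumor = rec.samples["TUMOR"]
            normal = rec.samples["NORMAL"]
            t_dp = int(tumor["DP"])
            t_ad = tumor["AD"]
            n_dp = normal.get("DP")
            n_ad = normal.get("AD")
            has_normal = n_dp is not None
            out.append(
                Variant(
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    ref=rec.ref,
                    alt=rec.alts[0],
                    vtype=str(info["VT"]),
                    tumor_depth=t_dp,
                    tumor_alt=int(t_ad[1]),
                    normal_depth=int(n_dp) if has_normal else None,
                    normal_alt=int(n_ad[1]) if has_normal and n_ad is not None else None,
                    callers=frozenset({caller}),
                    quality=round(float(rec.qual), 2),
                    pop_af=round(float(info["POPAF"]), 6) if "POPAF" in info else None,
                    predictor_verdicts=_mask_verdicts(int(info["PRED7"])),
                    clinvar=str(info["CLNSIG"]),
                    func_class=str(info["FUNC"]),
                    gene=str(info["GENE"]) if "GENE" in info else None,
                )
            )
    return out


def write_ai_table(segments: Iterable[Segment], path) -> None:
    rows = [
        {"chrom": s.chrom, "start": s.start, "end": s.end, "posterior": f"{s.value:.4f}"}
        for s in sorted(segments)
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "posterior"]).to_csv(
        path, sep="\t", index=False
    )


def read_ai_table(path) -> list[Segment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        Segment(str(r.chrom), int(r.start), int(r.end), "AI", float(r.posterior))
        for r in df.itertuples(index=False)
    ]


def write_seg_table(segments: Iterable[Segment], path, sample: str) -> None:
    rows = [
        {
            "sample": sample,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "n_markers": max(1, s.length // 10_000),
            "log2": f"{s.value:.4f}",
        }
        for s in sorted(segments)
    ]
    pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_markers", "log2"]
    ).to_csv(path, sep="\t", index=False)


def read_seg_table(path) -> list[Segment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        Segment(str(r.chrom), int(r.start), int(r.end), "LOGR", float(r.log2))
        for r in df.itertuples(index=False)
    ]
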