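"""Readers and writers for the tabular and VCF interchange formats.

Mutation tables travel either as a TSV dialect (columns: chrom, pos, ref,
alt, sample, t_depth, t_alt, n_depth, n_alt, effect) or as per-sample
VCF v4.2 with TUMOR/NORMAL columns carrying AD/DP.  Copy-number segments
are FACETS-style TSV (chrom, start, end, cn_total, cn_minor, sample) with
1-based inclusive coordinates.  VCF read counts are integers, so the
noise-free simulator's fractional expected counts are rounded on VCF
export; the TSV dialect preserves them exactly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

from .core import SamplePanel

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "sample",
                    "t_depth", "t_alt", "n_depth", "n_alt", "effect"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "cn_total", "cn_minor", "sample"]


def write_mutation_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_mutation_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    return df


def write_segment_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[SEGMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_segment_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    return df


def write_panel_tsv(panel: SamplePanel, path: str | Path) -> None:
    pd.DataFrame({
        "sample": panel.samples,
        "site": [panel.site_of[s] for s in panel.samples],
        "purity": [panel.purity[s] for s in panel.samples],
    }).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str | Path, patient_id: str = "patient") -> SamplePanel:
    df = pd.read_csv(path, sep="\t")
    return SamplePanel(
        patient_id,
        list(df["sample"].astype(str)),
        dict(zip(df["sample"].astype(str), df["site"].astype(str))),
        dict(zip(df["sample"].astype(str), df["purity"].astype(float))),
    )


def _vcf_header(sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in list(range(1, 23)) + ["X", "Y"]:
        header.contigs.add(str(c), length=250_000_000)
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer",
                       "Allelic depths (ref, alt)")
    header.info.add("EFFECT", 1, "String", "Functional annotation")
    header.add_sample("TUMOR")
    header.add_sample("NORMAL")
    header.add_line(f"##tumor_sample={sample}")
    return header


def write_vcf(df: pd.DataFrame, path: str | Path) -> None:
    """Write one sample's mutation rows as VCF v4.2 (counts rounded)."""
    samples = df["sample"].unique()
    if len(samples) != 1:
        raise ValueError("write_vcf expects rows from a single sample")
    header = _vcf_header(str(samples[0]))
    out = pysam.VariantFile(str(path), "w", header=header)
    df = df.sort_values(["chrom", "pos", "ref", "alt"],
                        key=lambda c: c.map(_chrom_key) if c.name == "chrom" else c)
    for row in df.itertuples(index=False):
        rec = out.new_record(
            contig=str(row.chrom), start=int(row.pos) - 1,
            alleles=(row.ref, row.alt), filter="PASS")
        rec.info["EFFECT"] = str(row.effect)
        t_alt = int(round(row.t_alt))
        n_alt = int(round(row.n_alt))
        rec.samples["TUMOR"]["DP"] = int(round(row.t_depth))
        rec.samples["TUMOR"]["AD"] = (int(round(row.t_depth)) - t_alt, t_alt)
        rec.samples["NORMAL"]["DP"] = int(round(row.n_depth))
        rec.samples["NORMAL"]["AD"] = (int(round(row.n_depth)) - n_alt, n_alt)
        out.write(rec)
    out.close()


def _chrom_key(c: str):
    c = str(c)
    return int(c) if c.isdigit() else 100 + ord(c[0])


def read_vcf(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a TUMOR/NORMAL VCF back into the mutation-table dialect."""
    vf = pysam.VariantFile(str(path))
    if sample_id is None:
        for line in str(vf.header).splitlines():
            if line.startswith("##tumor_sample="):
                sample_id = line.split("=", 1)[1]
        sample_id = sample_id or "TUMOR"
    rows = []
    for rec in vf:
        t = rec.samples["TUMOR"]
        n = rec.samples["NORMAL"]
        rows.append({
            "chrom": rec.contig, "pos": rec.pos,
            "ref": rec.ref, "alt": rec.alts[0],
            "sample": sample_id,
            "t_depth": float(t["DP"]), "t_alt": float(t["AD"][1]),
            "n_depth": float(n["DP"]), "n_alt": float(n["AD"][1]),
            "effect": rec.info.get("EFFECT", "other"),
        })
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)
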