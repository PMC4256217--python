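"""Readers and writers for the pipeline's on-disk formats.

Founder genotypes travel as VCF v4.2 (read back through pysam), the
annotation as GFF3 + FASTA (see annotation module), and everything else
as tab-separated tables with headers. Internal positions are 0-based;
VCF and the map table are 1-based on disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genmap import COLUMNS as MAP_COLUMNS
from .genmap import GeneticMap
from .simulate import FounderPanel


def write_founder_vcf(panel: FounderPanel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##common_parent={panel.common_parent}\n")
        for chrom in panel.sites["chrom"].unique():
            top = panel.sites.loc[panel.sites["chrom"] == chrom, "pos"].max() + 1
            fh.write(f"##contig=<ID={chrom},length={int(top)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.founder_ids) + "\n")
        for j, rec in enumerate(panel.sites.itertuples(index=False)):
            gts = "\t".join(f"{a}/{a}" for a in panel.alleles[:, j])
            fh.write(f"{rec.chrom}\t{rec.pos + 1}\tS{j + 1}\t{rec.ref}\t{rec.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_founder_vcf(path: str) -> FounderPanel:
    import pysam

    vcf = pysam.VariantFile(path)
    common = "CP"
    for rec in vcf.header.records:
        if rec.key == "common_parent":
            common = rec.value
    samples = list(vcf.header.samples)
    rows, cols = [], []
    for rec in vcf:
        rows.append((rec.chrom, rec.pos - 1, rec.ref, rec.alts[0]))
        cols.append([rec.samples[s]["GT"][0] for s in samples])
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    alleles = np.array(cols, dtype=np.int8).T
    return FounderPanel(sites, alleles, samples, common)


def write_map(gmap: GeneticMap, path: str) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_map(path: str) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, sep="\t")[MAP_COLUMNS])


def write_table(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    for col in out.columns:
        if out[col].map(lambda v: isinstance(v, (list, np.ndarray))).any():
            out[col] = out[col].map(
                lambda v: ",".join(f"{x:.6g}" for x in np.atleast_1d(v)))
    out.to_csv(path, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_dosage_matrix(dosages: np.ndarray, sites: pd.DataFrame,
                        ril_ids: list[str], path: str,
                        site_index_path: str | None = None) -> None:
    """Sites x RILs dosage TSV plus an optional site index file."""
    df = pd.DataFrame(dosages.T, columns=ril_ids)
    df.insert(0, "site", [f"S{j + 1}" for j in range(len(df))])
    df.to_csv(path, sep="\t", index=False, float_format="%.4g")
    if site_index_path:
        idx = sites.copy()
        idx.insert(0, "site", df["site"])
        idx["pos"] = idx["pos"] + 1  # 1-based on disk
        idx.to_csv(site_index_path, sep="\t", index=False)


def read_dosage_matrix(path: str) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    ril_ids = list(df.columns[1:])
    return df.iloc[:, 1:].to_numpy(float).T, ril_ids
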