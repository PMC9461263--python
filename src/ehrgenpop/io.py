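"""Readers/writers for PLINK bed/bim/fam filesets and plain-text VCF.

The bed codec implements the SNP-major 2-bit PLINK 1 format directly:
per variant, each sample occupies 2 bits with 00 = two copies of the bim
A1 allele, 10 = heterozygote, 11 = zero copies of A1, 01 = missing.
Internally dosages count A1 copies, matching the bim allele order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> A1 dosage
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, MISSING: 0b01}


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    bim = pd.DataFrame(
        {
            "chrom": g.variants["chrom"],
            "id": g.variants["id"],
            "cm": 0.0,
            "bp": g.variants["bp"],
            "a1": g.variants["allele1"],
            "a2": g.variants["allele2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": g.samples["id"],
            "iid": g.samples["id"],
            "father": 0,
            "mother": 0,
            "sex": g.samples.get("sex_code", pd.Series(0, index=g.samples.index)),
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n = g.n_samples
    n_bytes = (n + 3) // 4
    codes = np.empty_like(g.dosages, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[g.dosages == dosage] = code
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = np.zeros((g.n_variants, n_bytes), dtype=np.uint8)
        for offset in range(4):
            idx = np.arange(offset, n, 4)
            chunk = codes[idx, :].T  # variants x ceil-sized slice
            buf[:, : len(idx)] |= chunk << (2 * offset)
        fh.write(buf.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex_code", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    body = raw[3:].reshape(m, n_bytes)
    dosages = np.empty((n, m), dtype=np.int8)
    for offset in range(4):
        idx = np.arange(offset, n, 4)
        codes = (body[:, : len(idx)] >> (2 * offset)) & 0b11
        dosages[idx, :] = _CODE_TO_DOSAGE[codes].T
    variants = pd.DataFrame(
        {
            "chrom": bim["chrom"],
            "bp": bim["bp"],
            "id": bim["id"],
            "allele1": bim["a1"],
            "allele2": bim["a2"],
        }
    )
    samples = pd.DataFrame({"id": fam["iid"]})
    return GenotypeMatrix(dosages, variants, samples)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write an uncompressed VCF 4.2 with GT-only genotype fields.

    allele2 is emitted as REF and allele1 as ALT so that the internal
    A1-dosage equals the conventional ALT-allele count.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ids = list(g.samples["id"].astype(str))
    gt_strings = {2: "1/1", 1: "0/1", 0: "0/0", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ehrgenpop\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ids) + "\n"
        )
        for j, row in enumerate(g.variants.itertuples(index=False)):
            calls = "\t".join(gt_strings[int(d)] for d in g.dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.bp}\t{row.id}\t{row.allele2}\t{row.allele1}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a GT-only VCF produced by :func:`write_vcf` (plain text)."""
    path = Path(path)
    header_ids: list[str] = []
    chroms, bps, vids, a1s, a2s = [], [], [], [], []
    rows = []
    allele_count = {"0": 0, "1": 1, ".": None}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                header_ids = fields[9:]
                continue
            chroms.append(fields[0])
            bps.append(int(fields[1]))
            vids.append(fields[2])
            a2s.append(fields[3])  # REF
            a1s.append(fields[4])  # ALT
            row = np.empty(len(header_ids), dtype=np.int8)
            for i, call in enumerate(fields[9:]):
                gt = call.split(":", 1)[0].replace("|", "/")
                alleles = gt.split("/")
                counts = [allele_count.get(a) for a in alleles]
                row[i] = MISSING if None in counts else sum(counts)
            rows.append(row)
    dosages = np.vstack(rows).T if rows else np.empty((len(header_ids), 0), np.int8)
    variants = pd.DataFrame(
        {"chrom": chroms, "bp": bps, "id": vids, "allele1": a1s, "allele2": a2s}
    )
    samples = pd.DataFrame({"id": header_ids})
    return GenotypeMatrix(dosages, variants, samples)
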