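"""Readers and writers: VCF genotypes, phenotype/annotation TSVs, result tables.

Genotypes travel as biallelic-SNV VCF with annotation carried in the INFO
keys ``GENE``, ``FCLASS`` and ``DMG``; a sidecar annotation TSV may override
the INFO fields. All result tables are TSV with '#'-prefixed comment header
lines carrying the run seed and a config hash, so reader/writer pairs are
bit-stable roundtrips.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    FUNCTIONAL_CLASSES,
    MISSING,
    ContractError,
    GenotypeMatrix,
    ParameterError,
    PhenotypeTable,
)

FLOAT_FMT = "%.6g"


class VCFParseError(ContractError):
    """Malformed or unsupported VCF content; message names the record."""


def read_vcf(path: str, region_filter: str | None = None) -> GenotypeMatrix:
    """Read a biallelic-SNV VCF with GT fields into a :class:`GenotypeMatrix`.

    Dosages count alt alleles; ``./.`` becomes missing. Annotation is read
    from INFO keys GENE, FCLASS, DMG when present. Multi-allelic records are
    rejected (no split policy is implemented for exome-chip style input).
    """
    vcf = VCF(str(path), gts012=True)
    sample_ids = np.array(vcf.samples, dtype=object)
    rows = []
    dosage_cols = []
    for i, rec in enumerate(vcf(region_filter) if region_filter else vcf):
        if len(rec.ALT) != 1:
            raise VCFParseError(
                f"non-biallelic record at {rec.CHROM}:{rec.POS} (record {i + 1}): "
                f"ALT={rec.ALT}; split multi-allelics upstream"
            )
        fclass = rec.INFO.get("FCLASS", "Other")
        if fclass not in FUNCTIONAL_CLASSES:
            raise VCFParseError(
                f"unknown functional class {fclass!r} at {rec.CHROM}:{rec.POS}"
            )
        rows.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "gene": rec.INFO.get("GENE", "."),
                "functional_class": fclass,
                "damaging": bool(int(rec.INFO.get("DMG", 0))),
            }
        )
        # gts012: 0/1/2 alt count, 3 = unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        dosage_cols.append(g)
    if not rows:
        raise VCFParseError(f"no records read from {path}")
    dosages = np.column_stack(dosage_cols).astype(np.int8)
    return GenotypeMatrix(sample_ids, dosages, pd.DataFrame(rows))


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a :class:`GenotypeMatrix` as VCFv4.2 with annotation INFO keys."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=FCLASS,Number=1,Type=String,Description="Functional class">\n')
        fh.write('##INFO=<ID=DMG,Number=1,Type=Integer,Description="Damaging flag (0/1)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gm.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, gm.sample_ids))
            + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", int(MISSING): "./."}
        for j, v in gm.variants.iterrows():
            info = f"GENE={v.gene};FCLASS={v.functional_class};DMG={int(v.damaging)}"
            gts = "\t".join(gt_strings[int(d)] for d in gm.dosages[:, j])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t{info}\tGT\t{gts}\n"
            )


def apply_annotation_tsv(gm: GenotypeMatrix, path: str) -> GenotypeMatrix:
    """Override INFO-derived annotation from a sidecar TSV.

    Columns: variant_id, gene, functional_class, damaging (0/1).
    """
    ann = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene": str})
    bad = set(ann["functional_class"]) - set(FUNCTIONAL_CLASSES)
    if bad:
        raise ParameterError(f"unknown functional class(es) in annotation: {sorted(bad)}")
    ann = ann.set_index("variant_id")
    variants = gm.variants.copy()
    hit = variants["variant_id"].isin(ann.index)
    idx = variants.loc[hit, "variant_id"]
    variants.loc[hit, "gene"] = ann.loc[idx, "gene"].to_numpy()
    variants.loc[hit, "functional_class"] = ann.loc[idx, "functional_class"].to_numpy()
    variants.loc[hit, "damaging"] = ann.loc[idx, "damaging"].astype(bool).to_numpy()
    return GenotypeMatrix(gm.sample_ids, gm.dosages, variants)


def read_phenotypes(path: str) -> PhenotypeTable:
    """Read a phenotype TSV: sample_id, status, then covariate columns."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "status" not in df.columns:
        raise ParameterError("phenotype TSV requires 'sample_id' and 'status' columns")
    cov = df.drop(columns=["sample_id", "status"])
    return PhenotypeTable(df["sample_id"].to_numpy(object), df["status"].to_numpy(float), cov)


def write_phenotypes(pheno: PhenotypeTable, path: str) -> None:
    df = pd.DataFrame({"sample_id": pheno.sample_ids, "status": pheno.status})
    for c in pheno.covariates.columns:
        df[c] = pheno.covariates[c].to_numpy()
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def config_hash(config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_results(table: pd.DataFrame, path: str, seed: int | None = None,
                  config: dict | None = None) -> None:
    """Write a stage result table as TSV with a '#' comment header.

    Header lines record the run seed and a hash of the configuration so a
    result file is self-describing; floats use a fixed %.6g format.
    """
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    buf = _io.StringIO()
    buf.write(f"# seed={'' if seed is None else seed}\n")
    buf.write(f"# config_hash={config_hash(config)}\n")
    table.to_csv(buf, sep="\t", index=False, float_format=FLOAT_FMT)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def check_roundtrip(gm: GenotypeMatrix, other: GenotypeMatrix) -> bool:
    """True when two genotype matrices are identical in samples, dosages, meta."""
    if not np.array_equal(gm.sample_ids, other.sample_ids):
        return False
    if not np.array_equal(gm.dosages, other.dosages):
        return False
    a = gm.variants.astype({"pos": int})
    b = other.variants.astype({"pos": int})
    return a.astype(str).equals(b.astype(str))
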