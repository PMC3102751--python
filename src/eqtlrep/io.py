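"""Readers and writers for the standard interchange formats.

Genotypes travel as VCF (per-sample ``DS`` dosage field, read through pysam)
or as a tab-delimited matrix; expression as a probes x samples TSV whose
column headers encode technical replicates (``S1_r1``, ``S1_r2``); probe
annotations as BED6 plus gene_id/exon_id columns; gene models as BED12 or
GTF reduced to (TSS, strand); demographics and truth tables as TSV.

All intervals are 0-based half-open internally; VCF positions are 1-based
and converted on read.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .datatypes import Demographics, ExpressionMatrix, GenotypeMatrix

__all__ = [
    "read_genotypes", "write_genotypes_vcf", "write_genotypes_tsv",
    "read_expression", "write_expression_tsv",
    "read_demographics", "write_demographics_tsv",
    "read_probes_bed", "write_probes_bed",
    "read_genes_bed12", "write_genes_bed12", "read_genes_gtf",
]


# ---------------------------------------------------------------- genotypes

def write_genotypes_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as an uncompressed VCF with a per-sample DS field."""
    path = Path(path)
    meta = g.snp_meta
    chroms = list(dict.fromkeys(meta["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        fh.write('##INFO=<ID=IMP,Number=0,Type=Flag,'
                 'Description="Dosage-imputed marker">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        order = np.lexsort((meta["pos"].to_numpy(),
                            pd.Categorical(meta["chrom"],
                                           categories=chroms).codes))
        for k in order:
            snp = g.snp_ids[k]
            row = meta.iloc[k]
            info = "IMP" if bool(row.get("imputed", False)) else "."
            ds = "\t".join(
                "." if g.mask is not None and g.mask[i, k]
                else f"{g.dosages[i, k]:.4g}"
                for i in range(g.n_samples)
            )
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t"
                     f"{row.get('ref', 'A')}\t{row.get('alt', 'G')}\t.\t.\t"
                     f"{info}\tDS\t{ds}\n")


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    snp_ids, rows, meta_rows, mask_rows = [], [], [], []
    for rec in vf:
        if rec.id is None:
            raise ValueError(f"VCF record without ID at {rec.chrom}:{rec.pos}")
        if len(rec.alts or ()) != 1:
            raise ValueError(f"{rec.id}: exactly one ALT allele required")
        ds, miss = [], []
        for s in samples:
            v = rec.samples[s].get("DS")
            if v is None or (isinstance(v, tuple) and v[0] is None):
                ds.append(np.nan)
                miss.append(True)
            else:
                ds.append(float(v if np.isscalar(v) else v[0]))
                miss.append(False)
        snp_ids.append(rec.id)
        rows.append(ds)
        mask_rows.append(miss)
        meta_rows.append({
            "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
            "alt": rec.alts[0], "imputed": "IMP" in rec.info,
        })
    dos = np.array(rows, float).T
    mask = np.array(mask_rows, bool).T
    meta = pd.DataFrame(meta_rows, index=snp_ids)
    filled = np.where(mask, np.nan, dos)
    p = np.nanmean(filled, axis=0) / 2.0
    meta["maf"] = np.minimum(p, 1 - p)
    dos = np.where(mask, 0.0, dos)  # placeholder; mean-imputation is QC's job
    return GenotypeMatrix(sample_ids=samples, snp_ids=snp_ids,
                          dosages=dos, snp_meta=meta, mask=mask)


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """SNP-per-row TSV: id/chrom/pos/ref/alt/imputed then dosage columns."""
    meta = g.snp_meta
    df = pd.DataFrame({
        "snp_id": g.snp_ids,
        "chrom": meta["chrom"].to_numpy(),
        "pos": meta["pos"].to_numpy(),
        "ref": meta.get("ref", pd.Series("A", index=meta.index)).to_numpy(),
        "alt": meta.get("alt", pd.Series("G", index=meta.index)).to_numpy(),
        "imputed": meta.get(
            "imputed", pd.Series(False, index=meta.index)
        ).astype(int).to_numpy(),
    })
    dos = pd.DataFrame(g.dosages.T, columns=g.sample_ids)
    if g.mask is not None:
        dos = dos.mask(g.mask.T)
    pd.concat([df.reset_index(drop=True), dos.reset_index(drop=True)],
              axis=1).to_csv(path, sep="\t", index=False, na_rep="NA",
                             float_format="%.17g")


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"],
                     float_precision="round_trip")
    fixed = ["snp_id", "chrom", "pos", "ref", "alt", "imputed"]
    for c in fixed:
        if c not in df.columns:
            raise ValueError(f"genotype TSV missing column {c!r}")
    samples = [c for c in df.columns if c not in fixed]
    dup = df["snp_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate SNP ids: {df['snp_id'][dup].tolist()[:5]}")
    dos = df[samples].to_numpy(float).T
    mask = np.isnan(dos)
    meta = pd.DataFrame({
        "chrom": df["chrom"].to_numpy(), "pos": df["pos"].to_numpy(int),
        "ref": df["ref"].to_numpy(), "alt": df["alt"].to_numpy(),
        "imputed": df["imputed"].astype(bool).to_numpy(),
    }, index=df["snp_id"])
    p = np.nanmean(dos, axis=0) / 2.0
    meta["maf"] = np.minimum(p, 1 - p)
    return GenotypeMatrix(
        sample_ids=samples, snp_ids=list(df["snp_id"]),
        dosages=np.where(mask, 0.0, dos), snp_meta=meta, mask=mask,
    )


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF (``DS`` field) or TSV.

    Missing cells set the mask; mean-imputation is applied only during QC
    (:func:`eqtlrep.preprocess.filter_genotypes`).
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "tsv"
    if fmt == "vcf":
        return _read_genotypes_vcf(path)
    if fmt == "tsv":
        return _read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# --------------------------------------------------------------- expression

_REP_RE = re.compile(r"^(?P<sample>.+)_r(?P<rep>\d+)$")


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    cols = expr.replicate_ids if expr.replicate_ids is not None \
        else expr.sample_ids
    pd.DataFrame(expr.values, index=pd.Index(expr.probe_ids, name="probe_id"),
                 columns=cols).to_csv(path, sep="\t")


def read_expression(
    path: str | Path, probe_meta: pd.DataFrame | None = None
) -> ExpressionMatrix:
    """Read a probes x samples log2 TSV; ``S1_r2``-style headers mark
    technical replicate columns of sample ``S1``."""
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    if df.index.duplicated().any():
        raise ValueError("duplicate probe ids in expression file")
    sample_ids, replicate_ids = [], []
    for c in df.columns:
        m = _REP_RE.match(c)
        sample_ids.append(m.group("sample") if m else c)
        replicate_ids.append(c)
    if probe_meta is None:
        probe_meta = pd.DataFrame(
            {"gene_id": list(df.index), "exon_id": "", "chrom": "",
             "start": 0, "end": 0, "strand": "+", "n_probe_snps": 0},
            index=df.index,
        )
    else:
        probe_meta = probe_meta.loc[df.index]
    return ExpressionMatrix(
        probe_ids=list(df.index), sample_ids=sample_ids,
        values=df.to_numpy(float), probe_meta=probe_meta,
        replicate_ids=replicate_ids,
    )


# ------------------------------------------------------------- demographics

def write_demographics_tsv(dem: Demographics, path: str | Path) -> None:
    dem.table.to_csv(path, sep="\t", index_label="sample_id")


def read_demographics(path: str | Path) -> Demographics:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if df.index.duplicated().any():
        raise ValueError("duplicate sample ids in demographics file")
    return Demographics(df)


# ----------------------------------------------------------------- BED/GTF

def write_probes_bed(probe_meta: pd.DataFrame, path: str | Path) -> None:
    """BED6 + gene_id + exon_id, 0-based half-open, score = n_probe_snps."""
    with open(path, "w") as fh:
        for probe_id, row in probe_meta.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                f"{probe_id}\t{int(row.get('n_probe_snps', 0))}\t"
                f"{row['strand']}\t{row['gene_id']}\t"
                f"{row.get('exon_id', '')}\n"
            )


def read_probes_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "probe_id", "n_probe_snps",
               "strand", "gene_id", "exon_id"],
    )
    if df["probe_id"].duplicated().any():
        raise ValueError("duplicate probe ids in BED file")
    if (df["end"] <= df["start"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return df.set_index("probe_id")


def write_genes_bed12(genes: pd.DataFrame, path: str | Path,
                      length: int = 1000) -> None:
    """Write gene models as BED12; TSS is the strand-aware 5' end.

    ``genes`` is indexed by gene_id with columns chrom, tss (1-based),
    strand.
    """
    with open(path, "w") as fh:
        for gene_id, row in genes.iterrows():
            tss0 = int(row["tss"]) - 1
            if row["strand"] == "+":
                start, end = tss0, tss0 + length
            else:
                start, end = max(0, tss0 + 1 - length), tss0 + 1
            fh.write(
                f"{row['chrom']}\t{start}\t{end}\t{gene_id}\t0\t"
                f"{row['strand']}\t{start}\t{end}\t0\t1\t"
                f"{end - start},\t0,\n"
            )


def read_genes_bed12(path: str | Path) -> pd.DataFrame:
    """Reduce BED12 gene models to (chrom, tss, strand), tss 1-based."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=range(6),
                     names=["chrom", "start", "end", "gene_id", "score",
                            "strand"])
    tss = np.where(df["strand"] == "+", df["start"] + 1, df["end"])
    out = pd.DataFrame({"chrom": df["chrom"], "tss": tss.astype(int),
                        "strand": df["strand"]},
                       index=df["gene_id"])
    if out.index.duplicated().any():
        raise ValueError("duplicate gene ids in BED12 file")
    return out


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def read_genes_gtf(path: str | Path) -> pd.DataFrame:
    """Reduce GTF gene (or transcript) features to (chrom, tss, strand).

    For - strand features the TSS is the feature end coordinate.
    """
    rows = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GTF line: {line[:60]!r}")
            if f[2] not in {"gene", "transcript"}:
                continue
            m = _GTF_GENE_ID.search(f[8])
            if not m:
                raise ValueError(f"GTF attributes lack gene_id: {f[8][:60]!r}")
            gene = m.group(1)
            tss = int(f[3]) if f[6] == "+" else int(f[4])
            if gene not in rows or f[2] == "gene":
                rows[gene] = {"chrom": f[0], "tss": tss, "strand": f[6]}
    return pd.DataFrame.from_dict(rows, orient="index")
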