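"""Readers and writers: VCF/TSV genotypes, phenotype tables, configs, manifests.

Coordinates are 0-based half-open internally and 1-based in files (VCF
convention).  REF/ALT carry placeholder nucleotides A (ancestral, allele 0)
and T (derived, allele 1); the study is allele-label-agnostic.  TSV files
are tab-separated, UTF-8, with a '#'-prefixed header line and no quoting.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .coalsim import GenotypeMatrix, HaplotypePanel, SimConfig

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_phenotype_tsv",
    "read_phenotype_tsv",
    "read_inputs",
    "load_config",
    "write_manifest",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def _marker_records(gm: GenotypeMatrix):
    for col in range(gm.n_markers):
        chrom = f"chr{int(gm.marker_chrom[col]) + 1}"
        pos = int(gm.marker_pos[col]) + 1
        yield col, chrom, pos


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> Path:
    """Write diploid genotypes as an uncompressed VCF 4.2 file."""
    path = Path(path)
    n = genotypes.n_individuals
    chroms = sorted(set(int(c) for c in genotypes.marker_chrom))
    try:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=epiqtl\n")
            for c in chroms:
                length = int(genotypes.marker_pos[genotypes.marker_chrom == c].max()) + 1
                fh.write(f"##contig=<ID=chr{c + 1},length={length}>\n")
            fh.write('##INFO=<ID=QTL,Number=0,Type=Flag,Description="Designated trait locus">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            samples = "\t".join(f"ind{i}" for i in range(n))
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
            qtl = set(genotypes.qtl_cols)
            for col, chrom, pos in _marker_records(genotypes):
                info = "QTL" if col in qtl else "."
                gts = "\t".join(_GT[int(g)] for g in genotypes.genotypes[:, col])
                fh.write(f"{chrom}\t{pos}\tm{col}\tA\tT\t.\tPASS\t{info}\tGT\t{gts}\n")
    except OSError as exc:
        raise OSError(f"failed writing VCF to {path}: {exc}") from exc
    return path


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, list[str]]:
    """Read a biallelic VCF into a genotype matrix; returns (matrix, sample ids)."""
    path = Path(path)
    chroms, positions, rows, qtl_cols = [], [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for col, rec in enumerate(vcf.fetch() if vcf.index else vcf):
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{path}: record {rec.chrom}:{rec.pos} is not biallelic"
                )
            genos = []
            for s in samples:
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    raise ValueError(
                        f"{path}: missing genotype at {rec.chrom}:{rec.pos}"
                    )
                genos.append(sum(gt))
            rows.append(genos)
            chrom = rec.chrom[3:] if rec.chrom.startswith("chr") else rec.chrom
            chroms.append(int(chrom) - 1)
            positions.append(rec.pos - 1)
            if rec.info.get("QTL", False):
                qtl_cols.append(col)
    G = np.array(rows, dtype=np.uint8).T
    gm = GenotypeMatrix(
        genotypes=G,
        marker_chrom=np.array(chroms, dtype=np.int64),
        marker_pos=np.array(positions, dtype=np.int64),
        qtl_cols=tuple(qtl_cols),
    )
    return gm, samples


def write_genotype_tsv(genotypes: GenotypeMatrix, path: str | Path) -> Path:
    """Individuals x markers 0/1/2 matrix with 'chrN:pos' column names."""
    path = Path(path)
    names = [f"chr{c + 1}:{p + 1}" for _, c, p in
             ((col, int(genotypes.marker_chrom[col]), int(genotypes.marker_pos[col]))
              for col in range(genotypes.n_markers))]
    with open(path, "w") as fh:
        fh.write("#id\t" + "\t".join(names) + "\n")
        for i, row in enumerate(genotypes.genotypes):
            fh.write(f"ind{i}\t" + "\t".join(str(int(g)) for g in row) + "\n")
    return path


def read_genotype_tsv(path: str | Path) -> tuple[GenotypeMatrix, list[str]]:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    ids = df.iloc[:, 0].astype(str).tolist()
    marker_names = list(df.columns[1:])
    chroms, positions = [], []
    for name in marker_names:
        chrom, pos = name.split(":")
        chroms.append(int(chrom.removeprefix("chr")) - 1)
        positions.append(int(pos) - 1)
    G = df.iloc[:, 1:].to_numpy()
    if pd.isna(G).any():
        raise ValueError(f"{path}: missing genotype entries")
    G = G.astype(np.uint8)
    gm = GenotypeMatrix(
        genotypes=G,
        marker_chrom=np.array(chroms, dtype=np.int64),
        marker_pos=np.array(positions, dtype=np.int64),
        qtl_cols=(),
    )
    return gm, ids


def write_phenotype_tsv(
    phenotype: np.ndarray, path: str | Path, ids: list[str] | None = None
) -> Path:
    path = Path(path)
    if ids is None:
        ids = [f"ind{i}" for i in range(len(phenotype))]
    with open(path, "w") as fh:
        fh.write("#id\ttrait\n")
        for i, y in zip(ids, phenotype):
            fh.write(f"{i}\t{float(y)!r}\n")
    return path


def read_phenotype_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    ids = df.iloc[:, 0].astype(str).tolist()
    y = df.iloc[:, 1].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"{path}: missing trait values")
    return y, ids


def read_inputs(
    genotype_path: str | Path, phenotype_path: str | Path
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Load a genotype matrix (VCF or TSV) with an aligned phenotype vector.

    Individual ids must match one-to-one between the two files; the
    phenotype is reordered to the genotype file's sample order.
    """
    genotype_path = Path(genotype_path)
    if genotype_path.suffix in (".vcf", ".gz") or genotype_path.name.endswith(".vcf.gz"):
        gm, ids = read_vcf(genotype_path)
    else:
        gm, ids = read_genotype_tsv(genotype_path)
    y, pheno_ids = read_phenotype_tsv(phenotype_path)
    if sorted(ids) != sorted(pheno_ids):
        raise ValueError(
            "individual ids differ between genotype and phenotype files "
            f"({len(ids)} vs {len(pheno_ids)} ids)"
        )
    order = [pheno_ids.index(i) for i in ids]
    return gm, y[order]


def load_config(path: str | Path) -> SimConfig:
    """Simulation config from a YAML file mirroring SimConfig fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimConfig.from_dict(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path, config: SimConfig | dict, outputs: list[str | Path],
    seeds: dict | None = None,
) -> Path:
    """JSON run manifest: config snapshot, seed ledger and output checksums."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "version": __version__,
        "config": config.to_dict() if isinstance(config, SimConfig) else dict(config),
        "seeds": seeds or {},
        "outputs": {
            str(Path(p).name): _sha256(Path(p)) for p in outputs
        },
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
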