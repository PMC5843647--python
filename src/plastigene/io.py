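"""Reading and writing the pipeline's plain-text formats.

Count matrices round-trip as TSV (genes as rows, header = sample ids) or
MatrixMarket MTX plus gene/sample name files; sample sheets and result
tables as TSV; gene sets as one-id-per-line text; haplotype matrices as
per-gene 0/1 TSVs or a minimal biallelic VCF (one contig per gene, GT
fields; unphased diploid genotypes are expanded to 2n haplotypes).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .normalize import validate_counts
from .simulate import HaplotypeMatrix

log = logging.getLogger("plastigene")

_DESIGN_COLS = ["family", "season", "food", "tissue"]


def write_counts(counts: pd.DataFrame, path, fmt: str = "tsv") -> None:
    validate_counts(counts)
    path = Path(path)
    if fmt == "tsv":
        counts.to_csv(path, sep="\t", index_label="gene")
    elif fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.csr_matrix(counts.to_numpy()))
        (path / "genes.txt").write_text("\n".join(counts.index) + "\n")
        (path / "samples.txt").write_text("\n".join(counts.columns) + "\n")
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def read_counts(path) -> pd.DataFrame:
    """Read a count matrix from a TSV file or an MTX directory."""
    path = Path(path)
    if path.is_dir():
        m = spio.mmread(path / "matrix.mtx")
        genes = (path / "genes.txt").read_text().splitlines()
        samples = (path / "samples.txt").read_text().splitlines()
        m = np.asarray(m.todense()) if sparse.issparse(m) else np.asarray(m)
        if m.shape != (len(genes), len(samples)):
            raise ValueError(
                f"matrix shape {m.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        counts = pd.DataFrame(m, index=genes, columns=samples)
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
    if not all(np.issubdtype(dt, np.number) for dt in counts.dtypes):
        bad = [c for c, dt in counts.dtypes.items() if not np.issubdtype(dt, np.number)]
        raise ValueError(f"non-numeric count columns: {bad}")
    if not np.allclose(counts.to_numpy(float) % 1, 0):
        raise ValueError("counts must be integers")
    counts = counts.astype(np.int64)
    counts.index.name = None
    validate_counts(counts)
    return counts


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index_label="sample")


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", index_col="sample")
    missing = [c for c in _DESIGN_COLS[:3] if c not in design.columns]
    if missing:
        raise ValueError(f"design is missing required columns: {missing}")
    for lineno, (sid, row) in enumerate(design.iterrows(), start=2):
        if row["season"] not in ("dry", "wet"):
            raise ValueError(f"line {lineno}: bad season {row['season']!r} for {sid!r}")
        if row["food"] not in ("control", "stress"):
            raise ValueError(f"line {lineno}: bad food {row['food']!r} for {sid!r}")
    return design


def read_geneset(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_geneset(ids, path) -> None:
    Path(path).write_text("\n".join(ids) + ("\n" if ids else ""))


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick.rstrip() + "\n")


def write_phylip_distances(dist: pd.DataFrame, path) -> None:
    """Square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(dist)}\n")
        for name, row in dist.iterrows():
            vals = " ".join(format(v, ".10g") for v in row)
            fh.write(f"{name} {vals}\n")


def write_haplotypes_dir(haplotypes, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for h in haplotypes:
        df = pd.DataFrame(
            h.sites,
            index=[f"hap{i + 1}" for i in range(h.n_haplotypes)],
            columns=[f"s{j + 1}" for j in range(h.n_sites)],
        )
        with open(path / f"{h.gene_id}.tsv", "w") as fh:
            fh.write(f"# sequence_length={h.sequence_length}\n")
            df.to_csv(fh, sep="\t", index_label="haplotype")


def read_haplotypes_dir(path) -> list[HaplotypeMatrix]:
    out = []
    for f in sorted(Path(path).glob("*.tsv")):
        seq_len = 1000
        with open(f) as fh:
            first = fh.readline()
            if first.startswith("# sequence_length="):
                seq_len = int(first.split("=", 1)[1])
                df = pd.read_csv(fh, sep="\t", index_col=0)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", index_col=0)
        mat = df.to_numpy()
        if not np.isin(mat, (0, 1)).all():
            raise ValueError(f"{f.name}: haplotype entries must be 0/1")
        out.append(HaplotypeMatrix(gene_id=f.stem, sites=mat, sequence_length=seq_len))
    return out


def write_vcf_minimal(haplotypes, path) -> None:
    """Serialize haplotype matrices as a minimal biallelic VCF: one contig
    per gene, haplotypes paired into phased diploid GT columns."""
    hs = list(haplotypes)
    if not hs:
        raise ValueError("no haplotype matrices to write")
    n = hs[0].n_haplotypes
    if any(h.n_haplotypes != n for h in hs):
        raise ValueError("all genes must share the same number of haplotypes")
    if n % 2:
        raise ValueError("need an even number of haplotypes to form diploid GTs")
    samples = [f"ind{i + 1}" for i in range(n // 2)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for h in hs:
            fh.write(f"##contig=<ID={h.gene_id},length={h.sequence_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for h in hs:
            for j in range(h.n_sites):
                gts = [
                    f"{h.sites[2 * i, j]}|{h.sites[2 * i + 1, j]}"
                    for i in range(n // 2)
                ]
                fh.write(
                    f"{h.gene_id}\t{j + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                    + "\t".join(gts) + "\n"
                )


def read_vcf_minimal(path) -> list[HaplotypeMatrix]:
    """Parse a minimal biallelic-SNP VCF into per-contig haplotype
    matrices, expanding each diploid GT into two haplotypes.

    Unphased genotypes ('/') are accepted with a logged caveat: allele
    order within an individual is as written, which is arbitrary but has
    no effect on allele-frequency-based statistics.
    """
    import pysam

    contig_len: dict[str, int] = {}
    per_gene: dict[str, list[list[int]]] = {}
    unphased = False
    with pysam.VariantFile(str(path)) as vcf:
        for name, rec in vcf.header.contigs.items():
            contig_len[name] = rec.length or 1000
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError(
                    f"{rec.chrom}:{rec.pos}: only biallelic SNPs are supported"
                )
            col: list[int] = []
            for sample in rec.samples.values():
                alleles = sample["GT"]
                if any(a is None for a in alleles):
                    raise ValueError(f"{rec.chrom}:{rec.pos}: missing genotype")
                if not sample.phased:
                    unphased = True
                col.extend(int(a) for a in alleles)
            per_gene.setdefault(rec.chrom, []).append(col)
    if unphased:
        log.warning(
            "unphased genotypes expanded to haplotypes in written order; "
            "fine for frequency-based statistics"
        )
    out = []
    for gene, cols in per_gene.items():
        mat = np.array(cols, dtype=np.int8).T  # haplotypes x sites
        poly = (mat.sum(axis=0) > 0) & (mat.sum(axis=0) < mat.shape[0])
        out.append(
            HaplotypeMatrix(
                gene_id=gene,
                sites=mat[:, poly],
                sequence_length=contig_len.get(gene, 1000),
            )
        )
    return out
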