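"""Tabular file formats: frequency/depth matrices, GRMs, phenotypes, VCF.

Matrix files are TSV with SNP ids in the first column and family ids in the
header row; missing cells are written as ``NA``.  GRM files are square TSV
with family ids as both header and row names.  Phenotype files have columns
``family  rep  trial  pop1  pop2  value`` (trial/pop columns may be ``NA``).
Parsers raise :class:`~poolherit.errors.ParseError` with the offending line
number for ragged rows, non-numeric cells and duplicate ids.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .grm import GenomicRelationshipMatrix
from .snp_filters import PoolFrequencyMatrix

NA = "NA"


def _parse_table(path):
    """Parse a TSV into (header_ids, row_ids, rows of str cells); checks shape."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError("file is empty", str(path), 1)
    header = lines[0].rstrip("\n").split("\t")
    col_ids = header[1:]
    if len(set(col_ids)) != len(col_ids):
        dup = next(c for c in col_ids if col_ids.count(c) > 1)
        raise ParseError(f"duplicate column id {dup!r}", str(path), 1)
    row_ids, rows = [], []
    seen = set()
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(col_ids) + 1:
            raise ParseError(
                f"expected {len(col_ids) + 1} columns, found {len(cells)}",
                str(path), ln,
            )
        rid = cells[0]
        if rid in seen:
            raise ParseError(f"duplicate row id {rid!r}", str(path), ln)
        seen.add(rid)
        row_ids.append(rid)
        rows.append(cells[1:])
    return col_ids, row_ids, rows


def _to_float(cells, path, ln_start):
    out = np.empty((len(cells), len(cells[0]) if cells else 0))
    mask = np.zeros_like(out, dtype=bool)
    for i, row in enumerate(cells):
        for j, c in enumerate(row):
            if c == NA or c == "":
                mask[i, j] = True
                out[i, j] = 0.0
            else:
                try:
                    out[i, j] = float(c)
                except ValueError:
                    raise ParseError(
                        f"non-numeric cell {c!r} in column {j + 2}",
                        None, ln_start + i,
                    ) from None
    return out, mask


def read_frequency_matrix(path, depths_path=None) -> PoolFrequencyMatrix:
    """Read a SNP x family frequency TSV (and optional matching depth TSV)."""
    col_ids, row_ids, rows = _parse_table(path)
    values, missing = _to_float(rows, str(path), 2)
    depths = None
    if depths_path is not None:
        dcols, drows, dcells = _parse_table(depths_path)
        if dcols != col_ids or drows != row_ids:
            raise ValidationError("depth matrix ids do not match frequency matrix")
        depths, dmask = _to_float(dcells, str(depths_path), 2)
        depths[dmask] = 0.0
        missing = missing | (depths == 0)
    return PoolFrequencyMatrix(
        values=values, missing=missing, snp_ids=row_ids, family_ids=col_ids, depths=depths
    )


def write_frequency_matrix(path, matrix: PoolFrequencyMatrix, what: str = "values"):
    """Write frequencies (or, with ``what='depths'``, the depth matrix)."""
    data = matrix.values if what == "values" else matrix.depths
    if data is None:
        raise ValidationError(f"matrix has no {what}")
    with open(path, "w") as fh:
        fh.write("snp\t" + "\t".join(matrix.family_ids) + "\n")
        for i, sid in enumerate(matrix.snp_ids):
            cells = [
                NA if (what == "values" and matrix.missing[i, j]) else format(data[i, j], ".10g")
                for j in range(matrix.n_families)
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_grm(path) -> GenomicRelationshipMatrix:
    """Read a square GRM TSV; the scaling constant K is carried in a sidecar
    comment-free format, so a bare matrix yields K = nan."""
    col_ids, row_ids, rows = _parse_table(path)
    if col_ids != row_ids:
        raise ParseError("GRM row ids do not match column ids", str(path), 1)
    G, mask = _to_float(rows, str(path), 2)
    if mask.any():
        raise ParseError("GRM may not contain missing cells", str(path))
    return GenomicRelationshipMatrix(
        G=0.5 * (G + G.T),
        K=float("nan"),
        mean_diagonal=float(np.mean(np.diag(G))),
        family_ids=col_ids,
    )


def write_grm(path, grm: GenomicRelationshipMatrix):
    with open(path, "w") as fh:
        fh.write("family\t" + "\t".join(grm.family_ids) + "\n")
        for j, fid in enumerate(grm.family_ids):
            fh.write(fid + "\t" + "\t".join(format(v, ".10g") for v in grm.G[j]) + "\n")


PHENO_COLUMNS = ["family", "rep", "trial", "pop1", "pop2", "value"]


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV with columns family, rep, trial, pop1, pop2, value."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError("file is empty", str(path), 1)
    header = lines[0].split("\t")
    if header != PHENO_COLUMNS:
        raise ParseError(
            f"expected header {PHENO_COLUMNS}, found {header}", str(path), 1
        )
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(PHENO_COLUMNS):
            raise ParseError(
                f"expected {len(PHENO_COLUMNS)} columns, found {len(cells)}",
                str(path), ln,
            )
        fam, rep, trial, pop1, pop2, value = cells
        try:
            rep = int(rep)
            value = float(value)
        except ValueError:
            raise ParseError("non-numeric rep or value", str(path), ln) from None
        rows.append(
            (fam, rep, None if trial == NA else trial,
             None if pop1 == NA else pop1, None if pop2 == NA else pop2, value)
        )
    return pd.DataFrame(rows, columns=PHENO_COLUMNS)


def write_phenotypes(path, pheno: pd.DataFrame):
    df = pheno[PHENO_COLUMNS].copy()
    df = df.fillna(NA).replace({None: NA})
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def write_truth(path, scenario, dataset):
    """JSON sidecar recording the generator settings and simulated truth."""
    from dataclasses import asdict

    doc = {
        "scenario": asdict(scenario),
        "qtl_indices": dataset.qtl_indices.tolist(),
        "qtl_effects": dataset.qtl_effects.tolist(),
        "variance_settings": {
            "sigma2_g": 1.0,
            "sigma2_f": scenario.sigma2_f,
            "sigma2_e": scenario.sigma2_e,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def frequencies_from_vcf(vcf_path) -> PoolFrequencyMatrix:
    """Pool frequencies from per-sample allelic depths (AD) in a VCF.

    For each biallelic record and sample, frequency = alt depth / total depth
    and the total depth is recorded in the depth matrix; zero total depth
    marks the cell missing.  Multiallelic records are skipped (counted).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    snp_ids, freq_rows, depth_rows = [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ad = rec.format("AD")
        if ad is None:
            raise ValidationError(
                f"record {rec.CHROM}:{rec.POS} has no AD (allelic depth) field"
            )
        ad = np.asarray(ad, dtype=float)
        ad[ad < 0] = 0.0            # cyvcf2 encodes missing as negative
        total = ad.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(total > 0, ad[:, 1] / np.maximum(total, 1), 0.0)
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        freq_rows.append(freq)
        depth_rows.append(total)
    if n_multi:
        import logging

        logging.getLogger(__name__).warning("skipped %d multiallelic records", n_multi)
    values = np.array(freq_rows)
    depths = np.array(depth_rows)
    return PoolFrequencyMatrix(
        values=values,
        missing=depths == 0,
        snp_ids=snp_ids,
        family_ids=samples,
        depths=depths,
    )
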