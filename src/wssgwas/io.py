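"""Readers and writers for the pipeline's file formats.

Pedigree CSV: header ``animal,sire,dam``; "0" or empty marks an unknown
parent.  Phenotype CSV: header ``animal,dam,sex,birth_type,herd,
birth_year,dam_age,trait``.  Genotypes: PLINK .ped/.map text and
.bed/.bim/.fam binary (v1, SNP-major, magic 6c 1b 01); the counted
allele is A1, so the 2-bit codes {00, 10, 11, 01} decode to counts
{2, 1, 0, missing}.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MarkerMap, QCReport
from .gwas import WindowTable, WssgwasResult, window_table_for_result, top_windows
from .mixed_model import SolutionSet
from .pedigree import Pedigree, sort_pedigree

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes -> allele-1 counts (nan = missing)
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])
_BED_ENCODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


# ---------------------------------------------------------------- pedigree

def read_pedigree_csv(path: str | Path, sort: bool = True) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"animal", "sire", "dam"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: pedigree CSV must have columns {sorted(required)}")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        if not row.animal:
            raise ValueError(f"{path}:{lineno}: empty animal id")
        records.append((row.animal, row.sire or None, row.dam or None))
    ped = Pedigree.from_records(records)
    return sort_pedigree(ped) if sort else ped


def write_pedigree_csv(ped: Pedigree, path: str | Path) -> None:
    ped.to_frame().to_csv(path, index=False)


# -------------------------------------------------------------- phenotypes

PHENO_COLUMNS = ("animal", "dam", "sex", "birth_type", "herd", "birth_year", "dam_age", "trait")


def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: str for c in PHENO_COLUMNS if c != "trait"})
    missing = [c for c in ("animal", "dam", "trait") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phenotype CSV missing columns {missing}")
    if df["trait"].isna().any():
        lineno = int(df.index[df["trait"].isna()][0]) + 2
        raise ValueError(f"{path}:{lineno}: missing trait value")
    return df


def write_phenotypes_csv(phenos: pd.DataFrame, path: str | Path) -> None:
    phenos.to_csv(path, index=False)


# ------------------------------------------------------------- PLINK text

def write_plink_text(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write .ped/.map; counts code copies of allele_a; missing = '0 0'."""
    prefix = Path(prefix)
    tab = g.markers.table
    with open(prefix.with_suffix(".map"), "w") as fh:
        for r in tab.itertuples(index=False):
            fh.write(f"{r.chromosome}\t{r.snp_id}\t0\t{r.position_bp}\n")
    a = tab["allele_a"].to_numpy()
    b = tab["allele_b"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            row = g.counts[i]
            for j in range(len(row)):
                c = row[j]
                if np.isnan(c):
                    fields += ["0", "0"]
                elif c == 2:
                    fields += [a[j], a[j]]
                elif c == 1:
                    fields += [a[j], b[j]]
                else:
                    fields += [b[j], b[j]]
            fh.write(" ".join(map(str, fields)) + "\n")


def read_plink_text(prefix: str | Path) -> GenotypeMatrix:
    """Read .ped/.map; the counted allele per SNP is allele_a from the
    first non-missing genotype encountered (ties: lexicographically
    smaller allele)."""
    prefix = Path(prefix)
    map_rows = []
    with open(prefix.with_suffix(".map")) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{prefix}.map:{lineno}: expected 4 fields, got {len(parts)}")
            map_rows.append((parts[1], int(parts[0]), int(parts[3])))
    m = len(map_rows)

    sample_ids: list[str] = []
    geno_rows: list[list[str]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{prefix}.ped:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            geno_rows.append(parts[6:])
    n = len(sample_ids)
    counts = np.full((n, m), np.nan)
    allele_a = ["A"] * m
    allele_b = ["B"] * m
    alleles = np.array(geno_rows, dtype=object).reshape(n, m, 2) if n else np.empty((0, m, 2))
    for j in range(m):
        col = alleles[:, j, :]
        obs = col[(col[:, 0] != "0") & (col[:, 1] != "0")]
        uniq = sorted(set(obs.ravel().tolist()))
        if len(uniq) > 2:
            raise ValueError(f"{prefix}.ped: SNP {map_rows[j][0]} has >2 alleles: {uniq}")
        a1 = uniq[0] if uniq else "A"
        a2 = uniq[1] if len(uniq) > 1 else ("B" if a1 != "B" else "A")
        allele_a[j], allele_b[j] = a1, a2
        for i in range(n):
            x, y_ = col[i]
            if x == "0" or y_ == "0":
                continue
            counts[i, j] = float((x == a1) + (y_ == a1))
    markers = MarkerMap(
        pd.DataFrame(
            {
                "snp_id": [r[0] for r in map_rows],
                "chromosome": [r[1] for r in map_rows],
                "position_bp": [r[2] for r in map_rows],
                "allele_a": allele_a,
                "allele_b": allele_b,
            }
        )
    )
    return GenotypeMatrix(counts=counts, sample_ids=sample_ids, markers=markers)


# ----------------------------------------------------------- PLINK binary

def write_plink_bed(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write .bed/.bim/.fam (v1, SNP-major)."""
    prefix = Path(prefix)
    tab = g.markers.table
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for r in tab.itertuples(index=False):
            fh.write(f"{r.chromosome}\t{r.snp_id}\t0\t{r.position_bp}\t{r.allele_a}\t{r.allele_b}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in g.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    n, m = g.counts.shape
    nbytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(m):
            buf = np.zeros(nbytes, dtype=np.uint8)
            col = g.counts[:, j]
            for i in range(n):
                code = 0b01 if np.isnan(col[i]) else _BED_ENCODE[col[i]]
                buf[i // 4] |= code << ((i % 4) * 2)
            fh.write(buf.tobytes())


def read_plink_bed(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position_bp", "allele_a", "allele_b"],
        dtype={"snp_id": str, "allele_a": str, "allele_b": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic {raw[:3].hex()} (expected 6c1b01, v1 SNP-major)")
    nbytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if len(body) != m * nbytes:
        raise ValueError(f"{prefix}.bed: size mismatch ({len(body)} bytes for {n} x {m})")
    body = body.reshape(m, nbytes)
    # unpack 2-bit codes, little-endian within byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, np.newaxis] >> shifts[np.newaxis, np.newaxis, :]) & 0b11
    codes = codes.reshape(m, nbytes * 4)[:, :n]
    counts = _BED_DECODE[codes].T.copy()
    markers = MarkerMap(
        bim[["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]].copy()
    )
    return GenotypeMatrix(counts=counts, sample_ids=fam["iid"].tolist(), markers=markers)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read genotypes from ``prefix``: binary .bed/.bim/.fam if present,
    else text .ped/.map."""
    prefix = Path(prefix)
    if prefix.with_suffix(".bed").exists():
        return read_plink_bed(prefix)
    if prefix.with_suffix(".ped").exists():
        return read_plink_text(prefix)
    raise FileNotFoundError(f"no PLINK files at prefix {prefix}")


# ---------------------------------------------------------------- outputs

def write_qc_report(report: QCReport, path: str | Path) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False)


def write_solutions_tsv(sol: SolutionSet, path: str | Path) -> None:
    rows = []
    for lab, v in sol.fixed_solutions.items():
        rows.append(("fixed", lab, v))
    for aid, v in sol.a_hat.items():
        rows.append(("direct", aid, v))
    for aid, v in sol.m_hat.items():
        rows.append(("maternal", aid, v))
    for did, v in sol.p_hat.items():
        rows.append(("pe", did, v))
    pd.DataFrame(rows, columns=["effect_type", "level_or_animal", "estimate"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_windows_tsv(result: WssgwasResult, path: str | Path, window_bp: int = 1_000_000) -> None:
    frames = []
    for it in result.iterations:
        for eff in ("direct", "maternal"):
            wt = window_table_for_result(result, effect_type=eff, iteration=it.iteration, window_bp=window_bp)
            frames.append(wt.table.assign(effect_type=eff, iteration=it.iteration))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_snp_effects_tsv(result: WssgwasResult, path: str | Path) -> None:
    tab = result.markers.table
    frames = []
    for it in result.iterations:
        for eff, es in it.snp_effects.items():
            frames.append(
                pd.DataFrame(
                    {
                        "snp_id": tab["snp_id"],
                        "chromosome": tab["chromosome"],
                        "bp": tab["position_bp"],
                        "u_hat": es.u_hat,
                        "weight": it.weights.d,
                        "effect_type": eff,
                        "iteration": it.iteration,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_window_table_tsv(wt: WindowTable, path: str | Path) -> None:
    wt.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_relationship_lower_triangle(mat, path: str | Path) -> None:
    """Debug dump: row_id col_id value, lower triangle."""
    with open(path, "w") as fh:
        for i, rid in enumerate(mat.ids):
            for j in range(i + 1):
                fh.write(f"{rid} {mat.ids[j]} {mat.values[i, j]:.10g}\n")
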