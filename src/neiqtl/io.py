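"""Readers and writers for cross, spatial-map, and result files.

Cross CSV dialect (one canonical layout, permissive on genotype codes):

- row 1: column headers — phenotype names first, then marker names;
- row 2: chromosome id per marker column, empty for phenotype columns;
- row 3: cM position per marker column, empty for phenotype columns;
- remaining rows: one individual each.

Genotype codes default to ``AA/AB/BB`` with ``A/H/B`` accepted; ``-`` and
the empty string mean missing.  A phenotype column named ``id`` supplies
individual identifiers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .genotypes import AA, AB, BB, MISSING, CrossPopulation, GeneticMap
from .neighbors import SpatialMap
from .scan import PermutationThresholds, ScanResult

DEFAULT_GENOTYPE_CODES = {
    "AA": AA, "AB": AB, "BB": BB,
    "A": AA, "H": AB, "B": BB,
}
DEFAULT_NA = {"-", "", "NA", "nan"}

_CODE_LABEL = {AA: "AA", AB: "AB", BB: "BB", MISSING: "-"}


def config_hash(config: dict) -> str:
    """Stable short hash of a run configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def read_cross(
    path: str | Path,
    cross_type: str,
    genotype_codes: dict[str, int] | None = None,
    na_values: set[str] | None = None,
) -> tuple[CrossPopulation, pd.DataFrame]:
    """Read a cross CSV; returns the cross and a phenotype table."""
    codes = dict(DEFAULT_GENOTYPE_CODES if genotype_codes is None else genotype_codes)
    na = set(DEFAULT_NA if na_values is None else na_values)
    raw = pd.read_csv(path, header=None, dtype=str, comment="#").fillna("")
    if raw.shape[0] < 4:
        raise SchemaError(f"{path}: expected header + chromosome + position + data rows")
    header = [h.strip() for h in raw.iloc[0]]
    chrom_row = [c.strip() for c in raw.iloc[1]]
    pos_row = [p.strip() for p in raw.iloc[2]]
    is_marker = [c != "" for c in chrom_row]
    marker_cols = [k for k, m in enumerate(is_marker) if m]
    pheno_cols = [k for k, m in enumerate(is_marker) if not m]
    if not marker_cols:
        raise SchemaError(f"{path}: no marker columns (empty chromosome row?)")
    marker_names = [header[k] for k in marker_cols]
    if len(set(marker_names)) != len(marker_names):
        dup = {m for m in marker_names if marker_names.count(m) > 1}
        raise SchemaError(f"{path}: duplicated marker name(s) {sorted(dup)}")
    chroms = list(dict.fromkeys(chrom_row[k] for k in marker_cols))
    names = {c: [] for c in chroms}
    pos = {c: [] for c in chroms}
    for k in marker_cols:
        c = chrom_row[k]
        names[c].append(header[k])
        try:
            pos[c].append(float(pos_row[k]))
        except ValueError:
            raise SchemaError(
                f"{path}: bad position {pos_row[k]!r} for marker {header[k]}"
            ) from None
    gmap = GeneticMap(chroms, names, {c: np.asarray(v) for c, v in pos.items()})

    body = raw.iloc[3:].reset_index(drop=True)
    n = body.shape[0]
    geno = np.full((n, len(marker_cols)), MISSING, dtype=np.int8)
    for j, k in enumerate(marker_cols):
        col = body.iloc[:, k].str.strip()
        for i, val in enumerate(col):
            if val in na:
                continue
            if val not in codes:
                raise SchemaError(
                    f"{path}: unknown genotype code {val!r} at individual row {i + 1}, "
                    f"marker {header[k]}"
                )
            geno[i, j] = codes[val]

    pheno = pd.DataFrame({header[k]: body.iloc[:, k] for k in pheno_cols})
    if "id" in pheno.columns:
        ids = pheno["id"].astype(str).tolist()
    else:
        ids = [str(i + 1) for i in range(n)]
        pheno.insert(0, "id", ids)
    for c in pheno.columns:
        if c != "id":
            pheno[c] = pd.to_numeric(pheno[c].replace(sorted(na), np.nan), errors="coerce")
    cross = CrossPopulation(cross_type, geno, ids, gmap)
    return cross, pheno


def write_cross(
    cross: CrossPopulation, pheno: pd.DataFrame, path: str | Path
) -> None:
    """Write a cross + phenotypes in the canonical CSV dialect."""
    gmap = cross.map
    pheno = pheno.copy()
    if "id" not in pheno.columns:
        pheno.insert(0, "id", cross.ids)
    header, chrom_row, pos_row = [], [], []
    for c in pheno.columns:
        header.append(str(c))
        chrom_row.append("")
        pos_row.append("")
    for chrom in gmap.chromosomes:
        for name, p in zip(gmap.marker_names[chrom], gmap.positions[chrom]):
            header.append(name)
            chrom_row.append(chrom)
            pos_row.append(f"{p:g}")
    lines = [",".join(header), ",".join(chrom_row), ",".join(pos_row)]
    for i in range(cross.n_individuals):
        row = [str(pheno.iloc[i][c]) for c in pheno.columns]
        row += [_CODE_LABEL[int(g)] for g in cross.genotypes[i]]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_spatial(path: str | Path) -> SpatialMap:
    df = pd.read_csv(path, comment="#")
    missing = {"id", "x", "y"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: spatial map missing column(s) {sorted(missing)}")
    if df[["x", "y"]].isna().any().any():
        raise SchemaError(f"{path}: spatial coordinates contain missing values")
    return SpatialMap.from_frame(df)


def write_spatial(smap: SpatialMap, path: str | Path) -> None:
    smap.to_frame().to_csv(path, index=False)


def write_scan_result(
    res: ScanResult, path: str | Path, config: dict | None = None
) -> None:
    """Results CSV: chromosome, position, marker name, effects, LODs."""
    t = res.table
    out = pd.DataFrame(
        {
            "chromosome": t["chromosome"],
            "position_cM": t["position"],
            "marker_name": t["label"],
            "is_marker": t["is_marker"],
        }
    )
    for col in ("eff_2a1", "eff_d1", "lod_self", "eff_2a2sq", "eff_d2sq", "lod_nei"):
        if col in t.columns:
            out[col] = t[col]
    header = ""
    if config is not None:
        header = f"# neiqtl config={config_hash(config)} seed={config.get('seed', 'NA')}\n"
    with open(path, "w") as fh:
        fh.write(header)
        out.to_csv(fh, index=False)


def write_thresholds(
    thr: PermutationThresholds, path: str | Path, config: dict | None = None
) -> None:
    payload = thr.to_dict()
    if config is not None:
        payload["config_hash"] = config_hash(config)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
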