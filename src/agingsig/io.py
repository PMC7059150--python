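"""File formats and run manifests.

Expression matrices travel as GCT 1.2 or plain TSV (genes as rows, first
column the gene id); gene sets as GMT; donor/sample attribute tables as TSV
with a configurable column-name mapping so GTEx-style headers (SMRIN,
SMTSISCH, ...) drop in unchanged. All outputs are plain text and diffable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

#: default mapping from GTEx-style attribute headers to semantic fields
GTEX_COLUMN_MAP = {
    "SUBJID": "donor_id",
    "SAMPID": "sample_id",
    "AGE": "age",
    "SEX": "sex",
    "GENDER": "sex",
    "BMI": "bmi",
    "SMRIN": "rin",
    "SMTSISCH": "ischemic_time",
    "SMTSD": "tissue",
    "TRISCHD": "pmi",
    "DTHPMI": "pmi",
    "MHDISEASES": "disease_codes",
}

#: decade brackets ("50-59") map to their midpoints when ages arrive binned
def age_from_bracket(value) -> float:
    if isinstance(value, str) and "-" in value:
        lo, hi = value.split("-")
        return (float(lo) + float(hi) + 1.0) / 2.0
    return float(value)


def read_gct(path) -> pd.DataFrame:
    """Read a GCT 1.2 file into a genes x samples frame."""
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        nrow, ncol = (int(v) for v in fh.readline().split()[:2])
        df = pd.read_csv(fh, sep="\t")
    if df.shape[0] != nrow or df.shape[1] - 2 != ncol:
        raise ValueError(
            f"{path}: dimension line says {nrow} x {ncol} but body is "
            f"{df.shape[0]} x {df.shape[1] - 2}"
        )
    df = df.set_index(df.columns[0]).drop(columns=[df.columns[1]])
    _check_unique_genes(df)
    return df


def write_gct(df: pd.DataFrame, path, description=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        out = df.copy()
        out.insert(0, "Description", description if description is not None else "na")
        out.index.name = "Name"
        out.to_csv(fh, sep="\t")


def _check_unique_genes(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicated gene ids: {dups}")


def read_expression(path, counts: bool = False) -> pd.DataFrame:
    """Read an expression matrix from GCT 1.2 or TSV (sniffed by the '#1.2'
    header). ``counts=True`` additionally rejects negative values."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first == "#1.2":
        df = read_gct(path)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        _check_unique_genes(df)
    if counts and (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: counts matrix contains negative values")
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> gene...; order-free."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line "
                                 f"(need name, description, >=1 gene)")
            name = parts[0]
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_attribute_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a donor or sample TSV, renaming headers through the column map
    (defaults to the GTEx-style mapping) and converting bracketed ages."""
    df = pd.read_csv(path, sep="\t")
    cmap = dict(GTEX_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = df.rename(columns={c: cmap[c] for c in df.columns if c in cmap})
    if "age" in df.columns:
        df["age"] = df["age"].map(age_from_bracket)
    return df


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, config: dict, seed: int,
                   inputs: dict[str, str], stages: dict[str, dict]) -> dict:
    """Write the run manifest: config hash, seed, input checksums and
    per-stage row counts. Timestamp-free, so identical runs are
    byte-identical."""
    manifest = {
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "inputs": inputs,
        "stages": stages,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
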