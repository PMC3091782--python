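"""Table IO and schema validation.

All interchange is plain TSV with a mandatory header line; lines starting
with ``#`` are metadata comments (the writer records the seed and package
version there).  Schemas declare column names and dtypes; the reader
rejects malformed rows with their line number, rejects duplicated keys,
and sorts by position within chromosome (with a logged note) if the
input arrives unsorted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TableSchema:
    name: str
    dtypes: dict[str, type]          # column -> dtype
    key: tuple[str, ...] = ()        # uniqueness constraint
    sort_within: tuple[str, str] | None = None  # (group col, position col)
    non_negative: tuple[str, ...] = ()


PILEUP_SCHEMA = TableSchema(
    name="pileup",
    dtypes={"chrom": str, "pos": np.int64, "line": str,
            "ref_reads": np.int64, "nonref_reads": np.int64},
    key=("chrom", "pos", "line"),
    sort_within=("chrom", "pos"),
    non_negative=("pos", "ref_reads", "nonref_reads"),
)

CALLS_SCHEMA = TableSchema(
    name="calls",
    dtypes={"chrom": str, "pos": np.int64, "detected_high": bool,
            "detected_low": bool, "S_high": float, "S_low": float,
            "depth_high": np.int64, "depth_low": np.int64,
            "variation_class": str, "excluded": bool},
    key=("chrom", "pos"),
    sort_within=("chrom", "pos"),
    non_negative=("pos", "depth_high", "depth_low"),
)

CHIP_SUMMARY_SCHEMA = TableSchema(
    name="chip_summary",
    dtypes={"chrom": str, "pos": np.int64, "freq_high": float,
            "freq_low": float, "call_freq": float, "polymorphic": bool,
            "delta_p": float, "usable": bool},
    key=("chrom", "pos"),
    sort_within=("chrom", "pos"),
    non_negative=("pos",),
)

FSV_SCHEMA = TableSchema(
    name="fsv",
    dtypes={"chrom": str, "pos": np.int64, "window_total": np.int64,
            "n_high": np.int64, "n_low": np.int64,
            "mean_absdiff_high": float, "mean_absdiff_low": float,
            "fsv": float, "defined": bool, "density_pass": bool},
    key=("chrom", "pos", "window_total"),
    non_negative=("pos", "window_total", "n_high", "n_low"),
)

TRUTH_SNPS_SCHEMA = TableSchema(
    name="truth_snps",
    dtypes={"chrom": str, "pos": np.int64, "p_high": float, "p_low": float,
            "block_id": np.int64, "on_chip": bool},
    key=("chrom", "pos"),
    sort_within=("chrom", "pos"),
    non_negative=("pos", "block_id"),
)

SCHEMAS = {s.name: s for s in (
    PILEUP_SCHEMA, CALLS_SCHEMA, CHIP_SUMMARY_SCHEMA, FSV_SCHEMA,
    TRUTH_SNPS_SCHEMA,
)}


def write_table(frame: pd.DataFrame, path, comments: dict | None = None) -> None:
    """Write a TSV with ``#`` metadata comment lines above the header."""
    with open(path, "w") as fh:
        for k, v in (comments or {}).items():
            fh.write(f"# {k}: {v}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def read_table(path, schema: TableSchema | None = None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, validating against a schema."""
    frame = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    if schema is None:
        return frame
    return validate_table(frame, schema, source=str(path))


def validate_table(frame: pd.DataFrame, schema: TableSchema, source: str = "<memory>") -> pd.DataFrame:
    """Coerce and validate a frame against ``schema``.

    Raises ValueError naming the offending column/row; sorts by position
    within chromosome if needed (logged).
    """
    missing = [c for c in schema.dtypes if c not in frame.columns]
    if missing:
        raise ValueError(f"{source}: {schema.name} table missing columns {missing}")
    frame = frame[list(schema.dtypes)].copy()
    for col, dtype in schema.dtypes.items():
        if len(frame) == 0:
            frame[col] = frame[col].astype(dtype if dtype is not str else object)
            continue
        if dtype in (np.int64, bool):
            bad = frame[col].isna()
            if bad.any():
                row = int(bad.idxmax()) + 2  # 1-based + header line
                raise ValueError(
                    f"{source}: malformed {schema.name} row near line {row}: "
                    f"missing value in column {col!r}"
                )
        try:
            frame[col] = frame[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{source}: column {col!r} cannot be parsed as {dtype}: {exc}"
            ) from None
    for col in schema.non_negative:
        bad = frame.index[frame[col] < 0]
        if len(bad):
            raise ValueError(
                f"{source}: negative value in column {col!r} at row "
                f"{int(bad[0]) + 2}"
            )
    if schema.key:
        dup = frame.duplicated(list(schema.key))
        if dup.any():
            first = frame.loc[dup.idxmax(), list(schema.key)].tolist()
            raise ValueError(
                f"{source}: duplicated key {tuple(first)} in {schema.name} table"
            )
    if schema.sort_within is not None:
        group, poscol = schema.sort_within
        unsorted = frame.groupby(group, sort=False)[poscol].apply(
            lambda s: (s.diff().dropna() < 0).any()
        )
        if unsorted.any():
            logger.info("%s: sorting %s table by (%s, %s)", source, schema.name,
                        group, poscol)
            frame = frame.sort_values([group, poscol], kind="mergesort")
    return frame.reset_index(drop=True)


def write_genotypes(frame: pd.DataFrame, path, comments: dict | None = None) -> None:
    write_table(frame, path, comments)


def read_genotypes(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    ind_cols = [c for c in frame.columns if c not in ("chrom", "pos")]
    frame[ind_cols] = frame[ind_cols].astype("Int8")
    bad = [
        c for c in ind_cols
        if not bool(frame[c].dropna().isin([0, 1, 2]).all())
    ]
    if bad:
        raise ValueError(f"{path}: dosages outside {{0,1,2}} in columns {bad}")
    return frame


def write_chip_vcf(genotypes: dict[str, pd.DataFrame], path) -> None:
    """Minimal VCF export of chip genotypes (GT fields only).

    Alleles are written as symbolic REF=A, ALT=C since the generator
    models dosages, not nucleotides.
    """
    high, low = genotypes["high"], genotypes["low"]
    samples = (
        [f"high_{c}" for c in high.columns if c not in ("chrom", "pos")]
        + [f"low_{c}" for c in low.columns if c not in ("chrom", "pos")]
    )
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i in range(len(high)):
            row = [str(high["chrom"].iat[i]), str(high["pos"].iat[i]),
                   ".", "A", "C", ".", ".", ".", "GT"]
            for frame in (high, low):
                for c in frame.columns:
                    if c in ("chrom", "pos"):
                        continue
                    dosage = frame[c].iat[i]
                    row.append("./." if pd.isna(dosage) else gt_map[int(dosage)])
            fh.write("\t".join(row) + "\n")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
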