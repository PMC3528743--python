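"""File formats: siRNA CSV tables, FASTA input, feature-matrix CSV,
YAML run configuration and JSON diagnostics.

The canonical exchange format is a CSV with header columns
``id, antisense, efficacy, target_accession, domain_id`` (efficacy may
be empty for prediction-only records).  FASTA is accepted for sequences
only, with efficacy/domain labels supplied via a side CSV keyed by
record id.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .features import FeatureCatalog, FeatureMatrix, build_feature_matrix, default_catalog
from .records import DomainDataset, SequenceError, SirnaRecord

REQUIRED_COLUMNS = ("id", "antisense", "efficacy", "target_accession", "domain_id")


@dataclass
class RowError:
    line: int
    message: str


def read_sirna_table(path: str | Path) -> tuple[list[SirnaRecord], list[RowError]]:
    """Read and validate an siRNA CSV table.

    Invalid rows (bad sequence, efficacy outside [0, 1]) are rejected
    individually and reported with their line numbers; valid rows are
    kept.
    """
    path = Path(path)
    records: list[SirnaRecord] = []
    errors: list[RowError] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header required")
        missing = [c for c in ("id", "antisense") if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                eff_raw = (row.get("efficacy") or "").strip()
                efficacy = float(eff_raw) if eff_raw else None
                records.append(
                    SirnaRecord(
                        id=row["id"],
                        antisense=row["antisense"],
                        efficacy=efficacy,
                        target_accession=(row.get("target_accession") or None),
                        domain_id=row.get("domain_id") or "",
                    )
                )
            except (SequenceError, ValueError) as exc:
                errors.append(RowError(lineno, str(exc)))
    return records, errors


def read_fasta_records(
    fasta_path: str | Path, side_csv: Optional[str | Path] = None
) -> tuple[list[SirnaRecord], list[RowError]]:
    """Read sequences from FASTA; efficacy/domain from an optional side CSV.

    The side CSV must have columns ``id, efficacy[, domain_id]``.
    """
    meta: dict[str, dict] = {}
    if side_csv is not None:
        df = pd.read_csv(side_csv, dtype={"id": str})
        meta = {str(r["id"]): r for _, r in df.iterrows()}
    records: list[SirnaRecord] = []
    errors: list[RowError] = []
    for i, rec in enumerate(SeqIO.parse(str(fasta_path), "fasta")):
        try:
            m = meta.get(rec.id, {})
            eff = m.get("efficacy")
            records.append(
                SirnaRecord(
                    id=rec.id,
                    antisense=str(rec.seq),
                    efficacy=None if eff is None or pd.isna(eff) else float(eff),
                    domain_id=str(m.get("domain_id", "") or ""),
                )
            )
        except (SequenceError, ValueError) as exc:
            errors.append(RowError(i + 1, str(exc)))
    return records, errors


def write_sirna_table(records: Sequence[SirnaRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.antisense,
                    "" if r.efficacy is None else f"{r.efficacy:.6f}",
                    r.target_accession or "",
                    r.domain_id,
                ]
            )


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Feature matrix as CSV: record ids as rows, feature names as columns."""
    df = pd.DataFrame(fm.values, index=fm.record_ids, columns=fm.feature_names)
    df.index.name = "id"
    df.to_csv(path, float_format="%.6g")


def records_to_dataset(
    records: Sequence[SirnaRecord],
    name: str,
    role: str = "source",
    catalog: Optional[FeatureCatalog] = None,
) -> DomainDataset:
    """Featurize labeled records into a DomainDataset."""
    labeled = [r for r in records if r.efficacy is not None]
    if not labeled:
        raise ValueError(f"{name}: no records with efficacy values")
    if catalog is None:
        catalog = default_catalog()
    fm = build_feature_matrix(labeled, catalog)
    y = np.array([r.efficacy for r in labeled])
    return DomainDataset(
        name=name,
        X=fm.values,
        y=y,
        role=role,
        feature_names=catalog.names,
        records=labeled,
    )


def load_domain_csv(
    path: str | Path,
    role: str = "source",
    catalog: Optional[FeatureCatalog] = None,
) -> tuple[DomainDataset, list[RowError]]:
    records, errors = read_sirna_table(path)
    name = Path(path).stem
    return records_to_dataset(records, name, role, catalog), errors


def read_run_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def write_run_config(cfg: dict, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_json(doc: dict, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
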