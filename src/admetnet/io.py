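"""Delimited-text and SDF readers/writers for assay records and predictions."""

from __future__ import annotations

import numpy as np
import pandas as pd
from rdkit import Chem

from .preprocess import AssayRecord

RECORD_COLUMNS = ["compound_id", "smiles", "endpoint", "value", "qualifier", "date"]


def _record_from_row(compound_id, smiles, endpoint, value, qualifier, date) -> AssayRecord:
    qualifier = "eq" if qualifier in (None, "", "eq") or pd.isna(qualifier) else str(qualifier)
    qualifier = {"<": "lt", ">": "gt"}.get(qualifier, qualifier)
    parsed_date = None
    if date is not None and not pd.isna(date) and str(date) != "":
        parsed_date = np.datetime64(pd.Timestamp(date).date())
    return AssayRecord(compound_id=str(compound_id), smiles=str(smiles),
                       endpoint_code=str(endpoint), value=float(value),
                       qualifier=qualifier, date=parsed_date)


def read_assay_records(path, sep: str | None = None) -> list[AssayRecord]:
    """Read records from CSV/TSV with columns compound_id, smiles, endpoint,
    value and optional qualifier (eq/lt/gt or </>) and date columns."""
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = {"compound_id", "smiles", "endpoint", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(_record_from_row(
            row.compound_id, row.smiles, row.endpoint, row.value,
            getattr(row, "qualifier", None), getattr(row, "date", None)))
    return records


def write_assay_records(records: list[AssayRecord], path, sep: str = ",") -> None:
    df = pd.DataFrame(
        [(r.compound_id, r.smiles, r.endpoint_code, r.value, r.qualifier,
          "" if r.date is None else str(r.date)) for r in records],
        columns=RECORD_COLUMNS)
    df.to_csv(path, sep=sep, index=False)


def read_assay_records_sdf(path, id_field: str = "compound_id",
                           endpoint_field: str = "endpoint", value_field: str = "value",
                           qualifier_field: str = "qualifier",
                           date_field: str = "date") -> list[AssayRecord]:
    """Read records from an SDF where each entry carries assay properties."""
    records = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            continue
        props = mol.GetPropsAsDict()
        records.append(_record_from_row(
            props.get(id_field, mol.GetProp("_Name") if mol.HasProp("_Name") else ""),
            Chem.MolToSmiles(mol), props[endpoint_field], props[value_field],
            props.get(qualifier_field), props.get(date_field)))
    return records


def write_predictions(path, compound_ids, endpoint_codes, predictions: np.ndarray) -> None:
    """Write a long-format CSV (compound_id, endpoint, prediction)."""
    rows = [(cid, code, predictions[i, t])
            for i, cid in enumerate(compound_ids)
            for t, code in enumerate(endpoint_codes)]
    pd.DataFrame(rows, columns=["compound_id", "endpoint", "prediction"]).to_csv(path, index=False)
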