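"""Assay-record preprocessing.

Raw per-measurement records become a standardized compounds × tasks label
matrix in four steps:

1. qualifier adjustment — a censored measurement reported as ``< v`` is
   replaced by ``v / 2`` and ``> v`` by ``2 v`` (applied per measurement,
   before any averaging);
2. structure standardization and deduplication — compound identity is the
   canonical standardized structure, not the vendor identifier;
3. replicate aggregation — the arithmetic mean of the qualifier-adjusted
   raw values is taken as the final experimental value, then transformed
   to the modelling scale (e.g. mg/L → log10 mol/L for solubility);
4. per-task standard scaling to zero mean / unit variance, fitted on the
   training portion only when a split is supplied, so that endpoints with
   very different ranges (melting points vs log units) contribute
   comparably to a joint loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .endpoints import EndpointSpec
from .mol import MoleculeParseError, StandardizedMolecule, standardize_molecule

logger = logging.getLogger(__name__)

QUALIFIERS = ("eq", "lt", "gt")


@dataclass(frozen=True)
class AssayRecord:
    """One raw measurement of one compound in one assay."""

    compound_id: str
    smiles: str
    endpoint_code: str
    value: float
    qualifier: str = "eq"
    date: np.datetime64 | None = None

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError(f"non-finite assay value for {self.compound_id}/{self.endpoint_code}")
        if self.qualifier not in QUALIFIERS:
            raise ValueError(f"unknown qualifier {self.qualifier!r}")


def apply_qualifier(value: float, qualifier: str) -> float:
    """Resolve a censored measurement: ``<`` halves, ``>`` doubles.

    A value reported as "<10" is replaced by 5, ">10" by 20, and an exact
    measurement is passed through unchanged.
    """
    if not np.isfinite(value):
        raise ValueError("assay value must be finite")
    if qualifier == "eq":
        return float(value)
    if qualifier == "lt":
        return float(value) / 2.0
    if qualifier == "gt":
        return float(value) * 2.0
    raise ValueError(f"unknown qualifier {qualifier!r}")


def aggregate_replicates(records: list[AssayRecord]) -> float:
    """Mean of qualifier-adjusted raw values for one compound+endpoint."""
    if not records:
        raise ValueError("cannot aggregate an empty replicate list")
    keys = {(r.endpoint_code) for r in records}
    if len(keys) != 1:
        raise ValueError("replicates must share one endpoint")
    return float(np.mean([apply_qualifier(r.value, r.qualifier) for r in records]))


def to_model_scale(value: float, spec: EndpointSpec, mol_weight: float | None = None) -> float:
    """Transform a raw assay value onto the modelling scale.

    ``none`` passes through, ``log10`` takes log10 of the raw value, and
    ``log10_molar`` converts mg/L to mol/L before the log10.
    """
    if spec.transform == "none":
        return float(value)
    if value <= 0:
        raise ValueError(f"non-positive value {value} under log transform ({spec.code})")
    if spec.transform == "log10":
        return float(np.log10(value))
    if mol_weight is None or mol_weight <= 0:
        raise ValueError(f"molecular weight required for log10_molar transform ({spec.code})")
    return float(np.log10(value / 1000.0 / mol_weight))


def invert_model_scale(value: float, spec: EndpointSpec,
                       scaler: tuple[float, float] | None = None,
                       mol_weight: float | None = None) -> float:
    """Inverse of standardization followed by the inverse endpoint transform."""
    if scaler is not None:
        mean, sd = scaler
        value = value * sd + mean
    if spec.transform == "none":
        return float(value)
    if spec.transform == "log10":
        return float(10.0 ** value)
    if mol_weight is None or mol_weight <= 0:
        raise ValueError("molecular weight required to invert log10_molar")
    return float(10.0 ** value * 1000.0 * mol_weight)


@dataclass
class AssayMatrix:
    """Compounds × tasks label matrix on the modelling scale.

    ``values`` holds transformed (and, once :meth:`standardized` has been
    applied, standard-scaled) labels; entries where ``mask`` is False are
    NaN and never enter a loss.  ``scalers`` is None until standardization
    is fitted.
    """

    compound_ids: list[str]
    smiles: list[str]
    endpoint_codes: list[str]
    specs: list[EndpointSpec]
    values: np.ndarray          # (n, T) float, NaN where unmasked
    mask: np.ndarray            # (n, T) bool
    dates: np.ndarray           # (n, T) datetime64[D], NaT where absent
    mol_weights: np.ndarray     # (n,)
    scalers: np.ndarray | None = None  # (T, 2): mean, sd

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_tasks(self) -> int:
        return len(self.endpoint_codes)

    def task_sizes(self) -> np.ndarray:
        return self.mask.sum(axis=0)

    def helper_flags(self) -> np.ndarray:
        return np.array([s.helper for s in self.specs], dtype=bool)

    def standardized(self, train_mask: np.ndarray | None = None) -> "AssayMatrix":
        """Return a copy with per-task zero-mean/unit-sd values.

        Scalers are fitted on the cells where both ``mask`` and
        ``train_mask`` are True (all labeled cells when no split is given)
        and applied everywhere, so held-out cells are scaled without
        influencing the fit.
        """
        fit_mask = self.mask if train_mask is None else (self.mask & train_mask)
        scalers = np.empty((self.n_tasks, 2))
        values = self.values.copy()
        for t in range(self.n_tasks):
            col = self.values[fit_mask[:, t], t]
            if col.size == 0:
                raise ValueError(f"no training labels to fit scaler for task {self.endpoint_codes[t]}")
            mean = float(col.mean())
            sd = float(col.std())
            if sd == 0.0:
                raise ValueError(f"constant training labels for task {self.endpoint_codes[t]}")
            scalers[t] = (mean, sd)
            values[:, t] = (self.values[:, t] - mean) / sd
        return replace(self, values=values, scalers=scalers)

    def destandardized(self) -> "AssayMatrix":
        """Undo :meth:`standardized` exactly."""
        if self.scalers is None:
            return self
        values = self.values * self.scalers[:, 1] + self.scalers[:, 0]
        return replace(self, values=values, scalers=None)


def build_assay_matrix(records: list[AssayRecord], specs: list[EndpointSpec],
                       canonical_tautomer: bool = True) -> tuple[AssayMatrix, list[StandardizedMolecule]]:
    """Assemble the label matrix from raw records.

    Returns the matrix (transformed scale, not yet standardized) together
    with the standardized molecule per row.  Unparseable structures and
    records whose qualifier-adjusted value is non-positive under a log
    transform are dropped and counted in the log.
    """
    spec_of = {s.code: s for s in specs}
    codes = [s.code for s in specs]
    for r in records:
        if r.endpoint_code not in spec_of:
            raise ValueError(f"record endpoint {r.endpoint_code!r} not in endpoint specs")

    structures: dict[str, StandardizedMolecule] = {}
    canonical_of: dict[str, str] = {}  # raw smiles -> canonical
    n_unparseable = 0
    for r in records:
        if r.smiles in canonical_of:
            continue
        try:
            sm = standardize_molecule(r.smiles, canonical_tautomer=canonical_tautomer)
        except MoleculeParseError:
            n_unparseable += 1
            canonical_of[r.smiles] = ""
            continue
        canonical_of[r.smiles] = sm.canonical_smiles
        structures.setdefault(sm.canonical_smiles, sm)
    if n_unparseable:
        logger.warning("dropped %d records with unparseable structures", n_unparseable)

    # group replicates per (canonical structure, endpoint)
    cells: dict[tuple[str, str], list[AssayRecord]] = {}
    first_id: dict[str, str] = {}
    order: list[str] = []
    for r in records:
        canonical = canonical_of[r.smiles]
        if not canonical:
            continue
        if canonical not in first_id:
            first_id[canonical] = r.compound_id
            order.append(canonical)
        cells.setdefault((canonical, r.endpoint_code), []).append(r)

    n, T = len(order), len(codes)
    values = np.full((n, T), np.nan)
    mask = np.zeros((n, T), dtype=bool)
    dates = np.full((n, T), np.datetime64("NaT"), dtype="datetime64[D]")
    row_of = {c: i for i, c in enumerate(order)}
    n_nonpositive = 0
    for (canonical, code), cell_records in cells.items():
        i, t = row_of[canonical], codes.index(code)
        spec = spec_of[code]
        adjusted = [apply_qualifier(r.value, r.qualifier) for r in cell_records]
        if spec.transform != "none":
            kept = [(a, r) for a, r in zip(adjusted, cell_records) if a > 0]
            n_nonpositive += len(adjusted) - len(kept)
            if not kept:
                continue
            adjusted = [a for a, _ in kept]
            cell_records = [r for _, r in kept]
        raw_mean = float(np.mean(adjusted))
        values[i, t] = to_model_scale(raw_mean, spec, structures[canonical].mol_weight)
        mask[i, t] = True
        cell_dates = [r.date for r in cell_records if r.date is not None]
        if cell_dates:
            # latest replicate date: keeps late information out of training
            dates[i, t] = max(np.datetime64(d, "D") for d in cell_dates)
    if n_nonpositive:
        logger.warning("dropped %d records non-positive under a log transform", n_nonpositive)

    # prune rows that ended up with no labels at all
    keep = mask.any(axis=1)
    order = [c for c, k in zip(order, keep) if k]
    matrix = AssayMatrix(
        compound_ids=[first_id[c] for c in order],
        smiles=list(order),
        endpoint_codes=codes,
        specs=list(specs),
        values=values[keep],
        mask=mask[keep],
        dates=dates[keep],
        mol_weights=np.array([structures[c].mol_weight for c in order]),
    )
    return matrix, [structures[c] for c in order]
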