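"""Synthetic molecules and correlated multi-endpoint assay tables.

The generator makes every pipeline stage testable without proprietary
data.  Molecules are assembled from a fragment grammar (aryl/heteroaryl/
alicyclic cores plus polar and alkyl substituents), giving valence-valid,
drug-like structures whose heavy-atom counts follow a clipped normal
distribution.

Ground-truth endpoints are linear in cheap graph descriptors, so a
closed-form oracle (linear regression on the true descriptors) bounds the
achievable accuracy of any model from above:

- ``logKow* = a1·#C − a2·#(N,O) + ε`` — lipophilicity grows with carbon
  count and falls with polar-atom count;
- ``LMP* = m0 + m1·#rings + m2·#HBdonors + ε`` (°C) — rigid, hydrogen-
  bonded crystals melt higher;
- ``logS* = −0.01(LMP*−25) − logKow* + 0.5 + ε`` — solubility lies on the
  general solubility equation surface by construction;
- membrane affinity and serum-albumin binding are noisy affine functions
  of ``logKow*``; the helper solubility assays are re-noised copies of
  ``logS*``.

This reproduces the qualitative correlation structure of a real ADMET
panel: solubility endpoints mutually correlated, logD anticorrelated with
solubility, melting point only weakly coupled to the rest.  Records are
then sparsified to unequal task sizes, replicated, qualifier-censored
(``v`` becomes ``("<", 2v)`` or ``(">", v/2)``, so the preprocessing rule
approximately recovers ``v``) and dated; the acidic logD task carries no
dates and is split randomly in time splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .endpoints import EndpointSpec, default_endpoints
from .mol import StandardizedMolecule, standardize_molecule
from .preprocess import AssayRecord, invert_model_scale

__all__ = ["GeneratorConfig", "SyntheticStudy", "generate_molecules",
           "generate_endpoints", "generate_study", "latent_descriptors",
           "descriptor_matrix"]

CORES = [
    "c1ccccc1", "c1ccncc1", "c1cncnc1", "c1ccsc1", "c1ccoc1", "c1cnc[nH]1",
    "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1", "C1CCCCC1", "C1CCCC1", "C1CCNCC1",
    "C1COCCN1", "C1CCOC1",
]
SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "F", "Cl", "Br", "O", "OC", "N", "N(C)C",
    "C(=O)O", "C(=O)N", "C#N", "C(F)(F)F", "C(C)=O", "CO", "CCO", "CN", "OCC",
]

DEFAULT_TASK_FRACTIONS = {
    "LOD": 0.75, "LOA": 0.90, "LOM": 0.40, "LOH": 0.40, "LMP": 0.50,
    "LOO": 0.45, "LOP": 0.10, "LON": 0.35, "LOX": 0.25, "LOQ": 0.30,
}

# ground-truth coefficients (model scale)
ALPHA_CARBON, ALPHA_POLAR = 0.25, 0.55
MP_BASE, MP_RING, MP_DONOR = 60.0, 22.0, 18.0
NOISE_SD = {"logKow": 0.30, "LOD": 0.25, "LOA": 0.25, "LMP": 15.0,
            "LOO": 0.30, "LOP": 0.30, "LON": 0.35, "LOX": 0.35, "LOQ": 0.35,
            "LOM": 0.30, "LOH": 0.30}
JITTER_SD = {"LMP": 2.0}  # replicate measurement jitter; 0.05 log units otherwise
DEFAULT_JITTER = 0.05


@dataclass
class GeneratorConfig:
    n_compounds: int = 2000
    task_fractions: dict = field(default_factory=lambda: dict(DEFAULT_TASK_FRACTIONS))
    noise_scale: float = 1.0          # scales every ε; 0 → exact GSE surface
    replicate_rate: float = 0.15
    qualifier_rate: float = 0.05
    date_range: tuple[str, str] = ("2010-01-01", "2016-06-30")
    independent_solubility: bool = False  # break the GSE link (null model)
    size_mean: float = 22.0
    size_sd: float = 6.0
    size_range: tuple[int, int] = (8, 40)
    seed: int = 0

    def task_sizes(self) -> dict[str, int]:
        return {code: max(2, int(round(frac * self.n_compounds)))
                for code, frac in self.task_fractions.items()}


@dataclass
class SyntheticStudy:
    smiles: list[str]
    molecules: list[StandardizedMolecule]
    records: list[AssayRecord]
    truth: pd.DataFrame     # per-compound descriptors and model-scale truths
    config: GeneratorConfig
    specs: list[EndpointSpec] = field(default_factory=default_endpoints)


def _attach(mol: Chem.RWMol, fragment: str, rng: np.random.Generator) -> Chem.RWMol | None:
    """Bond atom 0 of `fragment` to a random H-bearing atom of `mol`."""
    hosts = [a.GetIdx() for a in mol.GetAtoms()
             if a.GetTotalNumHs() > 0 and a.GetFormalCharge() == 0]
    if not hosts:
        return None
    host = int(rng.choice(hosts))
    frag = Chem.MolFromSmiles(fragment)
    combined = Chem.RWMol(Chem.CombineMols(mol, frag))
    combined.AddBond(host, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        Chem.SanitizeMol(combined)
    except Exception:
        return None
    return combined


def _generate_one(rng: np.random.Generator, target_size: int) -> str | None:
    mol = Chem.RWMol(Chem.MolFromSmiles(CORES[rng.integers(len(CORES))]))
    for _ in range(40):
        if mol.GetNumAtoms() >= target_size:
            break
        room = target_size - mol.GetNumAtoms()
        if rng.random() < 0.25 and room >= 5:
            fragment = CORES[rng.integers(len(CORES))]
        else:
            fragment = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
        grown = _attach(mol, fragment, rng)
        if grown is not None:
            mol = grown
    try:
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)
    except Exception:
        return None


def generate_molecules(n: int, seed: int = 0, size_mean: float = 22.0,
                       size_sd: float = 6.0, size_range: tuple[int, int] = (8, 40)) -> list[str]:
    """Generate ``n`` unique, valence-valid SMILES, deterministic per seed.

    Heavy-atom counts follow a normal(size_mean, size_sd) clipped to
    ``size_range`` — the unimodal, drug-like size distribution of a
    typical corporate assay collection.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: dict[str, None] = {}
    attempts = 0
    while len(seen) < n and attempts < 200 * n:
        attempts += 1
        target = int(np.clip(round(rng.normal(size_mean, size_sd)), *size_range))
        smiles = _generate_one(rng, target)
        if smiles and smiles not in seen:
            seen[smiles] = None
    if len(seen) < n:
        raise RuntimeError(f"could only generate {len(seen)} unique molecules")
    return list(seen)


def latent_descriptors(molecule: StandardizedMolecule) -> dict[str, float]:
    """The cheap graph descriptors that drive the ground-truth endpoints."""
    mol = molecule.mol
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    return {
        "n_carbon": float(symbols.count("C")),
        "n_polar": float(symbols.count("N") + symbols.count("O")),
        "n_rings": float(rdMolDescriptors.CalcNumRings(mol)),
        "n_donors": float(rdMolDescriptors.CalcNumHBD(mol)),
    }


def descriptor_matrix(molecules: list[StandardizedMolecule]) -> np.ndarray:
    """(n, 4) array of the latent descriptors, fixed column order."""
    return np.array([[d["n_carbon"], d["n_polar"], d["n_rings"], d["n_donors"]]
                     for d in map(latent_descriptors, molecules)])


def _ground_truth(molecules, cfg: GeneratorConfig, rng) -> pd.DataFrame:
    desc = descriptor_matrix(molecules)
    n = len(molecules)
    s = cfg.noise_scale

    def eps(code):
        return rng.normal(0.0, NOISE_SD[code] * s, size=n) if s > 0 else np.zeros(n)

    log_kow = ALPHA_CARBON * desc[:, 0] - ALPHA_POLAR * desc[:, 1] + eps("logKow")
    lmp = MP_BASE + MP_RING * desc[:, 2] + MP_DONOR * desc[:, 3] + eps("LMP")
    if cfg.independent_solubility:
        log_s = rng.normal(-3.0, 1.5, size=n)
    else:
        log_s = -0.01 * (lmp - 25.0) - log_kow + 0.5 + eps("LOO")
    truth = pd.DataFrame(desc, columns=["n_carbon", "n_polar", "n_rings", "n_donors"])
    truth["logKow"] = log_kow
    truth["LOD"] = log_kow - 0.3 + eps("LOD")
    truth["LOA"] = log_kow - 1.2 + eps("LOA")
    truth["LMP"] = lmp
    truth["LOO"] = log_s
    truth["LOP"] = log_s + eps("LOP")
    truth["LON"] = log_s + eps("LON")
    truth["LOX"] = log_s + eps("LOX")
    truth["LOQ"] = log_s + eps("LOQ")
    truth["LOM"] = 0.7 * log_kow + 1.0 + eps("LOM")
    truth["LOH"] = 0.5 * log_kow + 0.8 + eps("LOH")
    return truth


def generate_endpoints(molecules: list[StandardizedMolecule], cfg: GeneratorConfig,
                       specs: list[EndpointSpec] | None = None,
                       truth: pd.DataFrame | None = None,
                       rng: np.random.Generator | None = None) -> tuple[list[AssayRecord], pd.DataFrame]:
    """Emit sparse, replicated, qualifier-censored, dated assay records."""
    specs = specs or default_endpoints()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    if truth is None:
        truth = _ground_truth(molecules, cfg, rng)
    sizes = cfg.task_sizes()
    start = np.datetime64(cfg.date_range[0], "D")
    n_days = int((np.datetime64(cfg.date_range[1], "D") - start).astype(int))
    records: list[AssayRecord] = []
    n = len(molecules)
    for spec in specs:
        size = min(sizes.get(spec.code, 0), n)
        if size == 0:
            continue
        chosen = rng.choice(n, size=size, replace=False)
        jitter_sd = JITTER_SD.get(spec.code, DEFAULT_JITTER)
        for i in chosen:
            molecule = molecules[i]
            model_value = float(truth.loc[i, spec.code])
            n_reps = 2 if rng.random() < cfg.replicate_rate else 1
            for _ in range(n_reps):
                jittered = model_value + rng.normal(0.0, jitter_sd) * cfg.noise_scale
                raw = invert_model_scale(jittered, spec, None, molecule.mol_weight)
                qualifier = "eq"
                if rng.random() < cfg.qualifier_rate:
                    if rng.random() < 0.5:
                        qualifier, raw = "lt", 2.0 * raw
                    else:
                        qualifier, raw = "gt", raw / 2.0
                date = None
                if spec.code != "LOA":  # acidic logD carries no dates
                    date = start + rng.integers(0, n_days + 1)
                records.append(AssayRecord(
                    compound_id=f"CPD-{i:05d}", smiles=molecule.canonical_smiles,
                    endpoint_code=spec.code, value=raw, qualifier=qualifier, date=date))
    return records, truth


def generate_study(cfg: GeneratorConfig | None = None) -> SyntheticStudy:
    """Full miniature study: molecules, ground truth and assay records."""
    cfg = cfg or GeneratorConfig()
    smiles = generate_molecules(cfg.n_compounds, seed=cfg.seed, size_mean=cfg.size_mean,
                                size_sd=cfg.size_sd, size_range=cfg.size_range)
    molecules = [standardize_molecule(s, canonical_tautomer=False) for s in smiles]
    records, truth = generate_endpoints(molecules, cfg)
    return SyntheticStudy(smiles=[m.canonical_smiles for m in molecules],
                          molecules=molecules, records=records, truth=truth,
                          config=cfg)
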