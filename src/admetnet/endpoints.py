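"""Endpoint (task) specifications.

Each assay endpoint carries a code, the transform taking raw assay units
onto the modelling scale, and a flag marking *helper* tasks — endpoints
trained jointly only to support related tasks, whose own accuracy is not a
deliverable.  The default study mirrors a ten-endpoint physico-chemical
ADMET panel: two logD assays, melting point, membrane affinity, human serum
albumin binding, and five solubility assays of which three are helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

TRANSFORMS = ("none", "log10", "log10_molar")


@dataclass(frozen=True)
class EndpointSpec:
    """One assay endpoint and how its raw values map to the model scale."""

    code: str
    transform: str = "none"
    helper: bool = False
    display_name: str = ""

    def __post_init__(self):
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r} for endpoint {self.code}")


def default_endpoints() -> list[EndpointSpec]:
    """The ten-endpoint ADMET panel used throughout the synthetic study.

    Solubility assays are recorded in mg/L and modelled as log10(mol/L);
    membrane affinity and serum albumin binding are log10-transformed;
    logD and melting point are taken as reported.
    """
    return [
        EndpointSpec("LOD", "none", False, "logD (pH 7.5)"),
        EndpointSpec("LOA", "none", False, "logD (pH 2.3)"),
        EndpointSpec("LOM", "log10", False, "Membrane affinity"),
        EndpointSpec("LOH", "log10", False, "Human serum albumin binding"),
        EndpointSpec("LMP", "none", False, "Melting point"),
        EndpointSpec("LOO", "log10_molar", False, "Solubility (DMSO)"),
        EndpointSpec("LOP", "log10_molar", False, "Solubility (powder)"),
        EndpointSpec("LON", "log10_molar", True, "Solubility (nephelometry)"),
        EndpointSpec("LOX", "log10_molar", True, "Solubility (DMSO, not fully dissolved)"),
        EndpointSpec("LOQ", "log10_molar", True, "Solubility (no assay annotation)"),
    ]


def load_endpoints(path) -> list[EndpointSpec]:
    """Read endpoint specs from a YAML file (list of mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = [EndpointSpec(code=e["code"], transform=e.get("transform", "none"),
                          helper=bool(e.get("helper", False)),
                          display_name=e.get("display_name", "")) for e in raw]
    codes = [s.code for s in specs]
    if len(set(codes)) != len(codes):
        raise ValueError("endpoint codes must be unique")
    return specs


def save_endpoints(specs, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([{"code": s.code, "transform": s.transform, "helper": s.helper,
                         "display_name": s.display_name} for s in specs], fh, sort_keys=False)
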