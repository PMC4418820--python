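"""Run configuration: YAML parsing, validation, bundled reference parameter sets."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .microdose import VesselArchitecture
from .model import SimulationGrid
from .pk import BiexponentialParams, DoseSpec, DrugProperties

__all__ = ["ConfigError", "RunConfig", "load_config", "reference_config", "REFERENCE_CONFIGS"]

# bundled parameter sets reproducing the clinical-trial disposition fits
REFERENCE_CONFIGS = {
    "doxil": "doxil_table1.yaml",
    "doxorubicin": "doxorubicin_table1.yaml",
}


class ConfigError(ValueError):
    """Invalid or incomplete run configuration; the message names the key."""


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a CLI run."""

    drug: DrugProperties
    dose: DoseSpec
    pk: Optional[BiexponentialParams] = None
    pk_data: Optional[Path] = None
    epr_ratios: tuple = (0.0, 1e-1, 1e-2, 1e-3, 1e-4)
    back_ratios: tuple = (0.0,)
    grid: SimulationGrid = SimulationGrid(t_end=240.0)
    architecture: VesselArchitecture = VesselArchitecture()
    id_denominator: Optional[float] = None  # default: initial blood amount A+B
    output_dir: Optional[Path] = None

    def __post_init__(self):
        if (self.pk is None) == (self.pk_data is None):
            raise ConfigError("exactly one of 'pk' parameters or 'pk_data' path must be provided")
        if self.pk_data is not None and not Path(self.pk_data).exists():
            raise ConfigError(f"pk_data path does not exist: {self.pk_data}")


def _get(block: dict, key: str, context: str):
    if key not in block:
        raise ConfigError(f"missing config key: {context}.{key}")
    return block[key]


def config_from_dict(raw: dict) -> RunConfig:
    """Build a RunConfig from a nested mapping (see bundled YAML for the schema)."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    try:
        drug_block = raw.get("drug") or {}
        drug = DrugProperties(
            name=drug_block.get("name", "drug"),
            molar_mass=float(drug_block.get("molar_mass_g_per_mol", 543.52)),
            payload_per_carrier=int(drug_block.get("payload_per_carrier", 1)),
        )

        pk = None
        if "pk" in raw and raw["pk"] is not None:
            pk_block = raw["pk"]
            pk = BiexponentialParams(
                A=float(_get(pk_block, "A_mg", "pk")),
                B=float(_get(pk_block, "B_mg", "pk")),
                alpha=float(_get(pk_block, "alpha_per_h", "pk")),
                beta=float(_get(pk_block, "beta_per_h", "pk")),
            )
        pk_data = Path(raw["pk_data"]) if raw.get("pk_data") else None

        dose_block = raw.get("dose") or {}
        dose = DoseSpec(
            dose_per_area=float(dose_block.get("mg_per_m2", 50.0)),
            body_surface_area=float(dose_block.get("bsa_m2", 1.8)),
            blood_volume=float(dose_block.get("blood_volume_L", 5.0)),
        )

        model_block = raw.get("model") or {}
        grid = SimulationGrid(
            t_end=float(model_block.get("t_end_h", 240.0)),
            n_points=int(model_block.get("n_points", 400)),
            spacing=str(model_block.get("spacing", "geometric")),
            t_min_geometric=float(model_block.get("t_min_h", 1e-3)),
        )
        epr_ratios = tuple(float(r) for r in model_block.get("epr_ratios", (0.0, 1e-1, 1e-2, 1e-3, 1e-4)))
        back_ratios = tuple(float(r) for r in model_block.get("back_ratios", (0.0,)))

        arch_block = raw.get("architecture") or {}
        arch = VesselArchitecture(
            tumor_volume=float(arch_block.get("tumor_volume_cm3", 1.0)),
            vessel_length_density=float(arch_block.get("vessel_length_density_mm_per_mm3", 150.0)),
            segment_length=float(arch_block.get("segment_length_um", 100.0)),
            vessel_diameter=float(arch_block.get("vessel_diameter_um", 30.0)),
        )

        out_block = raw.get("output") or {}
        output_dir = Path(out_block["directory"]) if out_block.get("directory") else None

        id_den = raw.get("id_denominator_mg")
        return RunConfig(
            drug=drug,
            dose=dose,
            pk=pk,
            pk_data=pk_data,
            epr_ratios=epr_ratios,
            back_ratios=back_ratios,
            grid=grid,
            architecture=arch,
            id_denominator=float(id_den) if id_den is not None else None,
            output_dir=output_dir,
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    return config_from_dict(raw or {})


def reference_config(name: str) -> RunConfig:
    """Load one of the bundled reference configurations ('doxil', 'doxorubicin')."""
    key = name.lower()
    if key not in REFERENCE_CONFIGS:
        raise ConfigError(
            f"unknown reference drug {name!r}; available: {sorted(REFERENCE_CONFIGS)}"
        )
    text = resources.files("eprkit").joinpath("configs", REFERENCE_CONFIGS[key]).read_text()
    return config_from_dict(yaml.safe_load(text))
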