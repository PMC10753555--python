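"""Packaged fixture registry and typed loaders.

Each fixture is a small plain-text transcription of a published
experimental record (provenance noted in the file's comment header); the
registry exposes paths, provenance one-liners and content checksums so
reports can pin exactly which inputs they consumed.
"""

from __future__ import annotations

from importlib.resources import as_file, files
from pathlib import Path

import yaml

from .combustion import CombustionExperiment, MolecularFormula
from .crystal_model import CoumarinDescriptor
from .enthalpy_chain import FusionRecord
from .group_additivity import CoefficientTable
from .homodesmic import Reaction, Species
from .io import file_checksum, read_table

__all__ = [
    "REGISTRY",
    "fixture_path",
    "fixture_checksums",
    "load_physical_properties",
    "load_combustion_runs",
    "load_fusion_records",
    "load_tga_table",
    "load_benson_table",
    "load_species",
    "load_crystal_descriptors",
    "load_chain_config",
    "load_reference_chain",
    "load_reaction",
]

#: fixture name -> (file name, provenance one-liner)
REGISTRY: dict[str, tuple[str, str]] = {
    "physical_properties": (
        "physical_properties.csv",
        "physical properties of sample, calibrant and fuse",
    ),
    "combustion_runs": (
        "combustion_runs.csv",
        "published bomb-combustion record (one full run of six)",
    ),
    "dsc_fusion": ("dsc_fusion.csv", "DSC fusion replicates"),
    "tga_series": ("tga_series.csv", "isothermal TGA mass-loss series"),
    "benson_coefficients": (
        "benson_coefficients.csv",
        "updated Benson group coefficient table",
    ),
    "homodesmic_species": (
        "homodesmic_species.csv",
        "literature/predicted gas-phase formation enthalpies",
    ),
    "coumarin_crystal": (
        "coumarin_crystal.csv",
        "crystalline coumarin targets with authored descriptors",
    ),
    "chain_config": ("chain_config.yaml", "scalar chain inputs and uncertainties"),
    "reference_chain": (
        "reference_chain.csv",
        "published chain values at printed precision",
    ),
    "reaction_demo": ("reaction_demo.yaml", "demonstration exchange reaction"),
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture (fixtures ship as real files)."""
    if name not in REGISTRY:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(REGISTRY)}")
    resource = files("thermoforge") / "data" / REGISTRY[name][0]
    with as_file(resource) as p:
        return Path(p)


def fixture_checksums() -> dict[str, str]:
    return {name: file_checksum(fixture_path(name)) for name in REGISTRY}


def load_physical_properties():
    return read_table(fixture_path("physical_properties")).set_index("compound")


def load_combustion_runs() -> list[CombustionExperiment]:
    df = read_table(fixture_path("combustion_runs"))
    return [
        CombustionExperiment(
            sample_mass=row.sample_mass_g,
            fuse_mass=row.fuse_mass_g,
            platinum_mass=row.platinum_mass_g,
            delta_Tc=row.delta_Tc_K,
            calor_equiv=row.calor_equiv_J_K,
            cont_term=row.cont_term_kJ,
            ignition_energy=row.ignition_energy_kJ,
            standard_state_correction=row.standard_state_correction_kJ,
            fuse_massic_energy=row.fuse_massic_energy_kJ_g,
        )
        for row in df.itertuples()
    ]


def load_fusion_records() -> list[FusionRecord]:
    df = read_table(fixture_path("dsc_fusion"))
    return [
        FusionRecord(
            purity=row.purity,
            melting_temperature=row.melting_temperature_K,
            fusion_enthalpy=row.fusion_enthalpy_kJ_mol,
        )
        for row in df.itertuples()
    ]


def load_tga_table():
    """TGA series as a DataFrame including the tabulated regression columns."""
    return read_table(fixture_path("tga_series"))


def load_benson_table() -> CoefficientTable:
    return CoefficientTable.from_csv(fixture_path("benson_coefficients"))


def load_species(
    value_column: str = "dfH_pred_kJ_mol", unknown: str | None = None
) -> dict[str, Species]:
    """Homodesmic species keyed by id.

    ``value_column`` selects experimental or predicted enthalpies;
    ``unknown`` marks one species' enthalpy as unknown (the solve target).
    """
    df = read_table(fixture_path("homodesmic_species"))
    out: dict[str, Species] = {}
    for row in df.itertuples():
        sid = row.species_id
        value = None if sid == unknown else float(getattr(row, value_column))
        out[sid] = Species(
            id=sid, formula=MolecularFormula.parse(row.formula), formation_enthalpy=value
        )
    return out


def load_crystal_descriptors() -> list[CoumarinDescriptor]:
    df = read_table(fixture_path("coumarin_crystal"))
    return [
        CoumarinDescriptor(
            compound_id=row.compound_id,
            h_count=int(row.h_count),
            o_count=int(row.o_count),
            radical_1=row.radical_1,
            radical_2=row.radical_2,
            target=row.target_minus_dfH_cr,
        )
        for row in df.itertuples()
    ]


def load_chain_config() -> dict:
    with open(fixture_path("chain_config"), encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_reference_chain():
    return read_table(fixture_path("reference_chain")).set_index("quantity")


def load_reaction(path: str | Path | None = None) -> tuple[Reaction, str]:
    """Read a reaction config; returns the reaction and the enthalpy column
    it asks to be resolved against (experimental or predicted)."""
    path = fixture_path("reaction_demo") if path is None else Path(path)
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    reaction = Reaction(
        stoichiometry={k: float(v) for k, v in cfg["stoichiometry"].items()},
        target=cfg["target"],
    )
    return reaction, cfg.get("enthalpy_column", "dfH_exp_kJ_mol")
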