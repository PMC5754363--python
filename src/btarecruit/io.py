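"""Run configuration, tabular I/O, and provenance records.

A run configuration is a YAML (or JSON — valid YAML) mapping that parses
into the validated domain objects of the other modules.  Concentrations may
be given either as plain numbers (interpreted as mol/L) or as strings with
an explicit unit (``"0.5 uM"``, ``"20 nM"``, ``"1.5e-6 M"``); unit-less
strings are rejected.  Unknown keys are rejected with a message naming the
offending key, and every default that is filled in is logged.

CSV schemas (column names and units) used throughout the package:

* titration: ``inhibitor_conc_M, activity, sd, n``
* trace:     ``time_s, fluorescence_au`` (long format adds ``condition``)
* exchange:  ``time_h, activity`` (optional ``sd, n``)

Extra columns are preserved on read.  Alongside every CLI output a
provenance JSON (config hash, seed, package version, defaults applied) is
written so runs are reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .geometry import (
    DEFAULT_AXIAL_RISE_NM,
    DEFAULT_RADIUS_NM,
    AssemblyComposition,
    FiberModel,
)
from .hybridization import DEFAULT_DUPLEX_KD, RecruitedSpecies
from .kinetics import EnzymeKinetics
from .recruitment import DEFAULT_KI_SOLUTION, InhibitionModel
from .synth import NoiseModel

logger = logging.getLogger("btarecruit")

_UNIT_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # µM
    "nM": 1e-9,
    "pM": 1e-12,
}
_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([munµp]?M)\s*$")

SCHEMAS: dict[str, list[str]] = {
    "titration": ["inhibitor_conc_M", "activity", "sd", "n"],
    "trace": ["time_s", "fluorescence_au"],
    "exchange": ["time_h", "activity"],
}


def parse_concentration(value: Any, key: str = "concentration") -> float:
    """Normalize a concentration to mol/L.

    Accepts a number (already molar) or a string with an explicit unit.
    """
    if isinstance(value, bool):
        raise ConfigError(f"{key}: expected a concentration, got a boolean")
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        # YAML leaves exponents like "5e-7" (no decimal point) as strings;
        # bare numerics are molar, anything else needs a recognised unit
        try:
            return float(value)
        except ValueError:
            pass
        m = _QUANTITY_RE.match(value)
        if not m:
            raise ConfigError(
                f"{key}: could not parse {value!r}; string concentrations "
                "need an explicit unit (M, mM, uM, nM, pM)"
            )
        return float(m.group(1)) * _UNIT_FACTORS[m.group(2)]
    raise ConfigError(f"{key}: expected number or unit string, got {type(value).__name__}")


@dataclass
class RunConfig:
    """Fully validated configuration of one modelling run."""

    fiber: FiberModel
    composition: AssemblyComposition
    species: list[RecruitedSpecies]
    inhibition: InhibitionModel
    kinetics: EnzymeKinetics
    noise: NoiseModel
    seed: int = 0
    apply_occupancy_to_inhibitor: bool = True
    grids: dict[str, list[float]] = field(default_factory=dict)
    displacement_steps: list[tuple[str, float]] = field(default_factory=list)
    defaults_used: list[str] = field(default_factory=list)

    def species_by_name(self, name: str) -> RecruitedSpecies:
        for s in self.species:
            if s.name == name:
                return s
        raise ConfigError(f"no species named {name!r} in the configuration")


def _check_keys(section: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {where}: {', '.join(sorted(unknown))}"
        )


def _get_default(section: Mapping[str, Any], key: str, default: Any,
                 defaults_used: list[str], where: str) -> Any:
    if key in section:
        return section[key]
    defaults_used.append(f"{where}.{key}={default}")
    logger.info("config default applied: %s.%s = %r", where, key, default)
    return default


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Defaults (radius 15 nm, axial rise 0.452 nm, duplex K_d 0.162 uM,
    K_i 1.5 uM, noise model, kinetics constants) are filled for missing
    keys and recorded in ``defaults_used``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping at the top level")
    _check_keys(
        raw,
        {
            "fiber",
            "composition",
            "species",
            "inhibition",
            "kinetics",
            "noise",
            "seed",
            "apply_occupancy_to_inhibitor",
            "grids",
            "displacement_steps",
        },
        "top level",
    )
    used: list[str] = []

    fib = raw.get("fiber", {}) or {}
    _check_keys(fib, {"radius_nm", "axial_rise_nm"}, "fiber")
    fiber = FiberModel(
        radius_nm=float(_get_default(fib, "radius_nm", DEFAULT_RADIUS_NM, used, "fiber")),
        axial_rise_nm=float(
            _get_default(fib, "axial_rise_nm", DEFAULT_AXIAL_RISE_NM, used, "fiber")
        ),
    )

    if "composition" not in raw:
        raise ConfigError("missing required section: composition")
    comp = raw["composition"]
    _check_keys(comp, {"conc_btadna", "conc_bta3oh"}, "composition")
    if "conc_btadna" not in comp:
        raise ConfigError("composition: missing required key conc_btadna")
    composition = AssemblyComposition(
        conc_btadna=parse_concentration(comp["conc_btadna"], "composition.conc_btadna"),
        conc_bta3oh=parse_concentration(
            _get_default(comp, "conc_bta3oh", 0.0, used, "composition"),
            "composition.conc_bta3oh",
        ),
    )

    species: list[RecruitedSpecies] = []
    for i, sp in enumerate(raw.get("species", []) or []):
        where = f"species[{i}]"
        _check_keys(
            sp,
            {"name", "recruiter_total", "protein_total", "duplex_kd", "has_toehold"},
            where,
        )
        if "name" not in sp:
            raise ConfigError(f"{where}: missing required key name")
        species.append(
            RecruitedSpecies(
                name=str(sp["name"]),
                recruiter_total=parse_concentration(
                    _get_default(sp, "recruiter_total", 0.0, used, where),
                    f"{where}.recruiter_total",
                ),
                protein_total=parse_concentration(
                    _get_default(sp, "protein_total", 0.0, used, where),
                    f"{where}.protein_total",
                ),
                duplex_kd=parse_concentration(
                    _get_default(sp, "duplex_kd", DEFAULT_DUPLEX_KD, used, where),
                    f"{where}.duplex_kd",
                ),
                has_toehold=bool(_get_default(sp, "has_toehold", False, used, where)),
            )
        )

    inh = raw.get("inhibition", {}) or {}
    _check_keys(inh, {"ki_solution"}, "inhibition")
    inhibition = InhibitionModel(
        ki_solution=parse_concentration(
            _get_default(inh, "ki_solution", DEFAULT_KI_SOLUTION, used, "inhibition"),
            "inhibition.ki_solution",
        )
    )

    kin = raw.get("kinetics", {}) or {}
    _check_keys(
        kin,
        {"kcat_over_km", "substrate_conc", "fluorescence_per_product", "duplex_koff"},
        "kinetics",
    )
    kin_defaults = EnzymeKinetics()
    kinetics = EnzymeKinetics(
        kcat_over_km=float(
            _get_default(kin, "kcat_over_km", kin_defaults.kcat_over_km, used, "kinetics")
        ),
        substrate_conc=parse_concentration(
            _get_default(
                kin, "substrate_conc", kin_defaults.substrate_conc, used, "kinetics"
            ),
            "kinetics.substrate_conc",
        ),
        fluorescence_per_product=float(
            _get_default(
                kin,
                "fluorescence_per_product",
                kin_defaults.fluorescence_per_product,
                used,
                "kinetics",
            )
        ),
        duplex_koff=float(
            _get_default(kin, "duplex_koff", kin_defaults.duplex_koff, used, "kinetics")
        ),
    )

    noi = raw.get("noise", {}) or {}
    _check_keys(noi, {"sd_activity", "sd_fluorescence", "n_replicates", "seed"}, "noise")
    seed = int(raw.get("seed", 0))
    noise = NoiseModel(
        sd_activity=float(_get_default(noi, "sd_activity", 0.03, used, "noise")),
        sd_fluorescence=float(_get_default(noi, "sd_fluorescence", 0.0, used, "noise")),
        n_replicates=int(_get_default(noi, "n_replicates", 3, used, "noise")),
        seed=int(noi.get("seed", seed)),
    )

    grids_raw = raw.get("grids", {}) or {}
    _check_keys(
        grids_raw, {"inhibitor_concs", "densities", "time_grid_h"}, "grids"
    )
    grids: dict[str, list[float]] = {}
    if "inhibitor_concs" in grids_raw:
        grids["inhibitor_concs"] = [
            parse_concentration(v, "grids.inhibitor_concs") for v in grids_raw["inhibitor_concs"]
        ]
    if "densities" in grids_raw:
        grids["densities"] = [float(v) for v in grids_raw["densities"]]
    if "time_grid_h" in grids_raw:
        grids["time_grid_h"] = [float(v) for v in grids_raw["time_grid_h"]]

    steps: list[tuple[str, float]] = []
    for j, step in enumerate(raw.get("displacement_steps", []) or []):
        if not (isinstance(step, (list, tuple)) and len(step) == 2):
            raise ConfigError(
                f"displacement_steps[{j}]: expected [strand, amount] pairs"
            )
        steps.append(
            (str(step[0]), parse_concentration(step[1], f"displacement_steps[{j}]"))
        )

    return RunConfig(
        fiber=fiber,
        composition=composition,
        species=species,
        inhibition=inhibition,
        kinetics=kinetics,
        noise=noise,
        seed=seed,
        apply_occupancy_to_inhibitor=bool(
            raw.get("apply_occupancy_to_inhibitor", True)
        ),
        grids=grids,
        displacement_steps=steps,
        defaults_used=used,
    )


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a CSV against a named schema, with row-indexed numeric errors."""
    if schema not in SCHEMAS:
        raise ConfigError(f"unknown table schema {schema!r}")
    frame = pd.read_csv(path)
    required = SCHEMAS[schema]
    for col in required:
        if col not in frame.columns:
            if schema == "titration" and col in ("sd", "n"):
                continue  # optional for externally supplied titrations
            raise ConfigError(f"{path}: missing required column {col!r}")
    for col in required:
        if col not in frame.columns:
            continue
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ConfigError(
                f"{path}: malformed numeric value in column {col!r}, row {row}: "
                f"{frame[col][row]!r}"
            )
        frame[col] = converted
    return frame


def write_table(frame: pd.DataFrame, path: str | Path, schema: str | None = None) -> None:
    """Write a CSV, checking required schema columns are present."""
    if schema is not None:
        for col in SCHEMAS[schema]:
            if col not in frame.columns and not (
                schema == "titration" and col in ("sd", "n")
            ):
                raise ConfigError(f"cannot write {schema} table: missing column {col!r}")
    frame.to_csv(path, index=False)


def config_hash(path: str | Path) -> str:
    """SHA-256 of the raw configuration file contents."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_provenance(
    out_path: str | Path,
    *,
    seed: int | None = None,
    config: str | Path | None = None,
    defaults_used: Sequence[str] = (),
    extra: Mapping[str, Any] | None = None,
) -> Path:
    """Write a provenance JSON sidecar next to an output file."""
    record: dict[str, Any] = {
        "btarecruit_version": __version__,
        "seed": seed,
        "config_sha256": config_hash(config) if config is not None else None,
        "defaults_used": list(defaults_used),
    }
    if extra:
        record.update(extra)
    sidecar = Path(str(out_path) + ".provenance.json")
    sidecar.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return sidecar
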