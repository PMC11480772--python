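"""File formats, packaged reference tables, configuration and pipeline.

Formats: PDB v3.3 ATOM/HETATM records (fixed columns, element from
columns 77-78 with a name-based fallback, formal charge from columns
79-80 — the toy bead models carry integer bead charges there),
multi-frame XYZ, two-column window sample series, TSV profiles, JSON
ledgers/fits, and an HDF5 container for umbrella window sets.

The packaged reference tables (free-energy contributions per water model
and salt concentration, and the unrestrained-separation totals) are
shipped as CSV exactly as printed, parenthetical errors included, and
are parsed into :class:`~bindfe.restraint_fe.FreeEnergyLedger` or
:class:`~bindfe.transitions.SaltSeries` objects.
"""

from __future__ import annotations

import json
import re
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .core import (BiasPotential, Topology, Trajectory, UmbrellaWindow,
                   UmbrellaWindowSet, element_from_name, _ELEMENT_MASSES)
from .estimators import PmfProfile
from .restraint_fe import FreeEnergyLedger, LEDGER_TERMS
from .transitions import FitResult, SaltSeries

__all__ = [
    "PdbParseError",
    "read_pdb",
    "write_pdb",
    "read_xyz",
    "write_xyz",
    "read_window_series",
    "write_window_series",
    "read_pmf_tsv",
    "write_pmf_tsv",
    "write_ledger_json",
    "read_ledger_json",
    "write_windows_h5",
    "read_windows_h5",
    "load_contribution_table",
    "load_separation_table",
    "ledger_from_table",
    "salt_series_from_table",
    "PipelineConfig",
    "run_pipeline",
]


class PdbParseError(ValueError):
    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(f"line {line_number}: {message}" if line_number else message)
        self.line_number = line_number


def read_pdb(path) -> tuple[Topology, np.ndarray]:
    """Parse ATOM/HETATM records of a PDB file into a topology + frame."""
    atoms = []
    coords = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line.rstrip("\n")) < 54:
            raise PdbParseError("record shorter than coordinate columns", lineno)
        try:
            name = line[12:16].strip()
            resname = line[17:20].strip() or "UNK"
            chain = line[21].strip() or "A"
            resseq = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PdbParseError(f"malformed ATOM record ({exc})", lineno) from None
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = element_from_name(name)
        element = element.capitalize()
        charge_field = line[78:80].strip() if len(line) >= 80 else ""
        charge = 0.0
        if charge_field:
            m = re.fullmatch(r"(\d+)([+-])", charge_field)
            if not m:
                raise PdbParseError(f"malformed charge field {charge_field!r}", lineno)
            charge = float(m.group(1)) * (1.0 if m.group(2) == "+" else -1.0)
        mass = _ELEMENT_MASSES.get(element, 12.0)
        atoms.append(dict(name=name, residue_index=resseq, residue_name=resname,
                          chain_id=chain, mass=mass, charge=charge,
                          is_hydrogen=element == "H"))
        coords.append((x, y, z))
    if not atoms:
        raise PdbParseError(f"no ATOM/HETATM records found in {path}")
    return Topology.from_atoms(atoms), np.array(coords)


def write_pdb(path, topology: Topology, frame: np.ndarray) -> None:
    """Write one frame as fixed-column ATOM records (with formal charges)."""
    frame = np.asarray(frame, float)
    with open(path, "w") as fh:
        for i in range(topology.n_atoms):
            q = topology.charge[i]
            qfield = ""
            if q != 0 and float(q).is_integer():
                qfield = f"{abs(int(q))}{'+' if q > 0 else '-'}"
            element = element_from_name(str(topology.names[i]))
            name = str(topology.names[i])
            name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
            fh.write(
                f"ATOM  {i + 1:5d} {name_field}"
                f" {str(topology.residue_name[i])[:3]:>3s} {str(topology.chain_id[i])[:1]}"
                f"{int(topology.residue_index[i]) % 10000:4d}    "
                f"{frame[i, 0]:8.3f}{frame[i, 1]:8.3f}{frame[i, 2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          "
                f"{element:>2s}{qfield:<2s}\n")
        fh.write("END\n")


def write_xyz(path, traj: Trajectory) -> None:
    """Multi-frame XYZ: per frame an atom-count header, comment, and rows."""
    with open(path, "w") as fh:
        for t in range(traj.n_frames):
            fh.write(f"{traj.topology.n_atoms}\n")
            fh.write(f"frame {t} time {traj.frame_times[t]}\n")
            for i in range(traj.topology.n_atoms):
                el = element_from_name(str(traj.topology.names[i]))
                x, y, z = traj.frames[t, i]
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path, topology: Topology | None = None) -> Trajectory | tuple[list, np.ndarray]:
    """Read a multi-frame XYZ file.

    With a topology, returns a :class:`Trajectory`; without, returns
    (elements, frames array).
    """
    frames = []
    elements = None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        rows = lines[i + 2:i + 2 + n]
        if len(rows) < n:
            raise ValueError("truncated XYZ frame")
        els = []
        coords = np.empty((n, 3))
        for j, row in enumerate(rows):
            parts = row.split()
            els.append(parts[0])
            coords[j] = [float(v) for v in parts[1:4]]
        if elements is None:
            elements = els
        frames.append(coords)
        i += 2 + n
    frames = np.array(frames)
    if topology is not None:
        return Trajectory(topology, frames)
    return elements, frames


def write_window_series(path, times: np.ndarray, values: np.ndarray) -> None:
    np.savetxt(path, np.column_stack([times, values]), fmt="%.8g")


def read_window_series(path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[None, :]
    return data[:, 0], data[:, 1]


def write_pmf_tsv(path, pmf: PmfProfile) -> None:
    header = f"bin_center\tfree_energy\tstderr\t# T={pmf.temperature} K"
    np.savetxt(path, np.column_stack([pmf.bin_centers, pmf.free_energy, pmf.stderr]),
               fmt="%.8g", delimiter="\t", header=header)


def read_pmf_tsv(path, temperature: float = 300.0) -> PmfProfile:
    with open(path) as fh:
        first = fh.readline()
    m = re.search(r"T=([0-9.]+)", first)
    if m:
        temperature = float(m.group(1))
    data = np.loadtxt(path, delimiter="\t")
    return PmfProfile(data[:, 0], data[:, 1], data[:, 2], temperature)


def write_ledger_json(path, ledger: FreeEnergyLedger) -> None:
    payload = {
        "temperature": ledger.temperature,
        "salt_mM": ledger.salt_mM,
        "water_model": ledger.water_model,
        "terms": {k: {"value": v, "stderr": e} for k, (v, e) in ledger.terms.items()},
        "tool_version": __version__,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ledger_json(path) -> FreeEnergyLedger:
    payload = json.loads(Path(path).read_text())
    ledger = FreeEnergyLedger(
        temperature=payload.get("temperature", 300.0),
        salt_mM=payload.get("salt_mM"),
        water_model=payload.get("water_model"))
    for name, rec in payload["terms"].items():
        ledger.set_term(name, rec["value"], rec.get("stderr", 0.0))
    return ledger


def write_windows_h5(path, windows: UmbrellaWindowSet) -> None:
    import h5py
    with h5py.File(path, "w") as h5:
        h5.attrs["reaction_coordinate_id"] = windows.reaction_coordinate_id
        h5.attrs["temperature"] = windows.temperature
        for i, w in enumerate(windows.windows):
            g = h5.create_group(f"window_{i:03d}")
            g.create_dataset("samples", data=w.samples)
            g.attrs["center"] = w.bias.center
            g.attrs["force_constant"] = w.bias.force_constant
            g.attrs["convention"] = w.bias.convention
            g.attrs["kind"] = w.bias.kind
            if w.seed is not None:
                g.attrs["seed"] = w.seed


def read_windows_h5(path) -> UmbrellaWindowSet:
    import h5py
    windows = []
    with h5py.File(path, "r") as h5:
        rcid = h5.attrs["reaction_coordinate_id"]
        temp = float(h5.attrs["temperature"])
        for key in sorted(k for k in h5.keys() if k.startswith("window_")):
            g = h5[key]
            bias = BiasPotential(str(g.attrs["kind"]), float(g.attrs["center"]),
                                 float(g.attrs["force_constant"]),
                                 str(g.attrs["convention"]))
            seed = int(g.attrs["seed"]) if "seed" in g.attrs else None
            windows.append(UmbrellaWindow(bias, g["samples"][...], temp, seed))
    return UmbrellaWindowSet(str(rcid), windows)


# ---------------------------------------------------------------------------
# packaged reference tables

_PAREN = re.compile(r"^(-?\d+\.?\d*)(?:\((\d+)\))?$")
_PLUSMINUS = re.compile(r"^(-?\d+\.?\d*)\s*±\s*(\d+\.?\d*)$")


def parse_printed_value(text: str) -> tuple[float, float]:
    """Parse '−7.61(2)' or '−20.0 ± 1.4' into (value, stderr).

    A parenthetical error applies to the last printed digit: 13.1(1)
    means 13.1 ± 0.1 and -7.61(2) means -7.61 ± 0.02.
    """
    text = text.strip().replace("−", "-")
    m = _PLUSMINUS.match(text)
    if m:
        return float(m.group(1)), float(m.group(2))
    m = _PAREN.match(text)
    if not m:
        raise ValueError(f"cannot parse printed value {text!r}")
    value = float(m.group(1))
    if m.group(2) is None:
        return value, 0.0
    digits = m.group(1).split(".")[1] if "." in m.group(1) else ""
    ulp = 10.0 ** (-len(digits))
    return value, float(m.group(2)) * ulp


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("bindfe.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh)
    parsed = df["printed"].map(parse_printed_value)
    df["value"] = [p[0] for p in parsed]
    df["stderr"] = [p[1] for p in parsed]
    return df


def load_contribution_table() -> pd.DataFrame:
    """Restraint-route free-energy contributions per condition (kcal/mol)."""
    return _load_table("contributions.csv")


def load_separation_table() -> pd.DataFrame:
    """Unrestrained-separation binding free energies per condition."""
    return _load_table("separation_totals.csv")


def ledger_from_table(water_model: str, salt_mM: float) -> FreeEnergyLedger:
    """Build a ledger from one column of the packaged contribution table.

    Printed site rows carry the assembly's minus sign; they are stored as
    magnitudes because the assembler re-applies signs.
    """
    df = load_contribution_table()
    sub = df[(df.water_model == water_model) & (df.salt_mM == salt_mM)]
    if sub.empty:
        raise KeyError(f"no column for {water_model} / {salt_mM} mM")
    ledger = FreeEnergyLedger(temperature=300.0, salt_mM=salt_mM,
                              water_model=water_model)
    for _, row in sub.iterrows():
        name = row["contribution"]
        if name.startswith("-"):           # printed with the site minus sign
            ledger.set_term(name[1:], -row["value"], row["stderr"])
        elif name in LEDGER_TERMS:
            ledger.set_term(name, row["value"], row["stderr"])
    return ledger


def printed_total(water_model: str, salt_mM: float) -> tuple[float, float]:
    """The printed assembled dG_b for one condition."""
    df = load_contribution_table()
    row = df[(df.contribution == "dG_b") & (df.water_model == water_model)
             & (df.salt_mM == salt_mM)]
    if row.empty:
        raise KeyError(f"no dG_b entry for {water_model} / {salt_mM} mM")
    return float(row.value.iloc[0]), float(row.stderr.iloc[0])


def salt_series_from_table(water_model: str, source: str = "contributions") -> SaltSeries:
    """Salt series of assembled dG_b values for one water model.

    ``source="contributions"`` uses the restraint-route totals;
    ``"separation"`` uses the unrestrained-separation totals.
    """
    if source == "contributions":
        df = load_contribution_table()
        df = df[df.contribution == "dG_b"]
    elif source == "separation":
        df = load_separation_table()
    else:
        raise ValueError("source must be 'contributions' or 'separation'")
    sub = df[df.water_model == water_model].sort_values("salt_mM")
    return SaltSeries(sub.salt_mM.to_numpy(float), sub.value.to_numpy(),
                      sub.stderr.to_numpy(), label=f"{water_model}/{source}")


# ---------------------------------------------------------------------------
# pipeline configuration and driver


class GenerateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    potential: str = "double_well"
    potential_params: dict = Field(default_factory=dict)
    centers_start: float = -2.0
    centers_stop: float = 2.0
    n_windows: int = 11
    k_bias: float = 10.0
    convention: str = "full"
    n_per_window: int = 3000
    step_size: float = 0.3


class EstimateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bin_width: float = 0.1
    tol: float = 1e-7
    max_iter: int = 100000
    n_error_blocks: int = 10


class LedgerConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    water_model: str = "TIP3P"
    salt_mM: float = 81.0


class FitsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    salt_log_base: str = "natural"
    interpolate_at: float | None = None


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    temperature: float = 300.0
    seed: int = 0
    output_dir: str = "pipeline_output"
    stages: list[str] = Field(default_factory=lambda: ["generate", "estimate",
                                                       "ledger", "fits"])
    generate: GenerateConfig = Field(default_factory=GenerateConfig)
    estimate: EstimateConfig = Field(default_factory=EstimateConfig)
    ledger: LedgerConfig = Field(default_factory=LedgerConfig)
    fits: FitsConfig = Field(default_factory=FitsConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig | str | Path, log=print) -> dict:
    """Run the requested stages in dependency order; returns a result bundle.

    Every run writes the resolved configuration and tool version next to
    its outputs; reruns with the same seed are numerically identical.
    """
    from . import synthetic, transitions
    from .estimators import wham_1d
    from .restraint_fe import assemble_binding_free_energy

    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.json").write_text(
        json.dumps({"config": config.model_dump(), "tool_version": __version__},
                   indent=2))
    results: dict = {"output_dir": str(outdir)}
    known = {"generate", "estimate", "ledger", "fits"}
    for stage in config.stages:
        if stage not in known:
            raise StageError(stage, ValueError("unknown stage"))

    dataset = None
    if "generate" in config.stages:
        try:
            g = config.generate
            potential = synthetic.AnalyticPotential(g.potential, g.potential_params)
            centers = np.linspace(g.centers_start, g.centers_stop, g.n_windows)
            dataset = synthetic.generate_umbrella_dataset(
                potential, centers, g.k_bias, g.convention,
                n_per_window=g.n_per_window, temperature=config.temperature,
                seed=config.seed, step_size=g.step_size)
            log(f"[generate] {g.n_windows} windows x {g.n_per_window} samples, "
                f"seed={config.seed}")
            results["dataset"] = dataset
        except Exception as exc:
            raise StageError("generate", exc) from exc

    if "estimate" in config.stages:
        try:
            if dataset is None:
                raise ValueError("estimate stage requires the generate stage")
            e = config.estimate
            pmf = wham_1d(dataset.windows, bin_width=e.bin_width, tol=e.tol,
                          max_iter=e.max_iter, n_error_blocks=e.n_error_blocks)
            write_pmf_tsv(outdir / "pmf.tsv", pmf)
            results["pmf"] = pmf
            log(f"[estimate] WHAM PMF over {len(pmf.bin_centers)} bins -> pmf.tsv")
        except Exception as exc:
            raise StageError("estimate", exc) from exc

    if "ledger" in config.stages:
        try:
            ledger = ledger_from_table(config.ledger.water_model, config.ledger.salt_mM)
            total, err = assemble_binding_free_energy(ledger)
            write_ledger_json(outdir / "ledger.json", ledger)
            results["ledger"] = ledger
            results["dG_b"] = (total, err)
            log(f"[ledger] {config.ledger.water_model}/{config.ledger.salt_mM} mM: "
                f"dG_b = {total:.2f} +- {err:.2f} kcal/mol")
        except Exception as exc:
            raise StageError("ledger", exc) from exc

    if "fits" in config.stages:
        try:
            series = salt_series_from_table(config.ledger.water_model,
                                            source="contributions")
            slope, stderr = transitions.salt_dependence_regression(
                series, log_base=config.fits.salt_log_base)
            results["salt_slope"] = (slope, stderr)
            log(f"[fits] salt slope {slope:.2f} +- {stderr:.2f} kcal/mol per log unit")
            if config.fits.interpolate_at is not None:
                conc = transitions.interpolate_concentration(
                    series, config.fits.interpolate_at,
                    log_base=config.fits.salt_log_base)
                results["interpolated_mM"] = conc
                log(f"[fits] dG={config.fits.interpolate_at} -> {conc:.0f} mM")
            fit_json = {"salt_slope": slope, "salt_slope_stderr": stderr,
                        "log_base": config.fits.salt_log_base}
            (outdir / "fits.json").write_text(json.dumps(fit_json, indent=2))
        except Exception as exc:
            raise StageError("fits", exc) from exc

    return results
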