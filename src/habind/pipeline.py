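"""Orchestration of the four analyses with file-based reporting.

Each ``run_*`` function consumes a :class:`RunConfig`, executes one of the
analyses end-to-end — fingerprint tables + classification, umbrella/WHAM
energetics, field-driven detachment, sliding — and writes its outputs
(TSV tables with units in the headers, JSON summaries, the resolved
config) into the output directory.  All randomness flows from the single
top-level seed, expanded per stage with ``numpy.random.SeedSequence``, so
a rerun with identical config and seed is byte-identical for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .assays import (
    detachment_table,
    detect_detachment,
    sliding_track,
    summarize_detachments,
)
from .contacts import ContactParams, contact_contour, replica_binding_table, \
    residue_contact_series, contact_count_series
from .energetics import (
    ThermoParams,
    delta_g_min,
    delta_g_min_uncertainty,
    preference_factor,
    to_kbt,
    wham,
)
from .errors import ConfigError
from .model_io import SelectionSpec, assign_ha_numbering, read_structure, \
    read_trajectory, write_structure, write_text_trajectory
from .modes import MODES, ReferenceFingerprints, classify, fingerprint
from .synthetic import ToySystemConfig, plant_mode, simulate, \
    umbrella_scan

log = logging.getLogger("habind")

#: Field strengths of the two in-silico electrophoresis presets
#: (kJ mol^-1 nm^-1 e^-1): "strong" detaches weak modes within a few ns,
#: "weak" is a tenth of it, as in the reference assay design.
FIELD_PRESETS = {"strong": 1.5, "weak": 0.15}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    outdir: Path
    seed: int = 0
    n_replicas: int = 3
    modes: tuple[str, ...] = MODES
    n_steps: int = 5000
    field_preset: str = "strong"
    censoring_time_ns: float | None = None
    contact: ContactParams = field(default_factory=ContactParams)
    thermo: ThermoParams = field(default_factory=ThermoParams)
    classify_threshold: float = 0.80
    system: ToySystemConfig = field(default_factory=ToySystemConfig)
    trajectories: tuple[str, ...] = ()   # external inputs, optional
    umbrella_centers: tuple[float, ...] = tuple(np.arange(0.7, 3.3, 0.1))
    umbrella_spring_k: float = 400.0
    umbrella_steps: int = 360_000
    dg_inputs: dict[str, float] | None = None   # mode -> dG (kJ/mol), no WHAM
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict[str, Any], outdir: str | Path,
                  seed: int | None = None) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "contact" in kwargs:
            kwargs["contact"] = ContactParams(**kwargs["contact"])
        if "thermo" in kwargs:
            kwargs["thermo"] = ThermoParams(**kwargs["thermo"])
        if "system" in kwargs:
            kwargs["system"] = ToySystemConfig(**kwargs["system"])
        for tup in ("modes", "trajectories", "umbrella_centers"):
            if tup in kwargs:
                kwargs[tup] = tuple(kwargs[tup])
        kwargs["outdir"] = Path(outdir)
        if seed is not None:
            kwargs["seed"] = seed
        cfg = cls(**kwargs)
        for m in cfg.modes:
            if m not in MODES:
                raise ConfigError(f"unknown binding mode {m!r}")
        if cfg.n_replicas < 1:
            raise ConfigError("n_replicas must be >= 1")
        if cfg.field_preset not in FIELD_PRESETS:
            raise ConfigError(f"unknown field preset {cfg.field_preset!r}; "
                              f"choose from {sorted(FIELD_PRESETS)}")
        return cfg

    def resolved(self) -> dict:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, Path):
                return str(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, tuple):
                return list(o)
            return o
        return {k: enc(v) for k, v in dataclasses.asdict(self).items()}

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage_seeds(config: RunConfig, stage: str, n: int) -> list[int]:
    """Deterministic per-replica seeds derived from (top seed, stage)."""
    tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(tag,))
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _prepare(config: RunConfig, stage: str) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    log.info("habind %s | stage %s | config %s | seed %d",
             __version__, stage, config.config_hash(), config.seed)
    with open(out / f"{stage}_config.json", "w") as fh:
        json.dump({"stage": stage, "version": __version__,
                   "config_hash": config.config_hash(),
                   "config": config.resolved()}, fh, indent=1)
    return out


def _ligand_selection() -> SelectionSpec:
    return SelectionSpec(name="ligand", role="polymer")


def run_fingerprint(config: RunConfig) -> dict:
    """Fingerprint table + per-replica classification on synthetic replicas.

    Generates ``n_replicas`` trajectories per requested mode, computes the
    per-replica residue contact series, aggregates the binding-percent
    table, classifies each replica, and writes a reference-layout TSV plus
    a JSON classification report.
    """
    out = _prepare(config, "fingerprint")
    refs = ReferenceFingerprints.from_package_data()
    ligand = _ligand_selection()
    report: dict[str, Any] = {"replicas": []}
    tables = {}
    if config.trajectories:
        return _fingerprint_external(config, out, refs, ligand, report)
    for mode in config.modes:
        seeds = _stage_seeds(config, f"fingerprint:{mode}", config.n_replicas)
        series_list = []
        for rep, seed in enumerate(seeds):
            traj = simulate(plant_mode(config.system, mode),
                            config.n_steps, seed=seed).trajectory
            fp = fingerprint(traj, ligand, params=config.contact)
            asg = classify(fp, refs, threshold=config.classify_threshold)
            series_list.append(residue_contact_series(
                traj, refs.residues, ligand, config.contact))
            report["replicas"].append({
                "mode_planted": mode, "replica": rep, "seed": seed,
                "label": asg.label,
                "similarities": {k: round(v, 4)
                                 for k, v in asg.similarities.items()}})
        tables[mode] = replica_binding_table(series_list)
    table = pd.DataFrame({"residue": refs.residues})
    for mode, t in tables.items():
        table[f"{mode}_percent"] = t.mean
        table[f"{mode}_se"] = t.se
    table.to_csv(out / "binding_percent.tsv", sep="\t", index=False,
                 float_format="%.1f", na_rep="N/A")
    with open(out / "classification.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return {"table": table, "report": report}


def _fingerprint_external(config: RunConfig, out: Path, refs, ligand,
                          report: dict) -> dict:
    """Fingerprint/classify externally supplied (structure, trajectory)
    pairs; each ``trajectories`` entry is a mapping with ``structure``,
    ``trajectory`` and optional ``protein_chain``/``polymer_chain`` keys."""
    series_list = []
    for rep, entry in enumerate(config.trajectories):
        if not isinstance(entry, dict) or \
                {"structure", "trajectory"} - set(entry):
            raise ConfigError(
                "each trajectories entry needs 'structure' and 'trajectory'")
        roles = {entry.get("protein_chain", "A"): "protein",
                 entry.get("polymer_chain", "P"): "polymer"}
        model = read_structure(entry["structure"], chain_roles=roles)
        traj = read_trajectory(entry["trajectory"], model)
        fp = fingerprint(traj, ligand, params=config.contact)
        asg = classify(fp, refs, threshold=config.classify_threshold)
        series_list.append(residue_contact_series(
            traj, refs.residues, ligand, config.contact))
        report["replicas"].append({
            "trajectory": str(entry["trajectory"]), "replica": rep,
            "label": asg.label,
            "similarities": {k: round(v, 4)
                             for k, v in asg.similarities.items()}})
    table_obj = replica_binding_table(series_list)
    table = table_obj.to_frame()
    table.to_csv(out / "binding_percent.tsv", sep="\t", index=False,
                 float_format="%.1f", na_rep="N/A")
    with open(out / "classification.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return {"table": table, "report": report}


def run_efield_assay(config: RunConfig) -> dict:
    """Detachment fractions and times per mode under a field preset.

    The censoring time is a required input (the simulated span per replica
    must be stated, not guessed); replicas are scored by the
    first-zero-contact rule and summarized per mode.
    """
    if config.censoring_time_ns is None:
        raise ConfigError("censoring_time_ns is required for the e-field assay")
    out = _prepare(config, "efield")
    field_val = FIELD_PRESETS[config.field_preset]
    sys_base = replace(config.system, n_mono=min(config.system.n_mono, 32),
                       end_restraint_k=0.0, lateral_restraint_k=0.0,
                       protein_fixed=True, field=field_val)
    dt_frame_ns = sys_base.timestep * sys_base.stride / 1000.0
    n_steps = int(round(config.censoring_time_ns * 1000 / sys_base.timestep))
    ligand = _ligand_selection()
    protein = SelectionSpec(name="protein", role="protein")
    summaries = {}
    for mode in config.modes:
        seeds = _stage_seeds(config, f"efield:{mode}:{config.field_preset}",
                             config.n_replicas)
        records = []
        for rep, seed in enumerate(seeds):
            traj = simulate(plant_mode(sys_base, mode), n_steps,
                            seed=seed).trajectory
            counts = contact_count_series(traj, protein, ligand, config.contact)
            records.append(detect_detachment(
                counts, dt_ns=dt_frame_ns,
                censoring_time_ns=config.censoring_time_ns, replica=rep,
                field_tag=config.field_preset))
        summaries[mode] = summarize_detachments(records)
    table = detachment_table(summaries)
    table.to_csv(out / "detachment.tsv", sep="\t", index=False,
                 float_format="%.2f", na_rep="N/A")
    return {"summaries": summaries, "table": table}


def run_energetics(config: RunConfig) -> dict:
    """PMFs per mode by umbrella scan + WHAM, or direct dG conversions.

    With ``dg_inputs`` set, skips sampling entirely and reports the unit
    conversions and pairwise preference factors for the given well depths.
    Otherwise runs a synthetic umbrella scan per requested mode, estimates
    each PMF by WHAM, and reports depths in both unit systems plus the
    preference factor between the first two modes.
    """
    out = _prepare(config, "energetics")
    report: dict[str, Any] = {"kbt_kJ_per_mol": config.thermo.kbt,
                              "convention": config.thermo.convention}
    if config.dg_inputs:
        entries = {}
        for mode, dg in config.dg_inputs.items():
            entries[mode] = {"dg_kJ_per_mol": dg,
                             "dg_kbt": to_kbt(dg, config.thermo)}
        pairs = {}
        items = list(config.dg_inputs.items())
        for (ma, da), (mb, db) in zip(items, items[1:]):
            pairs[f"{ma}_vs_{mb}"] = preference_factor(da, db, config.thermo)
        report.update({"modes": entries, "preference_factors": pairs})
    else:
        entries = {}
        dgs = {}
        for mode in config.modes:
            seed = _stage_seeds(config, f"energetics:{mode}", 1)[0]
            wins = umbrella_scan(plant_mode(config.system, mode),
                                 config.umbrella_centers,
                                 config.umbrella_spring_k,
                                 config.umbrella_steps, seed=seed)
            pmf = wham(wins, thermo=config.thermo, seed=seed)
            pmf.to_tsv(out / f"pmf_{mode}.tsv")
            dg = delta_g_min(pmf)
            dgs[mode] = dg
            entries[mode] = {"dg_min_kJ_per_mol": dg,
                             "dg_min_kbt": to_kbt(dg, config.thermo),
                             "dg_min_se": delta_g_min_uncertainty(pmf)}
        report["modes"] = entries
        if len(config.modes) >= 2:
            a, b = config.modes[0], config.modes[1]
            report["preference_factors"] = {
                f"{a}_vs_{b}": preference_factor(dgs[a], dgs[b], config.thermo)}
    with open(out / "energetics.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def run_sliding(config: RunConfig) -> dict:
    """Sliding tracks along the polymer for each requested mode.

    The receptor is tethered laterally (the membrane-anchor analog of the
    chain-at-a-surface setup) and free along the chain; tracks report the
    contact centroid per frame and the net displacement in monosaccharide
    units.
    """
    out = _prepare(config, "sliding")
    sys_base = replace(config.system,
                       receptor_tether_k=(0.0, 5.0, 50.0))
    ligand = _ligand_selection()
    protein = SelectionSpec(name="protein", role="protein")
    report = {}
    for mode in config.modes:
        seeds = _stage_seeds(config, f"sliding:{mode}", config.n_replicas)
        disps = []
        for rep, seed in enumerate(seeds):
            toy = simulate(plant_mode(sys_base, mode), config.n_steps,
                           seed=seed)
            traj = toy.trajectory
            rmap = assign_ha_numbering(traj.model, traj.get_frame(0)[0],
                                       key_residue=41)
            contour = contact_contour(traj, rmap, protein, config.contact)
            track = sliding_track(contour)
            track.to_frame().to_csv(out / f"sliding_{mode}_{rep}.tsv",
                                    sep="\t", index=False)
            disps.append(track.net_displacement)
        report[mode] = {"net_displacement_mono": disps,
                        "mean_abs_displacement":
                            float(np.mean(np.abs(disps)))}
    with open(out / "sliding.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def run_synth(config: RunConfig) -> dict:
    """Generate one synthetic trajectory per requested mode and write it
    through the columnar interchange plus a PDB of the toy topology."""
    out = _prepare(config, "synth")
    paths = {}
    for mode in config.modes:
        seed = _stage_seeds(config, f"synth:{mode}", 1)[0]
        toy = simulate(plant_mode(config.system, mode), config.n_steps,
                       seed=seed)
        pdb = out / f"toy_{mode}.pdb"
        trj = out / f"toy_{mode}.habtrj"
        write_structure(toy.model, pdb)
        write_text_trajectory(trj, toy.trajectory)
        paths[mode] = {"pdb": str(pdb), "trajectory": str(trj),
                       "seed": seed, "planted_mode": toy.planted_mode}
    with open(out / "synth.json", "w") as fh:
        json.dump(paths, fh, indent=1)
    return paths
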