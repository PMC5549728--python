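"""Toy Brownian-dynamics generator with planted binding modes.

The generator emulates the statistical structure the analysis modules
assume, at desk scale: a rigid pseudo-residue receptor bead cluster facing
a linear polyanionic polymer of alternating GlcUA/GlcNAc beads.  Exactly
one of three disjoint anchor patches (crystallographic / parallel /
upright) is attractive in a given system — the planted binding mode — with
well depths ordered crystallographic > upright > parallel in the default
("paper-ordered") preset.  A key-site bead cluster (the R41-like site plus
its groove neighbours) binds in every mode, so every planted fingerprint
shares the key residues, as the real modes do.

Dynamics are overdamped Langevin (no inertia):

    dx = (D / kBT) F dt + sqrt(2 D dt) eta,   eta ~ N(0, 1)

The receptor moves as a single rigid body (translation only); the polymer
is flexible with stiff harmonic bonds, optional end restraints and an
optional lateral tether that mimics a chain held at a surface.  An applied
uniform field acts on the charged GlcUA beads, pulling the polymer off a
held receptor — the in-silico electrophoresis assay.  Binding wells attract
the active patch beads to the GlcNAc beads of the chain (the planted analog
of the GlcNAc methyl anchoring), which makes the bound state corrugated
along the chain with period one disaccharide: shallow modes hop between
registry sites and slide, the deep mode stays put.

Umbrella scans run quasi-one-dimensionally: the receptor is restrained in
every direction except the detachment coordinate, so the reaction
coordinate carries no radial Jacobian term and a planted well of depth
epsilon is recovered by WHAM as a PMF well of depth epsilon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .energetics import GAS_CONSTANT_KJ, UmbrellaWindow
from .errors import ConfigError, GeometryError, StabilityError
from .model_io import InMemoryTrajectory, StructureModel

MODES = ("crystallographic", "parallel", "upright")

#: Pseudo-residues of the key site, bound in every mode.
KEY_RESIDUES: tuple[int, ...] = (41, 42, 78, 79)

#: Patch -> canonical residue numbers of the reference fingerprint set.
#: Residues shared between patches (e.g. 77, 88, 96-98 between the groove
#: and the upright face) carry one bead in each patch that uses them.
PATCH_RESIDUES: dict[str, tuple[int, ...]] = {
    "crystallographic": (76, 77, 88, 94, 96, 97, 98, 99, 105, 150),
    "parallel": (25, 40, 107, 110, 115, 152, 154, 155),
    "upright": (38, 43, 44, 57, 77, 88, 96, 97, 98, 158, 162, 164, 166),
}

_RESNAME_BY_LETTER = {"N": "ASN", "R": "ARG", "K": "LYS", "G": "GLY",
                      "Y": "TYR", "S": "SER", "I": "ILE", "T": "THR",
                      "C": "CYS", "A": "ALA", "L": "LEU", "D": "ASP",
                      "E": "GLU", "H": "HIS"}

_REF_NAMES = {25: "N", 29: "R", 38: "K", 40: "G", 41: "R", 42: "Y", 43: "S",
              44: "I", 57: "N", 68: "K", 76: "T", 77: "C", 78: "R", 79: "Y",
              80: "G", 88: "I", 94: "N", 96: "I", 97: "C", 98: "A", 99: "A",
              100: "N", 101: "N", 105: "Y", 106: "I", 107: "L", 110: "N",
              115: "D", 120: "N", 149: "N", 150: "R", 151: "D", 152: "G",
              154: "R", 155: "Y", 158: "K", 162: "R", 164: "N", 166: "E"}


@dataclass(frozen=True)
class ToySystemConfig:
    """Full parameterization of the synthetic Brownian system.

    Lengths nm, energies kJ/mol, times ps.  The default well depths
    (12, 8, 5) kJ/mol for (crystallographic, upright, parallel) follow the
    qualitative strength ordering of the three binding modes with a spread
    of a few kBT, shallow enough for desk-scale detachment statistics.
    """

    n_mono: int = 64                 # monosaccharide beads, even
    bond_length: float = 0.5         # nm
    bond_k: float = 2000.0           # kJ mol^-1 nm^-2
    end_restraint_k: float = 500.0   # chain-end tether (0 = free chain)
    lateral_restraint_k: float = 50.0  # per-bead y/z tether (0 = off)
    charge: float = -1.0             # e, on GlcUA beads
    well_depths: dict = field(default_factory=lambda: {
        "crystallographic": 12.0, "upright": 8.0, "parallel": 5.0})
    well_width: float = 0.3          # nm
    pair_depth_scale: float = 0.8    # per anchor-bead pair: depth = scale * eps
    contact_offset: float = 0.4      # initial patch-bead to chain-axis distance
    repulsion_r0: float = 0.35
    repulsion_k: float = 400.0
    temperature: float = 310.0       # K
    diffusion: float = 1.0e-3        # nm^2 ps^-1, beads and rigid receptor
    timestep: float = 0.3            # ps
    stride: int = 100                # steps between saved frames
    box_pad: float = 8.0             # box size beyond the chain, nm
    field: float = 0.0               # |E| in kJ mol^-1 nm^-1 e^-1, along -y on HA
    umbrella_k: float = 0.0          # kJ mol^-1 nm^-2 on xi (0 = off)
    umbrella_center: float = 0.0     # nm
    wall_k: float = 1000.0           # receptor-side wall at the chain axis
    planted_mode: str = "crystallographic"
    protein_fixed: bool = False
    move_axes: tuple[bool, bool, bool] = (True, True, True)
    receptor_tether_k: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mono < 4 or self.n_mono % 2:
            raise ConfigError("n_mono must be an even number >= 4")
        if self.planted_mode not in MODES:
            raise ConfigError(f"unknown binding mode {self.planted_mode!r}; "
                              f"choose from {MODES}")
        if set(self.well_depths) != set(MODES) or any(
                v < 0 for v in self.well_depths.values()):
            raise ConfigError("well_depths must map all three modes to >= 0")
        rms_step = math.sqrt(2 * self.diffusion * self.timestep)
        if rms_step >= 0.1 * self.well_width:
            raise ConfigError(
                f"timestep too large: per-step RMS displacement "
                f"{rms_step:.3g} nm >= 0.1 x well width {self.well_width} nm")

    @property
    def kbt(self) -> float:
        """Physical thermal energy for the dynamics, kJ/mol."""
        return GAS_CONSTANT_KJ * self.temperature

    @property
    def box(self) -> np.ndarray:
        lx = (self.n_mono - 1) * self.bond_length + self.box_pad
        return np.array([lx, 12.0, 12.0])

    def paper_ordered(self) -> bool:
        d = self.well_depths
        return d["crystallographic"] > d["upright"] > d["parallel"]


def plant_mode(config: ToySystemConfig, mode: str) -> ToySystemConfig:
    """Return a config with only ``mode``'s patch attractive and the
    receptor initialized pre-bound at that patch."""
    if mode not in MODES:
        raise ConfigError(f"unknown binding mode {mode!r}")
    return replace(config, planted_mode=mode)


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def _body_frame(config: ToySystemConfig) -> pd.DataFrame:
    """Receptor bead layout in the body frame.

    The polymer-facing plane is y = 0: key-site beads and the planted
    patch's beads sit there on an integer-nm x grid, commensurate with the
    GlcNAc spacing (one disaccharide = 1 nm).  Inactive patches sit on the
    back face (y = +1.4) offset in z, far outside the contact cutoff of a
    bound chain.  The core bead sits at y = +0.7.
    """
    rows = []
    active = list(KEY_RESIDUES) + list(PATCH_RESIDUES[config.planted_mode])
    for i, resid in enumerate(active):
        x = (i - len(active) // 2) * 1.0
        rows.append({"resid": resid, "x": x, "y": 0.0, "z": 0.0,
                     "patch": "key" if resid in KEY_RESIDUES
                     else config.planted_mode, "active": True})
    rows.append({"resid": 1, "x": 0.0, "y": 0.7, "z": 0.0,
                 "patch": "core", "active": False})
    zoff = {m: s for m, s in zip(MODES, (-0.9, 0.0, 0.9))}
    for m in MODES:
        if m == config.planted_mode:
            continue
        for j, resid in enumerate(PATCH_RESIDUES[m]):
            rows.append({"resid": resid, "x": (j - len(PATCH_RESIDUES[m]) // 2) * 0.3,
                         "y": 1.4, "z": zoff[m], "patch": m, "active": False})
    return pd.DataFrame(rows)


@dataclass
class ToySystem:
    """Realized geometry: polymer positions plus rigid receptor body."""

    config: ToySystemConfig
    polymer: np.ndarray            # (n_mono, 3), world frame
    body: pd.DataFrame             # receptor beads, body frame
    receptor_origin: np.ndarray    # (3,)
    axis_yz: tuple[float, float]

    def __post_init__(self) -> None:
        self.body_xyz = self.body[["x", "y", "z"]].to_numpy()
        self.active_mask = self.body["active"].to_numpy()

    def receptor_positions(self, origin: np.ndarray | None = None) -> np.ndarray:
        o = self.receptor_origin if origin is None else origin
        return self.body_xyz + o

    @property
    def glcnac_rows(self) -> np.ndarray:
        return np.arange(0, self.config.n_mono, 2)

    @property
    def glcua_rows(self) -> np.ndarray:
        return np.arange(1, self.config.n_mono, 2)


def _initial_system(config: ToySystemConfig) -> ToySystem:
    c = config
    box = c.box
    x0 = (box[0] - (c.n_mono - 1) * c.bond_length) / 2
    axis_y, axis_z = 4.0, box[2] / 2
    polymer = np.column_stack([
        x0 + np.arange(c.n_mono) * c.bond_length,
        np.full(c.n_mono, axis_y),
        np.full(c.n_mono, axis_z)])
    body = _body_frame(c)
    # registry: align facing beads with GlcNAc beads near the chain middle
    mid_glcnac = x0 + (2 * (c.n_mono // 4)) * c.bond_length
    origin = np.array([mid_glcnac, axis_y + c.contact_offset, axis_z])
    sys_ = ToySystem(config=c, polymer=polymer, body=body,
                     receptor_origin=origin, axis_yz=(axis_y, axis_z))
    rec = sys_.receptor_positions()
    d = np.linalg.norm(rec[:, None, :] - polymer[None, :, :], axis=-1)
    if d.min() < 0.5 * c.repulsion_r0:
        raise GeometryError("overlapping beads in the initial geometry")
    return sys_


def build_system(config: ToySystemConfig) -> StructureModel:
    """Deterministic initial :class:`StructureModel` for a config.

    Chain P (polymer) holds the alternating GlcNAc/GlcUA beads numbered
    from the reducing (GlcNAc) end; chain A (protein) holds the receptor
    pseudo-residues with their canonical residue numbers.
    """
    sys_ = _initial_system(config)
    rows = []
    coords = []
    for i in range(config.n_mono):
        mono = "NAG" if i % 2 == 0 else "GCU"
        rows.append({"name": "C1", "element": "C", "resid": i + 1,
                     "resname": mono, "chain": "P"})
        coords.append(sys_.polymer[i])
    rec = sys_.receptor_positions()
    for (_, b), xyz in zip(sys_.body.iterrows(), rec):
        resid = int(b["resid"])
        resname = (_RESNAME_BY_LETTER.get(_REF_NAMES.get(resid, ""), "COR")
                   if b["patch"] != "core" else "COR")
        rows.append({"name": "CB", "element": "C", "resid": resid,
                     "resname": resname, "chain": "A"})
        coords.append(xyz)
    model = StructureModel(atoms=pd.DataFrame(rows), coords=np.array(coords),
                           box=config.box,
                           roles={"P": "polymer", "A": "protein"})
    return model


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

@dataclass
class ToyTrajectory:
    """Trajectory plus immutable ground truth of the generating system."""

    trajectory: InMemoryTrajectory
    planted_mode: str
    bound: np.ndarray              # per-frame bool, any active bead in contact
    field: float
    umbrella: tuple[float, float] | None
    seed: int

    @property
    def model(self) -> StructureModel:
        return self.trajectory.model


def _forces(sys_: ToySystem, polymer: np.ndarray, origin: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Forces on polymer beads and net force on the rigid receptor."""
    c = sys_.config
    n = c.n_mono
    f_poly = np.zeros_like(polymer)
    # harmonic bonds
    dvec = polymer[1:] - polymer[:-1]
    dist = np.linalg.norm(dvec, axis=1)
    fb = (c.bond_k * (dist - c.bond_length) / dist)[:, None] * dvec
    f_poly[:-1] += fb
    f_poly[1:] -= fb
    # end restraints (to initial end positions)
    if c.end_restraint_k > 0:
        for idx in (0, n - 1):
            f_poly[idx] += c.end_restraint_k * (sys_.polymer[idx] - polymer[idx])
    # lateral tether toward the chain axis
    if c.lateral_restraint_k > 0:
        ay, az = sys_.axis_yz
        f_poly[:, 1] += c.lateral_restraint_k * (ay - polymer[:, 1])
        f_poly[:, 2] += c.lateral_restraint_k * (az - polymer[:, 2])
    # field on charged (GlcUA) beads: F = q E, E along +y, q < 0
    if c.field != 0.0:
        f_poly[sys_.glcua_rows, 1] += c.charge * c.field
    rec = sys_.receptor_positions(origin)
    f_rec = np.zeros(3)
    # binding wells: active beads <-> GlcNAc beads; Gaussian centred on
    # the bead, excluded volume sets the resting contact distance
    active = sys_.active_mask
    eps = c.well_depths[c.planted_mode]
    if eps > 0 and active.any():
        a_pos = rec[active]
        t_rows = sys_.glcnac_rows
        t_pos = polymer[t_rows]
        diff = a_pos[:, None, :] - t_pos[None, :, :]
        d = np.sqrt((diff ** 2).sum(-1))
        g = np.exp(-d ** 2 / (2 * c.well_width ** 2))
        # per-pair well depth = pair_depth_scale * eps, so the planted
        # strength ordering holds per contact and in total
        mag = -(eps * c.pair_depth_scale / c.well_width ** 2) * g * d
        f_pair = (mag / np.maximum(d, 1e-9))[:, :, None] * diff
        f_rec += f_pair.sum(axis=(0, 1))
        np.add.at(f_poly, t_rows, -f_pair.sum(axis=0))
    # soft excluded volume between every receptor bead and polymer bead
    diff = rec[:, None, :] - polymer[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    close = d < c.repulsion_r0
    if close.any():
        mag = np.where(close, c.repulsion_k * (c.repulsion_r0 - d) / np.maximum(d, 1e-9), 0.0)
        f_pair = mag[:, :, None] * diff
        f_rec += f_pair.sum(axis=(0, 1))
        f_poly -= f_pair.sum(axis=0)
    # membrane-side wall: the receptor protrudes from a surface on the +y
    # side of the chain and cannot slip through the polymer line
    if c.wall_k > 0 and origin[1] < sys_.axis_yz[0]:
        f_rec[1] += c.wall_k * (sys_.axis_yz[0] - origin[1])
    # receptor tether (membrane-anchor analog): harmonic per-axis pull
    # toward the initial bound origin
    tk = np.asarray(c.receptor_tether_k)
    if np.any(tk > 0):
        f_rec += tk * (sys_.receptor_origin - origin)
    # umbrella restraint on xi = |origin - nearest-segment reference|
    if c.umbrella_k > 0:
        ay, az = sys_.axis_yz
        xi = origin[1] - ay
        f_rec[1] += -c.umbrella_k * (xi - c.umbrella_center)
    return f_poly, f_rec


def _kernel_args(sys_: ToySystem):
    """Plain-array parameter pack for the compiled integrator."""
    c = sys_.config
    eps_pref = (c.well_depths[c.planted_mode] * c.pair_depth_scale
                / c.well_width ** 2)
    return dict(
        body_xyz=sys_.body_xyz.astype(np.float64),
        active_idx=np.nonzero(sys_.active_mask)[0].astype(np.int64),
        glcnac_idx=sys_.glcnac_rows.astype(np.int64),
        glcua_idx=sys_.glcua_rows.astype(np.int64),
        end_pos=sys_.polymer[[0, -1]].astype(np.float64),
        axis_y=float(sys_.axis_yz[0]), axis_z=float(sys_.axis_yz[1]),
        bond_k=c.bond_k, bond_length=c.bond_length,
        end_k=c.end_restraint_k, lat_k=c.lateral_restraint_k,
        q_field=c.charge * c.field,
        eps_pref=eps_pref, w2=c.well_width ** 2,
        rep_r0=c.repulsion_r0, rep_k=c.repulsion_k,
        tether_k=np.asarray(c.receptor_tether_k, dtype=np.float64),
        tether_center=sys_.receptor_origin.astype(np.float64),
        umb_k=c.umbrella_k, umb_center=c.umbrella_center,
        wall_k=c.wall_k,
        move_mask=np.asarray(c.move_axes, dtype=np.float64),
        protein_fixed=c.protein_fixed,
    )


def _make_chunk_kernel():
    from numba import njit

    @njit(cache=False)
    def chunk(polymer, origin, noise, mob,
              body_xyz, active_idx, glcnac_idx, glcua_idx, end_pos,
              axis_y, axis_z, bond_k, bond_length, end_k, lat_k, q_field,
              eps_pref, w2, rep_r0, rep_k, tether_k, tether_center,
              umb_k, umb_center, wall_k, move_mask, protein_fixed, limit):
        n = polymer.shape[0]
        nb = body_xyz.shape[0]
        f_poly = np.zeros((n, 3))
        for s in range(noise.shape[0]):
            for i in range(n):
                for k in range(3):
                    f_poly[i, k] = 0.0
            f_rec = np.zeros(3)
            # harmonic bonds
            for i in range(n - 1):
                dx = polymer[i + 1, 0] - polymer[i, 0]
                dy = polymer[i + 1, 1] - polymer[i, 1]
                dz = polymer[i + 1, 2] - polymer[i, 2]
                dist = math.sqrt(dx * dx + dy * dy + dz * dz)
                coef = bond_k * (dist - bond_length) / dist
                f_poly[i, 0] += coef * dx
                f_poly[i, 1] += coef * dy
                f_poly[i, 2] += coef * dz
                f_poly[i + 1, 0] -= coef * dx
                f_poly[i + 1, 1] -= coef * dy
                f_poly[i + 1, 2] -= coef * dz
            if end_k > 0:
                for e, i in enumerate((0, n - 1)):
                    for k in range(3):
                        f_poly[i, k] += end_k * (end_pos[e, k] - polymer[i, k])
            if lat_k > 0:
                for i in range(n):
                    f_poly[i, 1] += lat_k * (axis_y - polymer[i, 1])
                    f_poly[i, 2] += lat_k * (axis_z - polymer[i, 2])
            if q_field != 0.0:
                for j in glcua_idx:
                    f_poly[j, 1] += q_field
            # binding wells: active beads <-> GlcNAc beads
            if eps_pref > 0:
                for a in active_idx:
                    ax = body_xyz[a, 0] + origin[0]
                    ay = body_xyz[a, 1] + origin[1]
                    az = body_xyz[a, 2] + origin[2]
                    for t in glcnac_idx:
                        dx = ax - polymer[t, 0]
                        dy = ay - polymer[t, 1]
                        dz = az - polymer[t, 2]
                        d = math.sqrt(dx * dx + dy * dy + dz * dz)
                        g = math.exp(-d * d / (2 * w2))
                        mag = -eps_pref * g
                        f_rec[0] += mag * dx
                        f_rec[1] += mag * dy
                        f_rec[2] += mag * dz
                        f_poly[t, 0] -= mag * dx
                        f_poly[t, 1] -= mag * dy
                        f_poly[t, 2] -= mag * dz
            # soft excluded volume, every receptor bead vs polymer bead
            for b in range(nb):
                bx = body_xyz[b, 0] + origin[0]
                by = body_xyz[b, 1] + origin[1]
                bz = body_xyz[b, 2] + origin[2]
                for j in range(n):
                    dx = bx - polymer[j, 0]
                    dy = by - polymer[j, 1]
                    dz = bz - polymer[j, 2]
                    d = math.sqrt(dx * dx + dy * dy + dz * dz)
                    if d < rep_r0:
                        mag = rep_k * (rep_r0 - d) / max(d, 1e-9)
                        f_rec[0] += mag * dx
                        f_rec[1] += mag * dy
                        f_rec[2] += mag * dz
                        f_poly[j, 0] -= mag * dx
                        f_poly[j, 1] -= mag * dy
                        f_poly[j, 2] -= mag * dz
            for k in range(3):
                if tether_k[k] > 0:
                    f_rec[k] += tether_k[k] * (tether_center[k] - origin[k])
            if wall_k > 0 and origin[1] < axis_y:
                f_rec[1] += wall_k * (axis_y - origin[1])
            if umb_k > 0:
                f_rec[1] += -umb_k * ((origin[1] - axis_y) - umb_center)
            # overdamped update
            for i in range(n):
                for k in range(3):
                    dp = mob * f_poly[i, k] + noise[s, i, k]
                    if abs(dp) > limit:
                        return s
                    polymer[i, k] += dp
            if not protein_fixed:
                for k in range(3):
                    dr = (mob * f_rec[k] + noise[s, n, k]) * move_mask[k]
                    if abs(dr) > limit:
                        return s
                    origin[k] += dr
        return -1

    return chunk


_CHUNK_KERNEL = None


def _chunk_kernel():
    global _CHUNK_KERNEL
    if _CHUNK_KERNEL is None:
        _CHUNK_KERNEL = _make_chunk_kernel()
    return _CHUNK_KERNEL


def simulate(config: ToySystemConfig, n_steps: int,
             seed: int | None = None) -> ToyTrajectory:
    """Run overdamped Langevin dynamics and return the trajectory.

    Identical (config, seed) pairs give identical trajectories.  Raises
    :class:`StabilityError` on numeric blow-up (per-step displacement
    beyond half the box).
    """
    if n_steps < 1:
        raise ConfigError("n_steps must be >= 1")
    c = config
    seed = c.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sys_ = _initial_system(c)
    polymer = sys_.polymer.copy()
    origin = sys_.receptor_origin.copy()
    kbt = c.kbt
    mob = c.diffusion / kbt * c.timestep if kbt > 0 else 0.0
    noise_sd = math.sqrt(2 * c.diffusion * c.timestep) if c.temperature > 0 else 0.0
    limit = c.box.min() / 2
    kernel = _chunk_kernel()
    args = _kernel_args(sys_)

    frames, times, bound = [], [], []
    active = sys_.active_mask

    def snapshot(step: int) -> None:
        rec = sys_.receptor_positions(origin)
        frames.append(np.vstack([polymer, rec]))
        times.append(step * c.timestep)
        d = np.linalg.norm(rec[active][:, None, :]
                           - polymer[None, :, :], axis=-1)
        bound.append(bool((d <= 0.6).any()))

    snapshot(0)
    done = 0
    n_noise_rows = c.n_mono + 1
    while done < n_steps:
        chunk = min(c.stride, n_steps - done)
        noise = noise_sd * rng.standard_normal((chunk, n_noise_rows, 3)) \
            if noise_sd else np.zeros((chunk, n_noise_rows, 3))
        bad = kernel(polymer, origin, noise, mob, limit=limit, **args)
        if bad >= 0:
            raise StabilityError(
                f"displacement blew up at step {done + bad + 1}")
        done += chunk
        if done % c.stride == 0:
            snapshot(done)

    model = build_system(c)
    traj = InMemoryTrajectory(model, np.array(frames), np.array(times),
                              box=c.box)
    umb = (c.umbrella_k, c.umbrella_center) if c.umbrella_k > 0 else None
    return ToyTrajectory(trajectory=traj, planted_mode=c.planted_mode,
                         bound=np.array(bound), field=c.field,
                         umbrella=umb, seed=seed)


# --------------------------------------------------------------------------
# 1D umbrella scans
# --------------------------------------------------------------------------

def brownian_1d(force: Callable[[float], float], x0: float, n_steps: int,
                dt: float, diffusion: float, kbt: float,
                rng: np.random.Generator) -> np.ndarray:
    """Overdamped 1D Langevin integrator; returns the position series."""
    x = np.empty(n_steps + 1)
    x[0] = x0
    mob = diffusion / kbt * dt
    sd = math.sqrt(2 * diffusion * dt)
    noise = rng.standard_normal(n_steps)
    xi = x0
    for i in range(n_steps):
        xi = xi + mob * force(xi) + sd * noise[i]
        x[i + 1] = xi
    return x


def mode_well_force(config: ToySystemConfig, xi_bound: float = 1.1
                    ) -> Callable[[float], float]:
    """Force along the detachment coordinate of the planted mode well.

    U(xi) = -eps exp(-(xi - xi_bound)^2 / (2 w^2)) - q_total |E| xi, with
    a soft wall at small xi (the receptor cannot pass through the chain);
    the field term tilts the profile in the detaching direction by the
    total work of the charged beads engaged with the receptor.
    """
    c = config
    eps = c.well_depths[c.planted_mode]
    w = c.well_width
    q_tot = abs(c.charge) * c.field * (len(KEY_RESIDUES)
                                       + len(PATCH_RESIDUES[c.planted_mode]))
    wall = 0.5  # nm

    def force(xi: float) -> float:
        f = -eps * (xi - xi_bound) / w ** 2 * math.exp(
            -(xi - xi_bound) ** 2 / (2 * w ** 2))
        f += q_tot
        if xi < wall:
            f += 200.0 * (wall - xi)
        return f

    return force


def umbrella_scan(config: ToySystemConfig, centers: Sequence[float],
                  spring_k: float, steps_per_window: int,
                  seed: int = 0, xi_bound: float = 1.1,
                  burn_in: float = 0.1,
                  timestep: float = 0.05,
                  sample_stride: int = 300) -> list[UmbrellaWindow]:
    """Sample one umbrella window per center along the detachment coordinate.

    Quasi-1D: the receptor moves only along the detachment coordinate
    against the planted well (see :func:`mode_well_force`), plus the
    harmonic bias.  Warns (does not fail) when the predicted thermal width
    of neighbouring windows leaves a gap.

    The scan integrates with its own ``timestep`` (default 0.05 ps), finer
    than the 3D dynamics: the combined well + bias stiffness makes the
    Euler-Maruyama equilibrium density visibly too wide at the default
    3D step.  Only every ``sample_stride``-th position is kept (default
    every 15 ps, a bit over two relaxation times of a stiff window), so
    the stored samples are approximately independent and the downstream
    bootstrap uncertainties are honest.
    """
    centers = np.asarray(centers, dtype=float)
    if np.any(np.diff(centers) <= 0):
        raise ConfigError("umbrella centers must be strictly increasing")
    kbt = config.kbt
    sd_win = math.sqrt(kbt / spring_k)
    if np.any(np.diff(centers) > 4 * sd_win):
        import warnings

        warnings.warn("umbrella spacing exceeds 4 thermal widths; "
                      "windows may not overlap", stacklevel=2)
    base = mode_well_force(config, xi_bound)
    ss = np.random.SeedSequence(entropy=seed)
    out = []
    for center, child in zip(centers, ss.spawn(len(centers))):
        rng = np.random.default_rng(child)

        def biased(xi: float, c0=center) -> float:
            return base(xi) - spring_k * (xi - c0)

        x = brownian_1d(biased, float(center), steps_per_window,
                        timestep, config.diffusion, kbt, rng)
        skip = int(burn_in * len(x))
        out.append(UmbrellaWindow(center=float(center), spring_k=spring_k,
                                  samples=x[skip::sample_stride],
                                  temperature=config.temperature))
    return out
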