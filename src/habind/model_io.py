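"""Structure/trajectory data model, format IO and residue-numbering conventions.

The central objects are :class:`StructureModel` (an atom table plus one set of
coordinates) and :class:`TrajectoryHandle` (frame-indexed coordinates for the
same atom set).  All coordinates are stored in nanometres; PDB Angstroms are
converted on read.  Binary trajectory dialects (DCD, XTC) are read through
MDAnalysis; the package-native interchange is a plain columnar text format
(one row per atom per frame) that every module can write and read without
binary dependencies.

Hyaluronan residue numbering follows the convention used throughout the
analysis: the disaccharide closest to the key binding residue (R41 in CD44)
is disaccharide 0, numbers decrease toward the reducing (GlcNAc) end of the
chain and increase toward the non-reducing (GlcUA) end.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import (
    CompositionError,
    FormatError,
    SelectionError,
    TopologyError,
)

ANGSTROM_TO_NM = 0.1

#: Atom names that are hydrogens despite not starting with "H"
#: (e.g. PDB v2 names like 1HG1, 2HB).  Names starting with a digit
#: followed by H are hydrogens.
_ELEMENT_OVERRIDES: dict[str, str] = {
    "CAL": "CA",  # calcium ion mis-named
    "SOD": "NA",
    "CLA": "CL",
}

GLCUA = "GLCUA"
GLCNAC = "GLCNAC"
#: Accepted residue-name spellings for the two HA monosaccharides.
POLYMER_RESNAMES = {
    "GCU": GLCUA, "GLCUA": GLCUA, "GLCA": GLCUA, "BGC": GLCUA, "UA": GLCUA,
    "NAG": GLCNAC, "GLCNAC": GLCNAC, "NDG": GLCNAC, "NA2": GLCNAC,
}


def element_from_name(name: str, element: str | None = None) -> str:
    """Best-effort element symbol for a PDB atom.

    Uses the explicit element column when present, then an override table,
    then the leading alphabetic character(s) of the atom name.
    """
    if element:
        el = element.strip()
        if el:
            return el.upper()
    name = name.strip().upper()
    if name in _ELEMENT_OVERRIDES:
        return _ELEMENT_OVERRIDES[name]
    # strip leading digits: "1HG1" -> "HG1"
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] == "H":
        return "H"
    if stripped[:2] in ("CL", "BR", "NA", "MG", "ZN", "FE", "MN") and len(name) > 1:
        return stripped[:2]
    return stripped[0]


@dataclass
class StructureModel:
    """A labeled atom set with one coordinate frame.

    Parameters
    ----------
    atoms : pandas.DataFrame
        Columns ``name, element, resid, resname, chain``; the index is the
        contiguous 0-based atom index.
    coords : ndarray, shape (n_atoms, 3)
        Coordinates in nm.
    box : ndarray of shape (3,) or None
        Orthorhombic box lengths in nm; ``None`` for non-periodic systems.
    roles : dict
        Chain id -> molecule role tag, one of ``protein | polymer | other``.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    box: np.ndarray | None = None
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TopologyError(f"coords must be (n, 3), got {self.coords.shape}")
        if len(self.atoms) != len(self.coords):
            raise TopologyError(
                f"atom table has {len(self.atoms)} rows but coords has "
                f"{len(self.coords)}"
            )
        if len(self.atoms) == 0:
            raise TopologyError("empty model: no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise TopologyError("non-finite coordinates")
        if not np.array_equal(self.atoms.index.to_numpy(), np.arange(len(self.atoms))):
            self.atoms = self.atoms.reset_index(drop=True)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise TopologyError(f"box vectors must be positive, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def chain_role(self, chain: str) -> str:
        return self.roles.get(chain, "other")

    def atoms_of_role(self, role: str) -> np.ndarray:
        chains = [c for c, r in self.roles.items() if r == role]
        mask = self.atoms["chain"].isin(chains).to_numpy()
        return np.nonzero(mask)[0]

    def heavy_mask(self) -> np.ndarray:
        el = self.atoms["element"].to_numpy()
        return np.array([e != "H" for e in el])


@dataclass(frozen=True)
class SelectionSpec:
    """A named, declarative atom subset.

    Selections are resolved against a :class:`StructureModel` only; the
    result is therefore identical for identical (model, spec) pairs and
    independent of frame order.
    """

    name: str
    role: str | None = None
    chain: str | None = None
    resids: tuple[int, ...] | None = None
    resid_range: tuple[int, int] | None = None  # inclusive
    resnames: tuple[str, ...] | None = None
    atom_policy: str = "heavy"  # heavy | all

    def resolve(self, model: StructureModel) -> np.ndarray:
        """Return sorted atom indices matching the spec.

        Raises
        ------
        SelectionError
            If the resolved selection is empty.
        """
        mask = np.ones(model.n_atoms, dtype=bool)
        at = model.atoms
        if self.role is not None:
            chains = [c for c, r in model.roles.items() if r == self.role]
            mask &= at["chain"].isin(chains).to_numpy()
        if self.chain is not None:
            mask &= (at["chain"] == self.chain).to_numpy()
        if self.resids is not None:
            mask &= at["resid"].isin(self.resids).to_numpy()
        if self.resid_range is not None:
            lo, hi = self.resid_range
            r = at["resid"].to_numpy()
            mask &= (r >= lo) & (r <= hi)
        if self.resnames is not None:
            names = {n.upper() for n in self.resnames}
            mask &= at["resname"].str.upper().isin(names).to_numpy()
        if self.atom_policy == "heavy":
            mask &= model.heavy_mask()
        elif self.atom_policy != "all":
            raise SelectionError(f"unknown atom policy {self.atom_policy!r}")
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise SelectionError(f"selection {self.name!r} resolved to zero atoms")
        return idx


# --------------------------------------------------------------------------
# structure IO
# --------------------------------------------------------------------------

def read_structure(path: str | Path, chain_roles: dict[str, str] | None = None) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel` (coordinates in nm).

    Parameters
    ----------
    chain_roles : dict, optional
        Chain id -> role tag (``protein``/``polymer``/``other``).  Chains not
        listed default to ``other``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format="PDB")
        except Exception as exc:  # noqa: BLE001 - normalize parser errors
            raise FormatError(f"cannot parse PDB {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise TopologyError(f"empty model: {path} contains no atoms")
    names = [a.name for a in u.atoms]
    try:
        elements = [a.element for a in u.atoms]
    except Exception:  # noqa: BLE001 - element column absent
        elements = [None] * len(names)
    atoms = pd.DataFrame(
        {
            "name": names,
            "element": [element_from_name(n, e) for n, e in zip(names, elements)],
            "resid": [a.resid for a in u.atoms],
            "resname": [a.resname for a in u.atoms],
            "chain": [getattr(a, "chainID", "") or getattr(a, "segid", "A") or "A"
                      for a in u.atoms],
        }
    )
    coords = u.atoms.positions.astype(float) * ANGSTROM_TO_NM
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        box = u.dimensions[:3].astype(float) * ANGSTROM_TO_NM
    return StructureModel(atoms=atoms, coords=coords, box=box, roles=dict(chain_roles or {}))


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a :class:`StructureModel` as PDB (nm converted back to Angstrom)."""
    import MDAnalysis as mda

    n = model.n_atoms
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           residue_segindex=np.zeros(n, dtype=int), trajectory=True)
    # collapse to true residues
    resids = model.atoms["resid"].to_numpy()
    resnames = model.atoms["resname"].to_numpy()
    chains = model.atoms["chain"].to_numpy()
    keys = list(zip(chains, resids))
    uniq: list[tuple[str, int]] = []
    resindex = np.empty(n, dtype=int)
    for i, k in enumerate(keys):
        if not uniq or uniq[-1] != k:
            uniq.append(k)
        resindex[i] = len(uniq) - 1
    u = mda.Universe.empty(n, n_residues=len(uniq), atom_resindex=resindex,
                           residue_segindex=np.zeros(len(uniq), dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("name", model.atoms["name"].tolist())
    u.add_TopologyAttr("element", model.atoms["element"].tolist())
    first = [keys.index(k) for k in uniq]
    u.add_TopologyAttr("resid", [resids[i] for i in first])
    u.add_TopologyAttr("resname", [str(resnames[i])[:4] for i in first])
    u.add_TopologyAttr("chainID", chains.tolist())
    u.add_TopologyAttr("occupancy", np.ones(n))
    u.add_TopologyAttr("tempfactor", np.zeros(n))
    u.atoms.positions = model.coords / ANGSTROM_TO_NM
    if model.box is not None:
        u.dimensions = [*(model.box / ANGSTROM_TO_NM), 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

class TrajectoryHandle:
    """Frame-indexed coordinates (nm) for a reference :class:`StructureModel`.

    Subclasses implement :meth:`get_frame`; access cost per frame is
    independent of the total number of frames beyond a one-time index scan.
    """

    model: StructureModel
    times: np.ndarray  # ps
    stride: int = 1

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def get_frame(self, i: int) -> tuple[np.ndarray, np.ndarray | None]:
        """Return (coords_nm, box_nm) for frame ``i``."""
        raise NotImplementedError

    def iter_frames(self) -> Iterator[tuple[np.ndarray, np.ndarray | None]]:
        for i in range(self.n_frames):
            yield self.get_frame(i)

    def _check_times(self) -> None:
        if self.n_frames == 0:
            raise TopologyError("trajectory has no frames")
        if np.any(np.diff(self.times) <= 0):
            raise TopologyError("frame times must be strictly increasing")


class InMemoryTrajectory(TrajectoryHandle):
    """Trajectory held as a dense (frames, atoms, 3) array."""

    def __init__(self, model: StructureModel, coords: np.ndarray,
                 times: np.ndarray, box: np.ndarray | None = None,
                 stride: int = 1) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise TopologyError(f"coords must be (frames, atoms, 3), got {coords.shape}")
        if coords.shape[1] != model.n_atoms:
            raise TopologyError(
                f"trajectory has {coords.shape[1]} atoms, model has {model.n_atoms}"
            )
        self.model = model
        self._coords = coords
        self.times = np.asarray(times, dtype=float)
        if len(self.times) != len(coords):
            raise TopologyError("times and frames disagree in length")
        self._box = None if box is None else np.asarray(box, dtype=float)
        self.stride = stride
        self._check_times()

    def get_frame(self, i: int) -> tuple[np.ndarray, np.ndarray | None]:
        box = self._box
        if box is not None and box.ndim == 2:
            box = box[i]
        return self._coords[i], box


class TextTrajectory(TrajectoryHandle):
    """Columnar-text trajectory with an offset index for random access."""

    def __init__(self, path: str | Path, model: StructureModel) -> None:
        self.path = Path(path)
        self.model = model
        self._offsets: list[int] = []
        times: list[float] = []
        self._box = None
        n_atoms = None
        with open(self.path, "rb") as fh:
            header = fh.readline().decode()
            if not header.startswith("#habind-traj"):
                raise FormatError(f"{path}: not a habind columnar trajectory (line 1)")
            meta = json.loads(fh.readline().decode().lstrip("# ").strip())
            n_atoms = int(meta["n_atoms"])
            if meta.get("box") is not None:
                self._box = np.asarray(meta["box"], dtype=float)
            if n_atoms != model.n_atoms:
                raise TopologyError(
                    f"{path}: trajectory has {n_atoms} atoms, model has {model.n_atoms}"
                )
            while True:
                pos = fh.tell()
                line = fh.readline()
                if not line:
                    break
                if line.startswith(b"FRAME"):
                    parts = line.split()
                    self._offsets.append(pos)
                    times.append(float(parts[2]))
        if not self._offsets:
            raise FormatError(f"{path}: empty trajectory (no FRAME records)")
        self.times = np.asarray(times)
        self._n_atoms = n_atoms
        self.stride = 1
        self._check_times()

    def get_frame(self, i: int) -> tuple[np.ndarray, np.ndarray | None]:
        if not 0 <= i < self.n_frames:
            raise IndexError(i)
        with open(self.path, "rb") as fh:
            fh.seek(self._offsets[i])
            fh.readline()  # FRAME line
            rows = [fh.readline() for _ in range(self._n_atoms)]
        if not rows[-1]:
            raise FormatError(f"{self.path}: truncated frame {i}")
        try:
            data = np.loadtxt(io.BytesIO(b"".join(rows)), ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{self.path}: unreadable frame {i}: {exc}") from exc
        if data.shape != (self._n_atoms, 4):
            raise FormatError(f"{self.path}: truncated frame {i}")
        order = np.argsort(data[:, 0])
        return data[order, 1:4], self._box


class MDATrajectory(TrajectoryHandle):
    """DCD/XTC trajectory accessed through MDAnalysis (read-only)."""

    def __init__(self, path: str | Path, model: StructureModel,
                 fmt: str | None = None) -> None:
        import MDAnalysis as mda
        from MDAnalysis.coordinates.core import reader

        path = Path(path)
        if not path.exists():
            raise FormatError(f"no such file: {path}")
        try:
            self._reader = reader(str(path), format=fmt, n_atoms=model.n_atoms,
                                  convert_units=True)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"cannot open trajectory {path}: {exc}") from exc
        if self._reader.n_atoms != model.n_atoms:
            raise TopologyError(
                f"{path}: trajectory has {self._reader.n_atoms} atoms, "
                f"model has {model.n_atoms}"
            )
        self.model = model
        self.path = path
        n = len(self._reader)
        if n == 0:
            raise FormatError(f"{path}: empty trajectory")
        times = np.array([ts.time for ts in self._reader])
        if np.all(times == times[0]) and n > 1:
            times = np.arange(n, dtype=float)  # dialect without time stamps
        self.times = times
        self.stride = 1
        self._check_times()

    def get_frame(self, i: int) -> tuple[np.ndarray, np.ndarray | None]:
        ts = self._reader[i]
        box = None
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            box = ts.dimensions[:3].astype(float) * ANGSTROM_TO_NM
        return ts.positions.astype(float) * ANGSTROM_TO_NM, box


def read_trajectory(path: str | Path, model: StructureModel,
                    fmt: str | None = None) -> TrajectoryHandle:
    """Open a trajectory file (columnar text, DCD or XTC) for ``model``."""
    path = Path(path)
    suffix = (fmt or path.suffix.lstrip(".")).lower()
    if suffix in ("txt", "habtrj", "text"):
        return TextTrajectory(path, model)
    if suffix in ("dcd", "xtc", "trr"):
        return MDATrajectory(path, model, fmt=suffix.upper())
    # sniff: text header?
    with open(path, "rb") as fh:
        if fh.read(12).startswith(b"#habind-traj"):
            return TextTrajectory(path, model)
    return MDATrajectory(path, model)


def write_text_trajectory(path: str | Path, traj: TrajectoryHandle) -> None:
    """Write any trajectory in the columnar text interchange format.

    Layout: two header lines (magic + JSON metadata), then per frame a
    ``FRAME i t`` record followed by ``atom-index x y z`` rows (nm, ps).
    """
    box = None
    first_coords, first_box = traj.get_frame(0)
    if first_box is not None:
        box = np.asarray(first_box, dtype=float).tolist()
    with open(path, "w") as fh:
        fh.write("#habind-traj v1\n")
        fh.write("# " + json.dumps({"n_atoms": traj.model.n_atoms, "box": box,
                                    "units": {"length": "nm", "time": "ps"}}) + "\n")
        for i in range(traj.n_frames):
            coords, _ = traj.get_frame(i)
            fh.write(f"FRAME {i} {traj.times[i]:.6f}\n")
            for a in range(traj.model.n_atoms):
                x, y, z = coords[a]
                fh.write(f"{a} {x:.8f} {y:.8f} {z:.8f}\n")


# --------------------------------------------------------------------------
# HA residue numbering
# --------------------------------------------------------------------------

@dataclass
class ResidueMap:
    """Signed disaccharide numbering of an HA chain plus protein labels.

    ``polymer`` maps each polymer residue (by its file resid) to its
    monosaccharide type and signed disaccharide index; exactly one
    disaccharide carries index 0 (the one closest to the key residue).
    """

    polymer: pd.DataFrame  # columns: resid, mono (GLCUA|GLCNAC), disaccharide
    protein_resids: np.ndarray
    reducing_end: str  # "first" or "last" (position in file order)
    key_residue: int

    def __post_init__(self) -> None:
        d = np.sort(self.polymer["disaccharide"].unique())
        if not np.array_equal(d, np.arange(d[0], d[-1] + 1)):
            raise CompositionError("disaccharide indices must be consecutive")
        if 0 not in d:
            raise CompositionError("no disaccharide carries index 0")
        counts = self.polymer.groupby("disaccharide")["mono"].apply(
            lambda s: sorted(s.unique()))
        for idx, monos in counts.items():
            if monos != [GLCNAC, GLCUA]:
                raise CompositionError(
                    f"disaccharide {idx} does not contain one GlcUA and one GlcNAc")

    def monosaccharide_positions(self) -> pd.DataFrame:
        """Polymer residues ordered from reducing end, with a continuous
        monosaccharide coordinate (disaccharide index +/- half steps)."""
        df = self.polymer.copy()
        # GlcNAc sits on the reducing side of its disaccharide
        df["mono_index"] = df["disaccharide"] * 2.0 + np.where(
            df["mono"] == GLCNAC, 0.0, 1.0)
        return df.sort_values("mono_index").reset_index(drop=True)

    def to_json(self) -> str:
        return json.dumps({
            "key_residue": int(self.key_residue),
            "reducing_end": self.reducing_end,
            "polymer": self.polymer.to_dict(orient="records"),
        }, indent=1)


def _polymer_residue_table(model: StructureModel) -> pd.DataFrame:
    idx = model.atoms_of_role("polymer")
    if idx.size == 0:
        raise SelectionError("model has no chain tagged 'polymer'")
    at = model.atoms.iloc[idx]
    rows = []
    for (resid, resname), grp in at.groupby(["resid", "resname"], sort=False):
        mono = POLYMER_RESNAMES.get(str(resname).upper())
        if mono is None:
            raise CompositionError(f"unknown polymer residue name {resname!r}")
        rows.append({"resid": int(resid), "mono": mono,
                     "atom_idx": grp.index.to_numpy()})
    return pd.DataFrame(rows)


def assign_ha_numbering(model: StructureModel, coords: np.ndarray | None,
                        key_residue: int,
                        reducing_end: str | None = None) -> ResidueMap:
    """Assign signed disaccharide numbers to an alternating HA chain.

    The disaccharide whose minimum heavy-atom distance to ``key_residue``
    (a protein residue, R41 in CD44) is smallest receives index 0; indices
    decrease toward the reducing end and increase toward the non-reducing
    end.  A tie at machine precision is resolved toward the reducing end.

    Parameters
    ----------
    coords : ndarray or None
        Frame to measure distances in; defaults to the model coordinates.
    reducing_end : "first" | "last" | None
        Position of the reducing (GlcNAc) terminus in file order; inferred
        from the terminal monosaccharide types when ``None``.
    """
    if coords is None:
        coords = model.coords
    coords = np.asarray(coords, dtype=float)
    poly = _polymer_residue_table(model)
    seq = poly["mono"].tolist()
    for a, b in zip(seq, seq[1:]):
        if a == b:
            raise CompositionError(
                "polymer is not an alternating GlcUA/GlcNAc sequence")
    if len(seq) % 2 != 0:
        raise CompositionError("HA chain must contain whole disaccharides")
    if reducing_end is None:
        if seq[0] == GLCNAC and seq[-1] != GLCNAC:
            reducing_end = "first"
        elif seq[-1] == GLCNAC and seq[0] != GLCNAC:
            reducing_end = "last"
        else:
            raise CompositionError(
                "cannot infer the reducing end; pass reducing_end explicitly")
    elif reducing_end not in ("first", "last"):
        raise CompositionError(f"reducing_end must be 'first' or 'last'")
    # order residues from the reducing end outward (chemistry, not file order)
    order = np.arange(len(poly)) if reducing_end == "first" else np.arange(len(poly))[::-1]
    ordered = poly.iloc[order].reset_index(drop=True)
    if ordered["mono"].iloc[0] != GLCNAC:
        raise CompositionError("reducing terminus must be GlcNAc")
    n_disacc = len(ordered) // 2
    disacc_of_row = np.repeat(np.arange(n_disacc), 2)

    heavy = model.heavy_mask()
    key_idx = np.nonzero(
        (model.atoms["resid"].to_numpy() == key_residue)
        & np.isin(np.arange(model.n_atoms), model.atoms_of_role("protein"))
        & heavy)[0]
    if key_idx.size == 0:
        raise SelectionError(f"key residue {key_residue} not found in protein")
    key_xyz = coords[key_idx]

    dmin = np.empty(n_disacc)
    for d in range(n_disacc):
        rows = ordered.iloc[disacc_of_row == d]
        atom_idx = np.concatenate([r for r in rows["atom_idx"]])
        atom_idx = atom_idx[heavy[atom_idx]]
        diff = coords[atom_idx][:, None, :] - key_xyz[None, :, :]
        dmin[d] = np.sqrt((diff ** 2).sum(-1)).min()
    # ties resolved toward the reducing end: argmin takes the first (lowest
    # reducing-end-side ordinal) among equal minima
    zero = int(np.argmin(dmin))
    disacc_index = disacc_of_row - zero

    out = ordered[["resid", "mono"]].copy()
    out["disaccharide"] = disacc_index
    prot = model.atoms_of_role("protein")
    protein_resids = np.unique(model.atoms["resid"].to_numpy()[prot])
    return ResidueMap(polymer=out, protein_resids=protein_resids,
                      reducing_end=reducing_end, key_residue=int(key_residue))
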