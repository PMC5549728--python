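"""Contact kernels and contact statistics.

Two distinct estimators of "contact" are kept deliberately separate:

* residue-level boolean contact — a protein residue counts as bound in a
  frame when *any* of its (heavy) atoms lies within the cutoff of any
  ligand atom; binding percentages over frames and replica-averaged tables
  are built from this estimator;
* atom-pair counts — the number of (residue-atom, ligand-atom) pairs within
  the cutoff, used for per-residue contact profiles and for the
  polymer-residue x time contact contours that track a receptor's position
  along the chain.

The default cutoff is 0.6 nm on heavy atoms, with an inclusive boundary
(distance <= cutoff counts).  Distances optionally use the minimum-image
convention in orthorhombic boxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError, SelectionError
from .model_io import ResidueMap, SelectionSpec, StructureModel, \
    TrajectoryHandle

#: Sentinel for a standard error that is undefined (single replica) —
#: rendered as "N/A" in text reports.
SE_UNDEFINED = float("nan")


@dataclass(frozen=True)
class ContactParams:
    """Parameters of the contact criterion."""

    cutoff: float = 0.6          # nm
    atom_policy: str = "heavy"   # heavy | all
    periodic: bool = False
    stride: int = 1

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise DataError(f"cutoff must be > 0, got {self.cutoff}")


def _pair_distances(xa: np.ndarray, xb: np.ndarray,
                    box: np.ndarray | None) -> np.ndarray:
    """All pairwise distances between coordinate sets (nm).

    Minimum-image convention for orthorhombic boxes when ``box`` is given.
    Delegates to the MDAnalysis distance kernel.
    """
    from MDAnalysis.lib.distances import distance_array

    mdbox = None
    if box is not None:
        mdbox = np.array([*np.asarray(box, dtype=float), 90.0, 90.0, 90.0],
                         dtype=np.float32) * np.array([10, 10, 10, 1, 1, 1],
                                                      dtype=np.float32)
    # kernel works in Angstrom internally; scale to preserve precision
    d = distance_array((xa * 10).astype(np.float64),
                       (xb * 10).astype(np.float64), box=mdbox)
    return d / 10.0


def min_distance(model: StructureModel, sel_a: SelectionSpec | np.ndarray,
                 sel_b: SelectionSpec | np.ndarray, coords: np.ndarray,
                 params: ContactParams = ContactParams(),
                 box: np.ndarray | None = None) -> float:
    """Minimum pairwise distance between two selections in one frame."""
    ia = sel_a.resolve(model) if isinstance(sel_a, SelectionSpec) else np.asarray(sel_a)
    ib = sel_b.resolve(model) if isinstance(sel_b, SelectionSpec) else np.asarray(sel_b)
    if ia.size == 0 or ib.size == 0:
        raise SelectionError("empty selection in min_distance")
    use_box = box if params.periodic else None
    return float(_pair_distances(coords[ia], coords[ib], use_box).min())


@dataclass
class ResidueContactSeries:
    """Per-frame boolean contact state for a set of protein residues."""

    residues: np.ndarray          # residue numbers, shape (R,)
    contacts: np.ndarray          # bool, shape (frames, R)
    times: np.ndarray             # ps
    stride: int = 1

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts, dtype=bool)
        if self.contacts.shape != (len(self.times), len(self.residues)):
            raise SchemaError("contacts must be frames x residues")


@dataclass
class ContactCountSeries:
    """Per-frame atom-pair contact counts for a selection pair."""

    counts: np.ndarray            # int, shape (frames,)
    times: np.ndarray
    stride: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise DataError("contact counts must be >= 0")


@dataclass
class ContactContour:
    """Polymer-residue x time matrix of atom-pair contact counts."""

    mono_indices: np.ndarray      # continuous monosaccharide coordinate
    matrix: np.ndarray            # (P, frames) counts
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.mono_indices), len(self.times)):
            raise SchemaError("contour must be polymer-residues x frames")
        if np.any(self.matrix < 0):
            raise DataError("contour entries must be >= 0")

    def total_counts(self) -> ContactCountSeries:
        return ContactCountSeries(counts=self.matrix.sum(axis=0), times=self.times)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (time_ps, mono_index, count) export."""
        t, m = np.meshgrid(self.times, self.mono_indices)
        return pd.DataFrame({"time_ps": t.ravel(), "mono_index": m.ravel(),
                             "count": self.matrix.ravel()})


def _residue_atom_groups(model: StructureModel, residues: Sequence[int],
                         params: ContactParams,
                         role: str = "protein") -> list[np.ndarray]:
    """Atom-index groups per residue (possibly empty for absent residues)."""
    role_idx = model.atoms_of_role(role)
    resid_col = model.atoms["resid"].to_numpy()
    heavy = model.heavy_mask() if params.atom_policy == "heavy" else np.ones(
        model.n_atoms, dtype=bool)
    groups = []
    in_role = np.zeros(model.n_atoms, dtype=bool)
    in_role[role_idx] = True
    for r in residues:
        groups.append(np.nonzero((resid_col == r) & in_role & heavy)[0])
    return groups


def residue_contact_series(traj: TrajectoryHandle, residues: Sequence[int],
                           ligand: SelectionSpec | np.ndarray,
                           params: ContactParams = ContactParams()
                           ) -> ResidueContactSeries:
    """Boolean contact of each protein residue with the ligand per frame."""
    model = traj.model
    lig = ligand.resolve(model) if isinstance(ligand, SelectionSpec) else np.asarray(ligand)
    if lig.size == 0:
        raise SelectionError("ligand selection is empty")
    groups = _residue_atom_groups(model, residues, params)
    frames = range(0, traj.n_frames, params.stride)
    out = np.zeros((len(list(frames)), len(groups)), dtype=bool)
    times = []
    for fi, f in enumerate(range(0, traj.n_frames, params.stride)):
        coords, box = traj.get_frame(f)
        use_box = box if params.periodic else None
        lx = coords[lig]
        for gi, g in enumerate(groups):
            if g.size == 0:
                continue
            d = _pair_distances(coords[g], lx, use_box)
            out[fi, gi] = bool((d <= params.cutoff).any())
        times.append(traj.times[f])
    return ResidueContactSeries(residues=np.asarray(residues), contacts=out,
                                times=np.asarray(times), stride=params.stride)


def residue_binding_percent(series: ResidueContactSeries, residue: int) -> float:
    """Percentage of frames in which ``residue`` contacts the ligand."""
    where = np.nonzero(series.residues == residue)[0]
    if where.size == 0:
        raise KeyError(f"residue {residue} not in series")
    col = series.contacts[:, where[0]]
    if col.size == 0:
        raise DataError("series has no frames")
    return 100.0 * col.sum() / col.size


@dataclass
class BindingPercentTable:
    """Replica-aggregated binding percentages (mean +/- standard error)."""

    residues: np.ndarray
    mean: np.ndarray
    se: np.ndarray                 # NaN where undefined (single replica)
    per_replica: np.ndarray        # (n_replicas, R)
    n_replicas: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residues,
                             "binding_percent": self.mean,
                             "se": self.se})

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.to_csv(path, sep="\t", index=False, float_format="%.1f",
                  na_rep="N/A")


def _mean_se(values: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard error (sample sd / sqrt(n)); SE is NaN for n = 1."""
    values = np.asarray(values, dtype=float)
    n = values.shape[axis]
    mean = values.mean(axis=axis)
    if n <= 1:
        return mean, np.full_like(mean, SE_UNDEFINED)
    se = values.std(axis=axis, ddof=1) / math.sqrt(n)
    return mean, se


def replica_binding_table(series_list: Sequence[ResidueContactSeries]
                          ) -> BindingPercentTable:
    """Aggregate binding percentages over replicas.

    Mean over replica percentages; SE = sample standard deviation / sqrt(n)
    with n the replica count, undefined (NaN) for a single replica.
    """
    if len(series_list) == 0:
        raise SchemaError("need at least one replica")
    residues = series_list[0].residues
    for s in series_list[1:]:
        if not np.array_equal(s.residues, residues):
            raise SchemaError("replica residue sets differ")
    per = np.array([[residue_binding_percent(s, r) for r in residues]
                    for s in series_list])
    mean, se = _mean_se(per, axis=0)
    return BindingPercentTable(residues=residues, mean=mean, se=se,
                               per_replica=per, n_replicas=len(series_list))


def contact_count_series(traj: TrajectoryHandle,
                         sel_a: SelectionSpec | np.ndarray,
                         sel_b: SelectionSpec | np.ndarray,
                         params: ContactParams = ContactParams()
                         ) -> ContactCountSeries:
    """Number of atom pairs within the cutoff, per frame."""
    model = traj.model
    ia = sel_a.resolve(model) if isinstance(sel_a, SelectionSpec) else np.asarray(sel_a)
    ib = sel_b.resolve(model) if isinstance(sel_b, SelectionSpec) else np.asarray(sel_b)
    counts, times = [], []
    for f in range(0, traj.n_frames, params.stride):
        coords, box = traj.get_frame(f)
        use_box = box if params.periodic else None
        d = _pair_distances(coords[ia], coords[ib], use_box)
        counts.append(int((d <= params.cutoff).sum()))
        times.append(traj.times[f])
    return ContactCountSeries(counts=np.asarray(counts), times=np.asarray(times),
                              stride=params.stride)


def contact_count_profile(traj: TrajectoryHandle, residues: Sequence[int],
                          ligand: SelectionSpec | np.ndarray,
                          params: ContactParams = ContactParams()
                          ) -> pd.DataFrame:
    """Mean atom-pair contact count of the ligand with each residue.

    Returns a DataFrame (residue, mean_contacts); replica aggregation of
    several profiles reuses the mean/SE machinery of
    :func:`replica_binding_table` via :func:`aggregate_profiles`.
    """
    model = traj.model
    lig = ligand.resolve(model) if isinstance(ligand, SelectionSpec) else np.asarray(ligand)
    groups = _residue_atom_groups(model, residues, params)
    if all(g.size == 0 for g in groups):
        raise SelectionError("no atoms found for any requested residue")
    totals = np.zeros(len(groups))
    n_frames = 0
    for f in range(0, traj.n_frames, params.stride):
        coords, box = traj.get_frame(f)
        use_box = box if params.periodic else None
        lx = coords[lig]
        for gi, g in enumerate(groups):
            if g.size == 0:
                continue
            d = _pair_distances(coords[g], lx, use_box)
            totals[gi] += (d <= params.cutoff).sum()
        n_frames += 1
    return pd.DataFrame({"residue": np.asarray(residues),
                         "mean_contacts": totals / n_frames})


def aggregate_profiles(profiles: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Replica mean +/- SE of per-residue contact profiles."""
    res = profiles[0]["residue"].to_numpy()
    for p in profiles[1:]:
        if not np.array_equal(p["residue"].to_numpy(), res):
            raise SchemaError("profile residue sets differ")
    vals = np.array([p["mean_contacts"].to_numpy() for p in profiles])
    mean, se = _mean_se(vals, axis=0)
    return pd.DataFrame({"residue": res, "mean_contacts": mean, "se": se})


def contact_contour(traj: TrajectoryHandle, residue_map: ResidueMap,
                    protein: SelectionSpec | np.ndarray,
                    params: ContactParams = ContactParams()) -> ContactContour:
    """Atom-pair contact counts between each polymer residue and the protein
    selection, resolved in time (the receptor-tracking contour)."""
    model = traj.model
    prot = protein.resolve(model) if isinstance(protein, SelectionSpec) else np.asarray(protein)
    mono = residue_map.monosaccharide_positions()
    resid_col = model.atoms["resid"].to_numpy()
    heavy = model.heavy_mask() if params.atom_policy == "heavy" else np.ones(
        model.n_atoms, dtype=bool)
    poly_role = np.zeros(model.n_atoms, dtype=bool)
    poly_role[model.atoms_of_role("polymer")] = True
    groups = [np.nonzero((resid_col == r) & poly_role & heavy)[0]
              for r in mono["resid"]]
    frames = list(range(0, traj.n_frames, params.stride))
    mat = np.zeros((len(groups), len(frames)), dtype=int)
    times = []
    for fi, f in enumerate(frames):
        coords, box = traj.get_frame(f)
        use_box = box if params.periodic else None
        px = coords[prot]
        for gi, g in enumerate(groups):
            d = _pair_distances(coords[g], px, use_box)
            mat[gi, fi] = int((d <= params.cutoff).sum())
        times.append(traj.times[f])
    return ContactContour(mono_indices=mono["mono_index"].to_numpy(),
                          matrix=mat, times=np.asarray(times))


# --------------------------------------------------------------------------
# hydrogen bonds
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion.

    Donor-acceptor distance <= ``distance`` nm and, when an explicit
    hydrogen is attached to the donor, donor-H-acceptor angle >=
    ``angle`` degrees.
    """

    distance: float = 0.35
    angle: float = 150.0


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int | None
    acceptor: int
    distance: float
    angle: float | None
    frame: int


def hydrogen_bonds(model: StructureModel, coords: np.ndarray,
                   donors: np.ndarray, acceptors: np.ndarray,
                   criteria: HBondCriteria = HBondCriteria(),
                   hydrogens: Mapping[int, Sequence[int]] | None = None,
                   box: np.ndarray | None = None,
                   frame: int = 0) -> list[HBond]:
    """All donor-acceptor pairs satisfying the geometric criterion.

    ``hydrogens`` maps donor atom index -> indices of its bonded hydrogens;
    when a donor has hydrogens, at least one D-H...A angle must pass.
    """
    donors = np.asarray(donors)
    acceptors = np.asarray(acceptors)
    if donors.size == 0 or acceptors.size == 0:
        return []
    d = _pair_distances(coords[donors], coords[acceptors], box)
    out: list[HBond] = []
    for i, di in enumerate(donors):
        for j, aj in enumerate(acceptors):
            if di == aj or d[i, j] > criteria.distance:
                continue
            hyds = list(hydrogens.get(int(di), [])) if hydrogens else []
            if not hyds:
                out.append(HBond(int(di), None, int(aj), float(d[i, j]),
                                 None, frame))
                continue
            best = None
            for h in hyds:
                v1 = coords[di] - coords[h]
                v2 = coords[aj] - coords[h]
                cosang = float(np.dot(v1, v2)
                               / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                if ang >= criteria.angle and (best is None or ang > best[1]):
                    best = (h, ang)
            if best is not None:
                out.append(HBond(int(di), int(best[0]), int(aj),
                                 float(d[i, j]), float(best[1]), frame))
    return out
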