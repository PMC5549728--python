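"""Binding-mode fingerprinting, classification and A/B-form assignment.

Hyaluronan can sit on the CD44 HA-binding domain in three mutually
exclusive, topographically distinct arrangements: the crystallographic
groove mode, a parallel mode lower on the groove face, and an upright mode
perpendicular to the groove.  Each mode leaves a characteristic pattern of
per-residue contact percentages over a reference set of 39 literature
binding residues — its fingerprint.  Classification compares an observed
fingerprint against the packaged reference fingerprints by cosine
similarity: magnitudes vary between runs, the pattern is the signature.

The crystallographic complex additionally exists in two conformations of
the key arginine (R41): in the A-form the side chain points away from the
ligand, in the B-form it flips toward it and hydrogen-bonds the bound HA.
The backbone phi dihedral of the adjacent tyrosine (Y42) acts as the
bistable switch between the two.  A frame is assigned the B-form only when
phi lies in the B basin *and* at least one R41 side-chain hydrogen bond to
the ligand is present; everything else is the A-form.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import (
    ContactParams,
    HBondCriteria,
    hydrogen_bonds,
    residue_binding_percent,
    residue_contact_series,
)
from .errors import DataError, SchemaError, TopologyError
from .model_io import SelectionSpec, StructureModel, TrajectoryHandle

MODES = ("crystallographic", "parallel", "upright")

_REFERENCE_CACHE: pd.DataFrame | None = None


def reference_table() -> pd.DataFrame:
    """The packaged reference fingerprint table (39 residues x 3 modes)."""
    global _REFERENCE_CACHE
    if _REFERENCE_CACHE is None:
        with resources.files("habind.data").joinpath(
                "reference_fingerprints.tsv").open() as fh:
            _REFERENCE_CACHE = pd.read_csv(fh, sep="\t", comment="#")
    return _REFERENCE_CACHE.copy()


def reference_residues() -> np.ndarray:
    """Canonical residue numbers of the reference fingerprint set."""
    return reference_table()["resid"].to_numpy()


@dataclass
class FingerprintVector:
    """Per-residue binding percentages over a trajectory window."""

    residues: np.ndarray
    values: np.ndarray            # percent, same order as residues
    n_frames: int = 0
    window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.residues.shape:
            raise SchemaError("fingerprint values/residues length mismatch")
        if np.any((self.values < 0) | (self.values > 100)):
            raise DataError("fingerprint percentages must lie in [0, 100]")


@dataclass
class ReferenceFingerprints:
    """One reference fingerprint per binding mode."""

    residues: np.ndarray
    columns: dict[str, np.ndarray]

    @classmethod
    def from_package_data(cls) -> "ReferenceFingerprints":
        df = reference_table()
        return cls(residues=df["resid"].to_numpy(),
                   columns={m: df[m].to_numpy() for m in MODES})

    def vector(self, mode: str) -> FingerprintVector:
        return FingerprintVector(residues=self.residues,
                                 values=self.columns[mode])


@dataclass
class ModeAssignment:
    """Result of classifying one fingerprint window."""

    label: str                    # mode name, "unbound" or "ambiguous"
    similarities: dict[str, float]
    window: tuple[int, int] | None = None


def fingerprint(traj: TrajectoryHandle,
                ligand: SelectionSpec | np.ndarray,
                window: tuple[int, int] | None = None,
                params: ContactParams = ContactParams(),
                residues: Sequence[int] | None = None) -> FingerprintVector:
    """Binding percentage of each reference residue over a frame window.

    ``window`` is a half-open frame range (start, stop); residues absent
    from the model (e.g. unmapped pseudo-residues of a toy system) score 0.
    """
    if residues is None:
        residues = reference_residues()
    start, stop = window if window is not None else (0, traj.n_frames)
    if not (0 <= start < stop <= traj.n_frames):
        raise IndexError(f"window {window} outside trajectory of "
                         f"{traj.n_frames} frames")
    sub = _WindowView(traj, start, stop)
    series = residue_contact_series(sub, residues, ligand, params)
    values = np.array([residue_binding_percent(series, r) for r in residues])
    return FingerprintVector(residues=np.asarray(residues), values=values,
                             n_frames=stop - start, window=(start, stop))


class _WindowView(TrajectoryHandle):
    """Zero-copy frame-window view of another trajectory."""

    def __init__(self, base: TrajectoryHandle, start: int, stop: int) -> None:
        self._base = base
        self._start = start
        self.model = base.model
        self.times = base.times[start:stop]
        self.stride = base.stride

    def get_frame(self, i: int):
        return self._base.get_frame(self._start + i)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def classify(fp: FingerprintVector,
             refs: ReferenceFingerprints | None = None,
             threshold: float = 0.80) -> ModeAssignment:
    """Assign a binding-mode label to a fingerprint.

    Cosine similarity against each reference mode; the best mode wins when
    its similarity reaches ``threshold``, otherwise the window is
    ``ambiguous``.  An all-zero fingerprint (no residue ever in contact) is
    ``unbound``.
    """
    if refs is None:
        refs = ReferenceFingerprints.from_package_data()
    if not np.array_equal(fp.residues, refs.residues):
        raise SchemaError("fingerprint and reference residue orders differ")
    if np.all(fp.values == 0):
        return ModeAssignment(label="unbound",
                              similarities={m: 0.0 for m in refs.columns},
                              window=fp.window)
    sims = {m: cosine_similarity(fp.values, col)
            for m, col in refs.columns.items()}
    best = max(sims, key=sims.get)
    label = best if sims[best] >= threshold else "ambiguous"
    return ModeAssignment(label=label, similarities=sims, window=fp.window)


def detect_transitions(assignments: Sequence[ModeAssignment],
                       min_segment: int = 5) -> list[tuple[tuple[int, int], str]]:
    """Run-length segments of mode labels with flicker suppression.

    Runs shorter than ``min_segment`` windows are absorbed into the
    preceding segment (or the following one at the start of the series).
    Returns ((start_window, stop_window), label) pairs, half-open.
    """
    labels = [a.label for a in assignments]
    if not labels:
        return []
    runs: list[list] = []
    for i, lab in enumerate(labels):
        if runs and runs[-1][2] == lab:
            runs[-1][1] = i + 1
        else:
            runs.append([i, i + 1, lab])
    # absorb short runs
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for k, (s, e, lab) in enumerate(runs):
            if e - s < min_segment:
                if k > 0:
                    runs[k - 1][1] = e
                else:
                    runs[1][0] = s
                del runs[k]
                # merge neighbours that now share a label
                merged = [runs[0]]
                for r in runs[1:]:
                    if r[2] == merged[-1][2]:
                        merged[-1][1] = r[1]
                    else:
                        merged.append(r)
                runs = merged
                changed = True
                break
    return [((s, e), lab) for s, e, lab in runs]


# --------------------------------------------------------------------------
# A/B-form assignment
# --------------------------------------------------------------------------

@dataclass
class FormState:
    """Per-frame A/B conformation of the crystallographic complex."""

    frame: int
    state: str                    # "A" or "B"
    phi: float                    # Y42 backbone phi, degrees
    r41_hbonds: int


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle (degrees, IUPAC sign) of four points."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(b1 / np.linalg.norm(b1), n1)
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


@dataclass(frozen=True)
class PhiBasins:
    """Phi-dihedral basin boundaries for the bistable Y42 switch.

    Default: a sign split — B basin [-180, 0), A basin [0, 180).
    """

    b_low: float = -180.0
    b_high: float = 0.0

    def in_b(self, phi: float) -> bool:
        return self.b_low <= phi < self.b_high


def _backbone_atom(model: StructureModel, resid: int, name: str) -> int:
    at = model.atoms
    prot = np.zeros(model.n_atoms, dtype=bool)
    prot[model.atoms_of_role("protein")] = True
    hits = np.nonzero((at["resid"].to_numpy() == resid)
                      & (at["name"].str.strip().str.upper() == name).to_numpy()
                      & prot)[0]
    if hits.size == 0:
        raise TopologyError(f"missing backbone atom {name} in residue {resid}")
    return int(hits[0])


def ab_form(traj: TrajectoryHandle,
            ligand: SelectionSpec | np.ndarray,
            window: tuple[int, int] | None = None,
            key_residue: int = 41,
            switch_residue: int = 42,
            basins: PhiBasins = PhiBasins(),
            hbond_criteria: HBondCriteria = HBondCriteria(),
            sidechain_donor_names: Sequence[str] = ("NE", "NH1", "NH2"),
            acceptor_elements: Sequence[str] = ("O", "N")) -> list[FormState]:
    """Assign the A or B form per frame.

    phi(Y42) is computed from C(41)-N(42)-CA(42)-C(42); a frame is B iff
    phi lies in the B basin *and* the R41 side chain donates at least one
    hydrogen bond to the ligand.
    """
    model = traj.model
    c_prev = _backbone_atom(model, key_residue, "C")
    n = _backbone_atom(model, switch_residue, "N")
    ca = _backbone_atom(model, switch_residue, "CA")
    c = _backbone_atom(model, switch_residue, "C")
    at = model.atoms
    donors = np.nonzero(
        (at["resid"].to_numpy() == key_residue)
        & at["name"].str.strip().str.upper().isin(
            [s.upper() for s in sidechain_donor_names]).to_numpy())[0]
    lig = ligand.resolve(model) if isinstance(ligand, SelectionSpec) else np.asarray(ligand)
    acceptors = lig[np.isin(at["element"].to_numpy()[lig],
                            [e.upper() for e in acceptor_elements])]
    start, stop = window if window is not None else (0, traj.n_frames)
    out: list[FormState] = []
    for f in range(start, stop):
        coords, box = traj.get_frame(f)
        phi = dihedral(coords[c_prev], coords[n], coords[ca], coords[c])
        hb = hydrogen_bonds(model, coords, donors, acceptors,
                            criteria=hbond_criteria, box=None, frame=f)
        state = "B" if (basins.in_b(phi) and len(hb) >= 1) else "A"
        out.append(FormState(frame=f, state=state, phi=phi, r41_hbonds=len(hb)))
    return out
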