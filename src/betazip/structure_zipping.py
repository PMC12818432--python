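"""Beta-sheet zipping geometry on multi-model coordinate ensembles.

The alternative "zipped"/"unzipped" conformations of the SH2 central
beta-sheet are distinguished by the backbone amide-to-carbonyl distance
between the residue pair at the end of strands betaC/betaD (Phe41 N -
Ile56 O in SHP2 N-SH2): around 3 A the strands are hydrogen bonded
(zipped); beyond 3.4 A hydrogen bonding is precluded (unzipped).  The
Tyr66 OH - Asp40 carboxylate contact is classified separately, with a
short-hydrogen-bond category below 2.7 A.

Distances use a donor-acceptor criterion only (no angles); for a
carboxylate acceptor the nearer of the two oxygens is taken per model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

ZIP_THRESHOLD_A = 3.4      # boundary inclusive: d <= 3.4 A is zipped
SHB_THRESHOLD_A = 2.7      # short hydrogen bond
HBOND_THRESHOLD_A = 3.5    # ordinary hydrogen bond


@dataclass(frozen=True)
class AtomSpec:
    """Chain / residue number / atom name(s) resolving to one atom per model.

    `atom_name` may be a tuple of candidate names (e.g. ("OD1", "OD2") for
    a carboxylate); the candidate nearest to the partner atom is used in
    each model.
    """

    chain: str
    res_num: int
    atom_name: object

    @property
    def names(self) -> tuple:
        if isinstance(self.atom_name, str):
            return (self.atom_name,)
        return tuple(self.atom_name)

    def __str__(self):
        return f"{self.chain}/{self.res_num}/{'|'.join(self.names)}"


@dataclass
class CoordinateEnsemble:
    """Multi-model atomic coordinates keyed by (chain, res_num, atom_name)."""

    models: list            # list of dict key -> xyz ndarray (A)
    source: str = ""

    @property
    def n_models(self) -> int:
        return len(self.models)

    def coords(self, model_index: int, spec: AtomSpec,
               name: str | None = None) -> np.ndarray:
        names = (name,) if name else spec.names
        model = self.models[model_index]
        for nm in names:
            key = (spec.chain, spec.res_num, nm)
            if key in model:
                return model[key]
        raise KeyError(
            f"atom {spec} not found in model {model_index + 1}")


def read_coordinate_ensemble(path) -> CoordinateEnsemble:
    """Parse a (multi-MODEL) PDB file into a CoordinateEnsemble.

    Alternate locations are resolved to the highest-occupancy copy (ties
    broken alphabetically by altloc), with a warning.  A warning is also
    emitted when models differ in atom count.
    """
    import gemmi

    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as err:
        raise ValueError(f"cannot parse PDB file {path}: {err}") from err
    models = []
    saw_altloc = False
    for model in st:
        atoms = {}
        for chain in model:
            for res in chain:
                for atom in res:
                    key = (chain.name, res.seqid.num, atom.name)
                    if key in atoms:
                        saw_altloc = True
                        prev = atoms[key]
                        if atom.occ > prev[1] or (
                                atom.occ == prev[1]
                                and atom.altloc < prev[2]):
                            atoms[key] = (
                                np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                                atom.occ, atom.altloc)
                    else:
                        atoms[key] = (
                            np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            atom.occ, atom.altloc)
        models.append({k: v[0] for k, v in atoms.items()})
    if not models or all(len(m) == 0 for m in models):
        raise ValueError(f"no atomic coordinates found in {path}")
    if saw_altloc:
        warnings.warn(f"{path}: alternate locations resolved to highest "
                      "occupancy")
    counts = {len(m) for m in models}
    if len(counts) > 1:
        warnings.warn(f"{path}: atom count differs between models ({counts})")
    return CoordinateEnsemble(models=models, source=str(path))


@dataclass
class DistanceSeries:
    distances: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    @property
    def min(self) -> float:
        return float(self.distances.min())

    @property
    def max(self) -> float:
        return float(self.distances.max())


def ensemble_atom_distance(ensemble: CoordinateEnsemble, a: AtomSpec,
                           b: AtomSpec) -> DistanceSeries:
    """Euclidean distance between two atoms in every model (Angstrom).

    When either spec lists candidate atom names, the per-model distance is
    the minimum over candidates (nearer carboxylate oxygen rule).
    """
    out = np.empty(ensemble.n_models)
    for i in range(ensemble.n_models):
        best = np.inf
        for na in a.names:
            for nb in b.names:
                xa = ensemble.coords(i, a, na)
                xb = ensemble.coords(i, b, nb)
                best = min(best, float(np.linalg.norm(xa - xb)))
        out[i] = best
    return DistanceSeries(distances=out)


def classify_zipping(distance_a: float) -> str:
    """'zipped' when the strand contact is hydrogen-bond capable (<= 3.4 A)."""
    if distance_a <= 0.0:
        raise ValueError("distance must be positive")
    return "zipped" if distance_a <= ZIP_THRESHOLD_A else "unzipped"


def hydrogen_bond_class(donor_acceptor_distance_a: float) -> str:
    """'short_hbond' (<= 2.7 A), 'hbond' (<= 3.5 A) or 'none'."""
    d = donor_acceptor_distance_a
    if d <= 0.0:
        raise ValueError("distance must be positive")
    if d <= SHB_THRESHOLD_A:
        return "short_hbond"
    if d <= HBOND_THRESHOLD_A:
        return "hbond"
    return "none"


def survey_zipping(files: Sequence, mapping: Mapping):
    """Classify the zip distance in every model of every file.

    `mapping` assigns each file a pair of AtomSpecs (homologous to the
    strand-end amide nitrogen and carbonyl oxygen).  Files whose atoms
    cannot be resolved are reported in the skip list rather than aborting
    the survey.

    Returns ``(table, counts, skipped)``: a DataFrame with one row per
    model (file, model, distance_A, class), per-class counts, and the list
    of skipped files with reasons.
    """
    import pandas as pd

    rows = []
    skipped = []
    for path in files:
        spec_pair = mapping[path]
        try:
            ens = read_coordinate_ensemble(path)
            dist = ensemble_atom_distance(ens, spec_pair[0], spec_pair[1])
        except (ValueError, KeyError) as err:
            skipped.append((str(path), str(err)))
            continue
        for i, d in enumerate(dist.distances):
            rows.append((str(path), i + 1, float(d), classify_zipping(d)))
    table = pd.DataFrame(rows, columns=["file", "model", "distance_A",
                                        "class"])
    counts = table["class"].value_counts().to_dict() if len(table) else {}
    counts = {"zipped": counts.get("zipped", 0),
              "unzipped": counts.get("unzipped", 0)}
    return table, counts, skipped
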