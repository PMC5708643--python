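"""Load cases and boundary conditions for the molar-region models.

Three load cases are modelled on the loaded (first molar) tooth:

* ``occlusal`` - a bite force (default 500 N, a maximal human bite) spread
  over a small patch at the centre of the occlusal surface, directed
  corono-apically (-z).  The mesial and distal crown surfaces are held in
  the mesiodistal direction to represent contact with the neighbouring
  teeth.
* ``orth_mesiodistal`` - a small orthodontic force (default 1 N) on the
  buccal crown surface directed distal -> mesial (-y).
* ``orth_buccolingual`` - the same magnitude directed buccal -> lingual (-x).

Shared constraints: the mesial and distal cut faces of the corpus are held
in the mesiodistal direction (the continuity of the mandible), and a small
patch at the base of each cut face is fully fixed to remove rigid-body
motion.  The crown contact constraints are removed for the orthodontic
cases, where the tooth may tilt.

Note the occlusal default deliberately represents a *maximal* bite force;
absolute strains therefore exceed everyday loading and only comparisons
between model variants should be interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import ConstraintSet
from .meshdata import LabeledMesh

__all__ = ["LOAD_CASES", "LoadCase", "build_constraints", "build_load"]

LOAD_CASES = ("occlusal", "orth_mesiodistal", "orth_buccolingual")

_CASE_DEF = {
    # name: (default force N, unit direction, crown patch set)
    "occlusal": (500.0, np.array([0.0, 0.0, -1.0]), "occlusal_patch"),
    "orth_mesiodistal": (1.0, np.array([0.0, -1.0, 0.0]), "buccal_patch"),
    "orth_buccolingual": (1.0, np.array([-1.0, 0.0, 0.0]), "buccal_patch"),
}


@dataclass
class LoadCase:
    name: str
    total_force: float
    direction: np.ndarray
    patch_nodes: np.ndarray
    weights: np.ndarray          # per-node weights, sum to 1
    constraints: ConstraintSet

    def force_vector(self, n_nodes: int) -> np.ndarray:
        f = np.zeros(3 * n_nodes)
        for c in range(3):
            np.add.at(f, 3 * self.patch_nodes + c,
                      self.total_force * self.direction[c] * self.weights)
        return f


def build_constraints(mesh: LabeledMesh, name: str) -> ConstraintSet:
    """Constraint set of a load case (see module docstring)."""
    if name not in _CASE_DEF:
        raise ValueError(f"unknown load case {name!r}; expected one of {LOAD_CASES}")
    for req in ("cut_mesial", "cut_distal", "base_mesial", "base_distal"):
        if len(mesh.set_nodes(req)) == 0:
            raise ValueError(f"required node set {req!r} is empty")
    cuts = np.concatenate([mesh.set_nodes("cut_mesial"), mesh.set_nodes("cut_distal")])
    base = np.concatenate([mesh.set_nodes("base_mesial"), mesh.set_nodes("base_distal")])
    cs = ConstraintSet.from_nodes(cuts, [1]).merge(ConstraintSet.from_nodes(base, [0, 1, 2]))
    if name == "occlusal":
        contact = np.concatenate(
            [mesh.set_nodes("contact_mesial"), mesh.set_nodes("contact_distal")])
        cs = cs.merge(ConstraintSet.from_nodes(contact, [1]))
    return cs


def build_load(mesh: LabeledMesh, name: str, total_force: float | None = None) -> LoadCase:
    """Load case with equal nodal weights over the crown patch."""
    if name not in _CASE_DEF:
        raise ValueError(f"unknown load case {name!r}; expected one of {LOAD_CASES}")
    default_force, direction, patch_name = _CASE_DEF[name]
    patch = mesh.set_nodes(patch_name)
    if len(patch) == 0:
        raise ValueError(f"load patch {patch_name!r} is empty")
    weights = np.full(len(patch), 1.0 / len(patch))
    return LoadCase(
        name=name,
        total_force=float(total_force if total_force is not None else default_force),
        direction=direction,
        patch_nodes=patch,
        weights=weights,
        constraints=build_constraints(mesh, name),
    )
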