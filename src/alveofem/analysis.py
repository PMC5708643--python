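"""Comparison surfaces: strain profiles, difference fields and summaries.

Occlusal results are compared along vertical profiles of nodal principal
strains on the outer buccal and lingual cortical surfaces, taken in the
buccolingual plane through the centre of the occlusal load and ordered from
the alveolar crest down to the inferior border.  Orthodontic results are
compared along the inner (socket) surface of the alveolar bone adjacent to
the PDL, on a plane through the root apex, ordered crest -> apex.

Pairs of variants are compared element-wise by subtracting strains
(difference fields, antisymmetric by construction) and by summary ratios.
Strains are reported in microstrain; "peak" means the 95th percentile of
|strain| over a profile (robust to single-node concentrations), with the
maximum also reported.  Nodal values use superconvergent patch recovery
restricted to bone materials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fem import Solution, nodal_strains_spr, principal_strains
from .meshdata import InterfaceSets, LabeledMesh, median_edge_length
from .variants import crown_displacement

__all__ = [
    "StrainProfile", "DifferenceField",
    "vertical_profile", "socket_profile", "difference_field", "summarise",
]

MICRO = 1e6


@dataclass
class StrainProfile:
    """Ordered strain samples along a surface cut (positions in mm, strains in microstrain)."""

    positions: np.ndarray     # arc position from the superior-most sample
    e1: np.ndarray            # maximum (tensile) principal strain
    e3: np.ndarray            # minimum (compressive) principal strain
    nodes: np.ndarray
    surface: str
    plane: str

    def __len__(self):
        return len(self.positions)

    def peak(self, component: str = "e3", q: float = 95.0) -> float:
        return float(np.percentile(np.abs(getattr(self, component)), q))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position_mm": self.positions, "e1_ue": self.e1, "e3_ue": self.e3,
            "node": self.nodes, "surface": self.surface,
        })


def _bone_nodal_principals(mesh: LabeledMesh, solution: Solution,
                           labels=("cortical", "trabecular_bone")):
    vals, mask = nodal_strains_spr(mesh, solution.u, labels)
    pr = principal_strains(vals)
    return pr, mask


def _profile_from_nodes(mesh, nodes, pr, surface, plane) -> StrainProfile:
    # callers pass nodes ordered superior -> inferior with the on-plane node
    # first at each height; keep one sample per height
    z = mesh.nodes[nodes, 2]
    keep = np.concatenate([[True], np.abs(np.diff(z)) > 1e-9])
    nodes = nodes[keep]
    pts = mesh.nodes[nodes]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    positions = np.concatenate([[0.0], np.cumsum(seg)])
    return StrainProfile(
        positions=positions,
        e1=pr[nodes, 0] * MICRO, e3=pr[nodes, 2] * MICRO,
        nodes=nodes, surface=surface, plane=plane,
    )


def vertical_profile(mesh: LabeledMesh, solution: Solution, side: str,
                     plane_y: float | None = None,
                     tol: float | None = None) -> StrainProfile:
    """Nodal principal strains down the outer cortical surface.

    Samples the outer ``buccal`` or ``lingual`` surface along the
    buccolingual plane through the occlusal load centre, ordered
    superior -> inferior.
    """
    if side not in ("buccal", "lingual"):
        raise ValueError("side must be 'buccal' or 'lingual'")
    if plane_y is None:
        plane_y = mesh.meta["tooth_centres"][mesh.meta["loaded_tooth"]][1]
    if tol is None:
        tol = 0.5 * median_edge_length(mesh)
    pr, mask = _bone_nodal_principals(mesh, solution, ("cortical",))
    surf = mesh.set_nodes(f"outer_{side}")
    sel = surf[(np.abs(mesh.nodes[surf, 1] - plane_y) <= tol) & mask[surf]]
    # prefer the nodes nearest the plane at each height
    sel = sel[np.lexsort((np.abs(mesh.nodes[sel, 1] - plane_y), -mesh.nodes[sel, 2]))]
    if len(np.unique(mesh.nodes[sel, 2])) < 5:
        raise ValueError(
            f"fewer than 5 profile nodes on the {side} surface at y={plane_y}; "
            "increase the plane tolerance")
    return _profile_from_nodes(mesh, sel, pr, side, f"y={plane_y:.3f}")


def socket_profile(mesh: LabeledMesh, solution: Solution,
                   interfaces: InterfaceSets, side: str,
                   tooth: int | None = None,
                   tol: float | None = None) -> StrainProfile:
    """Nodal principal strains down the socket wall (bone adjacent to the PDL).

    ``side`` selects the mesial/distal (plane through the tooth axis,
    buccolingual normal) or buccal/lingual half of the bone-side interface,
    on the plane through the root apex, ordered crest -> apex.
    """
    sides = {"mesial": (1, -1), "distal": (1, +1), "lingual": (0, -1), "buccal": (0, +1)}
    if side not in sides:
        raise ValueError(f"side must be one of {sorted(sides)}")
    if tooth is None:
        tooth = mesh.meta.get("loaded_tooth", 0)
    if tol is None:
        tol = 0.5 * median_edge_length(mesh)
    axis, sign = sides[side]
    # the profile plane contains the socket axis: for buccal/lingual profiles
    # it is the plane y = y_apex, for mesial/distal the plane x = x_apex
    plane_axis = 1 - axis
    iface = interfaces[tooth]
    apex = iface.apex
    pr, mask = _bone_nodal_principals(mesh, solution, ("cortical", "trabecular_bone"))
    nodes = iface.bone_nodes
    pts = mesh.nodes[nodes]
    on_plane = np.abs(pts[:, plane_axis] - apex[plane_axis]) <= tol
    correct_side = sign * (pts[:, axis] - apex[axis]) > tol
    sel = nodes[on_plane & correct_side & mask[nodes]]
    if len(np.unique(mesh.nodes[sel, 2])) < 5:
        raise ValueError(
            f"fewer than 5 socket-profile nodes on the {side} side; "
            "increase the plane tolerance")
    sel = sel[np.lexsort((np.abs(mesh.nodes[sel, plane_axis] - apex[plane_axis]),
                          -mesh.nodes[sel, 2]))]
    return _profile_from_nodes(mesh, sel, pr, f"socket-{side}",
                               f"{'xy'[plane_axis]}={apex[plane_axis]:.3f}")


@dataclass
class DifferenceField:
    """Element-wise principal-strain differences, variant A minus variant B.

    Sign convention as in the source comparisons: for the maximum principal
    strain a negative difference means tension is higher in B; for the
    minimum principal strain a negative difference means compression is
    higher in A (more negative e3 in A).
    """

    d_e1: np.ndarray   # microstrain
    d_e3: np.ndarray
    pair: tuple[str, str]


def difference_field(sol_a: Solution, sol_b: Solution,
                     pair: tuple[str, str] = ("A", "B")) -> DifferenceField:
    if sol_a.elem_strain.shape != sol_b.elem_strain.shape:
        raise ValueError("difference fields require solutions on the same mesh")
    pa = principal_strains(sol_a.elem_strain)
    pb = principal_strains(sol_b.elem_strain)
    return DifferenceField(
        d_e1=(pa[:, 0] - pb[:, 0]) * MICRO,
        d_e3=(pa[:, 2] - pb[:, 2]) * MICRO,
        pair=pair,
    )


def summarise(mesh: LabeledMesh, interfaces: InterfaceSets,
              solutions: dict, cases: dict) -> pd.DataFrame:
    """Per-(variant, load case) summary table.

    ``solutions`` maps (variant_id, case_name) to a Solution; ``cases`` maps
    case names to LoadCase objects.  For the occlusal case the summary
    covers the outer cortical profiles, for orthodontic cases the socket
    profiles on the two sides transverse to the load.
    """
    rows = []
    for (vid, cname), sol in solutions.items():
        case = cases[cname]
        row = {"variant": vid, "case": cname,
               "crown_displacement_mm": crown_displacement(mesh, case, sol)}
        if cname == "occlusal":
            profs = [vertical_profile(mesh, sol, s) for s in ("buccal", "lingual")]
        elif cname == "orth_mesiodistal":
            profs = [socket_profile(mesh, sol, interfaces, s) for s in ("mesial", "distal")]
        else:
            profs = [socket_profile(mesh, sol, interfaces, s) for s in ("buccal", "lingual")]
        for prof in profs:
            for comp in ("e1", "e3"):
                v = np.abs(getattr(prof, comp))
                tag = f"{prof.surface}_{comp}"
                row[f"{tag}_peak_ue"] = float(np.percentile(v, 95))
                row[f"{tag}_max_ue"] = float(v.max())
                row[f"{tag}_median_ue"] = float(np.median(v))
        rows.append(row)
    df = pd.DataFrame(rows).set_index(["variant", "case"]).sort_index()
    return df
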