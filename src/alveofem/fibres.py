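"""Crossed tension-only fibre network of the periodontal ligament.

The PDL's collagen fibre bundles are represented by discrete two-node
tension-only bar elements that span the PDL layer, connecting nodes on the
alveolar-bone side of the PDL interface to nodes on the tooth-root side.
Every selected bone-side node spawns a crossed pair of fibres, one inclined
apically and one coronally, mimicking the criss-cross arrangement of the
real fibre meshwork; the pair members reference each other as cross
partners.  Fibres are grouped by normalised socket depth into the four
anatomical groups: crestal, horizontal, oblique and apical.

Fibre cross-sections are sized so the network realises a prescribed fibre
volume fraction of the PDL (collagen occupies roughly 50-75 % of the
tissue): the crossed pair at a bone-side node with tributary interface area
a_i gets A = phi * a_i / 2 per fibre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .meshdata import InterfaceSets, LabeledMesh, ToothInterface

__all__ = [
    "FIBRE_GROUPS", "FibreNetworkParams", "FibreSet",
    "assign_fibre_groups", "build_fibre_network", "fibre_area",
]

FIBRE_GROUPS = ("crestal", "horizontal", "oblique", "apical")


@dataclass(frozen=True)
class FibreNetworkParams:
    """Parameters of the PDL fibre network.

    ``band_splits`` partition the normalised socket depth s in [0, 1]
    (0 = alveolar crest, 1 = root apex) into the four anatomical groups;
    angles are inclinations from the interface normal towards the apex,
    in degrees.  The fibre Poisson ratio is recorded for completeness but
    has no effect on axial-only elements.
    """

    volume_fraction: float = 0.60
    band_splits: tuple[float, float, float] = (0.10, 0.25, 0.90)
    crestal_angle: float = 30.0
    oblique_angle: float = 45.0
    apical_spread: float = 20.0   # half-angle of the crossed pair at the apex
    search_cone: float = 20.0     # half-angle of the root-node search cone
    max_length: float = 2.0       # longest admissible fibre (mm): keeps fibres
                                  # local to the PDL gap, never across the root
    E: float = 1000.0
    nu: float = 0.35
    seed: int = 1

    def validate(self):
        if not 0.0 <= self.volume_fraction < 1.0:
            raise ValueError("fibre volume fraction must lie in [0, 1)")
        s = self.band_splits
        if not (0.0 < s[0] < s[1] < s[2] < 1.0):
            raise ValueError("band_splits must be strictly increasing within (0, 1)")
        for name in ("crestal_angle", "oblique_angle"):
            if not 0.0 <= getattr(self, name) < 90.0:
                raise ValueError(f"{name} must lie in [0, 90) degrees")


@dataclass
class FibreSet:
    """Arrays describing a set of tension-only PDL fibres."""

    bone_node: np.ndarray
    root_node: np.ndarray
    area: np.ndarray          # mm^2
    group: np.ndarray         # codes into FIBRE_GROUPS
    partner: np.ndarray       # index of the cross partner within this set
    E: float
    nu: float
    tooth: int
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.bone_node)

    def rest_lengths(self, mesh: LabeledMesh) -> np.ndarray:
        d = mesh.nodes[self.root_node] - mesh.nodes[self.bone_node]
        return np.linalg.norm(d, axis=1)

    def to_dataframe(self, mesh: LabeledMesh) -> pd.DataFrame:
        xa = mesh.nodes[self.bone_node]
        xb = mesh.nodes[self.root_node]
        return pd.DataFrame({
            "bone_node": self.bone_node, "root_node": self.root_node,
            "xa": xa[:, 0], "ya": xa[:, 1], "za": xa[:, 2],
            "xb": xb[:, 0], "yb": xb[:, 1], "zb": xb[:, 2],
            "group": np.asarray(FIBRE_GROUPS, dtype=object)[self.group],
            "area_mm2": self.area, "L0_mm": self.rest_lengths(mesh),
            "partner": self.partner,
        })

    def scaled(self, volume_fraction_ratio: float) -> "FibreSet":
        return replace(self, area=self.area * volume_fraction_ratio)


def assign_fibre_groups(s, band_splits=(0.10, 0.25, 0.90)):
    """Group index from normalised socket depth (0 = crest, 1 = apex)."""
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("normalised socket depth must lie in [0, 1]")
    return np.digitize(s, band_splits).astype(np.int8)


def fibre_area(tributary_area, volume_fraction):
    """Cross-section of each fibre of the crossed pair at one bone-side node."""
    return volume_fraction * np.asarray(tributary_area, dtype=float) / 2.0


def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def build_fibre_network(mesh: LabeledMesh, interfaces: InterfaceSets,
                        params: FibreNetworkParams | None = None,
                        tooth: int | None = None) -> FibreSet:
    """Construct the crossed fibre network around one tooth (the loaded molar).

    For each bone-side interface node, the nearest root-side node inside a
    search cone about the group's target direction is selected, once for an
    apically inclined fibre and once for a coronally inclined one.  Bone
    nodes with no admissible root node are skipped (counted, with a
    warning).  Deterministic: ties are broken by the smallest node id.
    """
    p = params if params is not None else FibreNetworkParams()
    p.validate()
    if tooth is None:
        tooth = mesh.meta.get("loaded_tooth", 0)
    iface: ToothInterface = interfaces[tooth]
    if len(iface.bone_nodes) == 0 or len(iface.root_nodes) == 0:
        raise ValueError("empty interface sets; cannot build fibre network")

    crest_z = mesh.meta.get("crest_z", float(mesh.nodes[iface.bone_nodes][:, 2].max()))
    apex = iface.apex
    depth = crest_z - apex[2]
    axis = iface.axis  # points crest -> apex

    root_pts = mesh.nodes[iface.root_nodes]
    cos_cone = np.cos(np.radians(p.search_cone))
    group_angle = {0: np.radians(p.crestal_angle), 1: 0.0,
                   2: np.radians(p.oblique_angle)}

    bone, root, grp, areas = [], [], [], []
    skipped = 0
    s_all = np.clip((crest_z - mesh.nodes[iface.bone_nodes][:, 2]) / depth, 0.0, 1.0)
    groups = assign_fibre_groups(s_all, p.band_splits)
    for k, b in enumerate(iface.bone_nodes):
        xb = mesh.nodes[b]
        g = int(groups[k])
        d0 = _unit(iface.bone_normals[k])
        if g == 3:  # apical: fibres converge toward the root apex
            centre = _unit(apex - xb) if np.linalg.norm(apex - xb) > 0 else -axis
            ang = np.radians(p.apical_spread)
            tilt = _unit(d0 - np.dot(d0, centre) * centre)
            if not np.isfinite(tilt).all() or np.linalg.norm(tilt) == 0:
                tilt = _unit(np.cross(centre, [1.0, 0, 0]))
            targets = (_unit(np.cos(ang) * centre + np.sin(ang) * tilt),
                       _unit(np.cos(ang) * centre - np.sin(ang) * tilt))
        else:
            ang = group_angle[g]
            # crossed pair: one fibre inclined apically, one coronally
            targets = (_unit(np.cos(ang) * d0 + np.sin(ang) * axis),
                       _unit(np.cos(ang) * d0 - np.sin(ang) * axis))
        a_pair = fibre_area(iface.bone_areas[k], p.volume_fraction)
        found = []
        rel = root_pts - xb
        dist = np.linalg.norm(rel, axis=1)
        for t_dir in targets:
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = (rel @ t_dir) / dist
            # widen the cone once before giving up (crest/apex rims have no
            # root node inside the nominal cone of the tilted target)
            near = (dist > 0) & (dist <= p.max_length)
            for cmin in (cos_cone, np.cos(2 * np.radians(p.search_cone))):
                ok = near & (cosang >= cmin)
                if ok.any():
                    break
            if not ok.any():
                continue
            cand = np.flatnonzero(ok)
            # nearest admissible root node; ties by smallest node id
            order = np.lexsort((iface.root_nodes[cand], dist[cand]))
            found.append(int(iface.root_nodes[cand[order[0]]]))
        if len(found) < 2:
            skipped += 1
            continue
        for rn in found:
            bone.append(b)
            root.append(rn)
            grp.append(g)
            areas.append(a_pair)
    if skipped:
        warnings.warn(f"fibre network: {skipped} bone-side nodes had no admissible "
                      "root-side node and were skipped", stacklevel=2)
    n = len(bone)
    partner = np.arange(n) ^ 1  # pairs are consecutive
    return FibreSet(
        bone_node=np.asarray(bone, dtype=np.int64),
        root_node=np.asarray(root, dtype=np.int64),
        area=np.asarray(areas), group=np.asarray(grp, dtype=np.int8),
        partner=partner, E=p.E, nu=p.nu, tooth=tooth, n_skipped=skipped,
    )
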