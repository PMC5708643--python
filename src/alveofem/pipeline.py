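"""One-command orchestration: geometry -> fibres -> variants -> solves -> analysis.

``run`` executes the full experiment described by a :class:`RunConfig`
(read from TOML with :func:`RunConfig.from_toml`): build the synthetic
geometry, attach the fibre network, optionally calibrate the solid-PDL and
bulk trabecular moduli, solve every requested variant under every requested
load case, and write meshes (MSH/VTU), fibre tables, strain profiles,
summaries and a JSON report.  Deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as afio
from .analysis import socket_profile, summarise, vertical_profile
from .fem import StiffnessCache, von_mises_strain, principal_strains, nodal_strains_spr
from .fibres import FibreNetworkParams, build_fibre_network
from .geometry import GeometryParams, build_socket_geometry
from .loads import LOAD_CASES, build_load
from .meshdata import tag_interfaces
from .variants import VARIANT_IDS, calibrate_variants, make_variant, solve_variant

__all__ = ["RunConfig", "run", "verify"]


@dataclass
class RunConfig:
    geometry: GeometryParams = field(default_factory=GeometryParams)
    fibres: FibreNetworkParams = field(default_factory=FibreNetworkParams)
    variants: tuple[str, ...] = VARIANT_IDS
    load_cases: tuple[str, ...] = LOAD_CASES
    optimise: bool = False
    outdir: str = "runs/default"
    seed: int = 1
    write_fields: bool = True

    def __post_init__(self):
        for v in self.variants:
            if v not in VARIANT_IDS:
                raise ValueError(f"unknown variant {v!r}")
        for c in self.load_cases:
            if c not in LOAD_CASES:
                raise ValueError(f"unknown load case {c!r}")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        seed = int(raw.get("seed", 1))
        geo = GeometryParams(**{**raw.get("geometry", {}), "seed": seed})
        fib = FibreNetworkParams(**{**raw.get("fibres", {}), "seed": seed})
        return cls(
            geometry=geo, fibres=fib,
            variants=tuple(raw.get("variants", VARIANT_IDS)),
            load_cases=tuple(raw.get("load_cases", LOAD_CASES)),
            optimise=bool(raw.get("optimise", False)),
            outdir=raw.get("outdir", "runs/default"),
            seed=seed,
            write_fields=bool(raw.get("write_fields", True)),
        )


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    mesh = _stage("geometry")(build_socket_geometry)(config.geometry)
    interfaces = _stage("interfaces")(tag_interfaces)(mesh)
    fibres = _stage("fibres")(build_fibre_network)(mesh, interfaces, config.fibres)
    cache = StiffnessCache(mesh)

    report: dict = {
        "config": _config_dict(config),
        "mesh": {
            "n_nodes": mesh.n_nodes, "n_elements": mesh.n_elements,
            "volume_mm3": float(mesh.volumes().sum()),
            "trabecular_bone_fraction": mesh.meta.get("trabecular_bone_fraction"),
        },
        "fibres": {"n": len(fibres), "n_skipped": int(fibres.n_skipped)},
    }
    if config.write_fields:
        afio.write_msh(mesh, out / "mesh.msh")
        afio.write_vtu(mesh, out / "mesh.vtu")
        fibres.to_dataframe(mesh).to_csv(out / "fibres.csv", index=False)
        afio.write_fibre_vtu(mesh, fibres, out / "fibres.vtu")

    solid_E, bulk_E = 49.0, 526.0
    if config.optimise:
        cal = _stage("optimisation")(calibrate_variants)(mesh, fibres, cache)
        solid_E, bulk_E = cal["solid_pdl_E"], cal["bulk_E"]
        report["optimisation"] = {
            "reference_displacement_mm": cal["reference_displacement_mm"],
            "solid_pdl_E_MPa": solid_E, "bulk_E_MPa": bulk_E,
            "solid_audit": cal["solid_match"].evaluations,
            "bulk_audit": cal["bulk_match"].evaluations,
        }

    cases = {name: build_load(mesh, name) for name in config.load_cases}
    solutions = {}
    for vid in config.variants:
        variant = make_variant(vid, fibres if vid.startswith("fibrous") else None,
                               solid_pdl_E=solid_E, bulk_E=bulk_E)
        for cname, case in cases.items():
            sol = _stage(f"solve {vid} / {cname}")(solve_variant)(mesh, variant, case, cache)
            solutions[(vid, cname)] = sol
            if config.write_fields:
                _write_solution(mesh, sol, out / f"{vid.replace('+', '_')}__{cname}.vtu")
            if sol.iterations:
                with open(out / f"{vid.replace('+', '_')}__{cname}_iterations.jsonl", "w") as fh:
                    for entry in sol.iterations:
                        fh.write(json.dumps(entry) + "\n")
    report["n_solutions"] = len(solutions)

    # pairwise element-strain difference fields between PDL types (occlusal)
    if config.write_fields:
        from .analysis import difference_field
        occ = {vid: s for (vid, c), s in solutions.items() if c == "occlusal"}
        pairs = [(a, b) for i, a in enumerate(occ) for b in list(occ)[i + 1:]]
        for a, b in pairs:
            diff = difference_field(occ[a], occ[b], (a, b))
            afio.write_vtu(mesh, out / f"diff_{a.replace('+', '_')}__vs__{b.replace('+', '_')}.vtu",
                           cell_data={"d_e1_ue": diff.d_e1, "d_e3_ue": diff.d_e3},
                           include_node_sets=False)

    table = _stage("summary")(summarise)(mesh, interfaces, solutions, cases)
    table.to_csv(out / "summary.csv")
    report["summary"] = json.loads(table.reset_index().to_json(orient="records"))
    for (vid, cname), sol in solutions.items():
        if cname != "occlusal":
            continue
        for side in ("buccal", "lingual"):
            prof = vertical_profile(mesh, sol, side)
            prof.to_dataframe().to_csv(
                out / f"profile_{vid.replace('+', '_')}_{side}.csv", index=False)
    _plot_profiles(mesh, solutions, out)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    with open(out / "report.txt", "w") as fh:
        fh.write(_human_report(report))
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=lambda o: getattr(o, "__dict__", str(o))))


def _write_solution(mesh, sol, path):
    pr_n, mask = nodal_strains_spr(mesh, sol.u, ("cortical", "trabecular_bone"))
    pr = principal_strains(pr_n)
    afio.write_vtu(
        mesh, path,
        point_data={
            "displacement_mm": sol.u,
            "e1_ue": pr[:, 0] * 1e6, "e3_ue": pr[:, 2] * 1e6,
            "von_mises_ue": von_mises_strain(pr_n) * 1e6,
        },
        cell_data={"strain": sol.elem_strain},
        include_node_sets=False,
    )


def _plot_profiles(mesh, solutions, out: Path):
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:
        return
    occ = [(vid, sol) for (vid, c), sol in solutions.items() if c == "occlusal"]
    if not occ:
        return
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, side in zip(axes, ("buccal", "lingual")):
        for vid, sol in occ:
            prof = vertical_profile(mesh, sol, side)
            ax.plot(prof.e3, prof.positions, label=f"{vid} e3")
        ax.set_title(side)
        ax.set_xlabel("strain (microstrain)")
        ax.invert_yaxis()
    axes[0].set_ylabel("distance below crest (mm)")
    axes[0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out / "profiles_occlusal.png", dpi=120)
    plt.close(fig)


def _human_report(report: dict) -> str:
    lines = ["alveofem run report", "==================="]
    m = report["mesh"]
    lines.append(f"mesh: {m['n_elements']} tet10 elements, {m['n_nodes']} nodes, "
                 f"volume {m['volume_mm3']:.1f} mm^3")
    lines.append(f"fibres: {report['fibres']['n']} (skipped {report['fibres']['n_skipped']})")
    if "optimisation" in report:
        o = report["optimisation"]
        lines.append(f"calibrated solid-PDL E = {o['solid_pdl_E_MPa']:.3g} MPa, "
                     f"bulk trabecular E = {o['bulk_E_MPa']:.3g} MPa "
                     f"(reference crown displacement {o['reference_displacement_mm']:.4g} mm)")
    lines.append(f"solutions computed: {report['n_solutions']}")
    return "\n".join(lines) + "\n"


def verify(suite: str, seed: int = 1) -> dict:
    """Run a named verification suite; failures are results, not errors."""
    from . import verification as V
    suites = {
        "elements": lambda: V.patch_test(),
        "beam": lambda: V.beam_benchmark(),
        "truss": lambda: V.series_bar_check(),
        "activeset": lambda: V.active_set_bruteforce(),
        "acceptance": lambda: V.compute_targets(seed),
    }
    if suite == "all":
        return {name: fn() for name, fn in suites.items()}
    if suite not in suites:
        raise ValueError(f"unknown suite {suite!r}; expected one of {sorted(suites)} or 'all'")
    return {suite: suites[suite]()}
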