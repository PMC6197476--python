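"""End-to-end analysis: candidate ensembles, chi-squared ranking, verdict.

Mirrors the full study design: for each candidate composition (antigen
alone; antibody alone; 1:1; 1:2; 2:1; 2:2 monodentate; 2:2 bidentate) an
ensemble of structures is generated, theoretical profiles are computed and
ranked by reduced chi-squared against the experimental profile, and a
composition passes the joint verdict only when (a) some member fits the
scattering data below the chi-squared threshold and (b) its stoichiometry is
consistent with the measured complex mass. The second criterion is what
rules out compositions (such as two antibodies on one antigen) whose
profiles alone can fit the data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import (
    AssemblyFilters,
    ComplexTopology,
    attach_antibody,
    attach_pose_antigen,
    build_bidentate_ensemble,
    build_monodentate_ensemble,
    symmetrize_pose,
)
from .binding import ComponentMass, stoichiometry_search
from .errors import ClashRejection, ValidationError
from .geometry import radius_of_gyration
from .saxscalc import FitConfig, debye_profile, fit_qgrid, reduced_chi2
from .structio import (
    ScatteringProfile,
    Structure,
    read_profile,
    write_structure,
)
from .synthetic_data import (
    NoiseModel,
    ToyBuildConfig,
    make_docked_pose,
    make_synthetic_profile,
    make_toy_antibody,
    make_toy_fab,
    make_toy_fc,
    make_toy_tetramer,
)
from .tamc import Ensemble, TamcConfig, tamc_sample

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "AnalysisReport",
    "rank_ensemble",
    "mass_consistency",
    "run_analysis",
    "build_candidate_ensembles",
    "make_extended_variant",
    "DEFAULT_CLASSES",
]

#: the seven candidate composition/topology classes, with (n_antigen, n_antibody)
DEFAULT_CLASSES = {
    "antigen": (1, 0),
    "antibody": (0, 1),
    "1ab_1ag": (1, 1),
    "1ab_2ag": (2, 1),
    "2ab_1ag": (1, 2),
    "2ab_2ag_monodentate": (2, 2),
    "2ab_2ag_bidentate": (2, 2),
}


@dataclass
class RunConfig:
    """Everything a full analysis run needs, seeds included.

    ``experiment`` may be a profile path or an in-memory profile. Candidate
    ensembles are generated from the toy world with per-class seeds derived
    from ``seed``; ``n_members`` bounds each class's ensemble size.
    ``chi2_threshold`` is the "consistent with the data" cut on the best
    reduced chi-squared of a class (default 2 on toy data).
    """

    experiment: str | ScatteringProfile
    toy: ToyBuildConfig = field(default_factory=ToyBuildConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    filters: AssemblyFilters = field(default_factory=AssemblyFilters)
    antigen_mass: ComponentMass = field(
        default_factory=lambda: ComponentMass("antigen", 63.3, 0.8)
    )
    antibody_mass: ComponentMass = field(
        default_factory=lambda: ComponentMass("antibody", 160.0, 3.0)
    )
    measured_mass: ComponentMass = field(
        default_factory=lambda: ComponentMass("complex", 447.0, 12.0)
    )
    mass_z_limit: float = 1.0
    chi2_threshold: float = 2.0
    n_members: int = 8
    seed: int = 0
    classes: tuple = tuple(DEFAULT_CLASSES)
    outdir: str | None = None


@dataclass
class AnalysisReport:
    """Ranked tables, per-class verdicts and the run log."""

    tables: dict
    verdict: dict
    passing_classes: tuple
    log: list
    seeds: dict

    def summary(self) -> str:
        lines = ["class                 best_chi2  mass_ok  passes"]
        for name, v in self.verdict.items():
            chi2 = v["best_chi2"]
            chi2_s = f"{chi2:9.3f}" if chi2 is not None else "      n/a"
            lines.append(
                f"{name:<22}{chi2_s}  {str(v['mass_consistent']):<7}"
                f"  {v['passes']}"
            )
        lines.append(f"passing classes: {', '.join(self.passing_classes) or 'none'}")
        return "\n".join(lines)


def rank_ensemble(
    e: Ensemble, experiment: ScatteringProfile, cfg: FitConfig | None = None
) -> pd.DataFrame:
    """Per-member profile fit table, sorted ascending by reduced chi-squared.

    Ties are broken by lower Rg. Columns: member, rg, chi2_red, scale, and
    best/worst flags on the extremes.
    """
    if len(e) == 0:
        raise ValidationError("cannot rank an empty ensemble")
    cfg = cfg or FitConfig()
    grid = fit_qgrid(cfg)
    rows = []
    for i, member in enumerate(e.members):
        model = debye_profile(member, grid)
        chi2, scale = reduced_chi2(model, experiment, cfg)
        rows.append(
            {
                "member": i,
                "rg": radius_of_gyration(member),
                "chi2_red": chi2,
                "scale": scale,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["chi2_red", "rg"], kind="mergesort", ignore_index=True
    )
    table["best"] = False
    table["worst"] = False
    table.loc[0, "best"] = True
    table.loc[len(table) - 1, "worst"] = True
    return table


def mass_consistency(
    topology: ComplexTopology | tuple,
    antigen: ComponentMass,
    antibody: ComponentMass,
    measured: ComponentMass,
    z_limit: float = 1.0,
) -> bool:
    """True iff the composition's predicted mass matches the measured mass.

    Accepts a :class:`ComplexTopology` or a bare (n_antigen, n_antibody)
    pair; the window test is the same one the stoichiometry search applies.
    """
    if isinstance(topology, ComplexTopology):
        i, j = topology.n_antigen, topology.n_antibody
    else:
        i, j = topology
    res = stoichiometry_search(
        antigen, antibody, measured, n_max=max(i, j, 1), z_limit=z_limit
    )
    return any(c.n_antigen == i and c.n_antibody == j for c in res.combos)


def make_extended_variant(s: Structure, factor: float = 1.8) -> Structure:
    """Artificially extended copy: labelled units pushed radially apart.

    Each top-level unit's centroid is moved away from the overall centroid by
    ``factor`` while internal geometry is preserved -- the "extended
    structures" foil used to test that the scattering ranking prefers compact
    models. Units are the coarsest labels that partition the structure; if
    none do, chains are used.
    """
    center = s.centroid()
    coord = s.coord.copy()
    units = _partition_units(s)
    for idx in units:
        c = s.coord[idx].mean(axis=0)
        coord[idx] += (factor - 1.0) * (c - center)
    return s.with_coord(coord)


def _partition_units(s: Structure) -> list[np.ndarray]:
    # prefer labels that partition the atoms; fall back to chains
    candidates = sorted(
        (k for k in s.labels if ":" not in k), key=lambda k: -len(s.labels[k])
    )
    chosen: list[np.ndarray] = []
    covered = np.zeros(s.n_atoms, dtype=bool)
    for key in candidates:
        idx = s.labels[key]
        if not covered[idx].any():
            chosen.append(idx)
            covered[idx] = True
    if covered.all() and len(chosen) > 1:
        return chosen
    return [np.flatnonzero(s.chain_id == c) for c in np.unique(s.chain_id)]


# ---------------------------------------------------------------------------
# candidate-ensemble construction
# ---------------------------------------------------------------------------


def _seed(base: int, k: int) -> int:
    return (base * 1009 + k * 9176) % (2**31 - 1)


def build_candidate_ensembles(
    toy: ToyBuildConfig,
    filters: AssemblyFilters,
    n_members: int,
    seed: int,
    classes: tuple = tuple(DEFAULT_CLASSES),
) -> tuple[dict, dict, list]:
    """Generate the candidate ensembles for the requested classes.

    Returns (ensembles by class, seeds by stage, log lines). All stage seeds
    are derived deterministically from ``seed``.
    """
    log: list[str] = []
    seeds: dict[str, int] = {}

    def stage_seed(name: str, k: int) -> int:
        s = _seed(seed, k)
        seeds[name] = s
        return s

    antibody0 = make_toy_antibody(toy)
    antigen = make_toy_tetramer(toy)
    fab = make_toy_fab(toy)
    fc = make_toy_fc(toy)

    tamc_cfg = TamcConfig(
        pivots=antibody0.meta["default_pivots"],
        n_accept=max(n_members, 4),
        max_step=30.0,
        seed=stage_seed("tamc", 1),
    )
    antibodies = tamc_sample(antibody0, tamc_cfg)
    log.append(
        f"tamc: {len(antibodies)} members, acceptance "
        f"{antibodies.info['acceptance_rate']:.3f}, seed {tamc_cfg.seed}"
    )

    # docked poses across subunits and seeded spins; pose diversity (spin
    # angles) is what makes ring closure reachable, so keep a healthy floor
    pose_members, pose_rows = [], []
    n_poses = max(4 * n_members, 32)
    for i in range(n_poses):
        sub = f"sub{(i % 4) + 1}"
        pose = make_docked_pose(
            fab, antigen, sub, gap=4.0, seed=stage_seed(f"pose_{i}", 100 + i)
        )
        pose_members.append(pose)
        pose_rows.append({"member": i, "subunit": sub})
    fab_poses = Ensemble(pose_members, pd.DataFrame(pose_rows), {"seed": seed})
    log.append(f"poses: {len(fab_poses)} docked Fab-antigen poses")

    # symmetrized two-Fab blocks over both recorded axes
    blk_members, blk_rows, rejected = [], [], 0
    for i, pose in enumerate(fab_poses.members):
        for axis_index in (0, 1):
            try:
                blk = symmetrize_pose(pose, axis_index=axis_index, filters=filters)
            except ClashRejection:
                rejected += 1
                continue
            blk_rows.append(
                {"member": len(blk_members), "pose": i, "axis": axis_index}
            )
            blk_members.append(blk)
    fab2_blocks = Ensemble(blk_members, pd.DataFrame(blk_rows), {"rejected": rejected})
    log.append(
        f"fab2 blocks: {len(fab2_blocks)} accepted, {rejected} clash-rejected"
    )
    if len(fab2_blocks) == 0:
        raise ValidationError("no symmetrized two-Fab block survived the clash rule")
    fc_blocks = Ensemble([fc], pd.DataFrame([{"member": 0}]), {})

    rng = np.random.default_rng(stage_seed("classes", 7))
    ensembles: dict[str, Ensemble] = {}
    for cls in classes:
        if cls == "antigen":
            ensembles[cls] = Ensemble([antigen], pd.DataFrame([{"member": 0}]), {})
        elif cls == "antibody":
            members = antibodies.members[:n_members]
            ensembles[cls] = Ensemble(
                members, antibodies.meta.iloc[: len(members)].copy(), {}
            )
        elif cls in ("1ab_1ag", "1ab_2ag"):
            ensembles[cls] = _build_single_antibody_class(
                cls, antibodies, fab_poses, filters, n_members, rng
            )
        elif cls == "2ab_1ag":
            ensembles[cls] = _build_two_antibody_one_antigen(
                antibodies, fab2_blocks, filters, n_members, rng
            )
        elif cls == "2ab_2ag_monodentate":
            ensembles[cls] = build_monodentate_ensemble(
                fab2_blocks,
                fab_poses,
                antibodies,
                filters,
                n_members,
                seed=stage_seed("monodentate", 23),
            )
        elif cls == "2ab_2ag_bidentate":
            ensembles[cls] = build_bidentate_ensemble(
                antibodies,
                fab2_blocks,
                fc_blocks,
                filters,
                n_members,
                seed=stage_seed("bidentate", 29),
            )
        else:
            raise ValidationError(f"unknown candidate class {cls!r}")
        log.append(f"class {cls}: {len(ensembles[cls])} members")
    return ensembles, seeds, log


def _build_single_antibody_class(
    cls: str,
    antibodies: Ensemble,
    fab_poses: Ensemble,
    filters: AssemblyFilters,
    n: int,
    rng: np.random.Generator,
) -> Ensemble:
    """1:1 and 1:2 complexes: antigens docked onto one antibody's Fabs."""
    members, rows = [], []
    attempts = 0
    cap = 200 * n + 50
    while len(members) < n and attempts < cap:
        attempts += 1
        i_ab = int(rng.integers(len(antibodies)))
        i_p1 = int(rng.integers(len(fab_poses)))
        ab = antibodies.members[i_ab]
        try:
            c = attach_pose_antigen(
                fab_poses.members[i_p1],
                ab,
                target_fab_align="fab1_align",
                target_fab_unit="Fab1",
                new_prefix="ag1",
                filters=filters,
            )
            if cls == "1ab_2ag":
                i_p2 = int(rng.integers(len(fab_poses)))
                c = attach_pose_antigen(
                    fab_poses.members[i_p2],
                    c,
                    target_fab_align="fab2_align",
                    target_fab_unit="Fab2",
                    new_prefix="ag2",
                    filters=filters,
                )
        except ClashRejection:
            continue
        rows.append({"member": len(members), "antibody": i_ab, "pose": i_p1})
        members.append(c)
    return Ensemble(members, pd.DataFrame(rows), {"attempts": attempts})


def _build_two_antibody_one_antigen(
    antibodies: Ensemble,
    fab2_blocks: Ensemble,
    filters: AssemblyFilters,
    n: int,
    rng: np.random.Generator,
) -> Ensemble:
    """2:1 complexes: two full antibodies on one shared antigen block."""
    members, rows = [], []
    attempts = 0
    cap = 200 * n + 50
    while len(members) < n and attempts < cap:
        attempts += 1
        i_blk = int(rng.integers(len(fab2_blocks)))
        i_a1 = int(rng.integers(len(antibodies)))
        i_a2 = int(rng.integers(len(antibodies)))
        try:
            c = attach_antibody(
                antibodies.members[i_a1],
                fab2_blocks.members[i_blk],
                anchor_prefix="fab_a",
                new_prefix="ab1",
                filters=filters,
            )
            c = attach_antibody(
                antibodies.members[i_a2],
                c,
                anchor_prefix="fab_b",
                new_prefix="ab2",
                filters=filters,
            )
        except ClashRejection:
            continue
        rows.append(
            {
                "member": len(members),
                "block": i_blk,
                "antibody_1": i_a1,
                "antibody_2": i_a2,
            }
        )
        members.append(c)
    return Ensemble(members, pd.DataFrame(rows), {"attempts": attempts})


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------


def run_analysis(cfg: RunConfig) -> AnalysisReport:
    """Generate, profile, rank and filter every candidate class.

    Emits per-class ranked TSVs, best/worst member PDBs and a machine-
    readable run log when ``cfg.outdir`` is set; always returns the
    :class:`AnalysisReport`. A class failing at some stage is reported with
    diagnostics instead of aborting the run. Reruns with an identical config
    produce byte-identical outputs.
    """
    if isinstance(cfg.experiment, (str, Path)):
        experiment = read_profile(cfg.experiment)
    else:
        experiment = cfg.experiment
    log: list[str] = [f"run seed {cfg.seed}"]
    if not cfg.classes:
        logger.warning("empty candidate list; nothing to do")
        return AnalysisReport({}, {}, (), log + ["empty candidate list"], {})
    ensembles, seeds, build_log = build_candidate_ensembles(
        cfg.toy, cfg.filters, cfg.n_members, cfg.seed, cfg.classes
    )
    log.extend(build_log)
    tables: dict[str, pd.DataFrame] = {}
    verdict: dict[str, dict] = {}
    for cls in cfg.classes:
        comp = DEFAULT_CLASSES[cls]
        ens = ensembles[cls]
        mass_ok = mass_consistency(
            comp,
            cfg.antigen_mass,
            cfg.antibody_mass,
            cfg.measured_mass,
            cfg.mass_z_limit,
        )
        if len(ens) == 0:
            verdict[cls] = {
                "composition": comp,
                "best_chi2": None,
                "mass_consistent": mass_ok,
                "passes": False,
                "n_members": 0,
            }
            log.append(f"class {cls}: empty ensemble ({ens.info.get('reason', 'n/a')})")
            continue
        table = rank_ensemble(ens, experiment, cfg.fit)
        tables[cls] = table
        best_chi2 = float(table["chi2_red"].iloc[0])
        verdict[cls] = {
            "composition": comp,
            "best_chi2": best_chi2,
            "mass_consistent": mass_ok,
            "passes": bool(best_chi2 <= cfg.chi2_threshold and mass_ok),
            "n_members": len(ens),
        }
        log.append(
            f"class {cls}: best chi2 {best_chi2:.3f}, mass_ok {mass_ok}, "
            f"passes {verdict[cls]['passes']}"
        )
    passing = tuple(c for c in cfg.classes if verdict.get(c, {}).get("passes"))
    report = AnalysisReport(tables, verdict, passing, log, seeds)
    if cfg.outdir is not None:
        _write_report(cfg, report, ensembles)
    return report


def _write_report(cfg: RunConfig, report: AnalysisReport, ensembles: dict) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for cls, table in report.tables.items():
        table.to_csv(out / f"rank_{cls}.tsv", sep="\t", index=False)
        ens = ensembles[cls]
        best = int(table["member"].iloc[0])
        worst = int(table["member"].iloc[-1])
        write_structure(ens.members[best], out / f"best_{cls}.pdb")
        write_structure(ens.members[worst], out / f"worst_{cls}.pdb")
    verdict_json = {
        "passing_classes": list(report.passing_classes),
        "seeds": report.seeds,
        "classes": {
            k: {kk: (vv if not isinstance(vv, tuple) else list(vv)) for kk, vv in v.items()}
            for k, v in report.verdict.items()
        },
    }
    (out / "verdict.json").write_text(json.dumps(verdict_json, indent=2, sort_keys=True))
    (out / "run.log").write_text("\n".join(report.log) + "\n")


def make_reference_experiment(
    toy: ToyBuildConfig,
    filters: AssemblyFilters,
    seed: int,
    noise: NoiseModel | None = None,
    qgrid: np.ndarray | None = None,
) -> tuple[ScatteringProfile, Structure]:
    """Synthetic "experimental" profile from a compact bidentate ground truth.

    Builds a small bidentate ensemble with the given seed, takes its most
    compact member as ground truth, and returns that structure's noisy
    profile (plus the structure itself). The default Q grid covers the
    chi-squared fit range with margin.
    """
    ensembles, _, _ = build_candidate_ensembles(
        toy, filters, n_members=4, seed=seed, classes=("2ab_2ag_bidentate",)
    )
    ens = ensembles["2ab_2ag_bidentate"]
    if len(ens) == 0:
        raise ValidationError("could not build a bidentate ground truth")
    rgs = [radius_of_gyration(m) for m in ens.members]
    truth = ens.members[int(np.argmin(rgs))]
    if qgrid is None:
        qgrid = np.linspace(0.002, 0.25, 100)
    noise = noise or NoiseModel(seed=_seed(seed, 77))
    profile = make_synthetic_profile(truth, qgrid, noise)
    return profile, truth
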