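"""Backbone torsion-angle Monte Carlo (TAMC) ensemble generation.

The sampling engine of the pipeline: starting from an overlap-free
structure, repeatedly pick one hinge pivot (chain, residue, phi|psi)
uniformly at random, draw a rotation delta ~ Uniform(-max_step, +max_step),
apply the torsion, and accept the move iff no atom of the moving rigid unit
comes closer than ``overlap_cutoff`` to the non-moving unit. Accepted
configurations become the current state (a Markov chain over hard-sphere-
allowed conformations -- no Metropolis energy, matching a pure
"non-overlapping configurations" criterion).

Pairs of atoms in the same chain whose residue numbers differ by at most one
are exempt from the cutoff; without that exemption the covalent geometry
across the pivot bond (N-C at 1.33 A) would reject every move.

On 1000 consecutive rejections the chain restarts from the input structure
(chain-growth restart) so a trapped state cannot stall production; the
accepted count keeps running. If the total attempt budget is exhausted a
:class:`~absaxs.errors.SamplingError` with the acceptance rate is raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import SamplingError, ValidationError
from .geometry import _torsion_atoms, apply_torsion, radius_of_gyration
from .structio import Structure, write_structure

__all__ = ["TamcConfig", "Ensemble", "tamc_sample"]


@dataclass(frozen=True)
class TamcConfig:
    """Sampling parameters.

    ``pivots`` are (chain_id, residue_number, "phi"|"psi") triples -- for the
    real antibody these are the heavy-chain upper-hinge residues 212-214; for
    the toy they default to the generator's recorded hinge pivots.
    ``overlap_cutoff`` defaults to 1.8 A (heavy-atom contact distance); one
    pivot is perturbed per move.
    """

    pivots: tuple
    n_accept: int
    max_step: float = 30.0
    overlap_cutoff: float = 1.8
    seed: int = 0
    restart_after: int = 1000
    max_attempts: int | None = None

    def __post_init__(self):
        if not (0.0 < self.max_step <= 180.0):
            raise ValidationError("max_step must be in (0, 180]")
        if self.n_accept < 0:
            raise ValidationError("n_accept must be >= 0")
        if self.overlap_cutoff <= 0:
            raise ValidationError("overlap_cutoff must be positive")
        if len(self.pivots) == 0:
            raise ValidationError("need at least one pivot")

    @property
    def attempt_budget(self) -> int:
        if self.max_attempts is not None:
            return self.max_attempts
        return 200 * max(self.n_accept, 1) + 10_000


@dataclass
class Ensemble:
    """A collection of same-topology structures with per-member metadata.

    ``meta`` is a DataFrame with one row per member (move index, pivot used,
    Rg, optionally chi2 once ranked); ``info`` carries run-level diagnostics
    such as attempt counts and acceptance rate.
    """

    members: list
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    info: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def save(self, directory) -> None:
        """Persist as a directory of PDB files plus a TSV manifest."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = self.meta.copy()
        files = []
        for i, member in enumerate(self.members):
            name = f"member_{i:05d}.pdb"
            write_structure(member, directory / name)
            files.append(name)
        meta["file"] = files
        meta.to_csv(directory / "manifest.tsv", sep="\t", index=False)


def _overlap_ok(
    s: Structure, movers: np.ndarray, cutoff: float
) -> tuple[bool, float]:
    """Hard-sphere check of the moving set against the static set.

    Same-chain pairs with |residue difference| <= 1 are exempt (covalent
    neighbourhood across the pivot bond).
    """
    mask = np.zeros(s.n_atoms, dtype=bool)
    mask[movers] = True
    static = np.flatnonzero(~mask)
    if static.size == 0 or movers.size == 0:
        return True, np.inf
    d = cdist(s.coord[movers], s.coord[static])
    same_chain = s.chain_id[movers][:, None] == s.chain_id[static][None, :]
    adjacent = np.abs(s.res_id[movers][:, None] - s.res_id[static][None, :]) <= 1
    exempt = same_chain & adjacent
    d = np.where(exempt, np.inf, d)
    dmin = float(d.min())
    return dmin >= cutoff, dmin


def tamc_sample(s: Structure, cfg: TamcConfig) -> Ensemble:
    """Generate an ensemble of non-overlapping torsion variants of ``s``.

    Deterministic for a given (structure, config): the same seed yields
    bit-identical member coordinates. ``n_accept = 0`` returns an empty
    ensemble without touching the input.
    """
    pivot_movers = {}
    for pivot in cfg.pivots:
        chain, res, ang = pivot
        axis, movers = _torsion_atoms(s, chain, res, ang)
        pivot_movers[tuple(pivot)] = movers
        ok, dmin = _overlap_ok(s, movers, cfg.overlap_cutoff)
        if not ok:
            raise ValidationError(
                f"input structure violates the overlap cutoff at pivot {pivot} "
                f"(min distance {dmin:.2f} A)"
            )
    if cfg.n_accept == 0:
        return Ensemble(members=[], meta=_empty_meta(), info={"attempts": 0})

    rng = np.random.default_rng(cfg.seed)
    current = s.copy()
    members: list[Structure] = []
    rows = []
    attempts = 0
    consecutive_rejects = 0
    while len(members) < cfg.n_accept:
        if attempts >= cfg.attempt_budget:
            raise SamplingError(
                "TAMC attempt budget exhausted; overlap cutoff may be too "
                "large or pivots too constrained",
                attempts=attempts,
                accepted=len(members),
            )
        attempts += 1
        pivot = cfg.pivots[int(rng.integers(len(cfg.pivots)))]
        delta = float(rng.uniform(-cfg.max_step, cfg.max_step))
        candidate = apply_torsion(current, tuple(pivot), delta)
        ok, _ = _overlap_ok(candidate, pivot_movers[tuple(pivot)], cfg.overlap_cutoff)
        if ok:
            current = candidate
            members.append(candidate.copy())
            rows.append(
                {
                    "member": len(members) - 1,
                    "move_index": attempts - 1,
                    "pivot_chain": pivot[0],
                    "pivot_res": int(pivot[1]),
                    "pivot_angle": pivot[2],
                    "delta_deg": delta,
                    "rg": radius_of_gyration(candidate),
                }
            )
            consecutive_rejects = 0
        else:
            consecutive_rejects += 1
            if consecutive_rejects >= cfg.restart_after:
                current = s.copy()
                consecutive_rejects = 0
    meta = pd.DataFrame(rows) if rows else _empty_meta()
    return Ensemble(
        members=members,
        meta=meta,
        info={
            "attempts": attempts,
            "accepted": len(members),
            "acceptance_rate": len(members) / attempts,
            "seed": cfg.seed,
        },
    )


def _empty_meta() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "member",
            "move_index",
            "pivot_chain",
            "pivot_res",
            "pivot_angle",
            "delta_deg",
            "rg",
        ]
    )
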