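"""Theoretical small-angle scattering and 1-D curve analyses.

Profile calculators
-------------------
* :func:`debye_profile` -- the exact orientationally averaged Debye double
  sum ``I(Q) = sum_ij f_i(Q) f_j(Q) sinc(Q r_ij)``. It is the reference
  evaluator; cost is O(N^2) in atoms but the pair distances are computed once
  and reused across the Q grid.
* :func:`golden_vector_profile` -- quasi-uniform orientational quadrature
  over a spherical Fibonacci (golden-angle) lattice of scattering directions,
  the fast evaluator used by ensemble pipelines. Converges to the Debye sum
  as the number of directions grows.

Both are in-vacuo: no excluded-volume or hydration-layer term. That is the
main fidelity gap against real solution data and is deliberate -- the toy
world's ground truth is generated by the same physics, so closed-form checks
stay exact.

Analyses
--------
Guinier fitting (``ln I`` vs ``Q^2`` with a self-consistent ``Qmax Rg``
window), coordinate-space pair-distance distributions, the Kratky transform,
and reduced chi-squared model/experiment comparison on a fixed low-Q grid
(default: 19 points on (0, 0.19] A^-1) with an analytically fitted scale
factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, cdist

from .errors import FitError, ValidationError
from .structio import ScatteringProfile, Structure

__all__ = [
    "FormFactorTable",
    "FitConfig",
    "GuinierResult",
    "PairDistribution",
    "debye_profile",
    "golden_vector_profile",
    "guinier_fit",
    "pair_distribution",
    "kratky_transform",
    "reduced_chi2",
    "fit_qgrid",
]

# Cromer-Mann 4-Gaussian X-ray form factor coefficients (a1..a4, b1..b4, c),
# International Tables for Crystallography Vol. C. Enough elements for
# protein work; anything else falls back to a constant f = Z.
_CROMER_MANN = {
    "H": ([0.489918, 0.262003, 0.196767, 0.049879],
          [20.6593, 7.74039, 49.5519, 2.20159], 0.001305),
    "C": ([2.31000, 1.02000, 1.58860, 0.865000],
          [20.8439, 10.2075, 0.568700, 51.6512], 0.215600),
    "N": ([12.2126, 3.13220, 2.01250, 1.16630],
          [0.005700, 9.89330, 28.9975, 0.582600], -11.5290),
    "O": ([3.04850, 2.28680, 1.54630, 0.867000],
          [13.2771, 5.70110, 0.323900, 32.9089], 0.250800),
    "S": ([6.90530, 5.20340, 1.43790, 1.58630],
          [1.46790, 22.2151, 0.253600, 56.1720], 0.866900),
    "P": ([6.43450, 4.17910, 1.78000, 1.49080],
          [1.90670, 27.1570, 0.526000, 68.1645], 1.11490),
}

_ELECTRON_COUNT = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "FE": 26, "ZN": 30,
}


@dataclass(frozen=True)
class FormFactorTable:
    """Per-element scattering factors f(Q), or a constant "point" mode.

    In ``point`` mode every atom scatters with ``f = constant`` (default 1),
    the natural choice for the pseudo-atom toy structures. In ``atomic`` mode
    f(Q) follows the Cromer-Mann parameterisation with ``f(0)`` equal to the
    element electron count.
    """

    mode: str = "point"
    constant: float = 1.0

    def __post_init__(self):
        if self.mode not in ("point", "atomic"):
            raise ValidationError(f"unknown form-factor mode {self.mode!r}")
        if self.mode == "point" and self.constant <= 0:
            raise ValidationError("point form factor must be positive")

    def factors(self, elements: np.ndarray, q: np.ndarray) -> np.ndarray:
        """(n_atoms, n_q) array of f_i(Q_k)."""
        q = np.asarray(q, dtype=np.float64)
        n = len(elements)
        if self.mode == "point":
            return np.full((n, len(q)), self.constant)
        out = np.empty((n, len(q)))
        # group by element so each f(Q) curve is evaluated once
        elements = np.char.upper(np.asarray(elements, dtype="U2"))
        s2 = (q / (4 * np.pi)) ** 2  # (sin theta / lambda)^2 = (Q / 4 pi)^2
        for el in np.unique(elements):
            key = el.capitalize() if el.capitalize() in _CROMER_MANN else el
            if key in _CROMER_MANN:
                a, b, c = _CROMER_MANN[key]
                f = c + sum(ai * np.exp(-bi * s2) for ai, bi in zip(a, b))
            else:
                z = _ELECTRON_COUNT.get(el)
                if z is None:
                    raise ValidationError(f"no form factor for element {el!r}")
                f = np.full_like(q, float(z))
            out[elements == el] = f
        return out


def _check_qgrid(qgrid: np.ndarray) -> np.ndarray:
    q = np.atleast_1d(np.asarray(qgrid, dtype=np.float64))
    if q.size == 0:
        raise ValidationError("empty Q grid")
    if np.any(q < 0):
        raise ValidationError("negative Q")
    return q


def debye_profile(
    s: Structure,
    qgrid: np.ndarray,
    ff: FormFactorTable | None = None,
    chunk: int = 2_000_000,
) -> ScatteringProfile:
    """Exact Debye-sum intensity of a structure on a Q grid.

    ``I(Q) = sum_i sum_j f_i(Q) f_j(Q) sinc(Q r_ij)`` with ``sinc(0) = 1``,
    so ``I(0) = (sum_i f_i(0))^2``. Pair distances are streamed in chunks to
    bound memory for large point clouds.
    """
    if s.n_atoms == 0:
        raise ValidationError("empty structure")
    q = _check_qgrid(qgrid)
    ff = ff or FormFactorTable()
    f = ff.factors(s.element, q)  # (n, nq)
    intensity = (f * f).sum(axis=0).astype(np.float64)  # self terms (i == j)
    if s.n_atoms > 1:
        if ff.mode == "point":
            d = pdist(s.coord)
            w0 = ff.constant * ff.constant
            for lo in range(0, len(d), chunk):
                dc = d[lo : lo + chunk]
                for k, qk in enumerate(q):
                    if qk == 0.0:
                        intensity[k] += 2.0 * w0 * len(dc)
                    else:
                        x = qk * dc
                        intensity[k] += 2.0 * w0 * float(np.sum(np.sin(x) / x))
        else:
            intensity += _debye_cross_terms(s, q, f, chunk)
    return ScatteringProfile(q.copy(), intensity)


def _debye_cross_terms(
    s: Structure, q: np.ndarray, f: np.ndarray, chunk: int
) -> np.ndarray:
    """i != j Debye terms grouped by element pair (distinct f curves)."""
    elements = np.char.upper(s.element)
    uniq = np.unique(elements)
    groups = {el: np.flatnonzero(elements == el) for el in uniq}
    acc = np.zeros(len(q))
    for a_i, el_a in enumerate(uniq):
        ia = groups[el_a]
        fa = f[ia[0]]
        for el_b in uniq[a_i:]:
            ib = groups[el_b]
            fb = f[ib[0]]
            if el_a == el_b:
                if len(ia) < 2:
                    continue
                d = pdist(s.coord[ia])
                mult = 2.0
            else:
                d = cdist(s.coord[ia], s.coord[ib]).ravel()
                mult = 2.0  # (i,j) and (j,i)
            for lo in range(0, len(d), chunk):
                dc = d[lo : lo + chunk]
                for k, qk in enumerate(q):
                    if qk == 0.0:
                        acc[k] += mult * fa[k] * fb[k] * len(dc)
                    else:
                        x = qk * dc
                        acc[k] += mult * fa[k] * fb[k] * float(np.sum(np.sin(x) / x))
    return acc


def golden_vectors(n: int) -> np.ndarray:
    """(n, 3) quasi-uniform unit vectors on a spherical Fibonacci lattice."""
    if n < 1:
        raise ValidationError("need at least one direction")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def golden_vector_profile(
    s: Structure,
    qgrid: np.ndarray,
    ff: FormFactorTable | None = None,
    n_vectors: int = 299,
) -> ScatteringProfile:
    """Orientationally averaged intensity via golden-angle direction quadrature.

    ``I(Q) = (1/M) sum_m |sum_j f_j(Q) exp(i q_m . r_j)|^2`` over M
    quasi-uniform directions.
    """
    if s.n_atoms == 0:
        raise ValidationError("empty structure")
    q = _check_qgrid(qgrid)
    ff = ff or FormFactorTable()
    f = ff.factors(s.element, q)  # (n, nq)
    dirs = golden_vectors(n_vectors)  # (M, 3)
    proj = s.coord @ dirs.T  # (n, M)
    intensity = np.empty(len(q))
    for k, qk in enumerate(q):
        phase = qk * proj
        fk = f[:, k]
        re = fk @ np.cos(phase)
        im = fk @ np.sin(phase)
        intensity[k] = float(np.mean(re * re + im * im))
    return ScatteringProfile(q.copy(), intensity)


# ---------------------------------------------------------------------------
# Guinier analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GuinierResult:
    """Result of a Guinier fit of ``ln I`` vs ``Q^2`` at low Q."""

    rg: float
    i0: float
    window: tuple[float, float]
    qmin_rg: float
    qmax_rg: float
    r2: float
    n_points: int

    def summary(self) -> str:
        lines = [
            "Guinier fit",
            f"  Rg       {self.rg:10.3f} A",
            f"  I(0)     {self.i0:10.4g}",
            f"  window   Q in [{self.window[0]:.4f}, {self.window[1]:.4f}] A^-1"
            f"  ({self.n_points} points)",
            f"  Qmin*Rg  {self.qmin_rg:7.3f}",
            f"  Qmax*Rg  {self.qmax_rg:7.3f}",
            f"  r^2      {self.r2:7.4f}",
        ]
        return "\n".join(lines)


def _weighted_linfit(x, y, w):
    """Weighted least squares y = a + b x; returns a, b, weighted r^2."""
    W = w / w.sum()
    xm = (W * x).sum()
    ym = (W * y).sum()
    sxx = (W * (x - xm) ** 2).sum()
    sxy = (W * (x - xm) * (y - ym)).sum()
    if sxx <= 0:
        raise FitError("degenerate Guinier window (no Q spread)")
    b = sxy / sxx
    a = ym - b * xm
    ss_res = (W * (y - a - b * x) ** 2).sum()
    ss_tot = (W * (y - ym) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return a, b, max(0.0, min(1.0, r2))


def guinier_fit(
    p: ScatteringProfile, qmax_rg_limit: float = 1.3, min_points: int = 3
) -> GuinierResult:
    """Self-consistent Guinier fit on the largest low-Q window with Qmax Rg <= limit.

    The fit of ``ln I`` against ``Q^2`` starts from the full profile and is
    shrunk until the window and the fitted Rg satisfy ``Qmax * Rg <=
    qmax_rg_limit`` self-consistently (fit, shrink, repeat to a fixed point).
    Weighted by sigma when present (errors propagated to log space),
    unweighted otherwise.
    """
    if len(p) < min_points:
        raise FitError("profile too short for Guinier analysis")
    pos = p.intensity > 0
    # candidate window must start at the lowest Q; stop at first nonpositive I
    first_bad = np.argmin(pos) if not pos.all() else len(p)
    if first_bad < min_points:
        raise FitError("nonpositive intensities at low Q")
    n = int(first_bad)

    def _fit(m: int):
        q = p.q[:m]
        i = p.intensity[:m]
        y = np.log(i)
        if p.sigma is not None:
            w = (i / p.sigma[:m]) ** 2  # var(ln I) = (sigma/I)^2
        else:
            w = np.ones(m)
        a, b, r2 = _weighted_linfit(q * q, y, w)
        if b >= 0:
            raise FitError("Guinier slope is nonnegative; no Rg defined")
        rg = float(np.sqrt(-3.0 * b))
        return a, rg, r2

    m = n
    seen = set()
    for _ in range(200):
        a, rg, r2 = _fit(m)
        # largest window satisfying the limit for THIS rg
        m_new = int(np.searchsorted(p.q, qmax_rg_limit / rg, side="right"))
        m_new = min(max(m_new, min_points), n)
        if m_new == m:
            break
        if m_new in seen:  # 2-cycle on noisy data: settle on the smaller window
            m = min(m, m_new)
            break
        seen.add(m)
        m = m_new
    else:
        raise FitError("Guinier window did not converge")
    a, rg, r2 = _fit(m)
    return GuinierResult(
        rg=rg,
        i0=float(np.exp(a)),
        window=(float(p.q[0]), float(p.q[m - 1])),
        qmin_rg=float(p.q[0] * rg),
        qmax_rg=float(p.q[m - 1] * rg),
        r2=r2,
        n_points=m,
    )


# ---------------------------------------------------------------------------
# pair distribution and Kratky
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairDistribution:
    """Coordinate-space pair-distance distribution, normalised to unit area.

    ``r`` holds bin centres; ``p`` is a density (area ``sum(p) * bin_width``
    equals 1); ``p = 0`` beyond ``dmax``, the largest pairwise distance.
    """

    r: np.ndarray
    p: np.ndarray
    dmax: float
    bin_width: float

    def rg(self) -> float:
        """Rg from the second moment, ``Rg^2 = Integral r^2 p(r) dr / 2``.

        For a unit-area distribution over distinct pairs this carries a
        relative O(1/N) bias versus the coordinate-space Rg (self-pairs are
        excluded from the histogram); it vanishes for large structures.
        """
        m2 = float((self.r**2 * self.p).sum() * self.bin_width)
        return float(np.sqrt(m2 / 2.0))


def pair_distribution(
    s: Structure,
    bin_width: float = 1.0,
    weights: np.ndarray | None = None,
) -> PairDistribution:
    """Weighted histogram of all pairwise distances, unit area.

    Weights default to 1 per atom (pseudo-atoms); pass ``f_i(0)`` values for
    atomic structures. Pair (i, j) carries weight ``w_i w_j``.
    """
    if s.n_atoms < 2:
        raise ValidationError("pair distribution needs >= 2 atoms")
    if bin_width <= 0:
        raise ValidationError("bin width must be positive")
    d = pdist(s.coord)
    if weights is None:
        wpair = None
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (s.n_atoms,):
            raise ValidationError("one weight per atom required")
        iu, ju = np.triu_indices(s.n_atoms, k=1)
        wpair = w[iu] * w[ju]
    dmax = float(d.max())
    nbins = max(1, int(np.ceil(dmax / bin_width)))
    hist, edges = np.histogram(
        d, bins=nbins, range=(0.0, nbins * bin_width), weights=wpair
    )
    p = hist.astype(np.float64)
    p /= p.sum() * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PairDistribution(r=centers, p=p, dmax=dmax, bin_width=bin_width)


def kratky_transform(p: ScatteringProfile) -> np.ndarray:
    """(n, 2) table of (Q, Q^2 I(Q)); no smoothing."""
    return np.column_stack([p.q, p.q**2 * p.intensity])


# ---------------------------------------------------------------------------
# reduced chi-squared
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """Model/experiment comparison grid and conventions.

    ``n_points`` equally spaced Q values on ``(0, q_max]`` (spacing
    ``q_max / n_points``), default 19 points up to 0.19 A^-1. ``scale_mode``
    is ``"fitted"`` (analytic least-squares scale, one parameter charged to
    the degrees of freedom) or ``"fixed"`` (scale 1, no parameter).
    ``constant_sigma`` supplies an explicit uncertainty when the experimental
    profile has none.
    """

    n_points: int = 19
    q_max: float = 0.19
    scale_mode: str = "fitted"
    constant_sigma: float | None = None

    def __post_init__(self):
        if self.n_points < 3:
            raise ValidationError("need >= 3 fit grid points")
        if self.q_max <= 0:
            raise ValidationError("q_max must be positive")
        if self.scale_mode not in ("fitted", "fixed"):
            raise ValidationError("scale_mode must be 'fitted' or 'fixed'")
        if self.constant_sigma is not None and self.constant_sigma <= 0:
            raise ValidationError("constant_sigma must be positive")

    @property
    def dof_parameters(self) -> int:
        return 1 if self.scale_mode == "fitted" else 0


def fit_qgrid(cfg: FitConfig) -> np.ndarray:
    """The comparison grid: n_points values with spacing q_max/n_points.

    Starts one grid spacing above zero (Q = 0 is unmeasurable) and ends at
    q_max, e.g. 0.01, 0.02, ..., 0.19 for the default configuration.
    """
    dq = cfg.q_max / cfg.n_points
    return dq * np.arange(1, cfg.n_points + 1)


def _interp_profile(p: ScatteringProfile, grid: np.ndarray, what: str):
    if grid[0] < p.q[0] - 1e-12 or grid[-1] > p.q[-1] + 1e-12:
        raise ValidationError(
            f"{what} profile [{p.q[0]:.4g}, {p.q[-1]:.4g}] does not cover "
            f"fit grid [{grid[0]:.4g}, {grid[-1]:.4g}]"
        )
    i = np.interp(grid, p.q, p.intensity)
    s = np.interp(grid, p.q, p.sigma) if p.sigma is not None else None
    return i, s


def reduced_chi2(
    model: ScatteringProfile,
    experiment: ScatteringProfile,
    cfg: FitConfig | None = None,
) -> tuple[float, float]:
    """Reduced chi-squared of a model profile against an experimental one.

    Both profiles are linearly interpolated onto the configuration's Q grid.
    With ``scale_mode = "fitted"`` the scale ``c`` minimising
    ``sum ((c I_m - I_e) / sigma)^2`` is used and one degree of freedom is
    charged; with ``"fixed"`` the scale is 1. Returns ``(chi2_red, scale)``.
    """
    cfg = cfg or FitConfig()
    grid = fit_qgrid(cfg)
    im, _ = _interp_profile(model, grid, "model")
    ie, se = _interp_profile(experiment, grid, "experiment")
    if se is None:
        if cfg.constant_sigma is None:
            raise ValidationError(
                "experiment has no sigma; set FitConfig.constant_sigma"
            )
        se = np.full_like(ie, cfg.constant_sigma)
    if np.any(se <= 0):
        raise ValidationError("nonpositive sigma on fit grid")
    if cfg.scale_mode == "fitted":
        denom = float(np.sum((im / se) ** 2))
        if denom == 0:
            raise ValidationError("model is identically zero on the fit grid")
        scale = float(np.sum(im * ie / se**2) / denom)
    else:
        scale = 1.0
    resid = (scale * im - ie) / se
    dof = cfg.n_points - cfg.dof_parameters
    return float(np.sum(resid**2) / dof), scale
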