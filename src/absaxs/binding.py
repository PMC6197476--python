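"""Binding kinetics and stoichiometry arithmetic.

Two quantitative side-computations accompany the scattering analysis:

* a 1:1 Langmuir interaction model for surface-plasmon-resonance
  sensorgrams -- closed-form association/dissociation curves, a seeded
  simulator, and a global nonlinear least-squares fit returning ka, kd,
  Rmax and the derived equilibrium constant KD = kd/ka with asymptotic
  standard errors;
* integer-combination search over component molar masses explaining a
  measured complex mass from size-exclusion/multi-angle-light-scattering
  (SEC-MALS), the computation that pins the 2:2 stoichiometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ValidationError

__all__ = [
    "KineticParams",
    "Sensorgram",
    "ComponentMass",
    "StoichiometryCombo",
    "StoichiometryResult",
    "OneToOneFitResult",
    "simulate_sensorgram",
    "fit_one_to_one",
    "stoichiometry_search",
]


@dataclass(frozen=True)
class KineticParams:
    """1:1 interaction model parameters.

    ``ka`` in 1/(M s), ``kd`` in 1/s, ``rmax`` in response units; the derived
    equilibrium dissociation constant is ``kD = kd / ka`` (M).
    """

    ka: float
    kd: float
    rmax: float

    def __post_init__(self):
        if self.ka <= 0 or self.kd <= 0 or self.rmax <= 0:
            raise ValidationError("ka, kd, rmax must all be positive")

    @property
    def kD(self) -> float:
        return self.kd / self.ka


@dataclass
class Sensorgram:
    """One phase of one injection: time (s), response (RU), analyte conc (M)."""

    time: np.ndarray
    response: np.ndarray
    concentration: float
    phase: str  # "association" | "dissociation"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=np.float64)
        self.response = np.asarray(self.response, dtype=np.float64)
        if self.time.shape != self.response.shape:
            raise ValidationError("time and response must have equal length")
        if len(self.time) and np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")
        if self.phase not in ("association", "dissociation"):
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.concentration < 0:
            raise ValidationError("concentration must be >= 0")


def association_curve(p: KineticParams, conc: float, t: np.ndarray) -> np.ndarray:
    """R(t) = Req (1 - exp(-(ka C + kd) t)), Req = rmax ka C / (ka C + kd)."""
    t = np.asarray(t, dtype=np.float64)
    kobs = p.ka * conc + p.kd
    req = p.rmax * p.ka * conc / kobs
    return req * (1.0 - np.exp(-kobs * t))


def dissociation_curve(p: KineticParams, r0: float, t: np.ndarray) -> np.ndarray:
    """R(t) = R(0) exp(-kd t) measured from the start of dissociation."""
    return r0 * np.exp(-p.kd * np.asarray(t, dtype=np.float64))


def simulate_sensorgram(
    p: KineticParams,
    conc: list[float],
    t_assoc: float = 60.0,
    t_dissoc: float = 120.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 121,
) -> list[Sensorgram]:
    """Closed-form 1:1 sensorgrams with optional additive Gaussian noise.

    Returns two :class:`Sensorgram` records (association then dissociation)
    per concentration, in input order. Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    out = []
    ta = np.linspace(0.0, t_assoc, n_points)
    td = np.linspace(0.0, t_dissoc, n_points)
    for c in conc:
        if c < 0:
            raise ValidationError("concentrations must be >= 0")
        ra = association_curve(p, c, ta)
        r_end = float(ra[-1])
        rd = dissociation_curve(p, r_end, td)
        if noise_sd > 0:
            ra = ra + rng.normal(0.0, noise_sd, size=ra.shape)
            rd = rd + rng.normal(0.0, noise_sd, size=rd.shape)
        out.append(Sensorgram(ta, ra, c, "association"))
        out.append(Sensorgram(td, rd, c, "dissociation"))
    return out


@dataclass(frozen=True)
class OneToOneFitResult:
    """Global 1:1 kinetic fit: estimates, asymptotic SEs and diagnostics."""

    params: KineticParams
    se_ka: float
    se_kd: float
    se_rmax: float
    kD: float
    se_kD: float
    rss: float
    n_obs: int

    def summary(self) -> str:
        p = self.params
        return "\n".join(
            [
                "1:1 interaction model (global nonlinear least squares)",
                f"  ka    {p.ka:12.5g} 1/(M s)   +/- {self.se_ka:.3g}",
                f"  kd    {p.kd:12.5g} 1/s       +/- {self.se_kd:.3g}",
                f"  Rmax  {p.rmax:12.5g} RU        +/- {self.se_rmax:.3g}",
                f"  KD    {self.kD:12.5g} M         +/- {self.se_kD:.3g}",
                f"  RSS   {self.rss:12.5g} over {self.n_obs} points",
            ]
        )


def _stack_residuals(data: list[Sensorgram], theta_log: np.ndarray) -> np.ndarray:
    ka, kd, rmax = np.exp(theta_log)
    p = KineticParams(ka, kd, rmax)
    res = []
    for sg in data:
        if sg.phase == "association":
            model = association_curve(p, sg.concentration, sg.time)
        else:
            r0 = association_curve(
                p, sg.concentration, np.array([sg.meta_t_assoc])
            )[0]
            model = dissociation_curve(p, r0, sg.time)
        res.append(model - sg.response)
    return np.concatenate(res)


def fit_one_to_one(data: list[Sensorgram]) -> OneToOneFitResult:
    """Global 1:1 fit of (ka, kd, rmax) over all curves, shared Rmax.

    Dissociation curves are tied to their association curve (same
    concentration): R at the start of dissociation is the model's association
    response at the association end time. Parameters are fitted in log space
    (positivity); standard errors are asymptotic (J^T J inverse scaled by the
    residual variance), with the KD uncertainty by the delta method.
    """
    assoc = [d for d in data if d.phase == "association"]
    dissoc = [d for d in data if d.phase == "dissociation"]
    if not assoc or not dissoc:
        raise ValidationError("need both association and dissociation phases")
    concs = sorted({d.concentration for d in assoc if d.concentration > 0})
    if len(concs) < 2:
        warnings.warn(
            "single analyte concentration: kinetic parameters are weakly "
            "identified; expect wide intervals",
            stacklevel=2,
        )
    elif concs[-1] / concs[0] < 10.0:
        warnings.warn(
            "concentration span < 10-fold: fit may be ill-conditioned",
            stacklevel=2,
        )
    # attach each dissociation record to its association end time
    t_assoc_by_conc = {d.concentration: float(d.time[-1]) for d in assoc}
    for d in dissoc:
        if d.concentration not in t_assoc_by_conc:
            raise ValidationError(
                "dissociation phase without matching association concentration"
            )
        d.meta_t_assoc = t_assoc_by_conc[d.concentration]

    rmax0 = max(float(np.max(d.response)) for d in assoc) or 1.0
    # crude kd from the tail ratio of the largest dissociation curve
    ref = max(dissoc, key=lambda d: abs(d.response[0]) if len(d.response) else 0.0)
    kd0 = 1e-3
    if len(ref.response) > 2 and ref.response[0] > 0 and ref.response[-1] > 0:
        span = ref.time[-1] - ref.time[0]
        if span > 0 and ref.response[-1] < ref.response[0]:
            kd0 = float(np.log(ref.response[0] / ref.response[-1]) / span)
            kd0 = min(max(kd0, 1e-6), 10.0)
    c_mid = float(np.median(concs)) if concs else 1e-7
    ka0 = kd0 / max(c_mid, 1e-12)
    x0 = np.log([ka0, kd0, 1.5 * rmax0])

    fitted = assoc + dissoc
    result = least_squares(
        lambda th: _stack_residuals(fitted, th),
        x0,
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=20000,
    )
    if not result.success and result.status <= 0:
        raise FitError(f"1:1 kinetic fit did not converge: {result.message}")
    ka, kd, rmax = np.exp(result.x)
    n = len(result.fun)
    dof = max(n - 3, 1)
    s2 = float(result.fun @ result.fun) / dof
    J = result.jac  # d residual / d log-theta
    try:
        cov_log = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov_log = np.full((3, 3), np.inf)
    # delta method back to natural scale: var(theta) = theta^2 var(log theta)
    se = np.sqrt(np.maximum(np.diag(cov_log), 0.0)) * np.array([ka, kd, rmax])
    kD = kd / ka
    # var(log kD) = var(log kd) + var(log ka) - 2 cov
    var_log_kD = cov_log[1, 1] + cov_log[0, 0] - 2.0 * cov_log[0, 1]
    se_kD = kD * float(np.sqrt(max(var_log_kD, 0.0)))
    return OneToOneFitResult(
        params=KineticParams(ka, kd, rmax),
        se_ka=float(se[0]),
        se_kd=float(se[1]),
        se_rmax=float(se[2]),
        kD=float(kD),
        se_kD=se_kD,
        rss=float(result.fun @ result.fun),
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# stoichiometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentMass:
    """A molar mass with uncertainty, in kDa."""

    name: str
    mw: float
    sigma: float = 0.0

    def __post_init__(self):
        if self.mw <= 0:
            raise ValidationError("molar mass must be positive")
        if self.sigma < 0:
            raise ValidationError("mass uncertainty must be >= 0")


@dataclass(frozen=True)
class StoichiometryCombo:
    n_antigen: int
    n_antibody: int
    predicted_mw: float
    predicted_sigma: float
    z: float


@dataclass(frozen=True)
class StoichiometryResult:
    """Accepted integer combinations, sorted by |z|."""

    combos: tuple
    measured: ComponentMass
    z_limit: float

    def unique(self) -> StoichiometryCombo | None:
        return self.combos[0] if len(self.combos) == 1 else None

    def summary(self) -> str:
        lines = [
            f"stoichiometry search vs measured {self.measured.mw:g} "
            f"+/- {self.measured.sigma:g} kDa (|z| <= {self.z_limit:g})",
            "  n_antigen n_antibody predicted_kDa sigma_kDa      z",
        ]
        for c in self.combos:
            lines.append(
                f"  {c.n_antigen:9d} {c.n_antibody:10d} "
                f"{c.predicted_mw:13.1f} {c.predicted_sigma:9.2f} {c.z:6.2f}"
            )
        if not self.combos:
            lines.append("  (no combination within the window)")
        return "\n".join(lines)


def stoichiometry_search(
    antigen: ComponentMass,
    antibody: ComponentMass,
    measured: ComponentMass,
    n_max: int = 4,
    z_limit: float = 1.0,
) -> StoichiometryResult:
    """Enumerate i antigen + j antibody combinations matching a measured mass.

    All (i, j) with 0 <= i, j <= n_max and i + j >= 1 are scored:
    ``predicted = i mw_ag + j mw_ab`` with uncertainty
    ``sqrt(i^2 s_ag^2 + j^2 s_ab^2)``; a combination is accepted when
    ``|predicted - measured| <= z_limit * sqrt(s_pred^2 + s_meas^2)``.
    Results are sorted by |z| (ties by (i, j)).
    """
    if n_max < 1:
        raise ValidationError("n_max must be >= 1")
    if z_limit <= 0:
        raise ValidationError("z_limit must be positive")
    accepted = []
    for i in range(n_max + 1):
        for j in range(n_max + 1):
            if i + j < 1:
                continue
            mw = i * antigen.mw + j * antibody.mw
            sig = float(np.hypot(i * antigen.sigma, j * antibody.sigma))
            denom = float(np.hypot(sig, measured.sigma))
            if denom == 0:
                z = 0.0 if mw == measured.mw else np.inf
            else:
                z = (mw - measured.mw) / denom
            if abs(z) <= z_limit:
                accepted.append(StoichiometryCombo(i, j, mw, sig, float(z)))
    accepted.sort(key=lambda c: (abs(c.z), c.n_antigen, c.n_antibody))
    return StoichiometryResult(tuple(accepted), measured, z_limit)
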