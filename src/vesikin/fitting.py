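"""Global fit of the non-pseudo-first-order relaxation model to k_obs data.

Fits (k_on, k_off, c1) by nonlinear least squares of

    k_obs(L) = sqrt( k_on^2 (E - c1 L)^2 + k_off^2 + 2 k_on k_off (E + c1 L) )

to an observed k_obs-vs-lipid table, with the protein concentration E held
fixed.  All three parameters are log-parameterised (positivity by
construction) and the optimiser is multi-started from a seeded Latin
hypercube, because the three-parameter surface has a ridge along the
pseudo-first-order direction where k_on and c1 trade off.

Two lipid-basis conventions are supported: ``c1`` applied to the
accessible (outer-leaflet) lipid concentration, or to the total lipid
concentration.  The two fits are identical up to rescaling c1 by the
leaflet factor, so both stoichiometries (lipids per protein) are always
reported; the convention sweep exists because published reports do not
always state which basis a stoichiometry refers to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .errors import DataError, FitError
from .kinetics import KineticParams, kobs_closed_form
from .traces import KobsPoint

__all__ = [
    "KineticFitResult",
    "FitConvention",
    "BootstrapResult",
    "fit_kobs_vs_lipid",
    "bootstrap_uncertainty",
    "stoichiometry_report",
    "sweep_conventions",
]

# log10 ranges of the multi-start hypercube
_START_RANGES = {
    "k_on": (-1.0, 1.0),  # 0.1 .. 10 μM⁻¹s⁻¹
    "k_off": (-2.0, math.log10(2.0)),  # 0.01 .. 2 s⁻¹
    "c1": (math.log10(0.005), -1.0),  # 0.005 .. 0.1
}
_TIE_TOL = 1e-10


@dataclass(frozen=True)
class FitConvention:
    """One interpretation of the ambiguous fit inputs.

    ``lipid_basis`` says whether c1 multiplies the accessible
    (leaflet-corrected) or the total lipid concentration.
    """

    protein_conc: float
    lipid_basis: str = "accessible"
    weighting: str = "none"

    def __post_init__(self) -> None:
        if self.lipid_basis not in ("accessible", "total"):
            raise DataError(f"lipid_basis must be 'accessible' or 'total', got {self.lipid_basis!r}")
        if self.weighting not in ("none", "inverse_variance"):
            raise DataError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class KineticFitResult:
    """Fitted parameters with derived K_D and stoichiometries.

    ``stoich_accessible`` is lipids-per-protein counting only accessible
    (outer-leaflet) lipid; ``stoich_total`` counts all lipid.  Both satisfy
    their defining identities against ``params`` exactly.
    """

    params: KineticParams
    kd: float
    stoich_accessible: float
    stoich_total: float
    rss: float
    param_se: dict[str, float]
    n_points: int
    convergence: dict
    convention: FitConvention
    leaflet_factor: float
    seed: int


def _site_lipid(points: Sequence[KobsPoint], convention: FitConvention, leaflet_factor: float) -> np.ndarray:
    """Lipid concentration that c1 multiplies, per the convention's basis."""
    acc = np.array([p.lipid_accessible for p in points], dtype=float)
    if convention.lipid_basis == "accessible":
        return acc
    return acc / leaflet_factor


def _weights(points: Sequence[KobsPoint], weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones(len(points))
    ses = [p.se for p in points]
    if any(s is None or s <= 0 for s in ses):
        raise DataError("inverse-variance weighting requires positive se on every point")
    return 1.0 / np.asarray(ses, dtype=float)


def fit_kobs_vs_lipid(
    points: Sequence[KobsPoint],
    protein_conc: float | None = None,
    *,
    convention: FitConvention | None = None,
    weighting: str = "none",
    n_starts: int = 16,
    seed: int = 0,
    leaflet_factor: float = 0.5,
) -> KineticFitResult:
    """Multi-start least-squares fit of the relaxation model to a k_obs table.

    Either pass ``protein_conc`` (accessible basis, given weighting) or a
    full :class:`FitConvention`.  Deterministic for a given seed; ties
    between multi-start optima (ΔRSS < 1e-10) are broken by smallest k_off.
    """
    points = list(points)
    if len(points) < 4:
        raise DataError(f"need >= 4 points to fit 3 parameters, got {len(points)}")
    if convention is None:
        if protein_conc is None:
            raise DataError("provide protein_conc or a FitConvention")
        convention = FitConvention(protein_conc, "accessible", weighting)
    e0 = convention.protein_conc
    if not e0 > 0:
        raise DataError("protein concentration must be > 0")

    lipid = _site_lipid(points, convention, leaflet_factor)
    kobs = np.array([p.k_obs for p in points], dtype=float)
    w = _weights(points, convention.weighting)

    def residuals(logp: np.ndarray) -> np.ndarray:
        kon, koff, c1 = np.exp(logp)
        pred = np.sqrt(
            kon**2 * (e0 - c1 * lipid) ** 2
            + koff**2
            + 2 * kon * koff * (e0 + c1 * lipid)
        )
        return w * (pred - kobs)

    # seeded Latin hypercube over the log10 parameter box, plus one
    # data-driven start from the pseudo-first-order line
    sampler = qmc.LatinHypercube(d=3, seed=seed)
    lows = np.array([r[0] for r in _START_RANGES.values()])
    highs = np.array([r[1] for r in _START_RANGES.values()])
    starts = [lows + sampler.random(1)[0] * (highs - lows) for _ in range(n_starts)]
    slope, intercept = np.polyfit(lipid, kobs, 1)
    c1_guess = 0.02
    if slope > 0:
        starts.append(
            np.log10([max(slope / c1_guess, 1e-3), max(intercept, 1e-3), c1_guess])
        )

    solutions = []
    diagnostics = []
    if convention.lipid_basis == "accessible":
        c1_max = 1.0
    else:
        # c1 on total lipid: at most one site per accessible lipid
        c1_max = leaflet_factor
    bounds = (
        np.log([1e-6, 1e-9, 1e-8]),
        np.log([1e6, 1e3, c1_max]),
    )
    for i, s in enumerate(starts):
        p0 = np.clip(np.asarray(s) * math.log(10), bounds[0] + 1e-9, bounds[1] - 1e-9)
        try:
            sol = least_squares(
                residuals,
                p0,
                bounds=bounds,
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=5000,
            )
        except Exception as exc:  # noqa: BLE001
            diagnostics.append({"start": i, "error": str(exc)})
            continue
        diagnostics.append({"start": i, "status": int(sol.status), "cost": float(sol.cost)})
        if sol.success:
            solutions.append((i, sol))
    if not solutions:
        raise FitError("all multi-starts failed", diagnostics={"starts": diagnostics})

    best_cost = min(sol.cost for _, sol in solutions)
    # ties broken by smallest k_off for determinism
    tied = [(i, sol) for i, sol in solutions if sol.cost - best_cost < _TIE_TOL / 2]
    best_i, best = min(tied, key=lambda t: t[1].x[1])

    kon, koff, c1 = np.exp(best.x)
    params = KineticParams(k_on=float(kon), k_off=float(koff), c1=float(min(c1, 1.0)))
    rss = float(2 * best.cost)

    dof = len(points) - 3
    se = {"k_on": 0.0, "k_off": 0.0, "c1": 0.0}
    if dof > 0 and rss > 0:
        try:
            cov = np.linalg.inv(best.jac.T @ best.jac) * rss / dof
            for j, name in enumerate(("k_on", "k_off", "c1")):
                se[name] = float(np.exp(best.x[j]) * math.sqrt(max(cov[j, j], 0.0)))
        except np.linalg.LinAlgError:
            se = {k: float("nan") for k in se}

    if convention.lipid_basis == "accessible":
        stoich_accessible = 1.0 / params.c1
        stoich_total = 1.0 / (params.c1 * leaflet_factor)
    else:
        stoich_total = 1.0 / params.c1
        stoich_accessible = leaflet_factor / params.c1

    return KineticFitResult(
        params=params,
        kd=params.kd,
        stoich_accessible=stoich_accessible,
        stoich_total=stoich_total,
        rss=rss,
        param_se=se,
        n_points=len(points),
        convergence={
            "n_starts": len(starts),
            "n_converged": len(solutions),
            "best_start": best_i,
            "status": int(best.status),
            "nfev": int(best.nfev),
        },
        convention=convention,
        leaflet_factor=leaflet_factor,
        seed=seed,
    )


@dataclass
class BootstrapResult:
    """Residual-resampling bootstrap percentile intervals."""

    intervals: dict[str, tuple[float, float]]
    level: float
    n_boot: int
    n_failed: int
    seed: int


def bootstrap_uncertainty(
    points: Sequence[KobsPoint],
    protein_conc: float,
    fit: KineticFitResult,
    n_boot: int = 500,
    seed: int = 0,
    *,
    level: float = 0.95,
) -> BootstrapResult:
    """Residual-resampling bootstrap confidence intervals for the fit.

    Residuals of the accepted fit are resampled with replacement onto the
    fitted curve and each pseudo-dataset is refit (single start at the
    point estimate — the resampled surface is a small perturbation of the
    original, so the original optimum is the natural start).  Failed
    refits are excluded and counted.
    """
    if n_boot < 100:
        raise DataError("n_boot must be >= 100")
    points = list(points)
    lipid = _site_lipid(points, fit.convention, fit.leaflet_factor)
    kobs = np.array([p.k_obs for p in points])
    e0 = fit.convention.protein_conc
    p = fit.params
    pred = np.sqrt(
        p.k_on**2 * (e0 - p.c1 * lipid) ** 2
        + p.k_off**2
        + 2 * p.k_on * p.k_off * (e0 + p.c1 * lipid)
    )
    resid = kobs - pred
    rng = np.random.default_rng(seed)
    logp0 = np.log([p.k_on, p.k_off, p.c1])

    samples: dict[str, list[float]] = {"k_on": [], "k_off": [], "c1": [], "kd": []}
    n_failed = 0
    for _ in range(n_boot):
        y = pred + rng.choice(resid, size=len(resid), replace=True)

        def residuals(logq):
            kon, koff, c1 = np.exp(logq)
            model = np.sqrt(
                kon**2 * (e0 - c1 * lipid) ** 2
                + koff**2
                + 2 * kon * koff * (e0 + c1 * lipid)
            )
            return model - y

        try:
            sol = least_squares(residuals, logp0, method="lm", max_nfev=2000)
        except Exception:  # noqa: BLE001
            n_failed += 1
            continue
        if not sol.success:
            n_failed += 1
            continue
        kon, koff, c1 = np.exp(sol.x)
        samples["k_on"].append(kon)
        samples["k_off"].append(koff)
        samples["c1"].append(c1)
        samples["kd"].append(koff / kon)

    alpha = (1 - level) / 2
    intervals = {
        name: (
            float(np.quantile(vals, alpha)),
            float(np.quantile(vals, 1 - alpha)),
        )
        for name, vals in samples.items()
        if vals
    }
    return BootstrapResult(
        intervals=intervals, level=level, n_boot=n_boot, n_failed=n_failed, seed=seed
    )


def stoichiometry_report(
    fit: "KineticFitResult | KineticParams | float", leaflet_factor: float = 0.5
) -> dict:
    """Protein-to-lipid stoichiometry as 1:N strings on both lipid bases.

    Accepts a fit result, bare parameters, or a c1 value interpreted on
    the accessible-lipid basis.
    """
    if isinstance(fit, KineticFitResult):
        acc, tot = fit.stoich_accessible, fit.stoich_total
    else:
        c1 = fit.c1 if isinstance(fit, KineticParams) else float(fit)
        if not c1 > 0:
            raise DataError("c1 must be > 0")
        acc, tot = 1.0 / c1, 1.0 / (c1 * leaflet_factor)
    return {
        "lipids_per_protein_accessible": acc,
        "lipids_per_protein_total": tot,
        "accessible": f"1:{round(acc)}",
        "total": f"1:{round(tot)}",
    }


def sweep_conventions(
    points: Sequence[KobsPoint],
    *,
    protein_concs: Sequence[float] = (0.2, 0.78),
    lipid_bases: Sequence[str] = ("accessible", "total"),
    weightings: Sequence[str] = ("none", "inverse_variance"),
    leaflet_factor: float = 0.5,
    n_starts: int = 16,
    seed: int = 0,
) -> list[KineticFitResult]:
    """Fit every combination of the documented input conventions.

    The reported protein concentration, the lipid basis of c1, and the
    use of the printed standard errors are each ambiguous in typical
    reports, so all combinations are fit and returned; callers decide
    which convention to treat as primary.  Weightings that cannot be
    applied (no standard errors) are skipped.
    """
    results = []
    for e0 in protein_concs:
        for basis in lipid_bases:
            for weighting in weightings:
                conv = FitConvention(e0, basis, weighting)
                try:
                    res = fit_kobs_vs_lipid(
                        points,
                        convention=conv,
                        n_starts=n_starts,
                        seed=seed,
                        leaflet_factor=leaflet_factor,
                    )
                except DataError:
                    continue  # e.g. weighting without standard errors
                results.append(res)
    return results
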