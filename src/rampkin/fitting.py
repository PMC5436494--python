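"""Global Arrhenius fitting of kinetic parameters to campaign data.

All profiles (every species at every injection across every ramp) enter
one nonlinear least-squares problem solved with Levenberg–Marquardt.
Rate constants are optimised as log(k_ref) so positivity is structural;
activation energies are optimised linearly with bounds.  The recommended
protocol mirrors transient-campaign practice: rate constants are first
fitted on the isothermal ramps at the reference temperature (where the
model is insensitive to Ea), then all parameters are refined against the
full data set simultaneously.

Uncertainty uses the linearised covariance s^2 (J^T J)^-1 at the
optimum, mapped to the natural parameter scale by the delta method, with
Student-t 95% half-widths.  Candidate rate-law motifs (different orders
in the aromatic component and the nucleophile) are discriminated by SSE
and by the corrected Akaike criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, DataError, IdentifiabilityError
from .network import ArrheniusParams, KineticScheme, StateVector, simulate_batch_profile
from .rig import SampleTable

#: species whose concentrations enter the residual by default (the
#: aromatic components quantified by HPLC; the amine is not followed)
DEFAULT_RESIDUAL_SPECIES = ("1", "3", "4", "5")


@dataclass(frozen=True)
class FitSpec:
    """What is fitted and how."""

    T_ref: float = 363.15  # K
    init_k_ref: float = 0.1  # M^-1 s^-1, common initial guess
    init_Ea: float = 50_000.0  # J mol^-1
    k_bounds: tuple[float, float] = (1e-6, 1e3)
    Ea_bounds: tuple[float, float] = (0.0, 200_000.0)
    vary_Ea: bool = True
    weighting: str = "absolute"  # "absolute" | "relative"
    relative_floor: float = 1e-3  # M, floor for relative weighting
    residual_species: tuple[str, ...] = DEFAULT_RESIDUAL_SPECIES
    max_nfev: int = 20_000
    xtol: float = 1e-10
    ftol: float = 1e-10

    def __post_init__(self):
        if not (self.k_bounds[0] < self.init_k_ref < self.k_bounds[1]):
            raise ConvergenceError("initial k_ref outside its bounds")
        if self.vary_Ea and not (
            self.Ea_bounds[0] <= self.init_Ea <= self.Ea_bounds[1]
        ):
            raise ConvergenceError("initial Ea outside its bounds")
        if self.weighting not in ("absolute", "relative"):
            raise ConvergenceError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class CandidateModel:
    """A rate-law motif: common reaction orders in the aromatic reactant
    and the nucleophile applied to every step of the network."""

    label: str
    aromatic_order: int
    nucleophile_order: int

    def __post_init__(self):
        if self.aromatic_order not in (0, 1, 2) or self.nucleophile_order not in (0, 1, 2):
            raise ConvergenceError("candidate orders must be in {0, 1, 2}")


def default_candidate_motifs() -> list[CandidateModel]:
    return [
        CandidateModel("second-order (1,1)", 1, 1),
        CandidateModel("zero-order in nucleophile (1,0)", 1, 0),
        CandidateModel("second-order in nucleophile (1,2)", 1, 2),
    ]


@dataclass
class FitResult:
    estimates: dict[str, dict[str, float]]  # step label -> {k_ref, Ea}
    stderr: dict[str, dict[str, float]]
    ci95: dict[str, dict[str, float]]  # 95% half-widths
    covariance: np.ndarray | None  # natural scale, ordered as param_names
    param_names: list[str]
    residuals: np.ndarray
    sse: float
    r_squared: float
    ndata: int
    nvarys: int
    dof: int
    success: bool
    message: str
    nfev: int
    minimizer_result: lmfit.minimizer.MinimizerResult = field(repr=False, default=None)

    def k_ref(self, label: str) -> float:
        return self.estimates[label]["k_ref"]

    def Ea(self, label: str) -> float:
        return self.estimates[label]["Ea"]


# ---------------------------------------------------------------------------
# residual machinery

def _ramp_groups(table: SampleTable, species_ids: list[str]):
    """Precompute per-ramp structures: initial state, temperature, sorted
    residence-time grid and row mapping."""
    groups = []
    for ramp_id, df in table.groupby_ramp():
        taus = df["tau_res_min"].to_numpy(float) * 60.0
        order = np.argsort(taus)
        T = float(df["temp_C"].iloc[0]) + 273.15
        c0 = {sid: 0.0 for sid in species_ids}
        c0["1"] = float(df["C1_0_M"].iloc[0])
        c0["2"] = float(df["C2_0_M"].iloc[0])
        groups.append({
            "ramp_id": ramp_id,
            "T": T,
            "state0": StateVector(c0, T),
            "taus_sorted": taus[order],
            "unsort": np.argsort(order),
            "rows": df.index.to_numpy(),
        })
    return groups


def model_concentrations(
    table: SampleTable, scheme: KineticScheme,
    species: tuple[str, ...] = DEFAULT_RESIDUAL_SPECIES,
) -> np.ndarray:
    """Model-predicted concentrations for every table row (rows, species),
    integrating the batch ODEs once per ramp."""
    sid_all = scheme.species_ids
    cols = [sid_all.index(s) for s in species]
    out = np.empty((len(table), len(species)))
    row_pos = {r: i for i, r in enumerate(table.data.index)}
    for g in _ramp_groups(table, sid_all):
        traj = simulate_batch_profile(scheme, g["state0"], g["T"], g["taus_sorted"])
        traj = traj[g["unsort"]]
        for r, c in zip(g["rows"], traj[:, cols]):
            out[row_pos[r]] = c
    return out


def _measured(table: SampleTable, species: tuple[str, ...]) -> np.ndarray:
    return table.data[[f"C{s}_M" for s in species]].to_numpy(float)


def _scheme_from_params(params: lmfit.Parameters, scheme: KineticScheme,
                        T_ref: float) -> KineticScheme:
    plist = []
    for step in scheme.steps:
        k = math.exp(params[f"lnk_{step.label}"].value)
        Ea = params[f"Ea_{step.label}"].value
        plist.append(ArrheniusParams(k, Ea, T_ref))
    return scheme.with_params(plist)


def fit_global(
    table: SampleTable,
    scheme: KineticScheme,
    spec: FitSpec = FitSpec(),
    init_k_ref: dict[str, float] | None = None,
) -> FitResult:
    """Simultaneous least-squares fit of (k_ref, Ea) for every step.

    ``init_k_ref`` optionally overrides the common initial guess per step
    label (e.g. the output of an isothermal pre-fit).
    """
    nvarys = len(scheme.steps) * (2 if spec.vary_Ea else 1)
    if len(table) * len(spec.residual_species) <= nvarys:
        raise DataError("fewer informative data points than free parameters")
    if spec.vary_Ea:
        temps = np.unique(np.round(table.data["temp_C"].to_numpy(float), 6))
        if len(temps) < 2:
            # a single temperature cannot constrain Ea; the Jacobian column
            # is exactly zero when that temperature is T_ref
            pass  # allowed to proceed: covariance machinery reports it

    params = lmfit.Parameters()
    for step in scheme.steps:
        k0 = (init_k_ref or {}).get(step.label, spec.init_k_ref)
        params.add(
            f"lnk_{step.label}", value=math.log(k0),
            min=math.log(spec.k_bounds[0]), max=math.log(spec.k_bounds[1]),
        )
        params.add(
            f"Ea_{step.label}", value=spec.init_Ea,
            min=spec.Ea_bounds[0], max=spec.Ea_bounds[1], vary=spec.vary_Ea,
        )

    measured = _measured(table, spec.residual_species)
    if spec.weighting == "relative":
        weights = 1.0 / np.maximum(np.abs(measured), spec.relative_floor)
    else:
        weights = np.ones_like(measured)

    def residual(p):
        sch = _scheme_from_params(p, scheme, spec.T_ref)
        model = model_concentrations(table, sch, spec.residual_species)
        return ((model - measured) * weights).ravel()

    minner = lmfit.Minimizer(residual, params)
    result = minner.minimize(
        method="leastsq", xtol=spec.xtol, ftol=spec.ftol, max_nfev=spec.max_nfev
    )
    if not result.success:
        raise ConvergenceError(f"global fit did not converge: {result.message}")
    return _build_fit_result(result, table, scheme, spec, measured, weights)


def fit_two_stage(
    table: SampleTable,
    scheme: KineticScheme,
    spec: FitSpec = FitSpec(),
    isothermal_tol_K: float = 0.5,
) -> FitResult:
    """Two-stage protocol: (1) fit rate constants alone on the ramps at
    the reference temperature; (2) refine all parameters globally from
    those starting values.  Returns the stage-2 result."""
    t_ref_C = spec.T_ref - 273.15
    iso = table.data[np.abs(table.data["temp_C"] - t_ref_C) <= isothermal_tol_K]
    if len(iso) == 0:
        raise DataError(
            f"no ramps at the reference temperature {t_ref_C:.0f} C for stage 1"
        )
    iso_table = SampleTable(iso.copy(), table.scheme_name, table.config_hash)
    from dataclasses import replace as _replace

    stage1 = fit_global(iso_table, scheme, _replace(spec, vary_Ea=False))
    inits = {label: est["k_ref"] for label, est in stage1.estimates.items()}
    return fit_global(table, scheme, spec, init_k_ref=inits)


def _build_fit_result(result, table, scheme, spec, measured, weights) -> FitResult:
    labels = [s.label for s in scheme.steps]
    names: list[str] = []
    for lab in labels:
        names.append(f"k_ref_{lab}")
        if spec.vary_Ea:
            names.append(f"Ea_{lab}")

    estimates, stderr_nat, ci_nat = {}, {}, {}
    dof = max(result.nfree, 0)
    tq = stats.t.ppf(0.975, dof) if dof > 0 else np.nan

    # delta method: var(k) = k^2 var(ln k); Ea is already natural scale
    internal = [f"lnk_{lab}" for lab in labels]
    if spec.vary_Ea:
        internal = [n for lab in labels for n in (f"lnk_{lab}", f"Ea_{lab}")]
    cov_nat = None
    if result.covar is not None:
        var_index = [p for p in result.var_names]
        scale = []
        for n in internal:
            v = result.params[n].value
            scale.append(math.exp(v) if n.startswith("lnk_") else 1.0)
        try:
            sub = np.array([
                [result.covar[var_index.index(a)][var_index.index(b)]
                 for b in internal] for a in internal
            ])
            s = np.asarray(scale)
            cov_nat = sub * np.outer(s, s)
        except ValueError:
            cov_nat = None

    for i, lab in enumerate(labels):
        lnk = result.params[f"lnk_{lab}"]
        Ea = result.params[f"Ea_{lab}"]
        k = math.exp(lnk.value)
        estimates[lab] = {"k_ref": k, "Ea": Ea.value}
        se_k = k * lnk.stderr if lnk.stderr is not None else np.nan
        se_E = Ea.stderr if (spec.vary_Ea and Ea.stderr is not None) else np.nan
        stderr_nat[lab] = {"k_ref": se_k, "Ea": se_E}
        ci_nat[lab] = {"k_ref": tq * se_k, "Ea": tq * se_E}

    resid = np.asarray(result.residual)
    sse = float(np.sum(((resid / weights.ravel())) ** 2))  # unweighted SSE
    r2 = _r_squared(sse, measured)
    return FitResult(
        estimates=estimates,
        stderr=stderr_nat,
        ci95=ci_nat,
        covariance=cov_nat,
        param_names=names,
        residuals=resid,
        sse=sse,
        r_squared=r2,
        ndata=result.ndata,
        nvarys=result.nvarys,
        dof=dof,
        success=bool(result.success),
        message=str(result.message),
        nfev=result.nfev,
        minimizer_result=result,
    )


def _r_squared(sse: float, measured: np.ndarray) -> float:
    sstot = float(np.sum((measured - measured.mean()) ** 2))
    if sstot == 0.0:
        raise DataError("total variance of the measurements is zero; "
                        "R^2 undefined")
    return 1.0 - sse / sstot


def goodness_of_fit(result: FitResult, table: SampleTable,
                    species: tuple[str, ...] = DEFAULT_RESIDUAL_SPECIES) -> float:
    """R^2 = 1 - SSE/SStot with SStot taken about the grand mean of all
    measured concentrations entering the residual (all species pooled)."""
    measured = _measured(table, species)
    return _r_squared(result.sse, measured)


def parameter_uncertainty(result: FitResult) -> pd.DataFrame:
    """Standard errors and 95% confidence half-widths on the natural
    parameter scale.

    Raises :class:`IdentifiabilityError` when the covariance at the
    optimum is singular (e.g. activation energies requested from data at
    a single temperature equal to T_ref).
    """
    if result.covariance is None or not np.all(np.isfinite(
        np.concatenate([list(v.values()) for v in result.stderr.values()])
    )):
        raise IdentifiabilityError(
            "singular or unavailable covariance at the optimum; the requested "
            "parameters are not identifiable from these data"
        )
    rows = []
    for lab, est in result.estimates.items():
        for pname in est:
            rows.append({
                "step": lab,
                "parameter": pname,
                "estimate": est[pname],
                "stderr": result.stderr[lab][pname],
                "ci95_halfwidth": result.ci95[lab][pname],
            })
    return pd.DataFrame(rows)


def aicc(sse: float, n: int, p: int) -> float:
    """Corrected Akaike information criterion for least squares."""
    if n - p - 1 <= 0:
        return np.inf
    return n * math.log(sse / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def discriminate_rate_orders(
    table: SampleTable,
    base_scheme: KineticScheme,
    candidates: list[CandidateModel] | None = None,
    spec: FitSpec = FitSpec(),
) -> pd.DataFrame:
    """Fit each candidate rate-law motif and rank by SSE and AICc.

    Candidates whose fit fails are ranked last and flagged.  Returns a
    DataFrame sorted best-first with columns label, sse, aicc, r_squared,
    success, rank.
    """
    if candidates is None:
        candidates = default_candidate_motifs()
    if len(candidates) == 0:
        raise DataError("at least one candidate motif is required")
    rows = []
    for cand in candidates:
        sch = base_scheme.with_orders(cand.aromatic_order, cand.nucleophile_order)
        try:
            res = fit_global(table, sch, spec)
            rows.append({
                "label": cand.label,
                "sse": res.sse,
                "aicc": aicc(res.sse, res.ndata, res.nvarys),
                "r_squared": res.r_squared,
                "success": True,
            })
        except Exception as exc:  # ranked last, with the failure recorded
            rows.append({
                "label": cand.label, "sse": np.inf, "aicc": np.inf,
                "r_squared": -np.inf, "success": False, "error": str(exc),
            })
    df = pd.DataFrame(rows).sort_values(
        ["success", "sse"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def table1_style_report(result: FitResult) -> str:
    """Human-readable parameter table: k +/- SE in 1e-2 M^-1 s^-1 at
    T_ref, Ea +/- SE in kJ mol^-1."""
    lines = [
        f"{'step':<8}{'k +/- SE (1e-2 M^-1 s^-1)':<28}{'Ea +/- SE (kJ mol^-1)'}",
    ]
    for lab, est in result.estimates.items():
        se = result.stderr[lab]
        k, sk = est["k_ref"] * 100, se["k_ref"] * 100
        E, sE = est["Ea"] / 1000, se["Ea"] / 1000
        lines.append(
            f"{lab:<8}{f'{k:.3g} +/- {sk:.2g}':<28}{f'{E:.3g} +/- {sE:.2g}'}"
        )
    lines.append(f"R^2 = {result.r_squared:.6f}   SSE = {result.sse:.4g}   "
                 f"n = {result.ndata}")
    return "\n".join(lines)
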