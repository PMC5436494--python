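"""Reaction networks of elementary steps with Arrhenius kinetics.

A :class:`KineticScheme` is a list of species plus a list of
:class:`ReactionStep` objects, each carrying power-law reactant orders, a
signed stoichiometry and Arrhenius parameters in the reference-temperature
parameterisation

    k(T) = k_ref * exp[-(Ea/R) * (1/T - 1/T_ref)]

which reports the rate constant directly at a temperature inside the
studied range (here 90 degC) instead of an extrapolated pre-exponential
factor; this strongly decorrelates k and Ea during fitting.

The built-in scheme (:func:`snar_scheme`) is the nucleophilic aromatic
substitution of 2,4-difluoronitrobenzene (1) with pyrrolidine (2) in
ethanol: two parallel substitutions to the ortho (3) and para (4)
mono-adducts, each followed by over-reaction to the bis-adduct (5).
All four steps are second order (first order in each reactant).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigError, IntegrationError, SchemaError

#: Gas constant, J mol^-1 K^-1
R_GAS = 8.314

#: Default integrator tolerances (relative; absolute in M)
RTOL_DEFAULT = 1e-8
ATOL_DEFAULT = 1e-10


@dataclass(frozen=True)
class Species:
    id: str
    name: str = ""
    role: str = "substrate"  # substrate | nucleophile | product | byproduct


@dataclass(frozen=True)
class ArrheniusParams:
    """Rate constant ``k_ref`` at ``T_ref`` (K) and activation energy
    ``Ea`` (J mol^-1)."""

    k_ref: float
    Ea: float
    T_ref: float

    def __post_init__(self):
        if self.k_ref <= 0:
            raise ConfigError(f"k_ref must be positive, got {self.k_ref}")
        if self.T_ref <= 0:
            raise ConfigError(f"T_ref must be positive, got {self.T_ref}")


@dataclass(frozen=True)
class ReactionStep:
    """One elementary step: rate = k(T) * prod_i C_i**order_i.

    ``stoichiometry`` gives the signed concentration change per reaction
    event for every species taking part.
    """

    reactant_orders: dict[str, float]
    stoichiometry: dict[str, float]
    params: ArrheniusParams
    label: str = ""

    def __post_init__(self):
        if not any(o > 0 for o in self.reactant_orders.values()):
            raise ConfigError(
                f"step {self.label!r}: at least one reactant must have a "
                "positive order"
            )
        if any(o < 0 for o in self.reactant_orders.values()):
            raise ConfigError(f"step {self.label!r}: negative reaction orders")


@dataclass(frozen=True)
class KineticScheme:
    species: tuple[Species, ...]
    steps: tuple[ReactionStep, ...]
    #: pyrrolidine molecules consumed per substitution event (1, or 2 if a
    #: second equivalent is sequestered as the amine hydrofluoride salt)
    nucleophile_stoich_factor: int = 1
    name: str = "custom"

    def __post_init__(self):
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"duplicate species ids in scheme: {ids}")
        known = set(ids)
        for step in self.steps:
            referenced = set(step.reactant_orders) | set(step.stoichiometry)
            missing = referenced - known
            if missing:
                raise SchemaError(
                    f"step {step.label!r} references unknown species {sorted(missing)}"
                )

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def stoichiometry_matrix(self) -> np.ndarray:
        """(n_species, n_steps) signed stoichiometric matrix S."""
        idx = {sid: i for i, sid in enumerate(self.species_ids)}
        S = np.zeros((len(self.species), len(self.steps)))
        for j, step in enumerate(self.steps):
            for sid, nu in step.stoichiometry.items():
                S[idx[sid], j] = nu
        return S

    def with_params(self, params: list[ArrheniusParams]) -> "KineticScheme":
        """Copy of the scheme with per-step Arrhenius parameters replaced."""
        if len(params) != len(self.steps):
            raise ConfigError(
                f"expected {len(self.steps)} parameter sets, got {len(params)}"
            )
        steps = tuple(replace(s, params=p) for s, p in zip(self.steps, params))
        return replace(self, steps=steps)

    def with_orders(self, aromatic_order: float, nucleophile_order: float,
                    nucleophile_id: str = "2") -> "KineticScheme":
        """Copy with every step's orders replaced: ``aromatic_order`` in the
        step's aromatic reactant and ``nucleophile_order`` in the
        nucleophile. Used to build candidate rate-law motifs."""
        steps = []
        for s in self.steps:
            arom = [sid for sid in s.reactant_orders if sid != nucleophile_id]
            orders = {a: aromatic_order for a in arom}
            orders[nucleophile_id] = nucleophile_order
            orders = {k: v for k, v in orders.items() if v > 0}
            steps.append(replace(s, reactant_orders=orders))
        return replace(self, steps=tuple(steps), name=f"{self.name}-orders"
                       f"({aromatic_order:g},{nucleophile_order:g})")


@dataclass
class StateVector:
    """Concentrations (M) of every species plus the temperature (K)."""

    concentrations: dict[str, float]
    temperature: float

    def as_array(self, species_ids: list[str]) -> np.ndarray:
        try:
            return np.array([self.concentrations[s] for s in species_ids], float)
        except KeyError as exc:
            raise SchemaError(f"state is missing species {exc.args[0]!r}") from exc


def arrhenius_rate_constant(params: ArrheniusParams, T: float) -> float:
    """Evaluate k(T) = k_ref exp[-(Ea/R)(1/T - 1/T_ref)].

    Exactly equal to ``k_ref`` at ``T = T_ref``; strictly increasing in T
    for positive activation energy.
    """
    if T <= 0:
        raise ConfigError(f"temperature must be positive, got {T} K")
    return params.k_ref * np.exp(-(params.Ea / R_GAS) * (1.0 / T - 1.0 / params.T_ref))


def reaction_rates(scheme: KineticScheme, state: StateVector) -> np.ndarray:
    """Per-step rates (M s^-1): rate_j = k_j(T) * prod_i C_i**order_ij."""
    conc = state.concentrations
    rates = np.empty(len(scheme.steps))
    for j, step in enumerate(scheme.steps):
        k = arrhenius_rate_constant(step.params, state.temperature)
        r = k
        for sid, order in step.reactant_orders.items():
            if sid not in conc:
                raise SchemaError(f"state is missing species {sid!r}")
            c = max(conc[sid], 0.0)
            r *= c ** order
        rates[j] = r
    return rates


def _rhs_factory(scheme: KineticScheme, T: float):
    """Return dC/dt = S.r(C, T) as a closure over precomputed arrays."""
    ids = scheme.species_ids
    idx = {sid: i for i, sid in enumerate(ids)}
    S = scheme.stoichiometry_matrix()
    ks = np.array([arrhenius_rate_constant(s.params, T) for s in scheme.steps])
    order_idx = [
        [(idx[sid], o) for sid, o in step.reactant_orders.items()]
        for step in scheme.steps
    ]

    def rhs(_t, y):
        r = ks.copy()
        for j, terms in enumerate(order_idx):
            for i, order in terms:
                # concentrations may dip infinitesimally below zero between
                # solver steps; the rate law sees them as zero
                c = y[i] if y[i] > 0.0 else 0.0
                r[j] *= c if order == 1.0 else c ** order
        return S @ r

    return rhs


def simulate_batch_profile(
    scheme: KineticScheme,
    state0: StateVector,
    T: float,
    tau_grid,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
) -> np.ndarray:
    """Integrate the batch kinetic ODEs at constant temperature.

    Parameters
    ----------
    state0 : initial composition (its own temperature field is ignored).
    T : reactor temperature, K.
    tau_grid : non-negative, strictly increasing reaction times (s).

    Returns
    -------
    (len(tau_grid), n_species) concentration array ordered as
    ``scheme.species_ids``; negative round-off is clipped to 0 in the
    output only, never inside the right-hand side.
    """
    tau = np.asarray(tau_grid, float)
    if tau.ndim != 1 or tau.size == 0:
        raise ConfigError("tau_grid must be a non-empty 1-D sequence")
    if tau[0] < 0 or np.any(np.diff(tau) <= 0):
        raise ConfigError("tau_grid must be non-negative and strictly increasing")
    y0 = state0.as_array(scheme.species_ids)

    if tau[-1] == 0.0:
        return y0[None, :].copy()

    rhs = _rhs_factory(scheme, T)
    sol = solve_ivp(
        rhs, (0.0, tau[-1]), y0, method="LSODA",
        t_eval=tau[tau > 0], rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"kinetic ODE integration failed: {sol.message}",
            diagnostics={"T": T, "tau_max": tau[-1], "status": sol.status},
        )
    out = np.empty((tau.size, y0.size))
    n0 = int(np.sum(tau == 0.0))
    if n0:
        out[:n0] = y0
    out[n0:] = sol.y.T
    return np.clip(out, 0.0, None)


def snar_scheme(nucleophile_stoich_factor: int = 1,
                T_ref: float = 363.15) -> KineticScheme:
    """The built-in SNAr network: 1 + 2 -> 3 (ortho), 1 + 2 -> 4 (para),
    3 + 2 -> 5, 4 + 2 -> 5, all steps second order overall.

    Rate constants at T_ref = 90 degC and activation energies are the
    fitted campaign estimates shipped as the package's reference
    parameter set.
    """
    nu = nucleophile_stoich_factor
    if nu not in (1, 2):
        raise ConfigError("nucleophile_stoich_factor must be 1 or 2")
    species = (
        Species("1", "2,4-difluoronitrobenzene", "substrate"),
        Species("2", "pyrrolidine", "nucleophile"),
        Species("3", "ortho mono-adduct", "product"),
        Species("4", "para mono-adduct", "byproduct"),
        Species("5", "bis-adduct", "byproduct"),
    )
    ref = [  # (k_ref M^-1 s^-1, Ea J mol^-1)
        (0.579, 33_300.0),
        (0.0270, 35_300.0),
        (0.00865, 38_900.0),
        (0.0163, 44_800.0),
    ]
    defs = [
        ("step1", "1", "3"),
        ("step2", "1", "4"),
        ("step3", "3", "5"),
        ("step4", "4", "5"),
    ]
    steps = tuple(
        ReactionStep(
            reactant_orders={arom: 1.0, "2": 1.0},
            stoichiometry={arom: -1.0, "2": -float(nu), prod: 1.0},
            params=ArrheniusParams(k, Ea, T_ref),
            label=label,
        )
        for (label, arom, prod), (k, Ea) in zip(defs, ref)
    )
    return KineticScheme(species, steps, nu, name="snar-default")


def reference_parameters() -> dict[str, dict[str, float]]:
    """The reference SNAr parameter set keyed by step label."""
    sch = snar_scheme()
    return {
        s.label: {"k_ref": s.params.k_ref, "Ea": s.params.Ea, "T_ref": s.params.T_ref}
        for s in sch.steps
    }
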