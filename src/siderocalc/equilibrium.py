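"""Mass-balance equilibrium solver and pH speciation tables.

Given a :class:`~siderocalc.chem.ChemicalModel` and analytical totals, the
solver finds the free component concentrations satisfying, for every component
``j`` that is not clamped,

    free_j + sum_i nu_ij * c_i = T_j,      c_i = 10**log_beta_i * prod_j free_j**nu_ij

by damped Newton iteration on the *logarithms* of the free concentrations,
which keeps every concentration strictly positive.  When a condition fixes the
pH, the free proton concentration is clamped at 10**-pH and the proton balance
is dropped (titration against pH, the convention used by speciation programs
for pH diagrams).  An implicit hydroxide pseudo-species with stoichiometry
{H: -1} and log beta = log Kw is added whenever a proton component is present.

The solver is vectorised over conditions: a whole titration schedule or pH grid
is one batched Newton iteration, which is what makes nonlinear refinement of
binding constants (see :mod:`siderocalc.titration`) affordable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import ChemicalModel, Condition, ModelError

__all__ = [
    "EquilibriumState",
    "SpeciationTable",
    "solve_equilibrium",
    "speciation_diagram",
    "predominant_species",
    "compile_model",
    "CompiledModel",
]

LN10 = math.log(10.0)
#: floor (molar) used for absent components so the log-space solve stays finite
_TOTAL_FLOOR = 1e-30
#: cap on ln concentration to avoid overflow in exp
_LNF_MAX = 60.0
_LNF_MIN = -690.0


class NonConvergenceError(RuntimeError):
    """Raised where the caller asked for a converged state and none was found."""


@dataclass
class EquilibriumState:
    """Free and species concentrations solving mass balance at one condition."""

    free: dict
    species_conc: dict
    residuals: dict
    converged: bool
    iterations: int
    condition: Condition | None = None
    _lnf: np.ndarray | None = field(default=None, repr=False)

    def total_in(self, component: str, predicate) -> float:
        """Sum of ``component`` bound in species whose label satisfies ``predicate``."""
        out = 0.0
        for label, conc in self.species_conc.items():
            if predicate(label):
                out += conc
        return out


# ---------------------------------------------------------------------------
# compilation


@dataclass
class CompiledModel:
    """Array form of a model: stoichiometry matrix ``A`` (n_species x n_components)
    and cumulative log-beta vector ``b``, with component bookkeeping."""

    model: ChemicalModel
    comp_names: list
    A: np.ndarray
    b: np.ndarray
    labels: list
    proton_idx: int | None

    def comp_index(self, name: str) -> int:
        return self.comp_names.index(name)

    def totals_matrix(self, conditions) -> np.ndarray:
        """Stack condition totals into an (N, m) array; missing components -> 0."""
        T = np.zeros((len(conditions), len(self.comp_names)))
        for i, cond in enumerate(conditions):
            for name, tot in cond.totals.items():
                if name not in self.comp_names:
                    raise ModelError(f"totals name {name!r} not a model component")
                T[i, self.comp_index(name)] = tot
        return T

    # -- core batched Newton -------------------------------------------

    def solve(
        self,
        totals: np.ndarray,
        ph: np.ndarray | None,
        start_lnf: np.ndarray | None = None,
        tol: float = 1e-9,
        max_iter: int = 200,
        b_override: np.ndarray | None = None,
    ):
        """Solve mass balance for a batch of conditions.

        Parameters
        ----------
        totals : (N, m) analytical totals aligned with ``comp_names``.
        ph : (N,) fixed pH per condition, or None for free proton balance.
        start_lnf : optional (N, m) warm start (natural log of free conc).
        b_override : optional replacement log-beta vector (used by refinement,
            which varies protein-adduct constants on a fixed structure).

        Returns
        -------
        lnf, conc, resid, converged, iterations
        """
        b = self.b if b_override is None else np.asarray(b_override, dtype=float)
        A = self.A
        totals = np.atleast_2d(np.asarray(totals, dtype=float))
        N, m = totals.shape
        if m != len(self.comp_names):
            raise ModelError("totals shape does not match model components")
        if np.any(totals < 0):
            raise ModelError("negative totals are infeasible")

        clamped = np.zeros(m, dtype=bool)
        if ph is not None:
            if self.proton_idx is None:
                raise ModelError("pH given but model has no proton component")
            clamped[self.proton_idx] = True
        solve_idx = np.where(~clamped)[0]
        As = A[:, solve_idx]

        # floor absent totals so log-space stays finite; the untouched proton
        # balance keeps its true total (hydroxide gives it negative terms)
        T = totals.copy()
        for j in solve_idx:
            if self.proton_idx is not None and j == self.proton_idx:
                continue
            T[:, j] = np.maximum(T[:, j], _TOTAL_FLOOR)

        lnf = np.empty((N, m))
        if start_lnf is not None:
            lnf[:] = start_lnf
        else:
            lnf[:, solve_idx] = np.log(np.maximum(T[:, solve_idx] * 0.5, _TOTAL_FLOOR))
            if self.proton_idx is not None and not clamped[self.proton_idx]:
                lnf[:, self.proton_idx] = LN10 * -7.0
        if ph is not None:
            lnf[:, self.proton_idx] = LN10 * -np.asarray(ph, dtype=float)

        def concentrations(lnf_):
            expo = b * LN10 + lnf_ @ A.T
            return np.exp(np.clip(expo, _LNF_MIN, 700.0))

        def scaled_residual(lnf_, rows=None):
            Ts = T[:, solve_idx] if rows is None else T[np.ix_(rows, solve_idx)]
            C = concentrations(lnf_)
            F = np.exp(lnf_[:, solve_idx]) + C @ As - Ts
            scale = np.maximum(Ts, _TOTAL_FLOOR)
            if self.proton_idx is not None and not clamped[self.proton_idx]:
                jj = list(solve_idx).index(self.proton_idx)
                robust = (
                    np.exp(lnf_[:, self.proton_idx])
                    + C @ np.abs(A[:, self.proton_idx])
                )
                scale[:, jj] = np.maximum(scale[:, jj], robust)
            return C, F / scale, scale

        converged = np.zeros(N, dtype=bool)
        iters = np.zeros(N, dtype=int)
        C, R, scale = scaled_residual(lnf)
        norm = np.max(np.abs(R), axis=1)
        for it in range(max_iter):
            converged = norm <= tol
            active = np.where(~converged)[0]
            if active.size == 0:
                break
            iters[active] += 1
            la = lnf[active]
            Ca = C[active]
            # Jacobian wrt ln free: J[n,j,k] = delta_jk f_j + sum_i nu_ij nu_ik c_i
            J = np.einsum("ij,ik,ni->njk", As, As, Ca, optimize=True)
            fdiag = np.exp(la[:, solve_idx])
            J[:, np.arange(len(solve_idx)), np.arange(len(solve_idx))] += fdiag
            J /= scale[active][:, :, None]
            rhs = -R[active]
            try:
                delta = np.linalg.solve(J, rhs[..., None])[..., 0]
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(
                    J.reshape(-1, len(solve_idx), len(solve_idx))[0], rhs[0], rcond=None
                )[0][None, :].repeat(len(active), axis=0)
            delta = np.clip(delta, -40.0, 40.0)

            # per-condition backtracking on the residual max-norm
            lam = np.ones(len(active))
            best_lnf = la.copy()
            best_norm = norm[active].copy()
            improved = np.zeros(len(active), dtype=bool)
            trial = la.copy()
            for _ in range(30):
                pending = ~improved
                if not pending.any():
                    break
                trial[pending] = la[pending].copy()
                trial[np.ix_(pending, solve_idx)] = np.clip(
                    la[np.ix_(pending, solve_idx)]
                    + lam[pending, None] * delta[pending],
                    _LNF_MIN,
                    _LNF_MAX,
                )
                _, Rt, _ = scaled_residual(trial[pending], active[pending])
                nt = np.max(np.abs(Rt), axis=1)
                good = nt < best_norm[pending]
                idx = np.where(pending)[0]
                gidx = idx[good]
                best_lnf[gidx] = trial[gidx]
                best_norm[gidx] = nt[good]
                improved[gidx] = True
                lam[idx[~good]] *= 0.5
            # conditions that never improved take the smallest damped step anyway
            # (helps crawl off plateaus; the iteration cap bounds the cost)
            stuck = ~improved
            if stuck.any():
                best_lnf[np.ix_(stuck, solve_idx)] = np.clip(
                    la[np.ix_(stuck, solve_idx)] + lam[stuck, None] * delta[stuck],
                    _LNF_MIN,
                    _LNF_MAX,
                )
            lnf[active] = best_lnf
            C_new, R_new, _ = scaled_residual(lnf[active], active)
            C[active] = C_new
            R[active] = R_new
            norm[active] = np.max(np.abs(R_new), axis=1)
        converged = norm <= tol

        resid = np.zeros((N, m))
        resid[:, solve_idx] = R
        return lnf, C, resid, converged, iters


def compile_model(model: ChemicalModel) -> CompiledModel:
    """Flatten a model into stoichiometry arrays, adding the implicit OH species."""
    comp_names = [c.name for c in model.components]
    proton = model.proton
    proton_idx = comp_names.index(proton.name) if proton is not None else None
    species = list(model.species)
    labels = [sp.label for sp in species]
    if proton is not None:
        oh_key = ((proton.name, -1),)
        if not any(sp.stoich_key() == oh_key for sp in species) and "OH" not in labels:
            from .chem import Species

            species.append(
                Species(label="OH", stoich={proton.name: -1}, log_beta=model.kw,
                        provenance="implicit water autoprotolysis")
            )
            labels.append("OH")
    A = np.zeros((len(species), len(comp_names)))
    b = np.zeros(len(species))
    for i, sp in enumerate(species):
        b[i] = sp.log_beta
        for name, nu in sp.stoich.items():
            A[i, comp_names.index(name)] = nu
    return CompiledModel(
        model=model, comp_names=comp_names, A=A, b=b, labels=labels,
        proton_idx=proton_idx,
    )


# ---------------------------------------------------------------------------
# public scalar interface


def _state_from_arrays(compiled, lnf, C, resid, conv, iters, condition):
    free = {
        name: float(np.exp(lnf[j])) for j, name in enumerate(compiled.comp_names)
    }
    # report true zeros for floored absent components
    for name in compiled.comp_names:
        if (
            condition is not None
            and name not in condition.totals
            and (condition.ph is None or name != (compiled.model.proton.name if compiled.model.proton else None))
        ):
            if free[name] <= _TOTAL_FLOOR * 10:
                free[name] = 0.0
    species_conc = {
        lab: float(C[i]) for i, lab in enumerate(compiled.labels)
    }
    residuals = {
        name: float(resid[j]) for j, name in enumerate(compiled.comp_names)
    }
    return EquilibriumState(
        free=free,
        species_conc=species_conc,
        residuals=residuals,
        converged=bool(conv),
        iterations=int(iters),
        condition=condition,
        _lnf=lnf.copy(),
    )


def solve_equilibrium(
    model: ChemicalModel,
    condition: Condition,
    start: dict | None = None,
    tol: float = 1e-9,
    max_iter: int = 200,
    _compiled: CompiledModel | None = None,
) -> EquilibriumState:
    """Solve the mass-balance system at one condition.

    Components absent from ``condition.totals`` are treated as absent (total
    zero).  A non-converged solve returns a flagged state (``converged=False``)
    with its residuals; infeasible input (negative totals) raises instead.
    Deterministic for fixed inputs.  Falls back to alternative starts and a
    homotopy ramp in the totals if plain damped Newton stalls.
    """
    compiled = _compiled or compile_model(model)
    T = compiled.totals_matrix([condition])
    ph = None if condition.ph is None else np.array([condition.ph])

    start_lnf = None
    if start is not None:
        start_lnf = np.log(
            np.maximum(
                [[start.get(n, max(condition.totals.get(n, 0.0) * 0.5, _TOTAL_FLOOR))
                  for n in compiled.comp_names]],
                _TOTAL_FLOOR,
            )
        )
    lnf, C, resid, conv, iters = compiled.solve(
        T, ph, start_lnf=start_lnf, tol=tol, max_iter=max_iter
    )
    total_iters = int(iters[0])
    if not conv[0]:
        # alternative cold starts
        for factor in (1e-6, 1e2, 1e-12):
            alt = np.log(np.maximum(T * factor, _TOTAL_FLOOR))
            lnf2, C2, resid2, conv2, it2 = compiled.solve(
                T, ph, start_lnf=alt, tol=tol, max_iter=max_iter
            )
            total_iters += int(it2[0])
            if conv2[0]:
                lnf, C, resid, conv = lnf2, C2, resid2, conv2
                break
        else:
            # homotopy: ramp the totals up from a dilute system, warm-starting
            warm = None
            ok = False
            for s in np.geomspace(1e-6, 1.0, 10):
                lnf2, C2, resid2, conv2, it2 = compiled.solve(
                    T * s, ph, start_lnf=warm, tol=tol, max_iter=max_iter
                )
                total_iters += int(it2[0])
                warm = lnf2
                ok = bool(conv2[0])
            if ok:
                lnf, C, resid, conv = lnf2, C2, resid2, conv2
    return _state_from_arrays(
        compiled, lnf[0], C[0], resid[0], conv[0], total_iters, condition
    )


def solve_many(
    model: ChemicalModel,
    conditions,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> list:
    """Batched :func:`solve_equilibrium` over several conditions (shared clamp mode)."""
    compiled = compile_model(model)
    phs = {c.ph is None for c in conditions}
    if len(phs) != 1:
        raise ModelError("solve_many requires all conditions clamped or all free")
    T = compiled.totals_matrix(conditions)
    ph = None if conditions[0].ph is None else np.array([c.ph for c in conditions])
    lnf, C, resid, conv, iters = compiled.solve(T, ph, tol=tol, max_iter=max_iter)
    return [
        _state_from_arrays(compiled, lnf[i], C[i], resid[i], conv[i], iters[i], c)
        for i, c in enumerate(conditions)
    ]


# ---------------------------------------------------------------------------
# speciation diagrams


@dataclass
class SpeciationTable:
    """Fractions of a reference component across a pH grid.

    Rows are the species that contain the reference component (the free
    component itself appears under its own name); each converged column sums
    to 1 within 1e-6.  Non-converged grid points are flagged in ``ok`` and
    excluded from the normalisation guarantee.
    """

    ph_grid: np.ndarray
    fractions: "object"  # pandas DataFrame, species x pH
    reference_component: str
    ok: np.ndarray

    def to_frame(self):
        return self.fractions

    def nearest_index(self, ph: float) -> int:
        return int(np.argmin(np.abs(self.ph_grid - ph)))

    def fractions_at(self, ph: float) -> dict:
        i = self.nearest_index(ph)
        return {lab: float(self.fractions.iloc[r, i]) for r, lab in enumerate(self.fractions.index)}


def speciation_diagram(
    model: ChemicalModel,
    totals: dict,
    ph_range=(2.0, 10.0),
    n_points: int = 81,
    reference_component: str | None = None,
    tol: float = 1e-9,
) -> SpeciationTable:
    """Tabulate speciation across a pH grid (one solve per point, warm-started).

    ``totals`` are analytical totals for the non-proton components; the
    reference component defaults to the metal.
    """
    import pandas as pd

    lo, hi = float(ph_range[0]), float(ph_range[1])
    if not (0.0 <= lo <= 14.0 and 0.0 <= hi <= 14.0):
        raise ModelError("ph_range must lie within [0, 14]")
    if n_points < 2:
        raise ModelError("n_points must be >= 2")
    compiled = compile_model(model)
    if compiled.proton_idx is None:
        raise ModelError("speciation diagrams need a proton component")
    if reference_component is None:
        metal = model.component_by_role("metal")
        if metal is None:
            raise ModelError("no metal component; pass reference_component explicitly")
        reference_component = metal.name
    ref_j = compiled.comp_index(reference_component)
    T_ref = float(totals.get(reference_component, 0.0))
    if T_ref <= 0:
        raise ModelError(f"reference component {reference_component!r} needs a positive total")

    grid = np.linspace(lo, hi, int(n_points))
    cond0 = Condition(totals=totals, ph=float(grid[0]))
    T = compiled.totals_matrix([cond0])

    rows = [
        (i, lab)
        for i, lab in enumerate(compiled.labels)
        if compiled.A[i, ref_j] > 0
    ]
    data = np.full((len(rows) + 1, len(grid)), np.nan)
    ok = np.zeros(len(grid), dtype=bool)
    warm = None
    for k, ph in enumerate(grid):
        lnf, C, resid, conv, iters = compiled.solve(
            T, np.array([ph]), start_lnf=warm, tol=tol
        )
        if not conv[0]:  # retry cold in case the warm start trapped the solve
            lnf, C, resid, conv, iters = compiled.solve(T, np.array([ph]), tol=tol)
        warm = lnf
        ok[k] = bool(conv[0])
        if conv[0]:
            data[0, k] = np.exp(lnf[0, ref_j]) / T_ref
            for r, (i, _) in enumerate(rows):
                data[r + 1, k] = compiled.A[i, ref_j] * C[0, i] / T_ref
    labels = [reference_component] + [lab for _, lab in rows]
    frame = pd.DataFrame(data, index=labels, columns=np.round(grid, 10))
    return SpeciationTable(
        ph_grid=grid, fractions=frame, reference_component=reference_component, ok=ok
    )


def predominant_species(table: SpeciationTable, ph: float, threshold: float = 0.1) -> list:
    """Species holding more than ``threshold`` of the reference component at ``ph``.

    Nearest-grid-point lookup; sorted by descending fraction, ties broken by
    table (label) order.
    """
    if table.fractions.shape[0] == 0 or len(table.ph_grid) == 0:
        raise ModelError("empty speciation table")
    fr = table.fractions_at(ph)
    items = [(lab, f) for lab, f in fr.items() if np.isfinite(f) and f > threshold]
    order = {lab: i for i, lab in enumerate(table.fractions.index)}
    items.sort(key=lambda kv: (-kv[1], order[kv[0]]))
    return [lab for lab, _ in items]
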