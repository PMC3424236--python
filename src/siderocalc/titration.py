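"""Fluorescence-quenching titration modelling and dissociation-constant refinement.

The observable is intrinsic protein fluorescence, modelled as linear in the
protein-containing species concentrations (the HypSpec-style treatment):

    F = [P]_free + sum_s  q_s * nP_s * [species_s],        q_s in [0, 1]

normalised so that the zero-ligand anchor reads exactly 1.  Refinement holds
every ligand-protonation, Fe-complexation and hydrolysis constant fixed (they
are literature knowns) and adjusts only the protein association constant(s),
log-parameterised to stay positive, plus the bound-species fluorescence
coefficients and optional per-replicate normalisation scalars.  Replicates are
fitted jointly by weighted least squares; standard errors come from the
Jacobian at the optimum and candidate stoichiometries are ranked by AIC.

Flat titrations (quench dynamic range below three times the noise level) are
refused a point estimate and reported as a dissociation-constant *lower bound*
instead — the behaviour appropriate for ligands whose binding is too weak to
quench measurably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .chem import ChemicalModel, ModelError, add_protein_binding
from .equilibrium import compile_model, speciation_diagram, predominant_species

__all__ = [
    "TitrationPoint",
    "TitrationDataset",
    "QuenchModel",
    "FitResult",
    "simulate_quench",
    "fit_kd",
    "select_species_model",
    "apply_dilution_correction",
    "read_titration_csv",
    "write_titration_csv",
    "estimate_noise",
]

#: columns of the titration CSV dialect
CSV_COLUMNS = ["ligand_total_M", "protein_total_M", "pH", "F_norm", "sigma", "replicate"]


@dataclass(frozen=True)
class TitrationPoint:
    ligand_total: float
    protein_total: float
    ph: float
    f_norm: float
    sigma: float | None = None

    def __post_init__(self):
        if self.ligand_total < 0:
            raise ModelError("ligand_total must be >= 0")
        if self.f_norm < 0:
            raise ModelError("f_norm must be >= 0")


@dataclass
class TitrationDataset:
    """One replicate titration: ordered points plus assay metadata.

    ``metadata`` may carry ``replicate`` (id), ``iron_to_ligand`` (total iron
    added per total ligand, e.g. 1/3 for the 0.33-equivalent ferric premix)
    and free-text assay descriptors.
    """

    points: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        lt = [p.ligand_total for p in self.points]
        if any(b < a for a, b in zip(lt, lt[1:])):
            raise ModelError("ligand_total must be non-decreasing within a titration")

    @property
    def iron_to_ligand(self) -> float:
        return float(self.metadata.get("iron_to_ligand", 0.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ligand_total_M": [p.ligand_total for p in self.points],
                "protein_total_M": [p.protein_total for p in self.points],
                "pH": [p.ph for p in self.points],
                "F_norm": [p.f_norm for p in self.points],
                "sigma": [np.nan if p.sigma is None else p.sigma for p in self.points],
                "replicate": self.metadata.get("replicate", 0),
            }
        )


def write_titration_csv(datasets: Sequence[TitrationDataset], path) -> None:
    """Write datasets in the documented CSV dialect (RFC-4180, '.' decimal)."""
    frame = pd.concat([d.to_frame() for d in datasets], ignore_index=True)
    frame.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def read_titration_csv(path, metadata: dict | None = None) -> list:
    """Read the titration CSV dialect back into per-replicate datasets."""
    frame = pd.read_csv(path)
    missing = {"ligand_total_M", "protein_total_M", "pH", "F_norm"} - set(frame.columns)
    if missing:
        raise ModelError(f"titration CSV missing column(s) {sorted(missing)}")
    if "replicate" not in frame.columns:
        frame["replicate"] = 0
    out = []
    for rep, grp in frame.groupby("replicate", sort=True):
        points = [
            TitrationPoint(
                ligand_total=float(r.ligand_total_M),
                protein_total=float(r.protein_total_M),
                ph=float(r.pH),
                f_norm=float(r.F_norm),
                sigma=None
                if "sigma" not in frame.columns or pd.isna(r.sigma)
                else float(r.sigma),
            )
            for r in grp.itertuples()
        ]
        md = dict(metadata or {})
        md["replicate"] = rep
        out.append(TitrationDataset(points=points, metadata=md))
    return out


@dataclass
class QuenchModel:
    """Observable configuration: which protein species fluoresce, and the
    candidate bound species whose association constants are unknown.

    ``fluorescent_coeffs`` maps species label -> relative molar fluorescence
    (free protein is fixed at 1; protein species absent from the map are taken
    as fully quenched, coefficient 0).  ``candidate_bound_species`` is a list
    of ``(label, stoichiometry)`` pairs, stoichiometry including the protein.
    """

    fluorescent_coeffs: dict = field(default_factory=dict)
    candidate_bound_species: list = field(default_factory=list)

    def __post_init__(self):
        for lab, c in self.fluorescent_coeffs.items():
            if not 0.0 <= c <= 1.0:
                raise ModelError(f"fluorescence coefficient for {lab!r} outside [0, 1]")


@dataclass
class FitResult:
    """Refined association constant(s) with uncertainties and diagnostics.

    ``log_k_assoc`` are stepwise log10 association constants onto the candidate
    cores; ``kd`` = 10**-log_k (molar).  For unidentifiable (flat) data the
    point estimates are NaN and ``kd_lower_bound`` carries the detection-limit
    bound instead.
    """

    log_k_assoc: np.ndarray
    kd: np.ndarray
    se_log_k: np.ndarray
    coeffs: np.ndarray
    scales: np.ndarray
    rss: float
    aic: float
    selected_model: list
    converged: bool
    identifiable: bool
    n_titrations: int
    n_points: int
    kd_lower_bound: float | None = None
    noise_estimate: float | None = None
    dynamic_range: float | None = None
    message: str = ""
    candidate_results: list | None = None

    @property
    def kd_se(self) -> np.ndarray:
        return math.log(10.0) * self.kd * self.se_log_k


# ---------------------------------------------------------------------------
# forward model


def _schedule_to_arrays(compiled, schedule, iron_to_ligand=0.0):
    """Translate schedule entries into a totals matrix and pH vector.

    Entries are ``(ligand_total, protein_total, ph)`` tuples — mapped through
    the model's unique ligand/protein components, with total iron set to
    ``iron_to_ligand * ligand_total`` when a metal is present — or explicit
    dicts of component totals plus a ``"ph"`` key.
    """
    model = compiled.model
    m = len(compiled.comp_names)
    T = np.zeros((len(schedule), m))
    ph = np.zeros(len(schedule))
    lig = model.component_by_role("ligand")
    prot = model.component_by_role("protein")
    metal = model.component_by_role("metal")
    for i, entry in enumerate(schedule):
        if isinstance(entry, Mapping):
            ph[i] = float(entry["ph"])
            for name, tot in entry.items():
                if name == "ph":
                    continue
                T[i, compiled.comp_index(name)] = float(tot)
        else:
            lt, pt, p = entry
            if lig is None or prot is None:
                raise ModelError("tuple schedule needs unique ligand and protein components")
            T[i, compiled.comp_index(lig.name)] = float(lt)
            T[i, compiled.comp_index(prot.name)] = float(pt)
            if metal is not None and iron_to_ligand:
                T[i, compiled.comp_index(metal.name)] = iron_to_ligand * float(lt)
            ph[i] = float(p)
    return T, ph


class _QuenchEngine:
    """Batched forward model: schedule totals -> normalised fluorescence.

    Appends the candidate bound species to the chemical model once, then
    varies only their log-beta entries during refinement.  Keeps a warm-start
    cache of the last equilibrium solution, which cuts Newton iterations to a
    handful per refinement step.
    """

    def __init__(self, model, quench, schedule, iron_to_ligand=0.0, tol=1e-9):
        prot = model.component_by_role("protein")
        if prot is None:
            raise ModelError("quench model needs a protein component")
        aug = model
        self.cand_labels = []
        for lab, stoich in quench.candidate_bound_species:
            aug = add_protein_binding(aug, stoich, 0.0, label=lab)
            self.cand_labels.append(lab)
        self.compiled = compile_model(aug)
        self.tol = tol
        self.prot_j = self.compiled.comp_index(prot.name)
        self.cand_idx = np.array(
            [self.compiled.labels.index(lab) for lab in self.cand_labels], dtype=int
        )
        self.base_b = self.compiled.b.copy()
        # protein-containing explicit species and their fixed coefficients
        self.prot_rows = np.where(self.compiled.A[:, self.prot_j] > 0)[0]
        self.nP = self.compiled.A[self.prot_rows, self.prot_j]
        fixed = np.array(
            [
                quench.fluorescent_coeffs.get(self.compiled.labels[i], 0.0)
                for i in self.prot_rows
            ]
        )
        self.fixed_coeffs = fixed
        self.cand_pos = np.array(
            [list(self.prot_rows).index(i) for i in self.cand_idx], dtype=int
        )

        T, ph = _schedule_to_arrays(self.compiled, schedule, iron_to_ligand)
        # zero-titrant anchors (ligand and co-titrated metal removed) for the
        # normalisation denominator, one per point for simplicity
        T0 = T.copy()
        lig = model.component_by_role("ligand")
        metal = model.component_by_role("metal")
        if lig is not None:
            T0[:, self.compiled.comp_index(lig.name)] = 0.0
        if metal is not None and iron_to_ligand:
            T0[:, self.compiled.comp_index(metal.name)] = 0.0
        self.T = np.vstack([T, T0])
        self.ph = np.concatenate([ph, ph])
        self.n = len(schedule)
        self.PT = T[:, self.prot_j]
        self._warm = None

    def f_norm(self, log_k: np.ndarray, cand_coeffs: np.ndarray):
        b = self.base_b.copy()
        b[self.cand_idx] += np.asarray(log_k, dtype=float)
        lnf, C, resid, conv, iters = self.compiled.solve(
            self.T, self.ph, start_lnf=self._warm, tol=self.tol, b_override=b
        )
        if not conv.all():  # retry cold where the warm start trapped Newton
            lnf2, C2, _, conv2, _ = self.compiled.solve(
                self.T, self.ph, tol=self.tol, b_override=b
            )
            bad = ~conv
            lnf[bad], C[bad], conv[bad] = lnf2[bad], C2[bad], conv2[bad]
        self._warm = lnf
        coeffs = self.fixed_coeffs.copy()
        coeffs[self.cand_pos] = cand_coeffs
        freeP = np.exp(lnf[:, self.prot_j])
        fluor = freeP + C[:, self.prot_rows] @ (coeffs * self.nP)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = fluor / np.maximum(np.concatenate([self.PT, self.PT]), 1e-300)
            f = r[: self.n] / r[self.n :]
        ok = conv[: self.n] & conv[self.n :]
        f = np.where(ok, f, np.nan)
        return f, ok


def simulate_quench(
    model: ChemicalModel,
    quench: QuenchModel,
    schedule,
    log_k_assoc=None,
    iron_to_ligand: float = 0.0,
    tol: float = 1e-9,
) -> np.ndarray:
    """Predict normalised fluorescence over a schedule.

    If ``log_k_assoc`` is None the candidate species' constants must already be
    final in ``quench`` (i.e. the model was built with :func:`add_protein_binding`
    and ``quench.candidate_bound_species`` is empty).  Non-converged points are
    returned as NaN (the propagated per-point flag).
    """
    q = quench
    if log_k_assoc is None:
        log_k = np.zeros(len(q.candidate_bound_species))
    else:
        log_k = np.atleast_1d(np.asarray(log_k_assoc, dtype=float))
        if len(log_k) != len(q.candidate_bound_species):
            raise ModelError("log_k_assoc length must match candidate list")
    engine = _QuenchEngine(model, q, schedule, iron_to_ligand=iron_to_ligand, tol=tol)
    cand_coeffs = np.array(
        [q.fluorescent_coeffs.get(lab, 0.0) for lab in engine.cand_labels]
    )
    f, ok = engine.f_norm(log_k, cand_coeffs)
    return f


# ---------------------------------------------------------------------------
# noise / identifiability


def estimate_noise(datasets: Sequence[TitrationDataset]) -> float:
    """Estimate the relative observation noise of a set of titrations.

    Preference order: stated per-point sigmas; replicate scatter at matched
    ligand totals; a robust (MAD-based) first-difference estimate on a single
    curve.
    """
    sigmas = [p.sigma for d in datasets for p in d.points if p.sigma is not None]
    if sigmas:
        return float(np.median(sigmas))
    frame = pd.concat([d.to_frame() for d in datasets], ignore_index=True)
    by_l = frame.groupby("ligand_total_M")["F_norm"]
    counts = by_l.count()
    if (counts >= 2).any():
        sds = by_l.std(ddof=1)[counts >= 2]
        pooled = float(np.sqrt(np.nanmean(sds.values ** 2)))
        if pooled > 0:
            return pooled
    f = frame.sort_values("ligand_total_M")["F_norm"].to_numpy()
    d = np.diff(f)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / math.sqrt(2.0)) or 1e-6


def _dynamic_range(datasets) -> float:
    frame = pd.concat([d.to_frame() for d in datasets], ignore_index=True)
    mean_curve = frame.groupby("ligand_total_M")["F_norm"].mean()
    return float(mean_curve.max() - mean_curve.min())


def _detection_limit_kd(datasets, quench_floor: float) -> float:
    """Weakest dissociation constant still detectable at this design.

    A 1:1, fully-quenching association at ligand excess would need a bound
    fraction of ``quench_floor`` at the largest ligand total to clear the
    noise, i.e. K >= q / ((1-q) L_max); anything weaker is invisible, so the
    data only support K_D > (1-q) L_max / q.
    """
    q = min(max(quench_floor, 1e-6), 0.999)
    l_max = max(p.ligand_total for d in datasets for p in d.points)
    return (1.0 - q) * l_max / q


# ---------------------------------------------------------------------------
# refinement


def _collect(datasets):
    lt, pt, ph, f, sig, rep = [], [], [], [], [], []
    for r, d in enumerate(datasets):
        for p in d.points:
            lt.append(p.ligand_total)
            pt.append(p.protein_total)
            ph.append(p.ph)
            f.append(p.f_norm)
            sig.append(np.nan if p.sigma is None else p.sigma)
            rep.append(r)
    return (np.array(lt), np.array(pt), np.array(ph), np.array(f),
            np.array(sig), np.array(rep, dtype=int))


def fit_kd(
    datasets: Sequence[TitrationDataset],
    model: ChemicalModel,
    quench: QuenchModel,
    fit_scales: bool = True,
    fit_coeffs: bool = True,
    multi_start_offsets=(-2.0, 0.0, 2.0),
    scan_grid=None,
    tol: float = 1e-9,
    range_over_noise: float = 3.0,
) -> FitResult:
    """Refine protein association constant(s) jointly over replicate titrations.

    Speciation constants stay fixed; only the candidate log K values, the
    bound-species fluorescence coefficients (in [0, 1]) and per-replicate
    normalisation scalars are adjusted, by bounded trust-region least squares
    from multiple starting log K values (lowest residual sum wins).

    Titrations whose quench dynamic range is below ``range_over_noise`` times
    the estimated noise are flagged unidentifiable and reported as a K_D lower
    bound rather than a point estimate.
    """
    if not datasets:
        raise ModelError("need at least one titration dataset")
    if not quench.candidate_bound_species:
        raise ModelError("quench model lists no candidate bound species")
    n_cand = len(quench.candidate_bound_species)
    lt, pt, ph, f_obs, sig, rep = _collect(datasets)
    n = len(f_obs)
    n_rep = len(datasets)
    noise = estimate_noise(datasets)
    rng = _dynamic_range(datasets)

    if rng < range_over_noise * noise:
        kd_lb = _detection_limit_kd(datasets, range_over_noise * noise)
        return FitResult(
            log_k_assoc=np.full(n_cand, np.nan),
            kd=np.full(n_cand, np.nan),
            se_log_k=np.full(n_cand, np.nan),
            coeffs=np.full(n_cand, np.nan),
            scales=np.ones(n_rep),
            rss=float("nan"),
            aic=float("inf"),
            selected_model=list(quench.candidate_bound_species),
            converged=False,
            identifiable=False,
            n_titrations=n_rep,
            n_points=n,
            kd_lower_bound=kd_lb,
            noise_estimate=noise,
            dynamic_range=rng,
            message=(
                "unidentifiable: quench dynamic range "
                f"{rng:.3g} < {range_over_noise:g} x noise {noise:.3g}; "
                f"data only support K_D > {kd_lb:.3g} M"
            ),
        )

    iron_to_ligand = max((d.iron_to_ligand for d in datasets), default=0.0)
    schedule = list(zip(lt, pt, ph))
    engine = _QuenchEngine(model, quench, schedule, iron_to_ligand=iron_to_ligand, tol=tol)
    weights = np.where(np.isnan(sig) | (sig <= 0), 1.0, sig)
    weights = 1.0 / weights

    def unpack(theta):
        log_k = theta[:n_cand]
        if fit_coeffs:
            coeffs = theta[n_cand : 2 * n_cand]
            rest = theta[2 * n_cand :]
        else:
            coeffs = np.array(
                [quench.fluorescent_coeffs.get(lab, 0.0) for lab in engine.cand_labels]
            )
            rest = theta[n_cand:]
        scales = rest if fit_scales else np.ones(n_rep)
        return log_k, coeffs, scales

    def residuals(theta):
        log_k, coeffs, scales = unpack(theta)
        f_pred, ok = engine.f_norm(log_k, coeffs)
        res = (scales[rep] * f_pred - f_obs) * weights
        return np.where(ok, res, 10.0)  # penalise non-converged points

    # coarse 1-D scan locates the identifiable log K decade before local fits
    if scan_grid is None:
        scan_grid = np.arange(0.0, 16.5, 1.0)
    best_scan, best_val = scan_grid[0], np.inf
    for g in scan_grid:
        v = float(np.sum(residuals(_pack(n_cand, g, 0.0, n_rep, fit_coeffs, fit_scales)) ** 2))
        if v < best_val:
            best_scan, best_val = g, v

    lb = np.concatenate(
        [np.full(n_cand, -5.0)]
        + ([np.zeros(n_cand)] if fit_coeffs else [])
        + ([np.full(n_rep, 0.5)] if fit_scales else [])
    )
    ub = np.concatenate(
        [np.full(n_cand, 30.0)]
        + ([np.ones(n_cand)] if fit_coeffs else [])
        + ([np.full(n_rep, 2.0)] if fit_scales else [])
    )
    best = None
    for off in multi_start_offsets:
        theta0 = _pack(n_cand, best_scan + off, 0.05, n_rep, fit_coeffs, fit_scales)
        theta0 = np.clip(theta0, lb, ub)
        sol = least_squares(residuals, theta0, bounds=(lb, ub), method="trf", x_scale="jac")
        if best is None or sol.cost < best.cost:
            best = sol

    log_k, coeffs, scales = unpack(best.x)
    rss = float(2.0 * best.cost)
    p_eff = len(best.x)
    dof = max(n - p_eff, 1)
    s2 = rss / dof
    J = best.jac
    try:
        cov = s2 * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov)[:n_cand], 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(n_cand, np.nan)
    aic = n * math.log(max(rss / n, 1e-300)) + 2 * p_eff
    return FitResult(
        log_k_assoc=np.asarray(log_k, dtype=float).copy(),
        kd=10.0 ** (-np.asarray(log_k, dtype=float)),
        se_log_k=se,
        coeffs=np.asarray(coeffs, dtype=float).copy(),
        scales=np.asarray(scales, dtype=float).copy(),
        rss=rss,
        aic=aic,
        selected_model=list(quench.candidate_bound_species),
        converged=bool(best.success),
        identifiable=True,
        n_titrations=n_rep,
        n_points=n,
        noise_estimate=noise,
        dynamic_range=rng,
        message=best.message,
    )


def _pack(n_cand, log_k, coeff, n_rep, fit_coeffs, fit_scales):
    parts = [np.full(n_cand, log_k)]
    if fit_coeffs:
        parts.append(np.full(n_cand, coeff))
    if fit_scales:
        parts.append(np.ones(n_rep))
    return np.concatenate(parts)


def select_species_model(
    datasets: Sequence[TitrationDataset],
    model: ChemicalModel,
    candidates: Sequence[QuenchModel],
    restrict: bool = True,
    speciation_totals: dict | None = None,
    assay_ph: float | None = None,
    predominance_threshold: float = 0.1,
    delta_aic_tie: float = 2.0,
    **fit_kwargs,
) -> FitResult:
    """Fit candidate bound-species models and return the AIC-best fit.

    With ``restrict=True`` and speciation conditions given, candidates whose
    metal-containing core is not a predominant solution species at the assay
    pH are dropped before fitting (the predominance-based model-selection
    step); metal-free cores are always retained.  AIC ties (delta < 2) are
    broken toward fewer parameters, then lower RSS.
    """
    if not candidates:
        raise ModelError("no candidate quench models supplied")
    metal = model.component_by_role("metal")
    pool = list(candidates)
    if restrict and speciation_totals is not None and assay_ph is not None and metal is not None:
        table = speciation_diagram(model, speciation_totals, (2.0, 10.0), 81)
        keep = set(predominant_species(table, assay_ph, predominance_threshold))
        prot = model.component_by_role("protein").name

        def core_ok(stoich):
            core = {k: v for k, v in stoich.items() if k != prot and v != 0}
            if metal.name not in core:
                return True
            sp = model.species_by_stoich(core)
            return sp is not None and sp.label in keep

        filtered = [
            q for q in pool
            if all(core_ok(st) for _, st in q.candidate_bound_species)
        ]
        if filtered:
            pool = filtered

    results = [(q, fit_kd(datasets, model, q, **fit_kwargs)) for q in pool]
    identifiable = [(q, r) for q, r in results if r.identifiable]
    if not identifiable:
        agg = results[0][1]
        agg.message = "all candidate species models unidentifiable; " + agg.message
        agg.candidate_results = [r for _, r in results]
        return agg

    def n_params(r):
        return len(r.log_k_assoc) * 2 + len(r.scales)

    best_aic = min(r.aic for _, r in identifiable)
    tied = [(q, r) for q, r in identifiable if r.aic - best_aic < delta_aic_tie]
    tied.sort(key=lambda qr: (n_params(qr[1]), qr[1].rss))
    chosen = tied[0][1]
    chosen.candidate_results = [r for _, r in results]
    return chosen


# ---------------------------------------------------------------------------
# dilution correction


def apply_dilution_correction(raw_intensities, initial_volume: float, additions=()):
    """Correct raw intensities for dilution by titrant additions.

    Each intensity is multiplied by (V0 + sum of additions so far) / V0, the
    standard back-correction for signal diluted by added ligand.  ``additions``
    holds one volume per post-anchor point; with no additions the intensities
    are returned unchanged.
    """
    raw = np.asarray(raw_intensities, dtype=float)
    additions = np.asarray(additions, dtype=float)
    if initial_volume <= 0:
        raise ModelError("initial volume must be positive")
    if additions.size and np.any(additions <= 0):
        raise ModelError("titrant addition volumes must be positive")
    cum = np.cumsum(additions) if additions.size else np.zeros(0)
    if additions.size == 0:
        offsets = np.zeros(raw.size)
    elif additions.size == raw.size:
        offsets = cum  # every intensity follows an addition
    elif additions.size == raw.size - 1:
        offsets = np.concatenate([[0.0], cum])  # first point is the undiluted anchor
    else:
        raise ModelError("need one addition per intensity (optionally minus the anchor)")
    factor = (initial_volume + offsets) / initial_volume
    return raw * factor
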