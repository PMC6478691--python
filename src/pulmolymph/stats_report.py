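"""Sensitivity protocol and statistics for morphometry/flow results.

Includes an exact Mann-Whitney U test (count-distribution recurrence for
small tie-free samples, normal approximation with tie and continuity
corrections otherwise), Pearson correlation/regression of morphometric
measures against pleural distance, group comparison across the six
measures, and the x100 parameter-sensitivity protocol around the flow
model's membrane conductivities and lymphatic inlet velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as sp_stats

from pulmolymph.core import FluidParameters
from pulmolymph.microflow import assemble, solve
from pulmolymph.model_prep import BoundarySpec, ModelVolume

MEASURES = (
    "volume_fraction",
    "sa_per_tissue_volume",
    "fractal_dimension",
    "branch_count",
    "junction_count",
    "mean_tortuosity",
)


# --------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=None)
def _u_count_table(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements giving each U value (tie-free case).

    Recurrence: c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u),
    the classic partition count of U among n1*n2 + 1 values.
    """
    max_u = n1 * n2
    # dp over (i, j): distribution of U for samples of size i vs j
    table = {(0, j): np.array([1] + [0] * max_u, dtype=object)
             for j in range(n2 + 1)}
    for i in range(1, n1 + 1):
        table[(i, 0)] = np.array([1] + [0] * max_u, dtype=object)
        for j in range(1, n2 + 1):
            a = np.roll(table[(i - 1, j)], j)
            a[:j] = 0
            table[(i, j)] = a + table[(i, j - 1)]
    return table[(n1, n2)]


def mann_whitney_u(
    x, y, alternative: str = "two-sided", exact_limit: int = 12
) -> tuple[float, float, str]:
    """Mann-Whitney U statistic and p-value; returns ``(U, p, method)``.

    The reported U counts pairs where an ``x`` observation exceeds a
    ``y`` observation (ties count half).  p is exact (distribution
    recurrence) when both samples have at most ``exact_limit``
    observations and no ties occur; otherwise the normal approximation
    with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError("alternative must be two-sided/less/greater")
    combined = np.concatenate([x, y])
    ranks = sp_stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    has_ties = len(np.unique(combined)) < n1 + n2

    if not has_ties and n1 <= exact_limit and n2 <= exact_limit:
        counts = _u_count_table(n1, n2)
        total = int(counts.sum())
        u_int = int(round(u1))
        cdf_le = int(counts[: u_int + 1].sum()) / total
        sf_ge = int(counts[u_int:].sum()) / total
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(cdf_le, sf_ge))
        elif alternative == "greater":
            p = sf_ge
        else:
            p = cdf_le
        return float(u1), float(p), "exact"

    mean = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return float(u1), 1.0, "normal"
    if alternative == "two-sided":
        z = (abs(u1 - mean) - 0.5) / np.sqrt(var)
        p = 2.0 * sp_stats.norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (u1 - mean - 0.5) / np.sqrt(var)
        p = sp_stats.norm.sf(z)
    else:
        z = (u1 - mean + 0.5) / np.sqrt(var)
        p = sp_stats.norm.cdf(z)
    return float(u1), float(min(p, 1.0)), "normal"


# --------------------------------------------------------------------------
# regression against pleural distance


@dataclass
class DistanceRegression:
    measure: str
    n: int
    r: float
    p: float
    slope: float
    intercept: float
    n_excluded: int


def correlate_with_distance(records, excluded=None,
                            measure: str = "") -> DistanceRegression:
    """Pearson correlation and least-squares line of a measure vs distance.

    ``records`` is a sequence of ``(distance_um, value)`` pairs;
    ``excluded`` an optional boolean sequence flagging records to drop
    (e.g. failed fractal fits).  p comes from the t-statistic
    ``r sqrt((n-2)/(1-r^2))``, equivalent to the slope test of the simple
    regression.
    """
    records = list(records)
    if excluded is None:
        excluded = [False] * len(records)
    kept = [(d, v) for (d, v), ex in zip(records, excluded)
            if not ex and v is not None and np.isfinite(v)]
    n_excl = len(records) - len(kept)
    if len(kept) < 3:
        raise ValueError("need at least 3 non-excluded records")
    d = np.array([r[0] for r in kept], dtype=float)
    v = np.array([r[1] for r in kept], dtype=float)
    if np.ptp(d) == 0 or np.ptp(v) == 0:
        raise ValueError("zero variance in distance or measure")
    r, p = sp_stats.pearsonr(d, v)
    slope, intercept = np.polyfit(d, v, 1)
    return DistanceRegression(measure=measure, n=len(kept), r=float(r),
                              p=float(p), slope=float(slope),
                              intercept=float(intercept), n_excluded=n_excl)


# --------------------------------------------------------------------------
# group comparison


@dataclass
class GroupComparison:
    per_measure: dict = field(default_factory=dict)
    # measure -> {U, p, p_bonferroni?, median_x, median_y, n_x, n_y, method}


def compare_groups(control_records, diseased_records,
                   bonferroni: bool = False) -> GroupComparison:
    """Mann-Whitney comparison of the six morphometric measures.

    ``*_records`` are sequences of mappings (or dataclasses) carrying the
    measure fields; ``None`` values (excluded fits) are dropped per
    measure.  Raw two-sided p-values are reported; Bonferroni adjustment
    is optional and off by default.
    """
    def col(recs, name):
        vals = []
        for rec in recs:
            v = rec.get(name) if isinstance(rec, dict) else getattr(rec, name)
            if v is not None and np.isfinite(v):
                vals.append(float(v))
        return np.array(vals)

    if not control_records or not diseased_records:
        raise ValueError("both cohorts must be non-empty")
    out = GroupComparison()
    n_tests = len(MEASURES)
    for m in MEASURES:
        x = col(control_records, m)
        y = col(diseased_records, m)
        if len(x) == 0 or len(y) == 0:
            out.per_measure[m] = {"U": None, "p": None,
                                  "note": "no valid values"}
            continue
        U, p, method = mann_whitney_u(x, y)
        entry = {
            "U": U, "p": p, "method": method,
            "median_x": float(np.median(x)), "median_y": float(np.median(y)),
            "n_x": int(len(x)), "n_y": int(len(y)),
        }
        if bonferroni:
            entry["p_bonferroni"] = min(1.0, p * n_tests)
        out.per_measure[m] = entry
    return out


# --------------------------------------------------------------------------
# sensitivity protocol


@dataclass
class SensitivityReport:
    base_Q_L_in: float
    discretization_error: float          # |ΔQ_L_in| between two grid levels
    rows: list = field(default_factory=list)
    # each row: {parameter, factor, Q_L_in, abs_change, pct_change,
    #            below_error, converged}


def _solve_Q_L_in(model, boundaries, params, tol):
    system = assemble(model, boundaries, params)
    sol = solve(system, tol=tol)
    return sol.fluxes.Q_L_in


def run_sensitivity(
    model: ModelVolume,
    boundaries: BoundarySpec,
    params: FluidParameters,
    factors=(100.0, 0.01),
    targets=("K_L", "K_B", "u_L"),
    tol: float = 1e-10,
    refined: tuple[ModelVolume, BoundarySpec] | None = None,
) -> SensitivityReport:
    """Perturb membrane conductivities and lymphatic inlet velocity x/÷100.

    Runs one base solve plus one per (target, factor) combination and
    reports the change in net volumetric flux into the lymphatic domain.
    The discretization-error estimate is |ΔQ_L_in| between the base case
    and a one-step grid refinement (``refined``), used for the
    below-error flags; without a refined model the estimate is 0 and the
    flags are not meaningful.
    """
    base_Q = _solve_Q_L_in(model, boundaries, params, tol)
    disc_err = 0.0
    if refined is not None:
        rmodel, rbounds = refined
        refined_Q = _solve_Q_L_in(rmodel, rbounds, params, tol)
        disc_err = abs(refined_Q - base_Q)
    report = SensitivityReport(base_Q_L_in=base_Q,
                               discretization_error=disc_err)
    for target in targets:
        for factor in factors:
            pert = params.replace(**{target: getattr(params, target) * factor})
            row = {"parameter": target, "factor": factor}
            try:
                q = _solve_Q_L_in(model, boundaries, pert, tol)
                row["Q_L_in"] = q
                row["abs_change"] = q - base_Q
                row["pct_change"] = (100.0 * (q - base_Q) / base_Q
                                     if base_Q != 0 else np.nan)
                row["below_error"] = abs(q - base_Q) <= disc_err
                row["converged"] = True
            except Exception as exc:   # per-run failure status
                row["converged"] = False
                row["error"] = str(exc)
            report.rows.append(row)
    return report
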