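"""Relative-affinity estimation from depletion data, and binding-isotherm fits.

The depletion of variant v relative to the reference at protein concentration
E follows the competitive-binding ratio

    S_ref/S_v = (S_ref,0/S_v,0) * (1 + E/K_v) / (1 + E/K_ref),

where S are free-RNA amounts, S_0 the no-protein control amounts and K the
apparent dissociation constants.  With the observable
R = (S_ref/S_v) * (S_v,0/S_ref,0) and E expressed in units of the reference
K_1/2 (E' = E/K_ref), inverting for the variant gives its relative
dissociation constant K_v/K_ref = E' / (R*(1 + E') - 1).  We report the
reciprocal, the relative association constant

    K_A,rel(v) = (R*(1 + E') - 1) / E',

so that higher affinity means larger K_A,rel and the reference is exactly 1.
Because E >> K_ref for nearly the whole concentration series, the estimate is
insensitive to the exact reference K_1/2 (twofold perturbation moves K_A,rel
by well under 1%).

Direct titrations are fit with the quadratic (ligand-depletion) isotherm

    FB = A * [(K + R0 + P0) - sqrt((K + R0 + P0)^2 - 4*R0*P0)] / (2*R0)

and competition experiments with

    FB = A * R1 / (R1 + K1 * (1 + R2/K2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

DEFAULT_REFERENCE = "UGCAUGU"
DEFAULT_REF_K_HALF = 1.6  # nM, apparent K_1/2 of the cognate reference


@dataclass
class AffinityTable:
    """Per-variant relative association constants (reference == 1).

    ``table`` columns: ka_rel, n_informative, below_detection.  ``per_conc``
    holds per-concentration estimates (NaN where the inversion denominator is
    nonpositive, i.e. the variant is outside the informative range at that
    concentration).
    """

    table: pd.DataFrame
    per_conc: pd.DataFrame
    reference: str
    ref_k_half: float

    @property
    def ka(self) -> pd.Series:
        return self.table["ka_rel"]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "variant", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, reference: str = DEFAULT_REFERENCE,
                 ref_k_half: float = DEFAULT_REF_K_HALF) -> "AffinityTable":
        df = pd.read_csv(path, sep="\t").set_index("variant")
        if "ka_rel" not in df.columns:
            raise ValueError(f"{path}: expected a 'ka_rel' column")
        if "n_informative" not in df.columns:
            df["n_informative"] = 1
        if "below_detection" not in df.columns:
            df["below_detection"] = False
        return cls(table=df, per_conc=df[["ka_rel"]].copy(),
                   reference=reference, ref_k_half=ref_k_half)

    @classmethod
    def from_series(cls, ka: pd.Series, reference: str = DEFAULT_REFERENCE,
                    ref_k_half: float = DEFAULT_REF_K_HALF) -> "AffinityTable":
        """Wrap a plain variant -> K_A,rel mapping (e.g. an external table)."""
        df = pd.DataFrame(
            {"ka_rel": ka.astype(float), "n_informative": 1, "below_detection": False}
        )
        df.index.name = "variant"
        return cls(table=df, per_conc=df[["ka_rel"]].copy(),
                   reference=reference, ref_k_half=ref_k_half)


def relative_affinity(
    normalized: pd.DataFrame,
    concs: Mapping[str, float],
    reference: str = DEFAULT_REFERENCE,
    ref_k_half: float = DEFAULT_REF_K_HALF,
    estimator: str = "median",
    counts: pd.DataFrame | None = None,
    equal_pool: bool = True,
) -> AffinityTable:
    """Estimate K_A,rel for every variant from control-normalised depletion.

    Parameters
    ----------
    normalized
        Variant x library table of control-normalised read frequencies
        (``normalize_counts`` output); a control column (conc 0) may be
        present and is ignored.
    concs
        Library label -> protein concentration (nM).
    reference
        Variant pinned to K_A,rel = 1 (the cognate 7-mer by default).
    ref_k_half
        Apparent K_1/2 of the reference in nM; sets the units of E.
    estimator
        "median" or "mean" of per-concentration estimates, or "global-fit"
        (per-variant Poisson maximum-likelihood fit of the depletion curve
        across the whole concentration series, with a jointly estimated
        per-library pool-renormalisation factor; requires ``counts``).
    counts
        Raw per-variant read counts (variants x libraries, control included);
        required by the "global-fit" estimator, ignored otherwise.
    equal_pool
        Whether the initial pool is equimolar by design ("global-fit" only).
        If True the known per-variant exposure is used, which roughly halves
        the estimation error; if False the observed control counts serve as
        exposure.

    Per concentration, R = normalized(ref)/normalized(v) and the estimate is
    (R*(1+E') - 1)/E' with E' = E/ref_k_half; nonpositive numerators are
    dropped as below-informative.  Variants with no informative concentration
    are flagged ``below_detection`` with ka_rel 0.
    """
    if reference not in normalized.index:
        raise ValueError(f"reference variant {reference!r} absent from table")
    protein_labels = [lb for lb in normalized.columns
                      if lb in concs and concs[lb] > 0]
    if not protein_labels:
        raise ValueError("no protein-containing libraries in `concs`")
    if estimator not in ("median", "mean", "global-fit"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if ref_k_half <= 0:
        raise ValueError("ref_k_half must be positive")

    per = {}
    for label in protein_labels:
        e_prime = concs[label] / ref_k_half
        col = normalized[label].to_numpy(dtype=float)
        ref_val = float(normalized.at[reference, label])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = ref_val / col
            est = (ratio * (1.0 + e_prime) - 1.0) / e_prime
        est[~np.isfinite(est) | (est <= 0)] = np.nan
        per[label] = est
    per_conc = pd.DataFrame(per, index=normalized.index)

    n_informative = per_conc.notna().sum(axis=1)
    if estimator == "mean":
        ka = per_conc.mean(axis=1)
        below = n_informative == 0
    elif estimator == "global-fit":
        if counts is None:
            raise ValueError(
                "the 'global-fit' estimator works on raw counts; pass the "
                "count table via counts=..."
            )
        ka, below = _pool_fit(
            counts, protein_labels, concs, reference, equal_pool=equal_pool
        )
        ka = ka.reindex(normalized.index)
        below = below.reindex(normalized.index)
        n_informative = pd.Series(len(protein_labels), index=normalized.index)
    else:
        ka = per_conc.median(axis=1)
        below = n_informative == 0
    if estimator != "global-fit":
        ka = ka.where(~below, 0.0)
    table = pd.DataFrame(
        {"ka_rel": ka, "n_informative": n_informative, "below_detection": below}
    )
    table.index.name = "variant"
    return AffinityTable(table=table, per_conc=per_conc,
                         reference=reference, ref_k_half=ref_k_half)


def _anderson_fixed_point(step_fn, x0, max_iter=60, tol=1e-6, memory=5):
    """Anderson-accelerated fixed point for x = step_fn(x) (small dense x)."""
    x = np.asarray(x0, dtype=float)
    xs: list[np.ndarray] = []
    res: list[np.ndarray] = []
    for _ in range(max_iter):
        gx = step_fn(x)
        f = gx - x
        if np.abs(f).max() < tol:
            return gx, True
        xs.append(x.copy())
        res.append(f.copy())
        if len(xs) > memory:
            xs.pop(0)
            res.pop(0)
        if len(xs) == 1:
            x = gx
        else:
            d_res = np.array([res[i + 1] - res[i] for i in range(len(res) - 1)]).T
            d_x = np.array([xs[i + 1] - xs[i] for i in range(len(xs) - 1)]).T
            gamma, *_ = np.linalg.lstsq(d_res, f, rcond=None)
            x = x + f - (d_x + d_res) @ gamma
    return x, False


def _pool_fit(
    counts: pd.DataFrame,
    labels: list[str],
    concs: Mapping[str, float],
    reference: str,
    equal_pool: bool = True,
    n_grid: int = 500,
) -> tuple[pd.Series, pd.Series]:
    """Per-variant Poisson ML depletion-curve fit across the whole series.

    The expected read count of variant v in the library at protein
    concentration E is ``a_v * t_E * f(Kd_v, E) / P(E)`` where ``f = Kd/(Kd+E)``
    is the free fraction, ``t_E`` the library's sequencing-depth ratio to the
    control, ``a_v`` the variant's control-library exposure and ``P(E)`` the
    pool-renormalisation factor (pool-average free fraction) shared by all
    variants in a library.  Each variant's Kd maximises the Poisson
    likelihood on a log-spaced grid with parabolic refinement; the shared
    profile is pinned by the self-consistency condition
    ``P(E) = mean_v f(Kd_v, E)`` (equimolar pool), solved by an
    Anderson-accelerated fixed point — plain alternation crawls along a
    near-neutral mode between P and the bulk Kd scale.  With ``equal_pool``
    the known uniform exposure ``depth/N`` is used; the estimator then runs
    at the Cramer-Rao bound of the counting experiment.  Fitting each
    variant over its own whole curve sidesteps the failure mode of
    per-concentration reference ratios, which lose the reference variant to
    depletion at high protein.  The reported K_A,rel is the fitted Kd of the
    reference divided by the variant's, so the reference is exactly 1 and
    the reference-K_1/2 unit cancels entirely.
    """
    if reference not in counts.index:
        raise ValueError(f"reference variant {reference!r} absent from counts")
    e = np.array([concs[lb] for lb in labels], dtype=float)
    c_prot = counts[labels].to_numpy(dtype=float)
    control_labels = [
        lb for lb in counts.columns if lb in concs and concs[lb] == 0
    ]
    if not control_labels:
        raise ValueError("global-fit needs a control (0 nM) library in counts")
    c0 = counts[control_labels[0]].to_numpy(dtype=float)
    depth0 = c0.sum()
    if depth0 <= 0:
        raise ValueError("control library is empty")
    t_ratio = c_prot.sum(axis=0) / depth0
    exposure = (
        np.full(len(counts), depth0 / len(counts))
        if equal_pool
        else np.maximum(c0, 0.5)
    )

    kd_grid = np.geomspace(
        max(e.min() / 100.0, 1e-6), e.max() * 1e3, n_grid
    )
    log_grid = np.log(kd_grid)
    f_grid = kd_grid[:, None] / (kd_grid[:, None] + e[None, :])  # (g, E)
    rows = np.arange(len(counts))
    step = log_grid[1] - log_grid[0]

    def fit_kd(inv_p: np.ndarray) -> np.ndarray:
        """Grid + parabolic-refinement ln(Kd) per variant at fixed 1/P."""
        m = f_grid * inv_p[None, :]  # model normalised signal per grid Kd
        # negative Poisson log-likelihood up to per-variant constants:
        # cost[v, g] = sum_E a_v*t_E*m[g,E] - c[v,E]*ln m[g,E]
        cost = np.outer(exposure, (m * t_ratio[None, :]).sum(axis=1)) - (
            c_prot @ np.log(m).T
        )
        g_best = np.argmin(cost, axis=1)
        gi = np.clip(g_best, 1, n_grid - 2)
        c_lo, c_mid, c_hi = cost[rows, gi - 1], cost[rows, gi], cost[rows, gi + 1]
        denom = c_lo - 2.0 * c_mid + c_hi
        shift = np.where(
            denom > 0, 0.5 * (c_lo - c_hi) / np.maximum(denom, 1e-300), 0.0
        )
        out = log_grid[gi] + np.clip(shift, -1.0, 1.0) * step
        out[g_best == 0] = log_grid[0]
        out[g_best == n_grid - 1] = log_grid[-1]
        return out

    def consistency_step(ln_p: np.ndarray) -> np.ndarray:
        lk = fit_kd(np.exp(-ln_p))
        f_hat = np.exp(lk)[:, None] / (np.exp(lk)[:, None] + e[None, :])
        return np.log(f_hat.mean(axis=0))

    ln_p, converged = _anderson_fixed_point(consistency_step, np.zeros(len(e)))
    if not converged:
        warnings.warn(
            "pool-factor self-consistency did not fully converge; "
            "estimates use the last iterate"
        )
    log_kd = fit_kd(np.exp(-ln_p))
    kd_hat = pd.Series(np.exp(log_kd), index=counts.index)
    outside = pd.Series(
        (log_kd <= log_grid[0]) | (log_kd >= log_grid[-1]) | (kd_hat > 10 * e.max()),
        index=counts.index,
    )
    ka = kd_hat[reference] / kd_hat
    return ka, outside


@dataclass
class IsothermFit:
    """Least-squares estimates from a direct or competition binding curve."""

    amplitude: float
    k_half: float  # nM: K_1/2 (direct) or the competitor's [K_1/2]_2
    se_amplitude: float
    se_k_half: float
    model: str  # "direct" | "competition"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.amplitude <= 1.2:
            warnings.warn(
                f"fitted amplitude {self.amplitude:.3g} outside the physical "
                "range (0, 1.2]"
            )
        if self.k_half <= 0:
            raise ValueError("fitted K_1/2 must be positive")


def quadratic_bound(p0, amplitude, k_half, r0):
    """Ligand-depletion binding isotherm (fraction bound vs protein P0)."""
    p0 = np.asarray(p0, dtype=float)
    s = k_half + r0 + p0
    disc = np.maximum(s * s - 4.0 * r0 * p0, 0.0)
    return amplitude * (s - np.sqrt(disc)) / (2.0 * r0)


def competition_bound(r2, amplitude, k2, r1, k1):
    """Competitive-inhibition isotherm (fraction bound vs competitor R2)."""
    r2 = np.asarray(r2, dtype=float)
    return amplitude * r1 / (r1 + k1 * (1.0 + r2 / k2))


def _multistart_fit(model, x, y, k_starts, bounds):
    best = None
    errors = []
    for k0 in k_starts:
        try:
            popt, pcov = curve_fit(
                model, x, y, p0=[1.0, k0], bounds=bounds, maxfev=20000
            )
        except RuntimeError as exc:
            errors.append(f"K0={k0:.4g}: {exc}")
            continue
        ssr = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise RuntimeError(
            "isotherm fit failed to converge from all starts: " + "; ".join(errors)
        )
    _, popt, pcov = best
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    return popt, se


def fit_isotherm(
    bound_fractions: Sequence[float],
    p0_series: Sequence[float],
    r0: float,
) -> IsothermFit:
    """Fit amplitude and apparent K_1/2 to a direct titration.

    ``bound_fractions`` are observed fraction-bound values at total protein
    concentrations ``p0_series`` (nM) with fixed RNA concentration ``r0`` (nM).
    K_1/2 is started at 0.1x, 1x and 10x the midpoint of the nonzero titrant
    range; the best-SSR solution wins.
    """
    y = np.asarray(bound_fractions, dtype=float)
    p0 = np.asarray(p0_series, dtype=float)
    if len(y) != len(p0):
        raise ValueError("bound_fractions and p0_series lengths differ")
    if len(y) < 3:
        raise ValueError("need at least 3 titration points")
    if (p0 < 0).any():
        raise ValueError("protein concentrations must be nonnegative")
    if r0 <= 0:
        raise ValueError("RNA concentration r0 must be positive")

    def model(p, amplitude, k_half):
        return quadratic_bound(p, amplitude, k_half, r0)

    mid = float(np.median(p0[p0 > 0])) if (p0 > 0).any() else 1.0
    popt, se = _multistart_fit(
        model, p0, y, [0.1 * mid, mid, 10 * mid], ([0.0, 1e-9], [1.5, np.inf])
    )
    return IsothermFit(
        amplitude=float(popt[0]), k_half=float(popt[1]),
        se_amplitude=float(se[0]), se_k_half=float(se[1]),
        model="direct", params={"r0": r0, "p0_series": list(map(float, p0))},
    )


def fit_competition(
    bound_fractions: Sequence[float],
    r1: float,
    r2_series: Sequence[float],
    k1: float,
) -> IsothermFit:
    """Fit amplitude and the competitor's K_1/2 to a competition series.

    ``r1`` is the labelled-substrate concentration (nM), ``k1`` its separately
    measured apparent K_1/2, ``r2_series`` the competitor concentrations.
    """
    y = np.asarray(bound_fractions, dtype=float)
    r2 = np.asarray(r2_series, dtype=float)
    if len(y) != len(r2):
        raise ValueError("bound_fractions and r2_series lengths differ")
    if len(y) < 3:
        raise ValueError("need at least 3 competition points")
    if k1 <= 0:
        raise ValueError("substrate K_1/2 (k1) must be positive")
    if not (y != 0).any():
        raise ValueError("no signal: all bound fractions are zero")

    def model(r, amplitude, k2):
        return competition_bound(r, amplitude, k2, r1, k1)

    mid = float(np.median(r2[r2 > 0])) if (r2 > 0).any() else 1.0
    popt, se = _multistart_fit(
        model, r2, y, [0.1 * mid, mid, 10 * mid], ([0.0, 1e-9], [1.5, np.inf])
    )
    return IsothermFit(
        amplitude=float(popt[0]), k_half=float(popt[1]),
        se_amplitude=float(se[0]), se_k_half=float(se[1]),
        model="competition",
        params={"r1": r1, "k1": k1, "r2_series": list(map(float, r2))},
    )
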