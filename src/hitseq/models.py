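"""Position-weight-matrix (PWM) and pairwise-coupling (PWC) binding models.

Both models are ordinary least squares regressions of ln(K_A,rel) on
indicator features of the sequence.  The cognate (baseline) sequence defines
the reference level: its nucleotide at each position carries coefficient 0,
so a PWM coefficient is the ln-affinity change of substituting that
nucleotide at that position away from the consensus (negative values mean
destabilisation).  The PWC model adds one coefficient per (position pair,
non-baseline nucleotide pair); couplings whose |t| exceeds 3.5 are flagged
significant.  The baseline variant itself is withheld from the fit — its
out-of-fit residual measures how far the consensus lies above the additive
expectation, the hallmark of a distinct cognate binding mode.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .sequences import RNA_BASES, validate_sequence

T_SIGNIFICANCE = 3.5  # |t| threshold for a coupling to be called significant
DEFAULT_FLOOR = 1e-4  # detection floor applied to K_A,rel before the log


def _positional_columns(baseline: str) -> list[tuple[int, str]]:
    return [
        (i, b)
        for i in range(len(baseline))
        for b in RNA_BASES
        if b != baseline[i]
    ]


def _pair_columns(baseline: str) -> list[tuple[int, int, str, str]]:
    cols = []
    for i, j in itertools.combinations(range(len(baseline)), 2):
        for bi in RNA_BASES:
            if bi == baseline[i]:
                continue
            for bj in RNA_BASES:
                if bj == baseline[j]:
                    continue
                cols.append((i, j, bi, bj))
    return cols


def encode_variants(
    kmers, baseline: str, pairwise: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Indicator design matrix under reference (baseline) coding.

    Positional columns ``p{i+1}:{b}`` are 1 when the variant carries
    non-baseline nucleotide b at position i; pairwise columns
    ``p{i+1}{bi}|p{j+1}{bj}`` require both.  The baseline k-mer encodes to the
    all-zero row.
    """
    validate_sequence(baseline, what="baseline")
    kmers = list(kmers)
    n = len(baseline)
    for km in kmers:
        if len(km) != n:
            raise ValueError(f"k-mer {km!r} length differs from baseline {baseline!r}")
        validate_sequence(km, what="k-mer")
    pos_cols = _positional_columns(baseline)
    names = [f"p{i + 1}:{b}" for i, b in pos_cols]
    arr = np.array([[1.0 if km[i] == b else 0.0 for i, b in pos_cols] for km in kmers])
    if pairwise:
        pair_cols = _pair_columns(baseline)
        names += [f"p{i + 1}{bi}|p{j + 1}{bj}" for i, j, bi, bj in pair_cols]
        pair_arr = np.array(
            [
                [
                    1.0 if km[i] == bi and km[j] == bj else 0.0
                    for i, j, bi, bj in pair_cols
                ]
                for km in kmers
            ]
        )
        arr = np.hstack([arr, pair_arr]) if len(kmers) else pair_arr
    return arr, names


def _coef_frame(baseline: str, values: dict[tuple[int, str], float]) -> pd.DataFrame:
    out = pd.DataFrame(
        0.0, index=pd.RangeIndex(len(baseline), name="position"),
        columns=list(RNA_BASES),
    )
    for (i, b), v in values.items():
        out.loc[i, b] = v
    return out


@dataclass
class PWMModel:
    """Fitted additive (per-position) model of ln(K_A,rel)."""

    baseline: str
    coefficients: pd.DataFrame  # position x nucleotide, baseline cells == 0
    se: pd.DataFrame
    t_values: pd.DataFrame
    intercept: float
    r2: float  # on the fitted set (baseline withheld)
    r2_with_baseline: float
    baseline_prediction: float
    baseline_residual: float  # observed - predicted for the withheld cognate
    n_obs: int
    residuals: pd.Series = field(repr=False, default=None)

    def predict(self, kmers) -> pd.Series:
        x, _ = encode_variants(kmers, self.baseline, pairwise=False)
        flat = np.array(
            [self.coefficients.loc[i, b] for i, b in _positional_columns(self.baseline)]
        )
        return pd.Series(self.intercept + x @ flat, index=list(kmers))

    def to_tsv(self, path) -> None:
        rows = []
        for i in range(len(self.baseline)):
            for b in RNA_BASES:
                rows.append(
                    (i + 1, b, self.coefficients.loc[i, b], self.se.loc[i, b],
                     self.t_values.loc[i, b], b == self.baseline[i])
                )
        pd.DataFrame(
            rows, columns=["position", "nucleotide", "coef", "se", "t", "is_baseline"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class PWCModel:
    """PWM plus pairwise nucleotide couplings."""

    baseline: str
    pwm: PWMModel
    interactions: pd.DataFrame  # pos_i, pos_j, base_i, base_j, coef, se, t, significant
    r2: float
    r2_with_baseline: float
    baseline_prediction: float
    baseline_residual: float
    n_obs: int

    @property
    def significance_mask(self) -> pd.Series:
        return self.interactions["significant"]

    def predict(self, kmers) -> pd.Series:
        x, names = encode_variants(kmers, self.baseline, pairwise=True)
        beta = self._beta_vector(names)
        return pd.Series(self.pwm.intercept + x @ beta, index=list(kmers))

    def _beta_vector(self, names: list[str]) -> np.ndarray:
        pos_flat = {
            f"p{i + 1}:{b}": self.pwm.coefficients.loc[i, b]
            for i, b in _positional_columns(self.baseline)
        }
        pair_flat = {
            f"p{r.pos_i + 1}{r.base_i}|p{r.pos_j + 1}{r.base_j}": r.coef
            for r in self.interactions.itertuples()
        }
        return np.array([pos_flat.get(nm, pair_flat.get(nm, 0.0)) for nm in names])

    def heatmap_matrix(self, value: str = "coef") -> pd.DataFrame:
        """(position, base) x (position, base) matrix of coupling values.

        Upper-triangle layout matching coefficient-heatmap figures: rows are
        the first (5'-most) position of a pair, columns the second.
        """
        idx = pd.MultiIndex.from_tuples(
            [(i + 1, b) for i in range(len(self.baseline)) for b in RNA_BASES],
            names=["position", "base"],
        )
        mat = pd.DataFrame(0.0, index=idx, columns=idx)
        for r in self.interactions.itertuples():
            mat.loc[(r.pos_i + 1, r.base_i), (r.pos_j + 1, r.base_j)] = getattr(r, value)
        return mat

    def to_tsv(self, path) -> None:
        out = self.interactions.copy()
        out["pos_i"] += 1
        out["pos_j"] += 1
        out.to_csv(path, sep="\t", index=False)


def _prepare_log_affinity(ka: pd.Series, floor: float | None) -> pd.Series:
    ka = ka.astype(float).dropna()
    if (ka <= 0).any():
        if floor is None:
            raise ValueError(
                "nonpositive K_A,rel values present; pass a positive detection "
                "floor (e.g. floor=1e-4) to clip them before the log transform"
            )
    if floor is not None:
        if floor <= 0:
            raise ValueError("floor must be positive")
        ka = ka.clip(lower=floor)
    return np.log(ka)


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify aliased columns via QR with column pivoting
        from scipy.linalg import qr

        _, r, piv = qr(x, mode="economic", pivoting=True)
        aliased = [names[p] for p in piv[rank:]]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]}); "
            f"aliased columns: {aliased[:10]}"
        )


def _ols(y: np.ndarray, x: np.ndarray, intercept: bool):
    design = sm.add_constant(x, has_constant="add") if intercept else x
    fit = sm.OLS(y, design).fit()
    params = fit.params
    bse = fit.bse
    tvals = fit.tvalues
    # an (effectively) exact fit leaves only rounding error in the residuals;
    # t-statistics are then ratios of numerical noise and carry no information
    if fit.scale < 1e-20 * max(1.0, float(np.mean(y * y))):
        tvals = np.zeros_like(tvals)
    if intercept:
        return float(params[0]), params[1:], bse[1:], tvals[1:], fit
    return 0.0, params, bse, tvals, fit


def _r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        return 0.0  # convention: no variance to explain
    return 1.0 - float(np.sum((observed - predicted) ** 2)) / ss_tot


def fit_pwm(
    table, baseline: str, intercept: bool = True, floor: float | None = DEFAULT_FLOOR
) -> PWMModel:
    """OLS fit of ln(K_A,rel) on per-position nucleotide indicators.

    ``table`` is a variant -> K_A,rel Series (or an AffinityTable / 5-mer
    summary frame with a ``value`` column).  The baseline variant is withheld
    from the fit; its residual is reported separately.
    """
    ka = _as_series(table)
    y_all = _prepare_log_affinity(ka, floor)
    fit_idx = [km for km in y_all.index if km != baseline]
    x, names = encode_variants(fit_idx, baseline, pairwise=False)
    n_params = x.shape[1] + int(intercept)
    if len(fit_idx) <= n_params:
        raise ValueError(
            f"{len(fit_idx)} observations cannot identify {n_params} parameters"
        )
    _check_rank(x, names)
    y = y_all.loc[fit_idx].to_numpy()
    const, params, bse, tvals, fit = _ols(y, x, intercept)

    pos_cols = _positional_columns(baseline)
    coef = _coef_frame(baseline, dict(zip(pos_cols, params)))
    se = _coef_frame(baseline, dict(zip(pos_cols, bse)))
    tv = _coef_frame(baseline, dict(zip(pos_cols, tvals)))

    predicted = const + x @ params
    r2 = _r2(y, predicted)
    base_pred = const  # baseline encodes to the zero row
    if baseline in y_all.index:
        base_obs = float(y_all.loc[baseline])
        obs_full = np.append(y, base_obs)
        pred_full = np.append(predicted, base_pred)
        r2_with = _r2(obs_full, pred_full)
        base_resid = base_obs - base_pred
    else:
        r2_with = r2
        base_resid = math.nan
    return PWMModel(
        baseline=baseline,
        coefficients=coef, se=se, t_values=tv,
        intercept=const, r2=r2, r2_with_baseline=r2_with,
        baseline_prediction=base_pred, baseline_residual=base_resid,
        n_obs=len(fit_idx),
        residuals=pd.Series(y - predicted, index=fit_idx),
    )


def fit_pwc(
    table, baseline: str, intercept: bool = True, floor: float | None = DEFAULT_FLOOR
) -> PWCModel:
    """OLS fit with positional plus pairwise-coupling indicators.

    Couplings with |t| > 3.5 are flagged significant (no multiple-testing
    correction — the bare threshold is the convention for this model family).
    """
    ka = _as_series(table)
    y_all = _prepare_log_affinity(ka, floor)
    fit_idx = [km for km in y_all.index if km != baseline]
    x, names = encode_variants(fit_idx, baseline, pairwise=True)
    n_params = x.shape[1] + int(intercept)
    if len(fit_idx) <= n_params:
        raise ValueError(
            f"{len(fit_idx)} observations cannot identify {n_params} parameters"
        )
    _check_rank(x, names)
    y = y_all.loc[fit_idx].to_numpy()
    const, params, bse, tvals, fit = _ols(y, x, intercept)

    pos_cols = _positional_columns(baseline)
    n_pos = len(pos_cols)
    coef = _coef_frame(baseline, dict(zip(pos_cols, params[:n_pos])))
    se = _coef_frame(baseline, dict(zip(pos_cols, bse[:n_pos])))
    tv = _coef_frame(baseline, dict(zip(pos_cols, tvals[:n_pos])))

    pair_cols = _pair_columns(baseline)
    interactions = pd.DataFrame(
        {
            "pos_i": [i for i, j, bi, bj in pair_cols],
            "pos_j": [j for i, j, bi, bj in pair_cols],
            "base_i": [bi for i, j, bi, bj in pair_cols],
            "base_j": [bj for i, j, bi, bj in pair_cols],
            "coef": params[n_pos:],
            "se": bse[n_pos:],
            "t": tvals[n_pos:],
        }
    )
    interactions["significant"] = interactions["t"].abs() > T_SIGNIFICANCE

    predicted = const + x @ params
    r2 = _r2(y, predicted)
    base_pred = const
    if baseline in y_all.index:
        base_obs = float(y_all.loc[baseline])
        r2_with = _r2(np.append(y, base_obs), np.append(predicted, base_pred))
        base_resid = base_obs - base_pred
    else:
        r2_with = r2
        base_resid = math.nan

    pwm_part = PWMModel(
        baseline=baseline, coefficients=coef, se=se, t_values=tv,
        intercept=const, r2=r2, r2_with_baseline=r2_with,
        baseline_prediction=base_pred, baseline_residual=base_resid,
        n_obs=len(fit_idx),
        residuals=pd.Series(y - predicted, index=fit_idx),
    )
    return PWCModel(
        baseline=baseline, pwm=pwm_part, interactions=interactions,
        r2=r2, r2_with_baseline=r2_with,
        baseline_prediction=base_pred, baseline_residual=base_resid,
        n_obs=len(fit_idx),
    )


def _as_series(table) -> pd.Series:
    from .affinity import AffinityTable

    if isinstance(table, AffinityTable):
        return table.ka
    if isinstance(table, pd.DataFrame):
        if "value" in table.columns:
            return table["value"]
        if "ka_rel" in table.columns:
            return table["ka_rel"]
        raise ValueError("expected a 'value' or 'ka_rel' column")
    return pd.Series(table)


def coefficient_difference(model_a, model_b) -> dict[str, pd.DataFrame]:
    """Elementwise coefficient differences (a - b) between two fitted models.

    Positive values mean the coefficient is larger in ``model_a``.  Models
    must share the baseline sequence (and hence k-mer length).
    """
    if model_a.baseline != model_b.baseline:
        raise ValueError(
            f"baseline mismatch: {model_a.baseline!r} vs {model_b.baseline!r}"
        )
    a_pwm = model_a.pwm if isinstance(model_a, PWCModel) else model_a
    b_pwm = model_b.pwm if isinstance(model_b, PWCModel) else model_b
    out = {"positional": a_pwm.coefficients - b_pwm.coefficients}
    if isinstance(model_a, PWCModel) and isinstance(model_b, PWCModel):
        merged = model_a.interactions.merge(
            model_b.interactions,
            on=["pos_i", "pos_j", "base_i", "base_j"],
            suffixes=("_a", "_b"),
        )
        merged["coef_diff"] = merged["coef_a"] - merged["coef_b"]
        out["interactions"] = merged[
            ["pos_i", "pos_j", "base_i", "base_j", "coef_diff"]
        ]
    return out
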