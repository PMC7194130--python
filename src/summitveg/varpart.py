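"""Variation partitioning of a per-quadrat response into elevation, aspect,
and survey-year fractions.

The total adjusted R² of the full linear model response ~ E + A + Y is split
into seven fractions — three pure effects (the gain in adjusted R² when a
variable is added last) and four shared components obtained by
inclusion–exclusion on the adjusted R² of the seven nested models. Shared
fractions are algebraic differences and may be slightly negative; they are
reported as computed. Pure fractions are testable by residual permutation
under the reduced model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, DomainError, RankDeficiencyError

__all__ = ["VarpartFractions", "adjusted_r2", "varpart3", "permute_fraction", "varpart_table"]


@dataclass(frozen=True)
class VarpartFractions:
    """Seven adjusted-R² fractions plus residual; they sum to the total."""

    pure_E: float
    pure_A: float
    pure_Y: float
    shared_EA: float
    shared_EY: float
    shared_AY: float
    shared_EAY: float
    total: float

    @property
    def residual(self) -> float:
        return 1.0 - self.total

    def as_dict(self) -> dict[str, float]:
        return {
            "pure_E": self.pure_E, "pure_A": self.pure_A, "pure_Y": self.pure_Y,
            "shared_EA": self.shared_EA, "shared_EY": self.shared_EY,
            "shared_AY": self.shared_AY, "shared_EAY": self.shared_EAY,
            "total": self.total, "residual": self.residual,
        }


def _design_columns(predictor, name: str) -> pd.DataFrame:
    """Expand one predictor into numeric design columns (factors → dummies)."""
    s = pd.Series(predictor).reset_index(drop=True)
    if s.dtype.kind in "ifu" and name == "E":
        return pd.DataFrame({name: s.astype(float)})
    if s.dtype.kind in "ifu" and s.nunique() > 8:
        return pd.DataFrame({name: s.astype(float)})
    dummies = pd.get_dummies(s.astype("category"), prefix=name, drop_first=True, dtype=float)
    return dummies


def _build_design(predictors: dict) -> np.ndarray:
    cols = [pd.DataFrame({"Intercept": np.ones(len(next(iter(predictors.values()))))})]
    for name, pred in predictors.items():
        cols.append(_design_columns(pred, name))
    X = pd.concat([c.reset_index(drop=True) for c in cols], axis=1)
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify aliased columns by incremental rank
        aliased = []
        r = 0
        for j in range(arr.shape[1]):
            rj = np.linalg.matrix_rank(arr[:, : j + 1])
            if rj == r:
                aliased.append(X.columns[j])
            r = rj
        raise RankDeficiencyError(f"design is rank deficient; aliased terms: {aliased}")
    return arr


def _adj_r2_from_design(y: np.ndarray, X: np.ndarray) -> float:
    n, p_full = X.shape
    p = p_full - 1  # predictors excluding intercept
    if n <= p + 1:
        raise DegenerateDesignError(f"n = {n} too small for {p} predictors")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise DegenerateDesignError("response is constant")
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def adjusted_r2(response, **predictors) -> float:
    """Adjusted R² of an OLS fit of response on the given predictors.

    Numeric predictors enter as covariates, categorical ones as indicator
    contrasts. Example: ``adjusted_r2(y, E=elev, A=aspect)``.
    """
    y = np.asarray(response, dtype=float)
    if not predictors:
        raise DomainError("at least one predictor required")
    X = _build_design(predictors)
    return _adj_r2_from_design(y, X)


def _check_varies(name: str, values) -> None:
    if len(pd.unique(pd.Series(values))) < 2:
        raise DegenerateDesignError(f"predictor {name} is constant")


def varpart3(response, E, A, Y) -> VarpartFractions:
    """Partition response variation into pure and shared E/A/Y fractions.

    E is elevation (numeric covariate by default, or summit identity if a
    categorical is passed), A the aspect factor, Y the survey-year factor.
    """
    y = np.asarray(response, dtype=float)
    for name, v in (("E", E), ("A", A), ("Y", Y)):
        _check_varies(name, v)

    r = {}
    combos = {
        "E": {"E": E}, "A": {"A": A}, "Y": {"Y": Y},
        "EA": {"E": E, "A": A}, "EY": {"E": E, "Y": Y}, "AY": {"A": A, "Y": Y},
        "EAY": {"E": E, "A": A, "Y": Y},
    }
    for key, preds in combos.items():
        r[key] = _adj_r2_from_design(y, _build_design(preds))

    pure_E = r["EAY"] - r["AY"]
    pure_A = r["EAY"] - r["EY"]
    pure_Y = r["EAY"] - r["EA"]
    shared_EA = r["EY"] + r["AY"] - r["EAY"] - r["Y"]
    shared_EY = r["EA"] + r["AY"] - r["EAY"] - r["A"]
    shared_AY = r["EA"] + r["EY"] - r["EAY"] - r["E"]
    shared_EAY = r["EAY"] - pure_E - pure_A - pure_Y - shared_EA - shared_EY - shared_AY
    return VarpartFractions(
        pure_E, pure_A, pure_Y, shared_EA, shared_EY, shared_AY, shared_EAY, r["EAY"]
    )


_PURE_TO_REDUCED = {"pure_E": ("A", "Y"), "pure_A": ("E", "Y"), "pure_Y": ("E", "A")}


def permute_fraction(
    response, E, A, Y, fraction: str = "pure_E", n_perm: int = 999, seed: int = 0
) -> dict:
    """Permutation p-value for one pure fraction.

    Residuals of the reduced model (omitting the tested variable) are
    permuted and added back to the reduced-model fit (Freedman–Lane); the
    partial pseudo-F of the tested variable is recomputed per permutation,
    and p = (1 + #{perm ≥ observed}) / (n_perm + 1). The pseudo-F is the
    permutation statistic because it is pivotal under this scheme — the
    adjusted-R² gain itself is not exchangeable across permutations (the
    reduced-model refit absorbs part of each permuted residual vector, which
    makes its permutation distribution conservative).
    """
    if fraction not in _PURE_TO_REDUCED:
        raise DomainError(
            f"only pure fractions are testable (shared fractions are obtained by "
            f"subtraction); got {fraction!r}"
        )
    y = np.asarray(response, dtype=float)
    named = {"E": E, "A": A, "Y": Y}
    for name, v in named.items():
        _check_varies(name, v)
    reduced_names = _PURE_TO_REDUCED[fraction]
    X_red = _build_design({k: named[k] for k in reduced_names})
    X_full = _build_design(named)
    n = len(y)
    p_red, p_full = X_red.shape[1] - 1, X_full.shape[1] - 1
    if n <= p_full + 1:
        raise DegenerateDesignError(f"n = {n} too small for {p_full} predictors")

    # orthonormal bases let us evaluate both models on many responses at once
    Q_red, _ = np.linalg.qr(X_red)
    Q_full, _ = np.linalg.qr(X_full)

    def partial_f(Ymat: np.ndarray) -> np.ndarray:
        ss = (Ymat**2).sum(axis=0)
        ssr_red = ss - ((Q_red.T @ Ymat) ** 2).sum(axis=0)
        ssr_full = ss - ((Q_full.T @ Ymat) ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return ((ssr_red - ssr_full) / (p_full - p_red)) / (ssr_full / (n - p_full - 1))

    observed_fraction = float(varpart3(y, E, A, Y).as_dict()[fraction])
    observed_f = float(partial_f(y[:, None])[0])
    if n_perm <= 0:
        return {"fraction": fraction, "observed": observed_fraction,
                "statistic": observed_f, "p_value": 1.0, "n_perm": 0}

    beta, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    fitted = X_red @ beta
    resid = y - fitted
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)], axis=1)
    Ystar = fitted[:, None] + resid[perms]
    stats_perm = partial_f(Ystar)
    p = (1 + int(np.count_nonzero(stats_perm >= observed_f - 1e-12))) / (n_perm + 1)
    return {"fraction": fraction, "observed": observed_fraction,
            "statistic": observed_f, "p_value": float(p), "n_perm": n_perm}


def varpart_table(responses: dict, E, A, Y, n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Table-layout output: one row per response, fraction columns, and
    permutation p-values for the three pure fractions."""
    rows = []
    for i, (name, y) in enumerate(responses.items()):
        fr = varpart3(y, E, A, Y)
        row = {"response": name, **fr.as_dict()}
        for j, frac in enumerate(("pure_E", "pure_A", "pure_Y")):
            row[f"p_{frac}"] = permute_fraction(
                y, E, A, Y, fraction=frac, n_perm=n_perm, seed=seed + 31 * i + j
            )["p_value"]
        rows.append(row)
    return pd.DataFrame(rows)
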